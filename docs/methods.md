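# Methods

## Polygenic model

Log relative risk is the sum of many small independent allele effects,
so relative risk *RR* is modelled log-normal(μ, σ²) with μ = −σ²/2,
giving E[*RR*] = 1 at birth. Per-locus variance contributions are
2p(1−p)[ln OR]² (Hardy–Weinberg, log-additive interaction, loci
independent — no linkage-disequilibrium adjustment). Per-allele odds
ratios are treated as relative risks on the log scale; for per-year
incidences of order 10⁻³–10⁻² the distinction is negligible.

The shipped panels carry only identifier, locus label, allele
frequency and odds ratio; per-locus variances are always recomputed.
Published per-locus variance tables for these panels contain several
cells inconsistent with their own frequency/odds-ratio pairs, and
column totals that do not match the headline variances; recomputation
gives totals of 0.389 (prostate, 31 loci) and 0.138 (breast, 18 loci).
The package reports recomputed values and does not attempt to
reverse-engineer the published cells. The X-linked prostate locus
rs5945619 is treated like an autosomal locus by default; the
`x_linked_hemizygous` flag switches it to the single-allele form
p(1−p)[ln OR]² appropriate for hemizygous males.

Cases are size-biased: the case density equals r·f_pop(r) (E[RR] = 1),
which for the log-normal is the population density shifted right by σ²
on the log scale. This shift is exact for incident cases drawn from an
undepleted population ("young ages") and the package, following the
modelling tradition it implements, applies it at **all** ages; see
*Limitations*.

## Absolute risk

Hazards are piecewise constant over one-year bands [a, a+1):
λ_c(a) = cases / person-years and λ_o(a) = (all-cause deaths − cancer
deaths) / person-years. No person-year correction is made for time
lived after a cancer diagnosis; at the rates involved this is a
first-order approximation. Within a band the competing-exponential
decomposition λ/(λ+δ)·(1−e^−(λ+δ)) allocates the first event, and
survival multiplies across bands. The polygenic relative risk scales
cancer incidence only. Windows must lie inside the table; no
extrapolation. Risk-curve evaluation truncates the window at the table
end and records the truncated end age.

## Screening comparison

Personalised eligibility at age a and threshold t is RR ≥ r*(a), where
r*(a) solves A(a, a+window | r) = t by Brent root-finding on
r ∈ [10⁻⁶, 10³] (xtol 10⁻¹³, keeping |A(r*) − t| ≲ 10⁻¹⁰). Thresholds
met at the bottom (top) of the range are flagged always-eligible
(never-eligible), contributing band fractions 1 (0). Eligible and
detectable-case fractions weight the log-normal tail fractions above
r*(a) by observed band population N(a) and observed case counts C(a);
eligibility is evaluated at integer ages, without within-band
interpolation. Reclassification tables scale to 100,000 population of
the age range; rounding to integer counts happens only at
presentation. "Potentially screen-detectable" means a case arising in
the eligible subgroup; no screening-sensitivity model is applied.

Matched thresholds are found by Brent's method on the monotone
eligible (or detectable-case) fraction, to 10⁻⁶ on the matched
fraction. With σ² = 0 the fraction is a step function of t, so a
target can be unattainable even inside the bracket; this is reported
as an error naming the nearest attainable fraction. The
variance-fraction sweep builds models with σ² = f·σ²_total, matches on
detected cases, and reports the relative reduction in eligible
population; it is non-decreasing in f.

## Synthetic rate tables

Real national registration extracts are not shipped. The generator
emulates their qualitative shape:

- **Incidence** λ_c(a) = k·e^(g·min(a, plateau)). Prostate-like:
  g = 0.11, plateau 75, ages 35–89. Breast-like: g = 0.08, plateau 55,
  ages 25–89. Slopes and plateaus were chosen once to mimic the steep
  mid-life rise (and late flattening) of the respective registries.
- **Calibration**: k is root-found so the ten-year absolute risk hits
  the anchor — 2% at age 55 (prostate), 2.5% at age 47 (breast) — to
  10⁻¹⁰ on continuous hazards; integer rounding of counts perturbs the
  realised anchor by ≲ 10⁻⁵.
- **Other-cause mortality**: Gompertz m₀·e^(0.0975·a) with m₀ =
  1.5×10⁻⁵ (men) and 1.0×10⁻⁵ (women), giving realistic all-cause
  hazards (~2×10⁻³ at 50, ~3×10⁻² at 80 for men).
- **Population**: a flat 100,000 person-years per band. Counts are
  hazards × person-years, rounded; cancer deaths are fixed at 0.2 of
  cases (they only enter the λ_o subtraction).

Generation is deterministic; the recorded seed (default 20110405)
exists for provenance and interface symmetry with the simulator.
Because the synthetic age structure is flat, *absolute* eligible
fractions differ from those of a real population pyramid (which thins
with age); the package's comparative statements (orderings, deficits,
matched thresholds) are the quantities the fixtures are designed to
support.

## Cohort micro-simulation

`simulate_cohort` draws each subject's RR once, then walks age bands
drawing competing exponential events with hazards (RR·λ_c, λ_o) — the
exact data-generating process behind the closed-form absolute risk, so
the two agree up to binomial noise at any fixed RR. The longitudinal
cohort, however, *depletes* high-risk subjects as they are diagnosed,
whereas the closed-form case distribution is age-invariant by
assumption; simulated case RR distributions therefore sit measurably
below the σ²-shifted form at old ages (the log-mean gap is roughly
σ² × cumulative incidence). Validation respects this: absolute risks
are checked against longitudinal cohorts at fixed RR; the σ² shift is
checked on cases diagnosed young (< 55), where depletion is
negligible; case tail fractions and detectable-case fractions are
checked against size-bias-weighted log-normal draws; and
`simulate_cross_section` (fresh population per band — the model's own
assumption) provides an end-to-end per-band case oracle. Validation
sizes: 10⁶ draws, 10⁶ (baseline) and 5×10⁵ (elevated-risk) cohort
subjects, 23 closed-form/simulation comparisons at three standard
errors each.

## Limitations

- Depletion of susceptibles is ignored in the closed forms (inherited
  modelling simplification; see above).
- No linkage disequilibrium between loci; odds ratios treated as
  relative risks.
- No screening-test sensitivity, overdiagnosis, mortality benefit or
  cost modelling; "detectable" counts cases in the eligible group only.
- Synthetic rates reproduce anchors and shape, not any real
  population's level or age structure; conclusions drawn from the
  fixtures are structural/comparative, not numerical forecasts.
- Genotype-level scoring of individuals is out of scope; the model
  works entirely at the distribution level.
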