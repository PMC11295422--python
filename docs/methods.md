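# Methods

## Problem setting

In model-based patient selection for proton therapy, each patient has two
treatment plans — a photon (VMAT) plan and a proton (IMPT) plan — and the
decision is made on predicted toxicity, not dose: NTCP models map each plan's
organ-at-risk (OAR) dose metrics to per-endpoint complication probabilities,
and the patient qualifies when ΔNTCP = NTCP_photon − NTCP_proton reaches the
protocol threshold for at least one endpoint (NIPP: ≥ 0.10 for grade ≥ 2
endpoints, ≥ 0.05 for grade ≥ 3; both thresholds inclusive and configurable).
`ntcpselect` consumes the *output* of treatment planning — cumulative DVHs —
and implements everything downstream: metrics, NTCP evaluation, qualification
and cohort statistics. Planning itself (beam arrangement, robust
optimization, dose calculation) is out of scope.

## DVH conventions

A cumulative DVH is stored as strictly increasing dose edges (Gy, starting at
0) with non-increasing volume *fractions* (starting at 1). Absolute structure
volume is metadata only; every implemented model uses whole-structure
Dmean or gEUD, so fractions suffice and avoid unit drift.

* **Interpolation** is linear on the cumulative curve. Dx (dose at volume
  fraction x) returns the lowest dose where the interpolated volume equals x,
  which makes plateaus deterministic; a request below the curve's minimum
  reachable volume returns the last dose edge with a warning, because coarse
  exports often truncate tails. Planning systems do not publish a common
  convention; on coarse bins, values may differ from a TPS at the sub-0.1 Gy
  level.
* **Dmean** is the trapezoid integral of the cumulative curve — identical to
  the midpoint rule on differential bins whenever the curve reaches zero
  volume. For truncated curves the residual volume beyond the last edge is
  not extrapolated, so Dmean and gEUD(a = 1) can then differ by
  V_end × d_end; the synthetic generator always emits curves reaching zero.
* **gEUD** is the power mean (∫ D^a dV)^(1/a) computed with an exact per-bin
  integral of D^a under the same piecewise-linear reading of the cumulative
  curve that Dmean uses. This agrees with the common discrete midpoint
  formula at a = 1 and in the fine-bin limit, but unlike the midpoint formula
  it is self-consistent with the interpolation convention and converges
  under grid refinement, which is what the oracle tests check. For a < 0 the
  quantity is undefined when any occupied bin touches 0 Gy (the integral
  diverges for a ≤ −1); `geud_from_bins` retains the discrete point-mass
  formula for users with pre-binned data.
* **Dose axis** is assumed RBE-weighted (planning systems export
  RBE-weighted proton dose, conventionally physical dose × 1.1). An optional
  `rbe_factor` (default 1.0) rescales curves for physical-dose exports.
* **Coverage**: D95 > 0.98 × prescription (strict) and D2 < 1.07 ×
  prescription (strict), per common SIB head-and-neck clinical goals.

## NTCP models

Two forms cover the registry:

* `logistic_linear`: NTCP = 1/(1 + exp(−S)), S = β₀ + Σ βᵢ xᵢ, where each
  covariate is either a dose metric addressed as `structure.metric`
  (metric ∈ {dmean, geud, d2, d1, dmax}) or a clinical covariate resolved
  from the patient's covariate vector.
* `lkb_probit` (Lyman–Kutcher–Burman): NTCP = Φ((gEUD − TD50)/(m·TD50)),
  with TD50 the 50 %-complication uniform dose (Gy), m the relative slope,
  and a the gEUD volume exponent; Φ is evaluated through the error function
  (`scipy.special.ndtr`), reproducible to 1e-12 across platforms.

Coefficients are **configuration**: published models belong to their authors
and are frequently revised, so the package validates and evaluates whatever
registry it is given (JSON; unknown fields rejected; duplicate names
rejected; per-form requirements enforced). The shipped registry of 7 entries
(swallowing dysfunction, dysgeusia ×2, hearing loss, tinnitus, acute oral
mucositis, trismus) uses *illustrative* placeholder values — literature-
plausible in form and magnitude (e.g. the swallowing model is a two-term
logistic on pharyngeal-constrictor and supraglottic-larynx mean dose) and
chosen to produce realistic NTCP ranges on the default synthetic cohort, but
not transcribed from any validated publication; each entry's
`source_citation` says so. The hearing-loss entry, mirroring common practice
where the only proton-derived model in a set is applied to both techniques,
is evaluated identically on photon and proton plans.

Missing structures are a hard error by default; with `allow_missing` the
(patient, model) pair is excluded from *both* techniques with a warning, so
ΔNTCP never mixes a defined with an undefined value (silent zeros would bias
qualification).

## Qualification and cohort summaries

An endpoint qualifies iff ΔNTCP ≥ threshold(grade class), inclusive; a
patient qualifies iff any endpoint does (inclusive "and/or"); qualification
is therefore monotone in every ΔNTCP. Cohort summaries report the number and
percentage of qualified patients (percentages rounded half-up to integers,
matching clinical-report style), per-endpoint totals and the exact
endpoint-combination breakdown.

Δdose tables report both the average and the median of per-patient
photon−proton differences *and* the difference of column statistics: for
means the two coincide (linearity), for medians they generally do not, and
published tables are often ambiguous about which was used — both are emitted
with explicit labels.

## Wilcoxon signed-rank test

Conventions: differences x − y, zeros dropped before ranking (`n_effective`
reported — contralateral-organ comparisons can contain exact zeros), midranks
for tied |d|, statistic W = min(W⁺, W⁻). For n_effective ≤ 25 the two-sided
p-value is permutation-exact: the full null distribution of W⁺ over all 2ⁿ
sign assignments is built by dynamic programming over doubled midranks
(midranks are half-integers), and p = P(W⁺ ≤ w) + P(W⁺ ≥ Σr − w), capped at
1. This is identical to brute-force enumeration, with or without ties.
Beyond 25 a normal approximation is used with the tie-corrected variance
Σrᵢ²/4 and a 0.5 continuity correction — a 37-patient cohort takes this path,
and its empirical type-I error at α = 0.05 is verified in the tests to sit
inside the binomial 99 % CI over 2,000 null cohorts. No multiple-testing
correction is applied (per-endpoint raw p-values are the convention in plan
comparison studies); reports footnote the number of tests.

## Synthetic cohort generator

The generator's job is *structural realism* — producing paired cohorts on
which the pipeline's qualitative behavior matches what planning studies
report — not the recreation of any real patient. Defaults emulate a
37-patient parotid-gland VMAT-vs-IMPT cohort:

* **Per-OAR mean-dose profiles** (photon/proton, Gy): oral cavity
  18.17/5.40, larynx 11.56/7.26, pharyngeal constrictors 27.64/17.34,
  contralateral parotid 6.65/0.00, contralateral submandibular gland
  8.31/0.03, supraglottic larynx 16.05/9.44, ipsilateral cochlea
  33.20/29.53, ipsilateral inner ear 29.45/25.18, plus an ipsilateral
  masseter (26/22) feeding the trismus model.
* **Between-patient variation**: bivariate normal per structure on the
  mean-dose scale with SD = 30 % of the photon mean (the proton SD scales by
  the proton/photon mean ratio, sharing the relative spread) and
  photon–proton correlation 0.6, clipped at 0 Gy. Published cohort tables
  give only means and medians, so the SD and correlation are free
  parameters; 30 %/0.6 yields realistic overlap between techniques and
  significant paired tests for the organs with large configured gaps.
  Clipping (rather than rejection) at zero intentionally creates the point
  mass at 0 Gy that contralateral organs show under protons.
* **Intra-structure heterogeneity**: a truncated normal with relative SD 0.2
  (jittered ±20 % per draw), discretized into 100 bins and cumulated; the
  dose axis is rescaled so the realized Dmean matches the sampled target
  exactly. Any unimodal shape would serve; the normal is the simplest family
  with a controllable mean.
* **Targets**: prescription-level combinations are sampled from a 9-entry
  menu (HD-CTV 60–70 Gy, optional ID/LD levels; median HD-CTV 66 Gy) with
  the study's frequencies as weights. CTV curves are near-step: mean 1.01 ×
  prescription, relative SD 1 %, which guarantees D95 > 98 % and D2 < 107 %
  with margin; the generator asserts the coverage report on every curve.
* **Laterality** is sampled 50/50 and used only for naming — the pipeline is
  DVH-level and has no geometry.

What the generator does **not** emulate: anatomical correlation between
organs (structures are sampled independently), realistic DVH shoulder/tail
shapes from actual planning, robustness scenarios, or clinical covariates.
Tests passing on synthetic cohorts therefore demonstrate the correctness of
the *pipeline arithmetic and statistics* under a plausible dose structure,
not the clinical validity of any NTCP model on real patients.

## Numerical choices

* Validation tolerance on curve invariants: 1e-9 (origin, monotonicity,
  bounds); differential round-trip exact to 1e-12.
* Dx at plateaus: lowest qualifying dose; Dmax: first dose where V reaches 0.
* Exact-test threshold n ≤ 25; above, normal approximation (a tied sample at
  small n still gets the permutation-exact p, since the DP handles
  midranks).
* Report serialization: 9 significant digits (round-trips below all
  tolerances); deterministic row ordering everywhere; no timestamps in data
  files.
* Problem sizes in the test suite — 1,000 random curves for the metric
  oracle sweep, 2,000 null cohorts for the calibration check, full 2ⁿ
  enumeration up to n = 12 — keep each check well-resolved while the whole
  suite runs in seconds.

## Known limitations

* The shipped registry is illustrative; conclusions about any real cohort
  require transcribing validated published coefficients (and then apply only
  within those models' populations — most head-and-neck NTCP models were
  developed on photon cohorts and other tumor subsites).
* NTCP models are applied to the supplied dose directly; no EQD2/BED
  conversion is performed.
* Equal-structure coverage between plans is required (or explicitly skipped
  with `allow_missing`); there is no imputation.
* The Wilcoxon implementation offers only the two-sided alternative, the one
  used in paired plan-comparison reporting.
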