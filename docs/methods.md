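# Methods

This note records the models, statistical procedures and numerical
choices behind `circaturn`, and what the synthetic-data checks do and
do not establish about real data.

## Kinetic model and the coupled-rhythm identity

Each protein follows a linear production–decay equation with
periodically modulated rates:

    s(t) = s0 · (1 + A_s · cos(2π(t − φ_s)/T))
    k(t) = k0 · (1 + A_k · cos(2π(t − φ_k)/T))
    dP/dt = s(t) − k(t) · P(t)

with `s0` the basal synthesis rate (intensity · h⁻¹), `k0` the basal
degradation rate (h⁻¹), relative amplitudes `A` in [0, 1) so rates stay
positive, phases in hours, and period `T` = 24 h. When `A_s = A_k` with
equal phases, `P ≡ s0/k0` solves the equation identically: coupled
rhythms cancel in abundance while turnover oscillates. This analytic
identity is the model's scientific core and is asserted exactly
(constant to < 1e-4 relative in the solved trajectories; the
quasi-steady initial condition `s/k = s0/k0` is the exact periodic
solution in this case, so no transient exists).

For a labelling window `[t0, t0+Δ]` the heavy (newly synthesised)
signal is the nascent protein **surviving to the window end**,

    H = ∫ s(u) · exp(−∫ᵤ^{t0+Δ} k(v) dv) du ,

i.e. `dH/dt = s − kH` from `H(t0) = 0`; total is `P(t0+Δ)`; light is
their difference. Including nascent degradation matters: quality
control degrades an appreciable share of new protein within the hour.
A flag (`include_nascent_degradation=False`) switches to the naive
`∫s dt` reading for didactic comparison.

Numerics: fixed-step RK4 vectorized over proteins, default step 0.05 h
(steps above 0.05 h are refused; halving the step changes window
quantities by < 1e-6 relative). Burn-in from the quasi-steady state is
min(10/k0, 500) h, suppressing initial transients by e⁻¹⁰ in the
regimes the tests use. With `A_k = 0` the solution has the textbook
sinusoidal steady state for a first-order system under sinusoidal
forcing; the solver matches it to ~1e-5 relative.

Timepoints are recorded at the labelling-window **midpoint**, the
convention used when aligning window-integrated measurements with a
continuous phase reference.

## Synthetic evidence: what it emulates, what it does not

`emit_evidence` turns kinetic amounts into a MaxQuant-style evidence
table: 3–8 peptides per protein with lognormal response factors
(σ = 0.5); per-cell multiplicative lognormal noise at a stated CV
(unit mean; default 10%, a typical reporter-ion precision); a fraction
of cells missing at random (default 2%); a fraction of peptide entries
split across two evidence rows with conserved channel sums (exercising
the collapsing step); fully heavy booster channels; and
contaminant/reverse decoy rows. Default kinetics: `k0` lognormal around
0.02 h⁻¹ (≈ 35-h half-life — mammalian proteins average half-lives of
days), `s0` lognormal, synthesis amplitude `A_s = 1/3` (peak/trough
fold change 2) for rhythmic classes, peak phases on the sampled
circadian grid (a `phases_on_grid=False` option draws them uniformly).
Proteins of the `abundance_rhythmic` class draw `k0` around 0.2 h⁻¹:
a degradation-driven abundance rhythm requires a short half-life,
because a first-order system attenuates rate modulations by
k0/√(k0² + ω²).

Deliberately **not** simulated: co-isolation interference and reporter
ratio compression, peptide-specific missingness (missingness is
MCAR here, while real MS missingness is intensity-dependent),
chromatographic or search-engine artefacts, shared/razor-peptide
ambiguity (each synthetic peptide belongs to one protein), and
between-channel loading imbalance. Passing the recovery tests
therefore shows the *pipeline logic* is correct under the stated noise
model, not that real-data peculiarities are handled; the pipeline's
normalization and filtering stages exist for exactly those real-data
effects.

Because the generator simulates equal loading, the noiseless
round-trip check runs with sample-loading normalization disabled:
estimated per-channel factors would otherwise introduce exactly the
correction the data do not need, breaking strict per-channel
proportionality.

## Rhythm detectors

**Umbrella test.** Observations are folded modulo the period into g ≥ 3
phase groups. The alternative is an umbrella ordering: means rise from
a trough group to a peak group and fall back, wrapping around the
cycle. For each candidate (peak, trough) pair the statistic sums
Mann–Whitney pair counts along the rising arm (trough → peak, forward)
and the falling arm (trough → peak, backward); the shared endpoint
pair carries weight 2. The candidate p-value is the upper tail of this
statistic under the permutation null:

- exact, by full enumeration of label arrangements, when the series has
  ≤ 12 observations (tie-free distributions are cached by group-size
  signature; tied data are enumerated directly against the observed
  values with the ½-tie convention);
- otherwise a normal approximation whose variance is the *exact*
  permutation variance of the weighted pair-count sum, assembled from
  indicator covariances (±1/12 for index pairs sharing one point,
  orientation-dependent). With ties this tie-free variance slightly
  overestimates, making the approximation conservative.

The reported p is the Bonferroni-corrected minimum over all g(g−1)
candidates; the reported phase is the winning peak group's circadian
time (ties break to the earliest phase). A constant series returns
p = 1. An earlier design combined per-arm p-values by Fisher's method;
because the two arms share their endpoint groups, that combination is
anticonservative (≈ 13% type-I at α = 0.05 in simulation) and was
replaced by the summed statistic (≈ 2% measured, with ~98% power at
fold change 2 and CV 10%). A `mode="longitudinal"` variant ranks
within replicate series only and sums the statistic across replicates
(exact null by convolution of per-replicate distributions), for
designs where replicate cultures are separate longitudinal series;
the default pools replicates within phase groups.

Being rank-based, the test is invariant under strictly monotone
transforms of the values.

**ANOVA.** One-way fixed-effects ANOVA on natural-log values across
circadian phase groups, with the two sampling days pooled as
replicates (each group needs ≥ 2 observations). The log base is
irrelevant to F and p; a common multiplicative factor cancels. Values
must be strictly positive.

**Damped cosine vs line.** The model is
`y = (mx + c) + a·e^{kx}·cos((2πx − r)/p)` with the period fixed (24 h
default, 25 h selectable), fitted by bounded least squares
(a ≥ 0, |k| ≤ 0.1 h⁻¹). The phase argument is implemented exactly as
written (peak at x = r/2π); a `convention="conventional"` flag uses
`cos(2π(x − r)/p)` (peak at x = r). The reported `peak_time_h` is the
argmax of the fitted oscillatory component over one period —
convention-independent, and shifted from the undamped peak by
atan(k/ω)/ω when k ≠ 0. The fit profiles the linear parameters
(m, c, a) over an 8-point phase grid × 7-point damping grid — the
(k, r) surface is multimodal — then polishes the best three starts
with `scipy.optimize.least_squares`; RSS ties break to the smallest
|k|. The line (null) and cosine (alternative) fits are compared by the
extra-sum-of-squares F test on (df₀ − df₁, df₁) = (3, n − 5) degrees
of freedom, cosine preferred at p < 0.05. The damping bound of
0.1 h⁻¹ is deliberately tight: circadian rhythms in confluent cultures
damp over days, and looser bounds let the exponential envelope chase
noise, inflating the F test's type-I error beyond its ≈5–6% measured
level (multi-start optimism accounts for the small residual excess
over the nominal 5%).

**Fold change.** Per sampling day (floor(t/period)), replicate
observations are averaged per timepoint and the day's fold change is
max/min of those means; days are then averaged. Always ≥ 1; undefined
(NaN, with a warning) when a trough is non-positive. At 6-h sampling
with the peak on the grid, a noiseless cosine of relative amplitude A
returns (1+A)/(1−A) exactly; window-integrated signals are attenuated
by the window average (factor sinc(πΔ/T) ≈ 0.90 for Δ = 6 h), which is
why a fold-change-2 synthesis rhythm reads as ≈ 1.8.

## Classification and multiple testing

Categories use strict inequality (p < α, α = 0.05 by default; boundary
ties are not rhythmic) and are computed separately per detector, never
mixed. The Fisher overlap test uses the standard two-sided convention
(sum of hypergeometric probabilities ≤ the observed table's, with a
1 + 1e-7 relative tolerance for probability ties); degenerate margins
return p = 1. The Mann–Whitney fold-change comparison uses the exact
distribution when n₁ + n₂ ≤ 20 without ties, otherwise the normal
approximation with tie and continuity corrections. Benjamini–Hochberg
q-values are emitted per metric alongside the raw p-values but the
classification itself uses raw p < 0.05.

## Complex coordination

Relative turnover per protein is the heavy/total ratio averaged over
timepoints (replicate channels averaged within a timepoint first —
mean of ratios, not ratio of means). Complexes with more than four
*detected* subunits contribute a sample SD (n−1 denominator) of their
members' turnover; a flag allows counting annotated subunits instead.
The null preserves the number of complexes and every subunit count:
pseudo-complex draws are without replacement within a complex (a real
complex never lists a protein twice) and with replacement across
complexes and iterations. Two p-values are reported: a one-sided
Mann–Whitney p that observed SDs are stochastically smaller than the
pooled null SDs (powerful, but conservative under the null because
null draws share the finite pool), and an empirical p comparing the
observed median SD with per-iteration null medians,
(1 + #{null ≤ obs})/(1 + iterations), which is uniform by
exchangeability when there is no coordination and is the value used
for calibration checks.

## Bulk-label calculators

All four are scale-invariant ratios. Negative degradation percentages
are returned as-is with a warning — they diagnose normalization
problems rather than being clipped. The heavy-UMP natural-abundance
correction subtracts the control fraction and floors at zero; at the
~1e-5 natural abundance of ¹⁵N₂ the renormalized variant
(f − f₀)/(1 − f₀) is numerically indistinguishable and is provided
behind a flag.

## Pipeline conventions and degenerate inputs

Zero reporter intensities are valid data; only empty cells are
missing, and a collapsed cell is missing only when every contributor
is missing. Exclusion for missingness happens after collapsing.
Leading-protein conflicts within a (sequence, state) group resolve to
the modal accession (ties: lexicographically smallest) and are
counted. The normalization target is the mean of non-booster channel
sums — any common target is equivalent up to a global factor, so the
scale-invariance property holds modulo that factor. Booster channels
are carried through I/O and normalization but excluded from the
normalization target, all time series, and all statistics. Proteins
without a detected heavy peptide are excluded from the analysis set;
with the pair filter enabled this is automatic, and the filter can be
disabled to reproduce the booster-assisted workflow where light
partners are not required. p-values are floored at 1e-300 rather than
reported as 0.

## Problem sizes in the verification suite

The checks run at desk scale chosen to make their Monte-Carlo error
small relative to the margins being tested: 2000 null series for
umbrella calibration, 1000 for the cosine-F calibration, 150 + 150
proteins for power/recovery at fold change 2 and CV 10%, 100 runs per
arm of the coordination study (20 complexes of 5–10 subunits from a
300-protein pool, 199 resampling iterations), all 2×2 tables with
margins ≤ 12 for the Fisher oracle, and a C(8,5) exhaustive
enumeration for the resampling-null expectation. Known limitations:
the umbrella test's Bonferroni correction over correlated candidates
makes it conservative (measured ≈ 2% at nominal 5%), tied data in the
large-sample branch use a slightly conservative variance, and the
cosine F test retains a small multi-start optimism.
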