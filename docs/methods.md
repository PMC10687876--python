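# Methods

## Model and estimators

The package analyzes half-reaction sampling in the energy-gap coordinate.
Two independent ensembles are assumed, one per charge state, with the
vertical gap ΔE = E(oxidized) − E(reduced) evaluated at fixed nuclei in
both. All energies are in eV, temperatures in K (k_B = 8.617333262×10⁻⁵
eV/K, CODATA), times in ps.

Mean-based estimators (exact within linear response):
ΔA = (⟨ΔE⟩_R + ⟨ΔE⟩_O)/2 and λ = (⟨ΔE⟩_R − ⟨ΔE⟩_O)/2. These are pure
arithmetic on the two ensemble averages; by construction ΔA + λ and ΔA − λ
reconstruct the inputs to machine precision. A negative λ is reported with
a warning rather than an error: it can only arise from unconverged or
mislabeled sampling and must be surfaced.

Variance-based reorganization energies: λ_i = β σ_i²/2 per state, with σ
the n−1 sample standard deviation (at n = 1000 the n vs n−1 distinction is
far below print precision; the choice is documented because conventions
differ).

Uncertainty convention: the headline ± on both ΔA and λ is
½·sqrt(σ_R² + σ_O²) — the distribution-width convention used in the tables
this package reproduces. It measures the width of the sampled distributions,
not the statistical error of the mean; the latter is estimated separately by
Flyvbjerg–Petersen blocking (repeated pairwise averaging; the plateau is
taken as the maximum naive SEM over block levels retaining ≥ 16 blocks) and
carried in every moments record.

## Free-energy curves

Curves are built on the shifted axis ΔE_μ = ΔE − ΔA (fictitious-electrode
chemical potential chosen so the driving force is zero). From a normalized
histogram, A(bin) = −k_BT ln P(bin) with per-bin probability mass; since
both state distributions are normalized on the same grid, the exact
relation A_O(ΔE_μ) = A_R(ΔE_μ) + ΔE_μ holds with *no* adjustable constant,
which fixes the sign convention (the two Marcus parabolas (x∓λ)²/4λ map
onto each other under ±x). Each state's combined curve prefers the direct
histogram wherever bin occupancy reaches `min_count` (default 10) and falls
back to the LFER extension from the partner state elsewhere; empty or
under-occupied bins are undefined, never zero — no pseudo-counts are ever
added. Combined curves are reported min-shifted to zero (the constant is
unobservable); the direct and LFER branches are additionally reported at
absolute placement so the two construction routes can be compared bin by
bin. Binning defaults to Freedman–Diaconis on the pooled shifted samples
and is overridable; parabola fits are unweighted least squares over the
combined curves' defined bins, reporting vertex, quadratic coefficient
(= 1/4λ in the Marcus picture) and rms residual.

A geometric fact worth stating: at λ ≈ 1 eV and 300 K the two gap
distributions sit ~9σ apart, so their histograms share no populated bins at
any realistic sample size — this is exactly why the LFER extension is
needed to draw both branches of each parabola. Bin-by-bin agreement between
the direct and LFER routes is therefore verified in a populated-overlap
regime (small λ), while the λ ≈ 1 eV regime is verified through vertex
positions (±λ), curvatures (1/4λ) and single-parabola residuals.

## Gaussianity and the Marcus verdict

Skewness and excess kurtosis use biased standardized central moments; the
omnibus normality statistic is the D'Agostino–Pearson K² assembled from the
stored moments (D'Agostino 1970 skewness transform, Anscombe–Glynn 1983
kurtosis transform), which equals the classical test on raw data and keeps
the diagnostic computable from summary statistics. The verdict is
deterministic: `marcus_consistent` iff |skew| < 0.5, |excess kurtosis| < 1.0
for both states and |σ_R − σ_O| < 0.05 eV (all configurable); exceedances
within 2× threshold are `borderline`, beyond that `non_marcus`. The numeric
thresholds operationalize the qualitative Marcus premise — Gaussian gap
distributions of equal width — and are deliberately conservative.

## Quadratic-model (beyond-Marcus) correction

Unequal state variances are modeled minimally: one Gaussian solvent mode q
with gap ΔE = ΔI + a·q + b·q². Both state Hamiltonians are then harmonic in
q with different force constants, so the exact free-energy difference has a
closed form. The correction is that exact value minus the mean-based
estimate; the two effective parameters are fixed by (λ_R, λ_O) alone, so
the correction needs nothing beyond the two state reorganization free
energies and the temperature, and the defining equations are solved
with a bracketed root find started from the analytic leading-order root.
Leading order in the variance mismatch the correction is (λ_O − λ_R)/6.
Contracts: exactly 0 when λ_R = λ_O; continuous in its inputs; a warning
(not an error) when the mean-based λ is wildly inconsistent with the
variance-based values, since that regime is outside the model's premise.

From 2-decimal rounded σ inputs this correction reproduces the reported
0.01–0.07 eV corrections in sign, ordering and magnitude but not to print
precision: a ±0.005 eV rounding of σ moves λ_i by ~0.05 eV and the
correction by ~0.01 eV, and a pair of σ values printed as equal forces a
zero correction whatever the unrounded data gave. Reports therefore carry
both the uncorrected ΔA and ΔA + correction; the published corrected values
are themselves not uniformly explainable as ΔA + correction at print
precision, and the package documents rather than reverse-engineers that
roundoff.

## Structural comparison

Property tables are consumed, never computed: long-format (frame, property,
bp_index, value) records, 1-based base-pair indices (groove-type parameters
may carry level indices on the same axis). Tail trimming removes `n_tail`
indices from each end of the *present* span, preserving labels, which makes
repeated trims compose cumulatively (146 bp, n_tail = 20 → indices 21–126,
106 bp). Each property reduces to its per-frame mean over retained base
pairs (uniform weights); every property must appear in every frame.

Significance rule: a difference in distribution means counts only if it
exceeds max(sd_a, sd_b) — the strictest reading of a spread-relative
significance criterion — configurable to min or pooled. A Welch-style
Z = (mean_a − mean_b)/sqrt(sd_a²/n_a + sd_b²/n_b) is reported alongside
(the source states that Z-scores were computed but not their form; the
Welch form is documented here as the package's choice). Localization
repeats the comparison over four fixed 21-bp sections (32–52, 53–73, 74–94,
95–115); by default only globally flagged properties are drilled into
(`section_mode="flagged"`), or all properties with `"all"`.

## Synthetic generators

Gap series: stationary AR(1) Gaussian processes with means ΔA ± λ and SDs
sqrt(2 λ_i k_BT), lag-1 autocorrelation exp(−dt/τ). Defaults are the
analysis' own study conditions: 1000 frames over 25 ps (dt = 0.025 ps),
300 K, ΔA = 6.81 eV, λ = 1.01 eV (σ ≈ 0.23 eV), τ = 5 frame intervals.
AR(1) is the minimal stationary correlated process; the generator's job is
stress-testing estimators under time correlation, not reproducing an ab
initio spectral density. Setting λ_R ≠ λ_O produces controlled non-Marcus
data.

Property tables: per property, frame-level means drawn N(baseline,
between_sd), base-pair values drawn around each frame mean with within_sd;
the defect table is identical in law up to an optional constant shift inside
a bp range. The 41-entry default registry uses published distribution
summaries where available (helical axis bend 4.93 ± 0.082°, rise 3.39 ±
0.011 Å, minor groove depth 5.56 ± 0.044 Å, major groove depth 4.7 ±
0.13 Å) and B-DNA-like baselines with comparable relative spreads
elsewhere; within-frame scatter is set several-fold larger than
between-frame drift, as per-base-pair values fluctuate far more than their
frame averages. What the generator does *not* emulate: sequence dependence,
inter-property correlations, slow conformational drift, and non-Gaussian
tails of real helical parameters — so passing tests demonstrate estimator
correctness under the stated noise model, not robustness to every feature
of real trajectories.

Seeding: one root seed; each stream (reduced gap, oxidized gap, wild-type
table, defect table) derives its generator from (seed, fixed offset), so
adding a stream never perturbs existing ones and every generator is a pure
function of its configuration.

## Problem sizes and numerical choices

The test suite exercises: curve construction at n = 10⁵ i.i.d. samples;
parameter recovery at 100 seeds × n = 1000 AR(1) frames (τ/dt = 5) for
ΔA ∈ {5.7, 6.8} × λ ∈ {1.0, 1.2}; structural specificity/power at 100
seeds × 100 frames × 146 bp × 41 properties (frame count chosen for a fast
suite; the flag rule's false-positive probability is ~10⁻¹² per property at
100 frames, so specificity and power conclusions are insensitive to the
reduction). Histogram fits exclude bins below `min_count`; root finds use
xtol = 10⁻¹⁴; display rounding to 2 decimals (eV) / 1 decimal (%) happens
only in reports, never in arithmetic.

## Known limitations

- The variance route to λ and the quadratic-model correction assume the
  sampled distributions are at worst mildly non-Gaussian; strongly
  multimodal gaps (bond making/breaking, coordination changes) are outside
  the model and are surfaced by the Gaussianity verdict, not corrected.
- No electrode alignment: ΔA values are unaligned half-reaction free
  energies, comparable between systems computed the same way but not to
  experimental electrode potentials without an alignment constant.
- No finite-size/background-charge corrections (negligible for the
  large, counterion-neutralized setups this analysis targets).
- Blocking SEM needs ≥ 16 samples and, like all blocking estimators, can
  underestimate errors when the correlation time approaches the series
  length.
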