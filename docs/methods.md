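# Methods

## Derivative mass arithmetic

Monoisotopic atomic masses are standard values to 10 decimal places
(¹H 1.0078250319, ²H 2.0141017781, C 12 exactly, N 14.0030740052,
O 15.9949146221; proton 1.0072764669 Da). Light DMED amidation adds
m(C4H12N2) − m(H2O) = 70.0895 Da to the neutral acid; the heavy tag
additionally substitutes four ¹H → ²H, so the light/heavy split is exactly
4 × 1.00627675 = 4.0251070 Da. All pairing windows are centered on this
exact value, not the 3-decimal 4.025 convention used in print; at the 5.0 mDa
matching tolerance the distinction is immaterial, but centering on the exact
value keeps the signed mass-error distribution symmetric.

Detected as [M+H]+ these give, e.g., caprylic acid at m/z 215.2118 /
219.2369 — the values the implementation reproduces to 4 decimals.

## Formula generation

Candidates over C/H/N/O are enumerated directly (C and N and O loops with the
H count solved from the residual mass window). A candidate is kept when its
mass lies within the tolerance (default 5.0 mDa) and, by default, when its
ring-plus-double-bond equivalents RDBE = C − H/2 + N/2 + 1 are non-negative
and integral — the even-electron plausibility filter; a flag disables it.
Default bounds C ≤ 50, H ≤ 100, N ≤ 6, O ≤ 10 cover very-long-chain acids and
the two label nitrogens across the instrument scan range (m/z 180–650).
Output is ordered by |mass error|, ties by fewer heteroatoms, then fewer
atoms, then the formula string, so results are deterministic. Annotation
back-transforms labeled candidates to parent acids by removing the net label
atoms (−C4H10N2, +O as written: C−4, H−10, N−2, O+1), dropping candidates
that would need negative counts.

## Retention-index calibration

The spiked d4-labeled C5:0..C24:0 ladder defines a Kovats-style index
RI(Cn:0) = 100·n. Ladder peaks are located by exact heavy-derivative m/z
(most intense feature within the m/z tolerance wins; a feature in range of
two expected masses is assigned to the closer one). The RT → RI map is
piecewise linear between anchors with end-segment linear extrapolation:
exact at anchors, strictly increasing, and exactly invariant under affine RT
drift; for smooth non-affine drifts the residual error between anchors stays
below one RI unit at realistic curvatures. Nonlinear (spline/LOESS)
calibration is deliberately out of scope — the anchors are dense (one per
CH2) and piecewise linearity adds no tuning parameters.

## Peak-pair extraction

A candidate pair must satisfy three conditions: |observed Δm − 4.0251070| ≤
5.0 mDa (the instrument-accuracy tolerance), |ΔRI| ≤ 5 (about 1/20 of one
CH2 ladder step), and intensity fold-difference ≤ 5 (the 1:1 mixing design
implies a near-unity ratio; the generous bound absorbs deuterium ionization
effects). Candidates are assigned greedily in ascending |mass error| (ties:
RI gap, then light m/z), each feature joining at most one pair, so the output
is order-independent and conflict resolution is deterministic. Greedy rather
than globally optimal matching is a documented simplification; at LC-MS
feature densities conflicts are rare. Cross-sample merging collapses pairs
agreeing within 5.0 mDa (light m/z) and 5 RI into one consensus potential
FFA with intensity-weighted mean coordinates; this merge step has no
published counterpart and is this package's construction.

## Quantitation

The heavy ladder in each light-labeled sample run serves twice. First, QC: a
sample is dropped unless it detects the full ladder (required fraction 1.0 by
default, configurable) — the all-or-nothing rule under which the original
four-region study removed three samples. Second, normalization: each analyte
intensity is divided by the intensity of the ladder standard nearest in RI
(ties to the lower carbon number), which cancels per-run global intensity
drift exactly. A bracketing two-standard scheme was considered and rejected
for the default: one-point normalization is the standard internal-standard
logic and is robust when an analyte sits outside the anchor range. Missing
analytes stay missing (NaN), never zero-filled.

## Statistics

Per FFA, a transform is gated in the fixed order none → sqrt → log10: the
first under which the pooled group-centered residuals pass Shapiro–Wilk
(α = 0.05) and the groups pass Levene (α = 0.05) is used; if none passes,
log10 is applied with a warning flag. Normality is tested on residuals
rather than per group because that is the actual ANOVA assumption and keeps
the combined false-rejection rate near α instead of compounding it across
groups. One-way ANOVA is the classical between/within F test; the degenerate
zero-within-variance case reports the smallest positive p with a flag.

PCA is SVD on autoscaled data (unit-variance scaling is the default, as in
common chemometrics practice; centering-only via flag), with per-component
R²X and Q² from 7-fold row-wise cross-validation of the reconstruction
error. OPLS-DA follows the orthogonal-projections construction: the first
PLS weight against the one-hot class matrix defines the predictive
direction; orthogonal components are stripped one at a time; a single
predictive component is then fit. The orthogonal-component count is chosen
to maximize 7-fold cross-validated Q² up to 5. With one predictive
component, VIPⱼ = √p·|wⱼ|/‖w‖, so ΣVIP² = p holds identically — this is
asserted on every fitted model. FFAs with more than 50 % missing values in
any region are excluded from the multivariate models and the remaining
missing values imputed with region-wise medians (ANOVA uses only observed
values); multivariate models run on log10 abundances, matching the
right-skew of intensity-ratio data.

Selection is the joint rule VIP > 1.0 ∧ p < 0.05 with no multiple-testing
correction by default — faithful to the original univariate treatment and a
known caveat; Benjamini–Hochberg is available behind a flag. At the design
sample size (4 regions × 12 samples, 56 FFAs) the null selection count is
about α·p ≈ 2–3; at much smaller n the joint rule inflates because spurious
VIP and p become correlated.

## Synthetic data

The generator emulates the two study designs at the feature level. Intensity
is log-normal: a per-FFA base level 10^N(6, 0.5) (area units), multiplied
per observation by exp N(0, σ) with σ set from the configured CV (default
20 %). m/z noise is Gaussian with σ = 1.0 mDa; retention-index jitter σ = 1
per channel; per-run RT drift is affine with small random per-run
coefficients around a configurable warp. Decoys are uniform over the scan
range m/z 180–650 but rejected inside ±10 mDa of any existing feature or its
± Δm image at a nearby RI, so they are guaranteed isolated singletons.
Ladder standards are emitted as heavy peaks at their exact anchor RIs with
5 % CV (a spiked standard mixture is pipetted far more reproducibly than a
biological analyte varies). Heavy-channel RI offsets are symmetric noise
rather than systematically early: at the amide-derivative level the
deuterium RT effect is below the jitter scale, and a systematic-offset
option exists for stress tests.

What the simulation does **not** model: chromatographic peak shapes, isotope
envelopes, ion suppression, chimeric/overlapping pairs, charge states beyond
1+, and real retention behavior (library RIs are a chain-length heuristic).
Passing tests therefore demonstrate the correctness of the downstream
arithmetic, matching, normalization and selection logic under controlled
noise — not feature-detection performance on raw instrument data.

## Problem sizes used in validation

The validation suite runs the generator at: 1000 planted pairs + 2000 decoys
(pair recall; recall ≥ 0.99 with zero decoy pairs), 12 runs with 3 planted
ladder-dropout samples (QC), 4 regions × 12 samples × 56 FFAs with 6 planted
fold-2.5 effects (end-to-end selection), 2000 null FFAs at 4 × 10 (ANOVA
type-I calibration), and 100 random masses in 100–500 Da against exhaustive
enumeration (formula generation). Exact-count identities (counts equal to
the manifest) are checked at reduced noise, since at full jitter a ~4σ draw
can legitimately push a pair outside the RI window — that is recall, not a
counting defect.

## Known limitations

- Greedy pairing can mis-assign in pathological near-coincidences.
- Formula-level classification cannot separate isomers, place double bonds,
  or recognize bile acids (carried as library metadata only).
- One predictive OPLS-DA component summarizes a k-class contrast; strongly
  multi-modal class structure would need the multi-component extension.
- The packaged library's reference RIs are synthetic; with a measured
  library the same file format applies unchanged.
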