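# Methods

## Problem and scope

Septic (infectious) arthritis needs urgent treatment, and one of its
laboratory signatures is a change in the viscosity of synovial fluid (SF).
A 10 MHz quartz crystal resonator (QCR) can measure that change on a ~50 µL
drop: a viscous liquid load shifts the series resonance frequency down and
broadens the conductance peak.  This package implements, end to end, the
analysis built on that measurement principle:

1. the resonator physics (frequency shift ↔ viscosity),
2. extraction of the resonance parameters from conductance sweeps,
3. a synthetic cohort generator standing in for the clinical samples
   (which are not publicly deposited),
4. two-group statistics and ROC analysis of the three sensor features, and
5. the tabular classification workflow (feed-forward network, linear SVM,
   random forest) with its splitting, scaling and oversampling steps.

## Resonator model

For a Newtonian semi-infinite liquid of density ρ_L and viscosity η_L on an
AT-cut crystal with fundamental frequency f₀, quartz density ρ_q and shear
modulus G_q, operated at overtone n, the Kanazawa–Gordon relation gives

    Δf = − n f₀^{3/2} √( ρ_L η_L / (π ρ_q G_q) )

with defaults f₀ = 10 MHz, ρ_q = 2648 kg m⁻³, G_q = 2.947×10¹⁰ N m⁻²,
n = 1.  Water (ρ = 1000, η = 1 mPa s) gives Δf ≈ −2019.6 Hz, the canonical
~2 kHz response of a 10 MHz crystal.  The inversion
η = Δf² π ρ_q G_q / (n² f₀³ ρ_L) is exact and round-trips to 10⁻¹² relative.

**Assumed fluid density.** Inverting Δf to η requires a density.  No single
density reconciles all four published (mean Δf, mean η) class pairs (the
implied values span ≈ 930–970 kg m⁻³), so the package fixes one documented
calibration constant, ρ_L = 951.9 kg m⁻³ — the brute-force scan value that
reconciles the EDTA inflammatory class means (Δf = −3665.36 Hz,
η = 3.46 mPa s) — and exposes it as a configuration parameter.

**Bandwidth.** Energy dissipation broadens the conductance peak; the
half-bandwidth-at-half-maximum shift is modelled as
ΔΓ = r·|Δf| with a dimensionless viscoelastic ratio r (r = 1 for the ideal
Newtonian limit, so ΔΓ = −Δf exactly).  Empirically the SF data sit near
r ≈ 0.49.

**Conductance curve.** No equivalent-circuit model is published for the
instrument, so sweeps are simulated with the standard near-resonance
Lorentzian of a series-resonant branch, G(f) = G_max / (1 + ((f−f_s)/Γ)²),
which makes every extraction step analytically checkable
(G(f_s ± Γ) = G_max/2 exactly).  The air reference resonates at f₀ with a
configurable high-Q half-bandwidth (default 150 Hz — a plausible unloaded
value; the instrument's own air bandwidth is not published).  Default sweep
grids span f_s ± 6Γ with 500 points; span and step of the real instrument
are likewise not published.

## Sweep processing

The series resonance frequency is the abscissa of the conductance maximum
refined by a three-point parabola (argmax alone would quantise Δf to the
grid step, far coarser than the Hz-scale structure of the data); for any
curve symmetric about its peak the parabola vertex is exact.  The
half-bandwidth is half the distance between the two half-maximum crossings,
each located by linear interpolation between bracketing grid points, with
the half level referenced to the interpolated peak (less noise-biased than
the raw grid maximum).  Degenerate inputs raise typed errors: a boundary
peak ("peak-truncated"), a missing half crossing or a constant curve
("bandwidth-truncated").  No smoothing is applied before extraction.
Extraction is exactly invariant to rescaling the conductance axis.

Under 1% relative conductance noise on a 500-point grid, the median
frequency error is below one grid step and the median bandwidth error below
2% (seeded estimator-consistency test).

## Synthetic cohorts

The generator reproduces the study geometry exactly: EDTA 25 inflammatory +
8 infectious samples and 4972 rows; lithium heparin 21 + 7 and 5248 rows;
3–5 repeats per sample × 50 points per repeat.  Because the published
totals are not divisible by the 50-point repeat block, rows are allocated
as: three full repeats per sample, leftover whole repeats (capped at five)
to seeded-random samples, and the sub-repeat remainder as a partial repeat
on the last sample.  This keeps every sample present at the exact total
(simply truncating a random allocation would delete whole samples).

Features are hierarchical Gaussian.  For class c and feature j with
published mean μ_cj and SD σ_cj, a sample draws its latent effect with
variance b·σ²_cj and points scatter around it with variance (1−b)·σ²_cj,
where b = `between_sample_fraction`.  Pooled class means and SDs therefore
equal the published values exactly in expectation (verified to 3% at 10⁵
rows), and the point-level marginal AUC of each feature matches its
binormal closed form Φ(Δμ/√(σ₁²+σ₂²)).

**Feature coupling.**  ΔΓ and η are physically driven by Δf, but the
published per-class SDs are not mutually consistent with a deterministic
link (e.g. pure Kanazawa coupling implies an EDTA inflammatory η SD of
0.256 mPa s against the published 0.21, while the heparin inflammatory ΔΓ
SD implied by the bandwidth ratio is 52.5 Hz against the published 95.89).
The generator therefore correlates each linked feature with Δf at the
strength implied by the (linearised) physics link — capped at 0.98 so no
feature degenerates into a deterministic function of Δf — and **pools the
correlation across the two classes of a tube**.  The classes then differ
in location and per-feature scale but share one correlation geometry.  An
earlier per-class calibration was rejected: it matched all moments but gave
the classes visibly different residual scatter around the physics curve,
which a classifier could exploit to reach near-perfect accuracy on unseen
samples — an artifact, not a property of the measurement.

**Between-sample fraction.**  b is the designated calibration knob of the
generator: it is set so that point-level-split classification accuracy
lands in the published 0.85–0.99 band.  With the pooled-correlation model
this calibration gives **b = 0.97**; at that value point-split network
accuracies are ≈ 0.95–0.98 (EDTA) and ≈ 0.99 (heparin), grouped-split
accuracies average ≈ 0.7, and the published qualitative ordering (heparin
easier than EDTA, SVM weakest) emerges.  b is a single number shared by
both tubes and both classes.

**Clinical covariates** are drawn once per sample (constant across its
rows): white-cell count as a log-normal matched by moments to the published
mean ± SD (the published SDs exceed the means, which no positive-support
normal model can produce), and neutrophils, glucose and proteins as normals
truncated to [0, 100]%, [0, ∞) and (0, ∞).  Truncation shifts their moments
slightly; the published values are treated as targets, not invariants.

**Raw-sweep emission** renders any row back into an (air, loaded) sweep
pair for exercising the extraction stage end to end.  A conductance sweep
encodes only f_s and Γ, so the round-trip comparison for η is against the
Kanazawa inversion of the row's own Δf; the row's stored η additionally
carries the independent noise component by design and is not recoverable
from a sweep.

What the generator deliberately does **not** model: temporal drift across
the 5-minute acquisition (rows are stationary and exchangeable within a
repeat), anticoagulant chemistry (the EDTA/heparin difference enters only
through the published class statistics), and the joint distribution of the
clinical covariates (they are drawn independently given the class).
Passing tests on these cohorts therefore demonstrate correctness of the
pipeline and the *structural* reproducibility of the published pattern, not
clinical performance on real fluids.

## Group statistics

Mann–Whitney U (midranks; exact enumeration when n₁+n₂ ≤ 12 and there are
no ties, otherwise the tie-corrected normal approximation with continuity
correction) and ROC/AUC per feature with the Hanley–McNeil standard error
(Q₁ = A/(2−A), Q₂ = 2A²/(1+A)) and a Wald 95% CI clipped to [0, 1] — the
standard nonparametric defaults matching common statistical-package output.
The orientation is fixed (infectious positive, larger more positive) and
never auto-flipped, so the viscosity feature reports its genuine AUC < 0.5.

The U test and the AUC default to per-sample means: repeated points are not
independent, and the published p-values (0.01–0.25) and AUC standard errors
(0.04–0.05) are only consistent with sample-level group sizes (n ≈ 30), not
point-level ones (n ≈ 5000).  A per-point mode is provided for comparison.
Means ± SD in the summary tables are computed from the measurement rows.

## Classification

Point-mode splitting shuffles rows 70/15/15 (train/validation/test; 85/15
for SVM and forest).  Partition sizes are ceil(fraction·n) for test and
validation with the remainder in training, which reproduces both published
test-set sizes (4972 → 746, 5248 → 788; plain rounding would give 787).
Grouped mode assigns whole samples, stratified by class.

Scaling is median/IQR (quartiles by linear interpolation) fitted on the
training partition only; a zero-IQR feature raises, naming the offender.
The scaled values are not clipped to [0, 1]: a median/IQR scaler is
unbounded by construction.

Random oversampling duplicates minority-class rows (with replacement) until
the classes match.  The default applies it **before** splitting, because
the published balanced test-set sizes (≈ 2·majority·0.15) imply that order;
note this leaks duplicated rows across partitions, and an after-split
option is provided as the sound alternative.

The network is input(3) → 50 relu units × {1, 2} → 2-class output, trained
with mini-batch Adam (batch 16, step 10⁻³, categorical cross-entropy — the
standard companion of a softmax output, not explicitly published) for
exactly 100/200/300 epochs with no early stopping.  It is driven through
scikit-learn's `MLPClassifier` one `partial_fit` epoch at a time, which
preserves the optimiser state and yields per-epoch accuracy/loss curves on
both the training and validation sets; for two classes scikit-learn uses a
single logistic output unit, mathematically identical to a 2-unit softmax.
The SVM is `LinearSVC` (C = 1, squared hinge); the forest is 2171 bootstrap
gini trees with minimum split 2 and depth cap 200, all treated as fixed
constants (the search that produced them is out of scope).

Confusion matrices use the clinical orientation (inflammatory positive),
and accuracy = (TP+TN)/total is reported both at full precision and
truncated to two decimals: recomputing all 24 published matrix/accuracy
pairs shows the published values are truncations (e.g. 640/746 = 0.8579
reported as 0.85), under which **all 24** pairs match exactly.  One
balanced-EDTA matrix sums to 1242 rows while its five siblings sum to 1142;
the verification flags it and does not attempt to reconcile it.

## Leakage

With b = 0.97 the 50 points of a repeat cluster tightly around their
sample's mean, so a point-level split places near-duplicates of each test
row in the training set: the classifier recognises the *sample*, not the
class.  A grouped-by-sample split removes this and costs ≈ 0.25 accuracy on
the default cohorts.  Because a grouped test partition holds only ~5
samples, single-split grouped accuracy varies widely (observed ≈ 0.50–0.90
across split seeds); the leakage gap is therefore assessed against the mean
over five grouped splits.  This is the structural reason the published
point-level accuracies (0.85–0.99) coexist with marginal AUCs of 0.55–0.65.

## Numerical and reproducibility choices

All internal physics is SI (Hz, kg m⁻³, Pa s); tables report η in mPa s.
Every stage derives its seed from one global seed hashed with the stage
name (SHA-256, 31 bits), so adding a stage never perturbs earlier streams;
identical configuration and seed reproduce every output file byte for byte.
Problem sizes used by the test suite: moment recovery at 10⁵ rows (2000
samples per class), binormal AUC at 10⁵ draws per class, estimator
consistency over 200 noisy sweeps, and the full six-configuration network
grid on both default cohorts.

## Known limitations

* The cohorts are Gaussian and stationary; real SF features are likely
  skewed, drifting and device-dependent.
* The assumed fluid density is a calibration constant; per-sample densities
  would change η by a few percent.
* The Hanley–McNeil/Wald interval is approximate at n ≈ 30 per group and
  degenerates (SE = 0) under perfect separation.
* Exact published accuracies are not reproducible without the clinical
  data; the classification criteria are deliberately property-based
  (bands and orderings, not point values).
* The 5-input network variant hinted at in the published architecture
  table (presumably adding clinical covariates) is configurable via
  `input_dim` but no claim is made about it.
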