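# Methods

## Signal model and three-point decomposition

Each voxel is modeled with a single fat spectral peak at −3.4 ppm relative
to water, so the fat–water frequency offset is Δf = −3.4 · γ · B0 (about
−1013 Hz at 7 T and −434 Hz at 3 T, γ = 42.58 MHz/T).  With non-negative
real amplitudes W (water) and F (fat) and local off-resonance ψ in Hz, the
echo-k signal is s_k = (W + F·c_k)·e^{i2πψTE_k} with c_k = e^{i2πΔfTE_k}.
Multi-peak fat spectra, T2* decay and coil effects are deliberately outside
the model.

For a trial ψ the demodulated samples are fitted over (W, F) ≥ 0 by exact
two-variable non-negative least squares (closed form: unconstrained 2×2
solve, falling back to the better of the two axis-constrained fits).  The
resulting residual profile R(ψ) is evaluated on a uniform grid over one
aliasing window [−1/(2ΔTE), +1/(2ΔTE)) taken from the first echo pair
(default grid step 8 Hz; the grid work is two complex matrix products per
chunk, so the scan is cheap).  The three best local minima are refined by
golden-section search inside their brackets (22 iterations, brackets clipped
to the window) and the best two distinct basins (≥ 2 Hz apart) become the
per-voxel candidate pair — the true field and the fat/water-swapped alias.
Degenerate voxels (magnitude below 10⁻⁹ of the volume maximum) get two
coincident zero candidates and are flagged.

The test-suite oracle for this machinery is an independent dense grid search
whose residuals come from `scipy.optimize.nnls` on the stacked
real/imaginary system.  Where water and fat amplitudes are nearly equal the
alias minimum sits on a plateau spanning hundreds of Hz; its *location* is
not numerically determined, so tests compare residual levels there instead
of positions.

### Swap resolution

One candidate per voxel is selected by per-slice region growing.  The seed
is the highest-magnitude voxel whose lower-residual candidate is
water-dominant (W ≥ F); at the seed, ties in residual (exact for pure-water
or pure-fat voxels) are broken toward the water-dominant interpretation —
the standard Dixon convention that the smooth field is anchored in
water-likely tissue.  Voxels are then visited in descending magnitude order
(binary heap), each taking the candidate whose phasor e^{i2πψΔTE} is closest
in angle to the mean phasor of already-resolved neighbors in the 3×3
window.  A single-voxel mask reduces to "take the lower-residual candidate".

## Two-point decomposition

The dual-echo protocol (TE 1.32/2.46 ms at 3 T) is treated as nominally
opposed-phase/in-phase.  The true fat–water angles at those echo times are
≈ 154° and ≈ −25°, not exactly 180°/0°; the nominal approximation biases fat
amplitude by ~10 % relative in fat-dominant voxels, which the 0.5
fat-fraction threshold used downstream tolerates.  This bias is
characterized in tests rather than corrected; a flexible-angle variant is
out of scope.

With complex data, the smooth phase-error field is estimated from the
squared first echo (squaring cancels the sign of W − F), smoothed with a
Gaussian of 5 voxels, and halved.  The halving restricts the resolvable
off-resonance to |ψ| < 1/(4·TE₁) ≈ 189 Hz, ample for the smooth fields the
phantom simulates (default 60 Hz amplitude at 3 T).  After demodulation,
W = (IP + OP)/2 and F = (IP − OP)/2, clamped at zero.  Magnitude-only input
uses |s₁|, |s₂| directly; fat-dominant voxels then come out swapped — a
known two-point limitation, flagged in the result metadata.

## Active-contour segmentation

Per axial slice, the body mask is an Otsu threshold on total signal (W+F)
with morphological closing (disk radius 2), hole filling and removal of
components under 50 voxels; each connected component (arms/legs on human
slices) is processed independently, largest first.  The outer boundary of a
component — the skin contour — is resampled to equidistant vertices
(200 human / 120 mouse) and initializes a closed snake on the fat image.

The snake evolves semi-implicitly: v ← (I + γ(αD₂ + βD₄))⁻¹(v + γ·f), with
tension α = 0.1, stiffness β = 0.05, step γ = 1, and external force
f = edge_weight·∇|∇(G_σ∗F)| (σ = 2 voxels, edge_weight = 2) plus an inward
balloon pressure κ = 0.3.  The contour is re-sampled to uniform arclength
each iteration and converges when the mean vertex displacement stays below
tol = 0.01 voxels for 5 consecutive iterations (collapse guard at 4 voxels²
of area; non-convergence at 500 iterations returns the last contour,
flagged).

**Gated balloon.** A strictly constant pressure cannot both escape the skin
edge ridge (where the contour starts) and stop at the equally sharp fascia
ridge, since the two edges have the same strength on a fat image.  The
balloon is therefore gated by a look-ahead test: pressure applies only while
the smoothed fat intensity 4 voxels ahead of the contour (along the inward
normal) exceeds 20 % of the slice maximum — i.e. while fat still lies
ahead.  Crossing the bright SCAT ring the gate is open; approaching the dark
muscle it closes, and the edge attraction centers the contour on the fascia
ridge.  On a constant (or zero) image the gate is trivially open and the
contour shrinks under pure pressure, as expected of a balloon force.  The
default tol of 0.01 voxels matters here: a looser tolerance stops the
contour a fraction of a voxel outside the fascia, visibly inflating VAT on
thin-SCAT anatomies.

Labels: fatty voxels (FF ≥ 0.5) outside the converged contour are SCAT,
fatty voxels inside it are VAT, all remaining body voxels are LTW; voxels of
a user-supplied exclusion mask (tumor, metal artifact) are labeled
"excluded" and removed from every compartment.  LTW is defined by voxel
count (water-dominant voxels × voxel volume), not by integrating the water
fraction; both definitions are defensible, the count-based one is simpler
and is used consistently.  The fat-fraction threshold 0.5 is a design
choice; it is exposed in the API.

## Volumes and change analysis

Volume = voxel count × voxel volume, in mm³ (1 mm³ = 1 µl).  The mouse voxel
is (38/162) × (45/192) × 2 mm ≈ 0.110 µl; the human voxel 2.6 × 2.6 × 3.1 mm
≈ 0.021 ml.  Slice index 0 is the most caudal slice everywhere; caudocranial
profiles sum exactly (in voxel counts) to the totals.  Follow-ups are
expressed per subject as 100·(V_t − V_0)/V_0, and group-level changes are
means of per-subject changes (not ratios of group means).  Report strings
round to the conventional precision (integer percent for liter-scale
volumes, one decimal otherwise); raw values are always retained.

## Cohort statistics

Summaries are mean ± sample SD (n − 1); a group of size 1 reports SD as
not-available rather than 0.  One-way ANOVA uses the classical between/within
F with (k−1, N−k) degrees of freedom; pairwise follow-ups multiply raw
pooled-variance two-sided p values by the number of comparisons (Bonferroni,
capped at 1) and report 95 % CIs from the pair-pooled standard error at the
unadjusted level, so a CI straddles zero exactly when the raw p exceeds
0.05.  Shapiro–Wilk, Pearson r and the unpaired t test delegate to
`scipy.stats`; hand-computed and permutation oracles in the test suite are
the independent check.  Significance is p < 0.05 throughout, held in a
single constant.

The packaged `table1.csv` holds the 18-patient melanoma cohort (body weight
and BMI at baseline/2 weeks/12 weeks, last-measurement percent changes of
VAT/SCAT/LTW, therapy, response).  Checkpoint-inhibitor-only analyses filter
therapy to PD-1/CTLA-4 antibodies (n = 16).  The MIXED and PD LTW-change
summaries recompute exactly from the table; the published RTT summary and
the accompanying ANOVA F do **not** recompute from the table's values
(recomputation gives mean −1.80 and F ≈ 4.4), a documented discrepancy of
the source material — the fixture is kept verbatim and those two numbers are
not asserted anywhere.

## Digital phantom

The phantom is a stylized elliptical torso per slice: a 0.5 mm lean skin
rim, a SCAT ring (1.2 mm mouse / 20 mm human), a lean muscle ring (2 mm /
15 mm) and a visceral cavity with seed-reproducible circular VAT blobs
(0.9–1.6 mm / 12–20 mm radius); an optional subcutaneous tumor bulges
through the body wall and is labeled distinctly.  Lean tissue carries fat
fraction 0.05 at unit proton density, adipose tissue 0.9 at density 0.95.
The B0 field is a fixed low-order 2-D polynomial per slice scaled to a
prescribed amplitude (defaults 150 Hz at 7 T, 60 Hz at 3 T — smooth fields
are the regime Dixon methods assume); noise is complex Gaussian on both
channels with SD expressed as a fraction of the mean in-body first-echo
magnitude (SNR 30 ⇒ noise_sd = 1/30).

Longitudinal series rescale geometry so ground-truth volumes follow
prescribed factors: VAT through blob radii, SCAT through the ring thickness
(closed form on ellipse ring areas), LTW through the body outline (solved
numerically with the SCAT area held fixed).  Because thin rings and small
discs rasterize with O(perimeter/area) bias, each analytic scale is refined
against actual rasterized voxel counts (two-stage 17-point scan), bringing
ground-truth trajectories within ±0.5 % of the prescribed factors — well
inside the ±2 % tolerance the generator guarantees.

**What the phantom does not emulate:** realistic organ anatomy, partial
volume at tissue interfaces beyond rasterization, coil sensitivity and bias
fields, motion/breathing, k-space sampling, Rician magnitude statistics of
low-SNR regions (complex data are simulated; magnitude export inherits
Rician statistics naturally), or metal-induced field distortions.  Passing
phantom tests therefore demonstrates correctness of the algorithms under
the stated signal model, not robustness to every artifact of in-vivo data —
which is why manual-override and exclusion-mask operations exist.

## Problem sizes and runtimes

Tests and the acceptance script use 3-slice phantoms on the native matrices
(162 × 192 mouse, 144 × 144 human), chosen so that a full three-point
decomposition runs in a few seconds and the complete suite in about two
minutes on one CPU while still exercising every pipeline stage at realistic
in-plane resolution.  The candidate grid step (8 Hz), golden-section depth
(22) and region-growing window (3×3) are fixed numerical choices validated
against the dense-grid oracle.

## Known limitations

- The three-point path assumes zero common initial phase (φ0 = 0); a
  nonzero transmit/receive phase would require complex amplitude fitting.
- The two-point path resolves |ψ| < 1/(4·TE₁) only, and its nominal
  IP/OP approximation biases fat-dominant fat fractions by a few percent.
- Snake parameters are phantom-tuned; no parameter values for the original
  in-house implementation are published, so defaults here are the package's
  own and are all exposed in `SnakeParams`.
- 2-D per-slice evolution only; no volumetric contour coupling.
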