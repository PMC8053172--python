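# adipoquant

Automated MRI body-composition analysis for longitudinal monitoring of
cancer-associated wasting (cachexia) and of treatment effects, in small
animals and in patients.  Starting from multi-echo Dixon gradient-echo
acquisitions, the package

1. **decomposes** each voxel into water and fat signal — a flexible
   three-point decomposition with off-resonance swap correction for the
   7 T three-echo small-animal protocol, and a dual-echo in/opposed-phase
   decomposition for the 3 T whole-body human protocol;
2. **segments** each axial slice into subcutaneous adipose tissue (SCAT),
   visceral adipose tissue (VAT) and lean tissue water (LTW) with an
   active-contour (snake) that starts on the skin outline and propagates
   inward until it locks onto the sharp fat→muscle edge at the deep fascia;
3. **quantifies** compartment volumes, caudocranial profiles and percent
   change from baseline across timepoints; and
4. **tests** cohort-level hypotheses (Shapiro–Wilk, one-way ANOVA with
   Bonferroni-corrected pairwise comparisons, unpaired t, Pearson r).

Because no image data accompany the study conditions the package emulates, a
first-class **digital phantom** module generates labeled anatomies with
analytic ground truth (water/fat density maps, B0 inhomogeneity, complex
Gaussian noise, prescribed longitudinal compartment trajectories), so every
stage of the pipeline is validated end to end against known truth.

## The models in brief

**Signal model.** With water and fat amplitudes W, F ≥ 0, the single-peak
chemical-shift offset Δf = −3.4 ppm · γ · B0 and local off-resonance ψ (Hz),
the echo-k signal is

    s_k = (W + F·e^{i·2π·Δf·TE_k}) · e^{i·2π·ψ·TE_k}.

Three-point decomposition minimizes the residual R(ψ) = min_{W,F≥0}
Σ_k |s_k − model|² per voxel; R has two local minima over one aliasing
window (the true field and a fat/water-swapped alias), and a region-growing
pass selects the spatially smooth candidate field.  The fat fraction is
FF = F/(W+F).

**Segmentation.** Per slice: Otsu body mask on W+F → outer skin contour →
snake minimizing tension + stiffness + edge energy −|∇(G_σ∗F)| with a gated
inward balloon force → SCAT (fatty voxels outside the converged contour),
VAT (fatty voxels inside), LTW (water-dominant voxels), with user-supplied
exclusion masks (e.g. tumor, metal prosthesis) removed from all compartments.

**Change analysis.** Volumes are voxel count × voxel volume (mouse reported
in µl, human in ml); follow-ups are expressed as 100·(V_t − V_0)/V_0 per
subject, and group statistics are computed on those per-subject changes.

## Worked example

```python
import adipoquant as aq

# three-timepoint mouse phantom whose VAT shrinks to 88 % then 75 % of baseline
spec = aq.mouse_spec(noise_sd=1/30, seed=11)
pairs = aq.make_longitudinal(spec, aq.MOUSE_7T, {"vat": [1.0, 0.88, 0.75]})

from adipoquant.dixon import decompose_three_point
from adipoquant.contour_seg import SnakeParams, segment_volume
from adipoquant.quantify import compartment_volumes, percent_change

vols = []
for anatomy, series in pairs:
    fw = decompose_three_point(series, mask=anatomy.body_mask)
    comp = segment_volume(fw, spacing=aq.MOUSE_7T.spacing,
                          params=SnakeParams(n_vertices=120))
    vols.append(compartment_volumes(comp))

for t in (1, 2):
    print(f"t{t}: VAT change {percent_change(vols[0]['vat'], vols[t]['vat']):+.1f}%")
```

prints

```
t1: VAT change -12.0%
t2: VAT change -24.9%
```

— the pipeline recovers the prescribed −12 %/−25 % VAT trajectory from the
simulated images.  Cohort statistics run on the packaged 18-patient table:

```python
from adipoquant.workflow import run_cohort
res = run_cohort(aq.load_table1(), variable="LTW", cit_only=True)
print(res["summary"].round(2))
```

```
          n  mean    sd
Response
MIXED     5  4.59  3.71
PD        6  1.97  2.19
RTT       5 -1.80  3.80
```

A thin CLI mirrors the library: `adipoquant phantom|dixon|segment|cohort|run`.

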