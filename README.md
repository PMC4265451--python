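# petasp

Shape analysis of metabolically active tumor volumes in 3D FDG-PET:
**asphericity (ASP)** and **solidity** of the delineated lesion, together
with the conventional uptake metrics (SUVmax, SUVmean, MTV, TLG),
background-corrected adaptive segmentation, and the survival-analysis
machinery used to evaluate such markers (IQR-constrained optimal-cutoff
proportional-hazards screening, Kaplan–Meier, log-rank).

It is aimed at quantitative-imaging researchers who want a tested,
scriptable implementation of these shape markers — and phantom/cohort
simulators with known ground truth, so every stage of the pipeline can be
validated without patient data.

## The core quantities

For a lesion with surface area *S* and volume *V*, the asphericity is the
relative excess of its surface over the surface of the equal-volume sphere:

```
ASP = 100 · [ ( S³ / (36 π V²) )^⅓ − 1 ]   (percent)
```

ASP is zero for a sphere, positive for every other shape (isoperimetric
inequality), scale-invariant, and grows with lobulation, invasive growth
and internal cavities (necrosis adds internal surface without volume).
Solidity is the complementary convexity measure: the fraction of voxels
inside the convex hull of the ROI that belong to the ROI, 1 for convex
lesions, and it falls as ASP rises.

The metabolically active volume is delineated by iterating a
volume-reproducing threshold relative to the local background,
`T = B + f·(mAV − B)` with default fraction `f = 0.39`, where `mAV` is the
mean uptake in the current mask and `B` the mean in a thin shell around it.

Prognostic screening binarizes a metric at every distinct observed value
inside its interquartile range, fits a univariate Cox model per candidate
indicator `[x > v]`, and reports the cutoff with the most significant Wald
statistic — together with the full scan table, because maximally selected
statistics are anti-conservative without correction.

## Worked example

```python
from petasp import *
from petasp.phantoms import PhantomSpec, CohortSimSpec, make_phantom, simulate_cohort

# a lobulated lesion, blurred by a 2 mm PSF, with noise
spec = PhantomSpec(shape="lobulated", radius_mm=12, lobulation_amplitude=0.35,
                   uptake=10.0, background=1.0, psf_sigma_mm=2.0, noise_sd=0.2,
                   grid_shape=(64, 64, 64), seed=42)
grid, truth, ref = make_phantom(spec)

res = adaptive_threshold_segment(grid)
rep = lesion_report(grid, res.mask.values)
```

prints (via the obvious f-strings):

```
final threshold   : 3.73 SUV (5 iterations)
MTV               : 9.1 ml   (continuous reference 7.6 ml)
SUVmax / SUVmean  : 10.7 / 7.5
TLG               : 68 ml
ASP               : 4.9 %  (continuous reference 7.5 %)
solidity          : 0.984
min-volume (3 ml) : pass
```

The delineated ASP (4.9%) sits below the continuous-limit reference of the
generating shape (7.5%): the scanner PSF smooths lobulation away, the
partial-volume effect that makes small irregular lesions look more
spherical than they are. On the survival side:

```python
cohort = simulate_cohort(CohortSimSpec(n=60, hazard_ratio=3.4, seed=2))
cut = optimal_cutoff(cohort, "asp_pct")
```

```
optimal ASP cutoff: >39.6 %
HR (95% CI), p    : 3.47 (1.82-6.61), p=0.0002
```

a 60-subject cohort simulated with a true hazard ratio of 3.4 for high-ASP
subjects, recovered by the cutoff scan.

The same pipeline is available from a shell:

```
petasp phantom --shape lobulated --radius-mm 12 --seed 42 --outdir out/
petasp metrics --volume out/phantom.nii.gz --segment --outdir out/
petasp simulate-cohort --n 60 --seed 2 --outdir out/
petasp survival --cohort out/cohort.csv --endpoint pfs --outdir out/
```

## Documentation

`docs/methods.md` describes the models, estimators, defaults and known
limitations in detail.
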