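# billflex

Quantitative analysis of upper-bill (maxillary) bending in nectar-feeding
hummingbirds. Hummingbirds reciprocate their tongues ~15 times per second
while drinking, and their upper bill bends dorsally at localized flexion
zones ("distal rhynchokinesis") to coordinate nectar wringing at the tip
with intra-oral transport toward the throat. `billflex` implements the
full quantitative evidence chain for this behavior as a reusable, tested
Python pipeline:

1. **Semi-landmark kinematics** — each video frame of a lick cycle is
   digitized as three bill profile lines (dorsal culmen, maxillary tomium,
   mandibular ventrum), resampled to 21 arc-length-equidistant
   semi-landmarks per line (63 per frame). Frames are superimposed by
   generalized Procrustes analysis (GPA) and per-landmark total variances

   S²(landmark) = var(x) + var(y)

   over the 11 frames of each cycle localize the bill's bending zones
   (mean ± t-based 95% CI across cycles). Optional semi-landmark sliding
   (Procrustes-distance criterion) and PCA of the aligned coordinates
   yield shape-space trajectories of lick cycles.
2. **Procrustes ANOVA (RRPP)** — shape change across frames is tested with
   Goodall-style trace statistics on the full multivariate set of
   Procrustes coordinates, type III sums of squares, and residual
   randomization permutation procedures (cycle and tracking-dataset enter
   as blocking factors).
3. **Flexural rigidity from CT** — per cross-section, density-calibrated
   flexural rigidity is accumulated pixel-by-pixel,

   EI(slice) = Σᵢ E(ρ(grayᵢ)) · (yᵢ − y_axis)² · dA,

   with the gray→mineral-density map fitted to hydroxyapatite phantom
   scans and E(ρ) a configurable power law. Profiles along the jaw are
   segmented into the three characteristic regions (nasal / intermediate
   bending zone / symphysial) and mapped onto the kinematic landmark axis
   (accounting for the keratin-only bill tip) so that EI minima can be
   juxtaposed with S² peaks.
4. **Nectar transport** — an annular Couette–Poiseuille model of the
   tongue–bill gap:

   v_z(r,z) = (G/4μ)(r² − h²) + [U − (G/4μ)(R₀² − h²)] · ln(r/h)/ln(R₀/h)

   with exact closed-form flow rate, mass-conserving pressure-gradient
   solve, wall shear force on the tongue, blunt-tip asymptotics, and
   cycle-level transport integration (retraction = shear-driven Couette
   flow; protrusion = pressure-driven Poiseuille flow from tip wringing).
5. **Synthetic ground truth** — generators for lick-cycle landmark
   sequences with known hinge positions, deflections and tracking noise,
   and for CT-like beam phantoms (annulus, rectangle, arched shell) with
   known density maps and closed-form EI, so every stage is testable
   against truth.

## Worked example

```python
import numpy as np
from billflex import synthetic as sy, morphometry as mo, shapestats as ss

tpl = sy.default_template()                      # 18 mm exposed culmen
sc = sy.BendingScenario(hinge_positions=(0.65,),  # hinge 65% from the base
                        tip_deflections_mm=(0.5,),
                        tracking_noise_sd=0.02, seed=1)
frames = sy.generate_lick_dataset(tpl, sc, n_cycles=10)   # 10 x 11 frames

res = mo.gpa_align(frames)
prof = mo.landmark_variance_profile(res, [f.cycle_id for f in frames])
est = mo.estimate_hinge_index(prof.line_mean("culmen"))
print(f"estimated hinge landmark: {est:.2f} (true 8.00)")

anova = ss.procrustes_anova(
    res,
    factors={"cycle": [f.cycle_id for f in frames],
             "frame": [f.frame_index for f in frames]},
    blocks=("cycle",), n_perm=999, seed=1)
print(anova.table[["df", "SS", "R2", "F", "p_perm"]].round(4))
```

Output:

```
estimated hinge landmark: 8.41 (true 8.00)
           df      SS      R2        F  p_perm
term
cycle       9  0.0002  0.0251   0.9318   0.927
frame      10  0.0060  0.7059  23.6160   0.001
residual   90  0.0023  0.2690      NaN     NaN
total     109  0.0085  1.0000      NaN     NaN
```

The variance-profile kink recovers the commanded hinge to within half a
landmark spacing; the ANOVA shows that shape change across the 11 frames
of a lick (the bending signal, R² = 0.71, permutation p = 0.001) dwarfs
the variation between replicate lick cycles (R² = 0.03, n.s.), the
signature of a repeatable bill-bending kinematic cycle.

The same analyses run from the command line over TPS/CSV landmark files,
multi-page TIFF stacks and YAML configs:

```bash
billflex all --out run1 --seed 1          # simulate -> kinematics ->
billflex fluid --out run2                 # rigidity -> fluid report
```

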