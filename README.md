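# wristmorph

Quantifying how faithfully an achieved distal-radius fracture reduction
reproduces its preoperative 3D plan.

Volar-plate osteosynthesis of distal radius fractures is increasingly planned
on 3D CT-derived bone models: fragments are virtually reduced and the implant
is positioned before surgery. Whether the surgeon actually achieves the
planned reduction is a 3D question that plain radiographic angles answer only
partially. `wristmorph` implements a reference-point based evaluation:

1. **Anatomical frame** — an ISB-style coordinate system is derived from the
   plan surface model: the *y*-axis is the long axis of the radius (proximal
   positive), the *z*-axis is the projection of the sigmoid-notch-base →
   radial-styloid line onto the plane ⊥ *y* (radial positive), *x = y × z*
   (palmar positive). The origin is where the long axis pierces the distal
   articular surface.
2. **Rigid registration** — the post-operative model is superposed onto the
   plan using only the intact proximal shaft (trimmed point-to-point ICP with
   an SVD inner solve, principal-axes initialisation), so the comparison is
   independent of scanner pose.
3. **Morphometry** — from the three articular reference points P₁ (radial
   styloid process), P₂ (sigmoid notch volar edge), P₃ (sigmoid notch dorsal
   edge), expressed in the plan frame:
   distances dᵢ = ‖Pᵢᵖˡᵃⁿ − Pᵢᵖᵒˢᵗ‖; barycenter distance
   d_b = ‖(ΣPᵢᵖˡᵃⁿ − ΣPᵢᵖᵒˢᵗ)/3‖; triangle plane area ½‖(P₂−P₁)×(P₃−P₁)‖;
   volar tilt VT = arctan((y₂−y₃)/|x₂−x₃|) in the sagittal projection; radial
   inclination RI = arctan((y₂−y₁)/|z₁−z₂|) in the coronal projection.
4. **Cohort statistics** — Shapiro–Wilk screening, one-way repeated-measures
   ANOVA over (d₁,d₂,d₃,d_b) with Holm-corrected pairwise paired-t contrasts,
   paired *t* for plan-vs-post plane area, and Shrout–Fleiss intraclass
   correlation (ICC(1,1), ICC(2,1), ICC(3,1) with 95% CIs) for the two angles.

Patient CT data of this kind are not publicly deposited, so the package ships
a synthetic-wrist generator (`wristmorph.synthetic`) that emulates the
relevant statistical structure with known ground truth: calibrated landmark
positions, between-subject anatomical variance, ~2 mm plan-to-post reduction
error, and an arbitrary rigid offset of the post-operative scene.

## Worked example

```bash
wristmorph simulate --n 63 --seed 1 --out cohort/
wristmorph run --input cohort/ --output results/
```

or equivalently in Python:

```python
import wristmorph as wm
from wristmorph.io import RunConfig
from wristmorph.pipeline import run_pipeline

wm.sample_cohort(63, wm.GeneratorConfig(), seed=1, out_dir="cohort")
summary, metrics = run_pipeline(RunConfig(input_dir="cohort", output_dir="results"))
print(summary.to_markdown())
```

For seed 1 the summary reports (values printed by the run above):

```
## Plan-to-post distances (mm)
- d1: 1.91 (SD 0.87)
- d2: 2.05 (SD 0.86)
- d3: 2.04 (SD 0.84)
- d_bary: 1.23 (SD 0.51)
```

The three reference points miss their planned positions by ≈2 mm on average
— the calibrated reduction-error scale — while their barycenter deviates
significantly less (Holm-corrected p < 1e-8 for every barycenter-vs-vertex
contrast in this run): averaging the three points cancels independent
per-point error by a factor approaching 1/√3 ≈ 0.577. The plan frame's volar tilt and radial
inclination means sit near 11° and 21°, and their plan-vs-post ICC(2,1)
quantifies how well the angular reduction parameters were reproduced.

Per-case outputs land in `results/metrics.csv` (one row per wrist, mm/mm²/deg),
registration transforms as 4×4 homogeneous JSON, and the cohort report as
`summary.json` / `summary.md`.

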