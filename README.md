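# meshdose

Mesh-based radiotherapy simulation for researchers and educators: refine
labeled organ point clouds into surface meshes, trace radiation beam axes
through them, estimate tumor-center dose with a correction-based
percentage-depth-dose (PDD) model, score organs at risk with the
Lyman–Kutcher–Burman (LKB) NTCP formalism, and check machine–patient
clearance with conservative bounding-box collision detection. Everything
runs on synthetic analytic phantoms, so every number has a closed-form
oracle — no imaging data required.

## The models

**Refinement.** A sparse labeled prediction is densified by 10-nearest-
neighbor majority voting, cleaned by statistical outlier removal (mean
30-NN distance > mean + 2σ), voxelized, surfaced with marching cubes and
smoothed by 80 umbrella-Laplacian iterations at relaxation 0.1; the
largest connected component is the organ model. Accuracy is measured with
the Dice coefficient 2|A∩B|/(|A|+|B|).

**Dose.** Central-axis depth dose follows the buildup-tail model

    PDD(d) ∝ d/(d² + n) · e^(−μd)

normalized to 100 % at its peak d_max. SSD changes are handled by the
Mayneord factor F = ((SSD₂+d_max)/(SSD₁+d_max))²·((SSD₁+d)/(SSD₂+d))²,
tissue heterogeneity by the equivalent depth d_eff = Σ zᵢ·ηᵢ (lung
η = 0.275, soft tissue η = 1), and monitor units convert by
TD = MU·Dref·PDD/100·Scrc·Spr·((SSD₀+d_ref)/(SSD+d_ref))².

**Risk.** DVHs reduce to an effective volume
Vol_eff = (1/Vol_ref) Σ Volᵢ(Dᵢ/D_max)^(1/n); NTCP = Φ(t) with
t = (D_max − TD50·v^(−n))/(m·TD50·v^(−n)). Serial organs are flagged when
the beam axis crosses them; for parallel organs the area under the tumor
depth-vs-gantry-angle curve scores beam arrangements (lower is better).

**Safety.** Machine and patient parts carry world-frame axis-aligned
bounding boxes, tested by the separating-axis theorem with a 5 cm safety
margin and a BVH for pair culling — conservative by construction.

## Worked example

```python
import numpy as np
from meshdose import (BeamSpec, MachineCalibration, PDDModel,
                      make_thorax_phantom, sweep_angles)
from meshdose.planning import reports_to_profile
from meshdose.radiobiology import depth_angle_auc

spec, meshes = make_thorax_phantom(seed=1)   # tumor in the left lung
organs = [(o.label, meshes[o.name], o.eta) for o in spec.organs]
model = PDDModel(n=2.25, mu=0.0465)          # 6 MV-like demo curve
cal = MachineCalibration()                   # 1 cGy/MU at 10 cm, SSD 100

template = BeamSpec(0.0, isocenter=spec.tumor_center, mu=100.0)
reports = sweep_angles(template, organs, 1, cal, model,
                       np.arange(0.0, 361.0, 15.0))
left = next(r for r in reports if r.angle == 90.0)
print(f"left lateral: depth {left.depth_cm:.2f} cm, "
      f"deff {left.deff_cm:.2f} cm, dose {left.dose_cgy:.1f} cGy")
print(f"depth-angle AUC {depth_angle_auc(reports_to_profile(reports)):.0f} deg·cm")
```

prints

```
left lateral: depth 9.00 cm, deff 6.46 cm, dose 41.0 cGy
depth-angle AUC 4338 deg·cm
```

The left-lateral beam crosses 4.0 cm of soft tissue, 3.5 cm of lung and
1.5 cm of tumor, so the water-equivalent depth (6.46 cm) is shallower than
the geometric depth (9.00 cm) and the delivered dose is correspondingly
higher than a homogeneous-water estimate; the AUC summarizes how deep the
tumor sits over a full gantry turn.

There is also a CLI: `meshdose phantom|refine|trace|dose|sweep|ntcp|collide|report --help`.

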