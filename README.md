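# negvol

**Negative-volume segmentation and left–right symmetry morphometry for
ball-and-socket joints in CT.**

Clinical assessment of compound joints — the temporomandibular joint (TMJ)
between the mandibular condyle and the temporal bone is the archetype —
usually falls back on a handful of linear 2D measurements, because the
joint's tissues are too intricate to contour reliably. `negvol` takes the
complementary route: instead of segmenting the hard-to-contour anatomy it
extracts the **empty space inside the joint** ("negative volume") as a
watertight mesh, and quantifies joint health volumetrically.

The pipeline: normalize the CT volume → localize both joints at coarse
resolution and cut one volume of interest (VOI) per body side → segment the
condyle and the socket bone with a volumetric network (V-Net / 3D U-Net /
attention 3D U-Net, implemented on a small numpy autodiff backend) →
refine the socket bone with a classical image-processing chain fused with
the network heatmap → reconstruct both bones as meshes → **inflate** the
condyle mesh along its vertex normals, with Laplacian regularization

    v  ←  (1−λ)·(v + step·n̂)  +  λ·mean(neighbors),

freezing each vertex as it contacts the socket surface → subtract the
original condyle and clip below the equatorial neck plane. The resulting
left (ℒ) and right (ℛ) negative volumes are compared, after mirroring
across the mid-sagittal plane, with

    H_LR = max{ sup_{l∈ℒ} inf_{r∈ℛ} d(l,r),  sup_{r∈ℛ} inf_{l∈ℒ} d(l,r) }    (mm)
    S_LR = max{S_L, S_R} / min{S_L, S_R}                                      (≥ 1)

where d is the Euclidean metric and S_L, S_R are the mesh surface areas.
An S_LR above a configurable threshold flags the pair as asymmetric.

Because clinical head-CT cohorts for this task are private, the package
ships a first-class **phantom generator**: ball-and-socket joints with a
uniform gap g around a condyle of radius r, whose negative volume has the
closed form `(2/3)π[(r+g)³ − r³]`, plus two-sided "head" phantoms with a
controllable left–right asymmetry factor. Every pipeline stage is tested
against these analytic truths.

## Worked example

Extract the negative volumes of an asymmetric phantom pair (right joint gap
scaled by 1.2) from the ground-truth bone meshes and compare the sides:

```python
from negvol import (PhantomSpec, make_joint_phantom, negative_volume,
                    InflationParams, symmetry_report, SymmetryConfig)

spec = PhantomSpec(condyle_radius=6.0, gap=2.0, asymmetry_factor=1.2)
params = InflationParams(step=0.1, max_iters=60, laplacian_weight=0.2)
meshes = {}
for side in ("left", "right"):
    joint = make_joint_phantom(spec, side)
    neg, vol, area, _ = negative_volume(joint.mc_mesh, joint.tb_mesh, params,
                                        clip_plane=joint.clip_plane)
    meshes[side] = neg
    print(f"{side}: negative volume {vol:7.1f} mm^3  "
          f"(analytic {joint.analytic_negative_volume:7.1f})")

mid = meshes["left"].vertices[:, 0].mean()
report = symmetry_report(meshes["left"], meshes["right"],
                         SymmetryConfig(mid_plane=((mid, 0, 0), (1, 0, 0)),
                                        flag_threshold=1.042))
print(f"S_LR = {report.S_LR:.3f}   "
      f"H_LR = {report.H_LR_mean:.2f} +- {report.H_LR_sd:.2f} mm   "
      f"asymmetric: {report.asymmetric}")
```

prints

```
left: negative volume   610.6 mm^3  (analytic   619.9)
right: negative volume   759.9 mm^3  (analytic   789.0)
S_LR = 1.068   H_LR = 0.63 +- 0.01 mm   asymmetric: True
```

The inflated shells recover the closed-form joint-space volumes to a few
percent; the enlarged right gap raises the surface-area ratio well above a
symmetric pair's S_LR ≈ 1.00, so the pair is flagged.

## Command line

```bash
negvol phantom --n 10 --seed 1 --n-asymmetric 3 --out phantoms/
negvol train   --n 10 --seed 1 --out models/
negvol infer   --input phantoms/phantom_000/head.nii.gz --models models/ --out out/
negvol report  --left out/left_negative_volume.stl \
               --right out/right_negative_volume.stl --mid-x 27.0
```

`infer` runs the full pipeline (localize → segment → enhance → reconstruct
→ inflate/clip → symmetry report) and writes masks (NIfTI), meshes (STL),
the symmetry report (JSON) and a stage-timing log.

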