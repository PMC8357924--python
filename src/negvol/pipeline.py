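"""End-to-end pipeline orchestration.

preprocess -> localize -> crop VOIs -> segment condyle (A) and socket bone
(B) -> classical enhancement + heatmap fusion (C) -> slice-stack smoothing
and surface reconstruction (D) -> inflation, clipping and negative-volume
extraction (E) -> left-right symmetry report.

Every stage failure aborts with the stage name and a machine-readable code;
all randomness flows from the single config seed; each stage's saved
artifacts are sufficient inputs for the next stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .enhancement import EnhanceParams, classical_tb_mask, fuse_with_heatmap, smooth_stack
from .errors import ConfigError, NegvolError
from .inflation import (
    InflationParams,
    condyle_equator_from_mask,
    estimate_neck_clip_plane,
    negative_volume,
)
from .io_formats import (
    Mask,
    Volume,
    mask_to_mesh,
    minmax_normalize,
    read_volume,
    resample,
    write_mesh,
    write_volume,
)
from .localization import coarse_segment, crop_voi, extract_voi_boxes, postprocess_localization
from .nets import SegmentationModel
from .symmetry import SymmetryConfig, SymmetryReport, symmetry_report

logger = logging.getLogger("negvol")


class StageError(NegvolError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, cause: Exception):
        self.stage = stage
        self.code = code
        self.cause = cause
        super().__init__(f"stage {stage!r} failed [{code}]: {cause}")


@dataclass
class PipelineConfig:
    input_path: str | None = None
    output_dir: str = "negvol_out"
    seed: int = 0
    localization_shape: tuple[int, int, int] = (160, 160, 160)
    loc_model_path: str | None = None
    seg_model_path: str | None = None
    voi_margin_frac: float = 0.1
    patch_shape: tuple[int, int, int] | None = None  # center-crop VOIs when set
    smooth_target_pitch: float | None = None  # default: keep VOI pitch
    smooth_irregularity_mm: float | None = None  # default: in-plane spacing
    use_enhancement: bool = True
    clip_mode: str = "condyle-equator"  # or "neck", "manual"
    clip_planes: dict | None = None  # side -> (point, normal) for "manual"
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    inflation: InflationParams = field(default_factory=InflationParams)
    symmetry: SymmetryConfig = field(default_factory=SymmetryConfig)
    save_artifacts: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_cls, d, where):
            names = {f.name for f in dataclasses.fields(dc_cls)}
            unknown = set(d) - names
            if unknown:
                raise ConfigError(
                    f"unknown config keys in {where}: {sorted(unknown)}"
                )
            return d

        raw = dict(raw)
        sub = {}
        for key, dc_cls in (
            ("enhance", EnhanceParams),
            ("inflation", InflationParams),
            ("symmetry", SymmetryConfig),
        ):
            if key in raw:
                sub[key] = dc_cls(**build(dc_cls, raw.pop(key), key))
        build(cls, raw, "pipeline")
        for k in ("localization_shape", "patch_shape"):
            if raw.get(k) is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw, **sub)


def _stage(name: str, code: str):
    """Decorator-free stage wrapper: call fn inside, re-raise as StageError."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.seconds = time.perf_counter() - self.t0
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, code, exc) from exc
            return False

    return _Ctx()


def run_pipeline(
    cfg: PipelineConfig,
    volume: Volume | None = None,
    loc_model: SegmentationModel | None = None,
    seg_model: SegmentationModel | None = None,
) -> tuple[SymmetryReport, dict]:
    """Execute the full pipeline on one head volume.

    Inputs may be given in memory or through config paths.  Returns the
    symmetry report and a detail dict (per-side negative-volume meshes,
    masks, boxes, stage timings).  Artifacts (NIfTI masks, STL meshes, JSON
    report, JSONL timing log) are written to ``cfg.output_dir``.
    """
    timings = []
    out_dir = Path(cfg.output_dir)
    if cfg.save_artifacts:
        out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load", "E_IO") as t:
        if volume is None:
            if cfg.input_path is None:
                raise ConfigError("no input volume: set input_path or pass volume=")
            volume = read_volume(cfg.input_path)
        if loc_model is None:
            if cfg.loc_model_path is None:
                raise ConfigError("no localization model")
            loc_model = SegmentationModel.load(cfg.loc_model_path)
        if seg_model is None:
            if cfg.seg_model_path is None:
                raise ConfigError("no segmentation model")
            seg_model = SegmentationModel.load(cfg.seg_model_path)
    timings.append(("load", t.seconds))

    with _stage("preprocess", "E_PREPROC") as t:
        norm = minmax_normalize(volume)
    timings.append(("preprocess", t.seconds))

    with _stage("localize", "E_LOCALIZE") as t:
        low = resample(norm, cfg.localization_shape)
        prob = coarse_segment(low, loc_model)
        loc_mask = postprocess_localization(prob)
        box_l, box_r = extract_voi_boxes(
            loc_mask, margin_frac=cfg.voi_margin_frac, full_shape=norm.shape
        )
        boxes = {"left": box_l, "right": box_r}
    timings.append(("localize", t.seconds))

    detail: dict = {"boxes": boxes, "sides": {}}
    neg_meshes = {}
    for side in ("left", "right"):
        box = boxes[side]
        with _stage(f"segment_{side}", "E_SEGMENT") as t:
            voi = crop_voi(norm, box, patch_shape=cfg.patch_shape)
            probs = seg_model.predict_proba(voi.data)
            labels = probs.argmax(axis=0)
            mc_raw = labels == 1
            if not mc_raw.any():
                raise NegvolError("condyle segmentation is empty")
            # the condyle is a single bone: stray disconnected predictions
            # (usually at the VOI walls) are dropped
            cc, n_cc = ndimage.label(mc_raw)
            if n_cc > 1:
                sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=np.arange(1, n_cc + 1))
                mc_raw = cc == (1 + int(np.argmax(sizes)))
            mc_mask = Mask(mc_raw.astype(np.uint8), voi.spacing, voi.origin)
            tb_heat = Volume(probs[2], voi.spacing, voi.origin)
        timings.append((f"segment_{side}", t.seconds))

        with _stage(f"enhance_{side}", "E_ENHANCE") as t:
            if cfg.use_enhancement:
                classical = classical_tb_mask(voi, cfg.enhance)
                # the classical route segments all bone; fuse only its
                # socket-bone part using the network's fossa heatmap gate
                tb_mask = fuse_with_heatmap(
                    classical,
                    tb_heat,
                    tau=cfg.enhance.fuse_tau,
                    tau_core=cfg.enhance.fuse_tau_core,
                    dilate_radius=cfg.enhance.fuse_dilate_radius,
                )
            else:
                tb_mask = Mask((labels == 2).astype(np.uint8), voi.spacing, voi.origin)
            # a voxel cannot belong to both bones; the condyle label wins so
            # the inflation bound never overlaps the starting mesh
            tb_mask = Mask(
                (tb_mask.data.astype(bool) & ~mc_mask.data.astype(bool)).astype(np.uint8),
                voi.spacing,
                voi.origin,
            )
            if not tb_mask.data.any():
                raise NegvolError("socket-bone mask is empty")
        timings.append((f"enhance_{side}", t.seconds))

        with _stage(f"reconstruct_{side}", "E_RECON") as t:
            pitch = cfg.smooth_target_pitch or float(voi.spacing[2])
            irr = cfg.smooth_irregularity_mm or float(voi.spacing[:2].min())
            mc_smooth = smooth_stack(mc_mask, target_pitch=pitch, irregularity_mm=irr)
            tb_smooth = smooth_stack(tb_mask, target_pitch=pitch, irregularity_mm=irr)
            mc_mesh = mask_to_mesh(mc_smooth)
            tb_mesh = mask_to_mesh(tb_smooth)
        timings.append((f"reconstruct_{side}", t.seconds))

        with _stage(f"inflate_{side}", "E_INFLATE") as t:
            if cfg.clip_mode == "manual":
                if not cfg.clip_planes or side not in cfg.clip_planes:
                    raise ConfigError(f"clip_mode manual needs clip_planes[{side!r}]")
                clip = cfg.clip_planes[side]
            elif cfg.clip_mode == "neck":
                clip = estimate_neck_clip_plane(mc_mesh)
            elif cfg.clip_mode == "condyle-equator":
                toward = float(
                    tb_mesh.vertices.mean(axis=0)[2] - mc_mesh.vertices.mean(axis=0)[2]
                )
                clip = condyle_equator_from_mask(mc_mask, toward_sign=toward)
            else:
                raise ConfigError(f"unknown clip_mode {cfg.clip_mode!r}")
            inf_params = cfg.inflation
            if inf_params.max_initial_penetration is None:
                # contact noise between adjacent predicted masks scales with
                # the mask voxel, not with the SDF grid
                inf_params = dataclasses.replace(
                    inf_params, max_initial_penetration=float(np.max(voi.spacing))
                )
            neg, vol_mm3, area_mm2, trace = negative_volume(
                mc_mesh, tb_mesh, inf_params, clip_plane=clip
            )
            if vol_mm3 <= 0:
                raise NegvolError("negative volume is empty")
        timings.append((f"inflate_{side}", t.seconds))

        neg_meshes[side] = neg
        detail["sides"][side] = {
            "mc_mask": mc_mask,
            "tb_mask": tb_mask,
            "mc_mesh": mc_mesh,
            "tb_mesh": tb_mesh,
            "negative_mesh": neg,
            "negative_volume_mm3": vol_mm3,
            "negative_area_mm2": area_mm2,
            "clip_plane": tuple(np.asarray(x, dtype=float) for x in clip),
            "inflation_trace": trace,
        }
        if cfg.save_artifacts:
            write_volume(
                Volume(mc_mask.data, mc_mask.spacing, mc_mask.origin),
                out_dir / f"{side}_condyle_mask.nii.gz",
            )
            write_volume(
                Volume(tb_mask.data, tb_mask.spacing, tb_mask.origin),
                out_dir / f"{side}_socket_mask.nii.gz",
            )
            write_mesh(mc_mesh, out_dir / f"{side}_condyle.stl")
            write_mesh(tb_mesh, out_dir / f"{side}_socket.stl")
            write_mesh(neg, out_dir / f"{side}_negative_volume.stl")

    with _stage("symmetry", "E_SYMMETRY") as t:
        mid_x = volume.origin[0] + volume.shape[0] * volume.spacing[0] / 2.0
        sym_cfg = dataclasses.replace(
            cfg.symmetry,
            mid_plane=((mid_x, 0.0, 0.0), (1.0, 0.0, 0.0)),
            seed=cfg.seed,
        )
        report = symmetry_report(neg_meshes["left"], neg_meshes["right"], sym_cfg)
    timings.append(("symmetry", t.seconds))

    detail["timings_s"] = timings
    if cfg.save_artifacts:
        (out_dir / "symmetry_report.json").write_text(report.to_json(indent=2))
        (out_dir / "boxes.json").write_text(
            json.dumps({s: b.to_dict() for s, b in boxes.items()}, indent=2)
        )
        with open(out_dir / "timings.jsonl", "w") as fh:
            for name, sec in timings:
                fh.write(json.dumps({"stage": name, "seconds": sec}) + "\n")
    return report, detail
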