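"""End-to-end planning pipeline: volume -> mask -> tree -> path -> roadmap.

``run_plan`` chains every stage with a single flat configuration object and
writes all intermediate artifacts plus a provenance log (every parameter,
seed, and per-stage diagnostic).  ``run_phantom_demo`` exercises the whole
pipeline on a synthetic phantom with a lesion planted near a leaf.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import phantom as ph
from .instructions import encode_instructions, export_roadmap
from .planner import plan_path
from .segmentation import segment_airways, DEFAULT_SCALES_MM
from .skeleton import (build_skeleton_graph, direct_from_root, extend_leaf_tips,
                       prune_spurs, skeletonize)
from .tree import AirwayTree
from .volume import CTVolume, load_volume, save_nifti, voxel_from_world, world_from_voxel

__all__ = ["PlanConfig", "PipelineError", "run_plan", "run_phantom_demo"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PlanConfig:
    """Flat configuration mirrored by CLI flags; serializable to TOML."""

    scales_mm: tuple = DEFAULT_SCALES_MM
    tau: float | str = "auto"
    spur_min_length_mm: float = 3.0
    setback_mm: float = 5.0
    fov_deg: float = 120.0
    close_mm: float = 6.0
    merge_close: bool = False
    seed: int = 0
    formats: tuple = ("json", "txt")

    def __post_init__(self) -> None:
        for name in ("spur_min_length_mm", "setback_mm", "fov_deg", "close_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive")
        if not isinstance(self.tau, str) and self.tau <= 0:
            raise ValueError("tau must be positive or 'auto'")

    def to_file(self, path) -> None:
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            elif isinstance(v, (tuple, list)):
                items = ", ".join(f'"{x}"' if isinstance(x, str) else repr(float(x) if isinstance(x, float) else x)
                                  for x in v)
                lines.append(f"{k} = [{items}]")
            else:
                lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PlanConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        for key in ("scales_mm", "formats"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_plan(volume_path, lesion, config: PlanConfig | None = None,
             out_dir="plan_out") -> dict:
    """Execute load -> segment -> skeletonize/tree -> plan -> encode -> export.

    Returns a summary dict (artifact paths plus the provenance record).  Any
    stage failure raises :class:`PipelineError` carrying the stage name.
    """
    config = config or PlanConfig()
    out_dir = Path(out_dir)
    lesion = np.asarray(lesion, dtype=float).reshape(3)
    prov: dict = {"config": _config_record(config), "stages": {}}

    try:
        vol = load_volume(volume_path)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    ijk = voxel_from_world(vol, lesion)
    if np.any(ijk < -0.5) or np.any(ijk > np.asarray(vol.shape) - 0.5):
        raise PipelineError("load", f"lesion {lesion.tolist()} outside volume bounds")
    prov["stages"]["load"] = {"shape": list(vol.shape),
                              "spacing_mm": vol.spacing.tolist()}

    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        mask = segment_airways(vol, scales_mm=config.scales_mm, tau=config.tau)
    except Exception as exc:
        raise PipelineError("segment", str(exc)) from exc
    save_nifti(mask.mask, out_dir / "mask.nii.gz", affine=mask.affine)
    prov["stages"]["segment"] = {"voxels": int(mask.mask.sum()),
                                 "seed": list(mask.seed)}

    try:
        skel = skeletonize(mask)
        graph = build_skeleton_graph(skel, mask.affine)
        graph = extend_leaf_tips(graph, mask.mask, mask.affine)
        graph = prune_spurs(graph, config.spur_min_length_mm,
                            mask=mask.mask, affine=mask.affine)
        diag: dict = {}
        seed_world = world_from_voxel(vol, mask.seed)
        tree = direct_from_root(graph, seed_world, diagnostics=diag)
        tree.validate(endpoint_tol_mm=float(np.linalg.norm(vol.spacing)) * 2)
    except Exception as exc:
        raise PipelineError("tree", str(exc)) from exc
    tree.to_json(out_dir / "tree.json")
    prov["stages"]["tree"] = {"skeleton_voxels": int(len(skel.points)),
                              "nodes": len(tree), "leaves": len(tree.leaves()),
                              "discarded_edges": diag.get("discarded_edges", 0)}

    try:
        path = plan_path(tree, lesion)
    except Exception as exc:
        raise PipelineError("plan", str(exc)) from exc
    path.to_json(out_dir / "path.json")
    prov["stages"]["plan"] = {"segments": path.n,
                              "gap_mm": path.anchor.gap_mm,
                              "anchor_edge": list(path.anchor.edge)}

    try:
        roadmap = encode_instructions(path, tree, setback_mm=config.setback_mm,
                                      fov_deg=config.fov_deg,
                                      close_mm=config.close_mm,
                                      merge_close=config.merge_close)
        written = export_roadmap(roadmap, out_dir, formats=config.formats,
                                 allow_empty=True)
    except Exception as exc:
        raise PipelineError("roadmap", str(exc)) from exc
    prov["stages"]["roadmap"] = {"instructions": len(roadmap.instructions),
                                 "files": [p.name for p in written]}

    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=1))
    return {"out_dir": str(out_dir), "provenance": prov,
            "tree": tree, "path": path, "roadmap": roadmap}


def _config_record(config: PlanConfig) -> dict:
    d = asdict(config)
    d["scales_mm"] = list(d["scales_mm"])
    d["formats"] = list(d["formats"])
    return d


def run_phantom_demo(seed: int = 0, out_dir="demo_out", levels: int = 4,
                     shape=(128, 128, 128), noise_sd_hu: float = 0.0,
                     config: PlanConfig | None = None) -> dict:
    """Generate a phantom, plant a lesion near a random leaf, run the plan.

    Writes the volume, ground truth, mask, tree, path, and roadmap under
    ``out_dir`` and returns the run summary plus the ground-truth objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = ph.generate_phantom_spec(levels=levels, jitter_sd=3.0, seed=seed,
                                    noise_sd_hu=noise_sd_hu)
    vol = ph.rasterize_phantom(spec, shape=shape)
    truth = ph.truth_tree(spec)
    save_nifti(vol, out_dir / "volume.nii.gz")
    truth.to_json(out_dir / "truth.json")

    leaf_ids = truth.leaves()
    leaf = leaf_ids[int(rng.integers(len(leaf_ids)))]
    lesion = truth.nodes[leaf].point + rng.normal(0.0, 1.0, 3)

    config = config or PlanConfig(seed=seed)
    summary = run_plan(out_dir / "volume.nii.gz", lesion, config, out_dir)
    summary["spec"] = spec
    summary["truth"] = truth
    summary["lesion"] = lesion
    summary["true_leaf"] = leaf
    return summary
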