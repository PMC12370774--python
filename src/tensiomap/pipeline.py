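"""End-to-end orchestration: image -> masks -> platelets -> proximity -> stats.

``run_pipeline`` executes, per image: ratiometrics (Otsu masks, ratio
map, untensed density), tension-class masks (trained classifier or the
threshold baseline), CD31 detection + DAPI gating, per-platelet proximity,
and finally the across-image comparison of mean distances to stretched
vs. untensed fibers. Failures on individual images are quarantined and
reported, not fatal. The report contains no timestamps, so a rerun with
identical config and inputs reproduces it byte-for-byte; wall-clock
metadata lives only in the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ChannelMissingError, ConfigError, TensiomapError
from . import image_io
from .classifier import PixelClassifierModel, apply_classifier, threshold_baseline_masks
from .detection import DetectorConfig, GateConfig, detect_cd31_objects, gate_platelets
from .proximity import ContactRule, platelet_distances, summarize_proximity
from .ratiometrics import joint_mask, ratio_map, untensed_density
from .simulate import SceneParams, simulate_scene, write_scene
from .stats import compare_groups

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_fixture_suite"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    inputs: list
    channel_map: dict | None = None
    pixel_size_um: float | None = None
    n_bins: int = 256
    background: float = 0.0
    classifier: str = "threshold-baseline"  # or a model path
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    contact: ContactRule = field(default_factory=ContactRule)
    alpha: float = 0.05
    out_dir: str | None = None
    save_masks: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs:
            raise ConfigError("no input images")
        for p in self.inputs:
            if not Path(p).exists():
                raise ConfigError(f"input not found: {p}")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.classifier != "threshold-baseline" and not Path(self.classifier).exists():
            raise ConfigError(f"classifier model not found: {self.classifier}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = [str(p) for p in d["inputs"]]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("detector", DetectorConfig), ("gate", GateConfig), ("contact", ContactRule)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    version: str
    config: dict
    per_image: list
    pooled_proximity: dict | None
    comparison: dict | None
    warnings: list
    failed_images: list

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _analyze_one(img, cfg: RunConfig, model, out_dir: Path | None) -> tuple:
    """Single-image analysis; returns (report_entry, platelet_records_df)."""
    entry: dict = {"source": img.source_id, "warnings": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fn_mask, fnbpa5_mask, joint = joint_mask(img, cfg.n_bins)
        density = untensed_density(fn_mask, fnbpa5_mask)
        entry["density"] = dataclasses.asdict(density)
        fn_thr = float(img["FN"][fn_mask.grid].min()) if fn_mask.count else float("nan")
        rmap = ratio_map(img, joint, fn_thr, 0.0, background=cfg.background)

        if model is not None:
            untensed_mask, stretched_mask = apply_classifier(model, img, fn_mask)
        else:
            untensed_mask, stretched_mask = threshold_baseline_masks(img, fn_mask, cfg.n_bins)
        entry["untensed_mask_px"] = untensed_mask.count
        entry["stretched_mask_px"] = stretched_mask.count

        records = None
        try:
            objects, label_img = detect_cd31_objects(img, cfg.detector)
            gated = gate_platelets(objects, label_img, img, cfg.gate)
            platelets = gated[gated["is_platelet"]].reset_index(drop=True)
            entry["n_objects"] = int(len(gated))
            entry["n_platelets"] = int(len(platelets))
            if len(platelets):
                records = platelet_distances(
                    platelets, untensed_mask, stretched_mask, cfg.contact
                )
                summary = summarize_proximity(records).iloc[0].to_dict()
                summary.pop("group", None)
                entry["proximity"] = summary
            else:
                entry["proximity"] = None
        except ChannelMissingError as exc:
            entry["n_objects"] = None
            entry["n_platelets"] = None
            entry["proximity"] = None
            entry["warnings"].append(f"proximity stage skipped: {exc}")

        if out_dir is not None and cfg.save_masks:
            tables = {}
            if records is not None:
                tables["proximity_records"] = records
            image_io.write_outputs(
                out_dir,
                masks=[fn_mask, fnbpa5_mask, joint, untensed_mask, stretched_mask],
                tables=tables,
                maps={"ratio_map": rmap.grid},
            )
        entry["warnings"] += [str(w.message) for w in caught]
    return entry, records


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis over ``config.inputs``.

    Per-image failures are quarantined into ``failed_images``; the run
    only raises if the config is invalid or every image fails.
    """
    config.validate()
    model = None
    if config.classifier != "threshold-baseline":
        model = PixelClassifierModel.load(config.classifier)

    out_root = Path(config.out_dir) if config.out_dir else None
    if out_root:
        out_root.mkdir(parents=True, exist_ok=True)

    per_image, failed, all_records, run_warnings = [], [], [], []
    t0 = time.time()
    for path in config.inputs:
        stem = Path(path).parent.name + "_" + Path(path).stem
        try:
            img = image_io.read_image(
                path,
                channel_map=config.channel_map,
                pixel_size_um=config.pixel_size_um,
                require=("FN", "FNBPA5"),
            )
            entry, records = _analyze_one(
                img, config, model, (out_root / stem) if out_root else None
            )
            per_image.append(entry)
            if records is not None:
                records = records.copy()
                records["image"] = str(path)
                all_records.append(records)
        except TensiomapError as exc:
            failed.append({"source": str(path), "error": f"{type(exc).__name__}: {exc}"})
    if not per_image:
        raise TensiomapError(f"all {len(config.inputs)} input images failed analysis")

    pooled = None
    if all_records:
        pooled_df = pd.concat(all_records, ignore_index=True)
        pooled = summarize_proximity(pooled_df).iloc[0].to_dict()
        pooled.pop("group", None)

    comparison = None
    d_s = [e["proximity"]["mean_d_stretched_um"] for e in per_image if e.get("proximity")]
    d_u = [e["proximity"]["mean_d_untensed_um"] for e in per_image if e.get("proximity")]
    d_s = [v for v in d_s if v == v]
    d_u = [v for v in d_u if v == v]
    if len(d_s) >= 2 and len(d_u) >= 2:
        res = compare_groups(d_s, d_u, alpha=config.alpha)
        comparison = {
            "what": "per-image mean distance to stretched vs untensed fibers (um)",
            "test_name": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "stars": res.stars,
            "mean_stretched": res.mean_a,
            "mean_untensed": res.mean_b,
            "n_images": res.n_a,
        }

    report = RunReport(
        version=__version__,
        config=config.to_dict(),
        per_image=per_image,
        pooled_proximity=pooled,
        comparison=comparison,
        warnings=run_warnings,
        failed_images=failed,
    )
    if out_root:
        (out_root / "report.json").write_text(report.to_json())
        manifest = {
            "elapsed_s": time.time() - t0,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "n_images": len(per_image),
            "n_failed": len(failed),
        }
        (out_root / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


# ---------------------------------------------------------------------------
# versioned synthetic fixture suites

DENSITY_GRID = (0.1, 0.25, 0.4, 0.6, 0.8)
CONTACT_GRID = (0.2, 0.5, 0.8)
SEEDS_PER_POINT = 10


def _suite_scenes(preset: str) -> list:
    scenes = []
    if preset == "smoke":
        for j in range(3):
            scenes.append(
                {
                    "name": f"smoke_s{j}",
                    "grid": "smoke",
                    "params": SceneParams(
                        image_shape=(96, 96),
                        n_fibers=12,
                        fiber_length_px=50.0,
                        n_platelets=12,
                        n_nucleated=2,
                        seed=j,
                    ),
                }
            )
    elif preset == "acceptance":
        for i, f in enumerate(DENSITY_GRID):
            for j in range(SEEDS_PER_POINT):
                scenes.append(
                    {
                        "name": f"density_f{f:g}_s{j}",
                        "grid": "density",
                        "params": SceneParams(untensed_fraction=f, seed=10 * i + j),
                    }
                )
        for i, p in enumerate(CONTACT_GRID):
            for j in range(SEEDS_PER_POINT):
                scenes.append(
                    {
                        "name": f"contact_p{p:g}_s{j}",
                        "grid": "contact",
                        "params": SceneParams(contact_fraction=p, seed=500 + 10 * i + j),
                    }
                )
    else:
        raise ConfigError(f"unknown preset {preset!r} (smoke | acceptance)")
    return scenes


def make_fixture_suite(out_dir, preset: str = "smoke") -> dict:
    """Write a versioned synthetic test suite (scenes over fixed grids/seeds).

    Returns (and writes as ``suite_manifest.json``) a manifest listing
    every scene with its generating parameters and artifact paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for spec in _suite_scenes(preset):
        params: SceneParams = spec["params"]
        truth, img = simulate_scene(params)
        paths = write_scene(truth, img, out_dir / spec["name"])
        entries.append(
            {
                "name": spec["name"],
                "grid": spec["grid"],
                "untensed_fraction": params.untensed_fraction,
                "contact_fraction": params.contact_fraction,
                "offset_distance_um": params.offset_distance_um,
                "snr": params.snr,
                "seed": params.seed,
                "paths": paths,
            }
        )
    manifest = {"preset": preset, "version": __version__, "scenes": entries}
    (out_dir / "suite_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
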