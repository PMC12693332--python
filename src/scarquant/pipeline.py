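"""End-to-end pipeline: preprocess -> detect -> quantify -> report.

The pipeline consumes a co-registered BR/BL pair plus contour and
landmark files, runs one of the scar detectors, quantifies the result on
the AHA 16-segment and 100-chord geometries, and writes every
intermediate artifact together with a checksum manifest.  Given the same
configuration (and fixed timestamp, the default) the outputs are
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import imaging_io as io
from . import preprocess as pp
from . import quantify as q
from . import report as rep
from . import scar_detect as sd
from .imaging_io import BL, BR

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    br: str = ""
    bl: str = ""
    contours: str = ""
    landmarks: str = ""
    out_dir: str = "out"
    method: str = "otsu"
    max_deviation: float = 25.0
    seeds: Optional[dict] = None
    external_mask: Optional[str] = None
    normalize: bool = True
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    basal_first: bool = True
    patient_id: str = "anonymous"
    study_date: str = ""
    timestamp: Optional[str] = None  # None -> fixed epoch (deterministic)
    seed: int = 0

    def validate(self) -> None:
        if self.method not in ("otsu", "region_growing", "external"):
            raise ValueError(f"unknown detection method {self.method!r}")
        for name in ("br", "bl", "contours", "landmarks"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"input '{name}' missing or not found: {p!r}")
        if self.method == "external" and not self.external_mask:
            raise ValueError("method 'external' requires external_mask")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            doc = json.loads(text)
        else:
            doc = tomllib.loads(text)
        cfg = cls()
        flat = {}
        for key, val in doc.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        for key, val in flat.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "stretch_percentiles":
                val = (float(val[0]), float(val[1]))
            if key == "seeds" and val is not None:
                val = {int(k): (int(v[0]), int(v[1])) for k, v in val.items()}
            setattr(cfg, key, val)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def save(name: str, path: Path) -> None:
        artifacts[name] = {"path": str(path.relative_to(out)), "sha256": _sha256(path)}

    # --- ingest -----------------------------------------------------------
    try:
        br = io.read_stack(config.br, BR)
        bl = io.read_stack(config.bl, BL)
        pair = io.CoRegisteredPair(br, bl)
        contours = io.read_contours(config.contours)
        landmarks = io.read_landmarks(config.landmarks)
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    # --- preprocess -------------------------------------------------------
    try:
        bl_work = pp.normalize_255(bl, config.stretch_percentiles) if config.normalize else bl
        contours_bl = pp.propagate_mask(contours, br, bl)
        myo = io.rasterize_myocardium(contours_bl, bl.geometry)
        work_pair = io.CoRegisteredPair(br, bl_work)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    # --- detect -----------------------------------------------------------
    try:
        scar, cmap = sd.detect_scar(
            work_pair, myo, config.method,
            max_deviation=config.max_deviation,
            seeds=config.seeds,
            external_mask=config.external_mask,
        )
        io.write_mask(scar, out / "scar_mask.nii.gz")
        save("scar_mask", out / "scar_mask.nii.gz")
        detect_meta: dict = {"method": config.method}
        if cmap is not None:
            io.write_stack(io.ImageStack(cmap.labels.astype(np.uint16), bl.geometry, BL),
                           out / "class_map.nii.gz")
            save("class_map", out / "class_map.nii.gz")
            detect_meta["thresholds"] = list(cmap.thresholds.as_tuple())
        if config.method == "region_growing":
            detect_meta["max_deviation"] = config.max_deviation
        (out / "detection.json").write_text(json.dumps(detect_meta, indent=1, sort_keys=True))
        save("detection", out / "detection.json")
    except Exception as exc:
        raise PipelineError("detect", exc) from exc

    # --- quantify ---------------------------------------------------------
    try:
        levels = q.assign_levels(myo, basal_first=config.basal_first)
        segmap = q.build_segment_map(myo, contours_bl, landmarks, levels)
        extents = q.segment_extent(scar, segmap)
        chords = q.build_centerline_chords(contours_bl, landmarks, bl.geometry,
                                           slices=sorted(levels))
        profile = q.chord_transmurality(scar, chords, myo)
        metrics = q.global_metrics(myo, scar, profile, extents, bl.geometry)

        io.write_mask(io.MyocardiumMask(segmap.labels > 0, bl.geometry), out / "myocardium.nii.gz")
        save("myocardium", out / "myocardium.nii.gz")
        io.write_stack(io.ImageStack(segmap.labels.astype(np.uint16), bl.geometry, BL),
                       out / "segments.nii.gz")
        save("segments", out / "segments.nii.gz")
        pd.DataFrame(extents.to_rows()).to_csv(out / "extent_16.csv", index=False)
        save("extent_16", out / "extent_16.csv")
        rows = []
        for i in sorted(chords.chords):
            for k, ch in enumerate(chords.chords[i]):
                rows.append({
                    "slice": i, "chord": k, "angle_deg": ch.angle_deg,
                    "thickness_mm": ch.thickness_mm,
                    "transmurality": profile.values[i][k],
                })
        pd.DataFrame(rows).to_csv(out / "chords.csv", index=False)
        save("chords", out / "chords.csv")
        (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=1, sort_keys=True))
        save("metrics", out / "metrics.json")
    except Exception as exc:
        raise PipelineError("quantify", exc) from exc

    # --- report -----------------------------------------------------------
    try:
        rep.generate_report(
            {"id": config.patient_id, "study_date": config.study_date},
            metrics, extents, profile, out,
            provenance={"method": config.method,
                        "max_deviation": config.max_deviation if config.method == "region_growing" else None,
                        "software": f"scarquant {__version__}",
                        "seed": config.seed},
            timestamp=config.timestamp,
        )
        for name in ("report.json", "report.html", "bullseye_16.png", "bullseye_chords.png"):
            save(name.replace(".", "_"), out / name)
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    manifest = {"out_dir": str(out), "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
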