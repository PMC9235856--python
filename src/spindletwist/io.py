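"""Readers/writers and run configuration.

File formats
------------
* Stacks: multi-page grayscale TIFF (8/16-bit), axes (plane, row, col).
* Traces CSV: ``spindle_id, bundle_id, point_order, x_px, y_px, plane``.
* Poles CSV: ``spindle_id, pole_label (1|2), x_px, y_px, plane``.
* Config / ground truth / run records: JSON.

Calibration lives in the JSON config, not in TIFF tags: the axial
refractive-index correction has no standard TIFF representation, and a
single explicit config beats scattered metadata.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flow import FlowConfig, ImageStack
from .geometry import Calibration, PixelPoint
from .tracing import BundleTrace, ObliqueCircleFit, SpindleTwistSummary

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_traces",
    "read_poles",
    "write_traces",
    "write_poles",
    "bundle_table",
    "spindle_table",
]

TRACE_COLUMNS = ["spindle_id", "bundle_id", "point_order", "x_px", "y_px",
                 "plane"]
POLE_COLUMNS = ["spindle_id", "pole_label", "x_px", "y_px", "plane"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, JSON-serializable."""

    calibration: Calibration = field(default_factory=Calibration)
    flow: FlowConfig = field(default_factory=FlowConfig)
    rho_min_um: float = 0.25
    max_tilt_deg: float = 20.0
    weak_threshold: float = 1.0
    strong_threshold: float = 2.0
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "calibration" in d:
            d["calibration"] = Calibration(**d["calibration"])
        if "flow" in d:
            d["flow"] = FlowConfig(**d["flow"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def read_stack(
    path: str | Path, calibration: Calibration | None = None
) -> ImageStack:
    """Load a multi-page grayscale TIFF as an :class:`ImageStack`."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError(
            f"{path}: single-plane image; a stack needs >= 2 planes"
        )
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale z-stack (plane, row, col); "
            f"got shape {data.shape} (RGB/multichannel input is not "
            "supported - select one channel first)"
        )
    return ImageStack(data, calibration or Calibration())


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.data)


def write_traces(traces: list[BundleTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, p in enumerate(tr.points):
            rows.append(
                (tr.spindle_id, tr.bundle_id, i, p.x_px, p.y_px, p.plane)
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def write_poles(
    poles: tuple[PixelPoint, PixelPoint],
    path: str | Path,
    spindle_id: str = "synthetic",
) -> None:
    p1, p2 = poles
    pd.DataFrame(
        [
            (spindle_id, 1, p1.x_px, p1.y_px, p1.plane),
            (spindle_id, 2, p2.x_px, p2.y_px, p2.plane),
        ],
        columns=POLE_COLUMNS,
    ).to_csv(path, index=False)


def read_traces(path: str | Path) -> dict[str, list[BundleTrace]]:
    """Parse a traces CSV into per-spindle lists of bundle traces.

    Row-level validation errors name the offending bundle.
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[BundleTrace]] = {}
    for (sid, bid), grp in df.groupby(["spindle_id", "bundle_id"],
                                      sort=True):
        grp = grp.sort_values("point_order")
        if len(grp) < 3:
            raise ValueError(
                f"{path}: bundle {bid!r} of spindle {sid!r} has "
                f"{len(grp)} points; a trace needs >= 3"
            )
        pts = tuple(
            PixelPoint(x_px=r.x_px, y_px=r.y_px, plane=r.plane)
            for r in grp.itertuples()
        )
        out.setdefault(str(sid), []).append(
            BundleTrace(bundle_id=str(bid), points=pts, spindle_id=str(sid))
        )
    return out


def read_poles(path: str | Path) -> dict[str, tuple[PixelPoint, PixelPoint]]:
    df = pd.read_csv(path)
    missing = set(POLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, tuple[PixelPoint, PixelPoint]] = {}
    for sid, grp in df.groupby("spindle_id", sort=True):
        labels = sorted(grp["pole_label"].tolist())
        if labels != [1, 2]:
            raise ValueError(
                f"{path}: spindle {sid!r} needs exactly pole labels 1 and "
                f"2, got {labels}"
            )
        byl = {
            int(r.pole_label): PixelPoint(
                x_px=r.x_px, y_px=r.y_px, plane=r.plane
            )
            for r in grp.itertuples()
        }
        out[str(sid)] = (byl[1], byl[2])
    return out


def bundle_table(fits: list[ObliqueCircleFit]) -> pd.DataFrame:
    """Tidy per-bundle results table."""
    return pd.DataFrame(
        {
            "bundle_id": [f.bundle_id for f in fits],
            "twist_deg_per_um": [f.twist_deg_per_um for f in fits],
            "curvature_per_um": [f.curvature_per_um for f in fits],
            "contour_length_um": [f.contour_length_um for f in fits],
            "radius_um": [f.radius for f in fits],
            "beta_deg": [f.beta_deg for f in fits],
            "rho_mean_um": [f.rho_mean_um for f in fits],
            "flags": [";".join(f.flags) for f in fits],
        }
    )


def spindle_table(summaries: list[SpindleTwistSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spindle_id": [s.spindle_id for s in summaries],
            "mean_twist": [s.mean_twist for s in summaries],
            "sem": [s.sem for s in summaries],
            "n_bundles": [s.n_bundles for s in summaries],
            "class": [s.twist_class for s in summaries],
        }
    )
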