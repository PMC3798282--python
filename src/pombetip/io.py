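"""Readers and writers for contours, outlines, samples and metrics.

CSV files carry explicit headers and full float precision (round trips
are exact); metrics and manifests are JSON.  Decimal points are always
dots, independent of locale.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contour import MeridianContour
from .outline2d import CellOutline2D
from .stability import MTTipSample

__all__ = [
    "ContourFormatError",
    "write_contour",
    "read_contour",
    "contour_to_records",
    "contour_from_records",
    "write_outline",
    "read_outline",
    "write_mt_sample",
    "read_mt_sample",
    "write_metrics_json",
    "lineage_to_frame",
]

_FLOAT_FMT = "%.17g"


class ContourFormatError(ValueError):
    pass


def _write_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_contour(path, contour: MeridianContour) -> None:
    _write_csv(
        path,
        pd.DataFrame({"s": contour.s, "z": contour.z, "rho": contour.rho}),
    )


def read_contour(path, spacing: float | None = None) -> MeridianContour:
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("s", "z", "rho"):
        if col not in frame.columns:
            raise ContourFormatError(f"missing column {col!r} in {path}")
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    bad = frame[["z", "rho"]].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ContourFormatError(f"unparseable row at line {line} of {path}")
    z = frame["z"].to_numpy()
    rho = frame["rho"].to_numpy()
    if spacing is None:
        s = frame["s"].to_numpy()
        spacing = float(np.mean(np.diff(s)))
    return MeridianContour(z, rho, spacing)


def contour_to_records(contour: MeridianContour) -> list[dict]:
    return [
        {"s": float(s), "z": float(z), "rho": float(r)}
        for s, z, r in zip(contour.s, contour.z, contour.rho)
    ]


def contour_from_records(records: list[dict], spacing: float | None = None):
    z = np.array([r["z"] for r in records])
    rho = np.array([r["rho"] for r in records])
    if spacing is None:
        s = np.array([r["s"] for r in records])
        spacing = float(np.mean(np.diff(s)))
    return MeridianContour(z, rho, spacing)


def write_outline(path, outline: CellOutline2D) -> None:
    _write_csv(path, pd.DataFrame({"x": outline.x, "y": outline.y}))


def read_outline(path) -> CellOutline2D:
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("x", "y"):
        if col not in frame.columns:
            raise ContourFormatError(f"missing column {col!r} in {path}")
    return CellOutline2D(frame["x"].to_numpy(), frame["y"].to_numpy())


def write_mt_sample(path, sample: MTTipSample) -> None:
    n = sample.n_samples
    _write_csv(
        path,
        pd.DataFrame(
            {
                "position": sample.contact_positions,
                "diameter": np.full(n, sample.cell_diameter),
                "length": np.full(n, sample.cell_length),
                "seed": np.full(n, sample.seed, dtype=int),
            }
        ),
    )


def read_mt_sample(path) -> MTTipSample:
    frame = pd.read_csv(path, float_precision="round_trip")
    return MTTipSample(
        cell_diameter=float(frame["diameter"].iloc[0]),
        cell_length=float(frame["length"].iloc[0]),
        contact_positions=frame["position"].to_numpy(),
        seed=int(frame["seed"].iloc[0]),
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_metrics_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def lineage_to_frame(generations) -> pd.DataFrame:
    """Flatten simulate_lineage output to one row per tracked birth."""
    rows = []
    for gen_cells in generations:
        for cell in gen_cells:
            rows.append(
                dict(
                    generation=cell.generation,
                    birth_length=cell.birth_length,
                    birth_width=cell.birth_width,
                    n_segments=cell.seg_lengths.size,
                )
            )
    return pd.DataFrame(rows)
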