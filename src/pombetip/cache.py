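"""Cached steady tip profiles bridging the 3D and 2D models.

The 2D growth stencil is the cross-section of a steady 3D tip.  Steady
shapes are scale-free in the signal width, so profiles are computed once
at sigma = 1 per (Poisson ratio, signal family, shape) and rescaled on
use.  An optional on-disk cache (CSV + JSON) avoids recomputation across
processes; a corrupt cache entry triggers recomputation with a warning.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

from .contour import MeridianContour
from .evolve import TipMetrics, steady_state_tip
from .mechanics import WallMaterial
from .signal import GrowthSignal

__all__ = ["cache_tip_profile", "clear_memory_cache"]

_MEMORY: dict[tuple, tuple[MeridianContour, TipMetrics]] = {}


def _key(nu, family, shape_q, spacing_frac, tolerance):
    return (round(nu, 10), family, round(shape_q, 10), round(spacing_frac, 10), tolerance)


def clear_memory_cache() -> None:
    _MEMORY.clear()


def cache_tip_profile(
    nu: float = 0.5,
    family: str = "gaussian",
    shape_q: float = 2.0,
    spacing_frac: float = 1.0 / 40.0,
    tolerance: float = 1e-4,
    cache_dir: str | Path | None = None,
) -> tuple[MeridianContour, TipMetrics]:
    """Steady tip contour and metrics at sigma = 1 for the given material.

    Results are memoized in process and, if ``cache_dir`` is given, on
    disk.  Callers rescale the profile to any signal width.
    """
    key = _key(nu, family, shape_q, spacing_frac, tolerance)
    if key in _MEMORY:
        return _MEMORY[key]

    disk_base = None
    if cache_dir is not None:
        tag = "_".join(str(k).replace("/", "-") for k in key)
        disk_base = Path(cache_dir) / f"tip_{tag}"
        result = _load_disk(disk_base)
        if result is not None:
            _MEMORY[key] = result
            return result

    signal = GrowthSignal(family=family, sigma=1.0, shape_q=shape_q)
    material = WallMaterial(nu=nu)
    contour, metrics = steady_state_tip(
        signal, material, spacing=spacing_frac, tolerance=tolerance
    )
    _MEMORY[key] = (contour, metrics)
    if disk_base is not None:
        _store_disk(disk_base, contour, metrics)
    return contour, metrics


def _store_disk(base: Path, contour: MeridianContour, metrics: TipMetrics) -> None:
    from .io import write_contour, write_metrics_json

    base.parent.mkdir(parents=True, exist_ok=True)
    write_contour(base.with_suffix(".csv"), contour)
    payload = {"spacing": contour.spacing, "metrics": metrics}
    write_metrics_json(base.with_suffix(".json"), payload)


def _load_disk(base: Path):
    from .io import read_contour

    csv_path, json_path = base.with_suffix(".csv"), base.with_suffix(".json")
    if not (csv_path.exists() and json_path.exists()):
        return None
    try:
        meta = json.loads(json_path.read_text())
        contour = read_contour(csv_path, spacing=float(meta["spacing"]))
        metrics = TipMetrics(**meta["metrics"])
        return contour, metrics
    except Exception as err:  # corrupted cache: recompute
        warnings.warn(f"tip-profile cache at {base} unreadable ({err}); recomputing")
        return None
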