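"""Deterministic on-disk fixtures for tests and demos.

``make_fixture`` renders a small artifact (contour, outline, sample or
curve) from a :class:`FixtureSpec`; the same spec and seed always produce
byte-identical files, recorded alongside a JSON manifest.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contour import hemisphere_cap_contour
from .io import _FLOAT_FMT, write_contour, write_mt_sample, write_outline
from .outline2d import CellOutline2D, resegment_outline
from .stability import synth_mt_tips, synthetic_mt_unfocusing_curve

__all__ = ["FixtureSpec", "make_fixture"]

_KINDS = (
    "initial_meridian_contour",
    "spherocylinder_outline",
    "mt_tip_sample",
    "sigma_mt_curve",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _semicircle_spherocylinder(length: float, width: float, spacing: float):
    r = width / 2.0
    half = length / 2.0 - r
    th = np.linspace(-np.pi / 2, np.pi / 2, 40)
    right = np.column_stack([half + r * np.cos(th), r * np.sin(th)])
    left = np.column_stack([-half - r * np.cos(th), r * np.sin(th)])[::-1]
    top = np.column_stack([np.linspace(half, -half, 20)[1:-1], np.full(18, r)])
    bot = np.column_stack([np.linspace(-half, half, 20)[1:-1], np.full(18, -r)])
    pts = np.vstack([right, top, left, bot])
    outline = CellOutline2D(pts[:, 0], pts[:, 1])
    return resegment_outline(outline, spacing=spacing)


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write the fixture and its manifest; returns the artifact path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = dict(spec.params)
    path = out_dir / f"{spec.kind}.csv"
    if spec.kind == "initial_meridian_contour":
        contour = hemisphere_cap_contour(
            radius=p.get("radius", 1.2),
            spacing=p.get("spacing", 0.05),
            total_arc=p.get("total_arc", 8.0),
        )
        write_contour(path, contour)
    elif spec.kind == "spherocylinder_outline":
        outline = _semicircle_spherocylinder(
            length=p.get("length", 8.0),
            width=p.get("width", 3.2),
            spacing=p.get("spacing", 0.15),
        )
        write_outline(path, outline)
    elif spec.kind == "mt_tip_sample":
        sigma = p.get("sigma", 1.0)
        sample = synth_mt_tips(
            lambda w, L: sigma,
            cell_diameter=p.get("diameter", 3.2),
            cell_length=p.get("length", 8.0),
            n_samples=p.get("n_samples", 1000),
            seed=spec.seed,
        )
        write_mt_sample(path, sample)
    else:  # sigma_mt_curve
        w, s = synthetic_mt_unfocusing_curve(
            cell_length=p.get("cell_length", 8.0),
            sigma_floor=p.get("sigma_floor", 0.08),
            slope=p.get("slope", 0.05),
            spike_amplitude=p.get("spike_amplitude", 0.2),
        )
        pd.DataFrame({"diameter": w, "sigma_mt": s}).to_csv(
            path, index=False, float_format=_FLOAT_FMT
        )
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "spec": asdict(spec),
        "version": __version__,
        "sha256": digest,
    }
    (out_dir / f"{spec.kind}.manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    return path
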