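"""Synthetic tracked-cell tables and reference trajectories.

Generates inputs with the statistical structure the metrics pipeline and
control loop assume, so every module is testable without microscopy data.
The heading model is deliberately simple and analytically transparent: a
mobile cell's step heading is +x (or -x for negative bias) with probability
|b| and uniform on the circle otherwise, which makes the expected
instantaneous directedness exactly b.  Immobile cells receive sub-pixel
jitter.  Positions are in unitless pixels.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .loop import ReferenceTrajectory
from .tracks import TrackTable

__all__ = ["TrackGenSpec", "generate_tracks", "generate_reference", "make_fixture_suite"]


@dataclass(frozen=True)
class TrackGenSpec:
    """Parameters of the synthetic track generator.

    ``bias`` b in [-1, 1] shifts heading mass toward +x (or -x when
    negative); expected per-step directedness of a mobile cell equals b.
    ``step_length``/``step_dispersion`` give the mean and standard
    deviation of the per-step displacement in pixels (Gamma-distributed;
    dispersion 0 means a constant step).  ``immobile_fraction`` of the
    cells only jitter within ``jitter`` pixels.
    """

    n_cells: int = 100
    n_frames: int = 25
    frame_interval: float = 5.0
    step_length: float = 3.0
    step_dispersion: float = 1.0
    bias: float = 0.0
    immobile_fraction: float = 0.0
    jitter: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 2:
            raise ValueError("need n_cells >= 1 and n_frames >= 2")
        if not -1 <= self.bias <= 1:
            raise ValueError("bias must lie in [-1, 1]")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if self.step_length < 0 or self.step_dispersion < 0:
            raise ValueError("step_length and step_dispersion must be >= 0")


def _step_lengths(rng: np.random.Generator, spec: TrackGenSpec, n: int) -> np.ndarray:
    if spec.step_dispersion == 0 or spec.step_length == 0:
        return np.full(n, spec.step_length)
    shape = (spec.step_length / spec.step_dispersion) ** 2
    scale = spec.step_dispersion**2 / spec.step_length
    return rng.gamma(shape, scale, size=n)


def generate_tracks(spec: TrackGenSpec) -> TrackTable:
    """Biased random-walk tracks as a validated :class:`TrackTable`.

    The first ``round(immobile_fraction * n_cells)`` cells are immobile;
    the rest take ``n_frames - 1`` steps whose headings follow the mixture
    model described in the module docstring.  Deterministic under
    ``spec.seed``; cell streams are sub-seeded so changing ``n_cells``
    leaves earlier cells' tracks untouched.
    """
    n_immobile = int(round(spec.immobile_fraction * spec.n_cells))
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_cells)
    frames = np.arange(spec.n_frames)
    xs = np.empty((spec.n_cells, spec.n_frames))
    ys = np.empty((spec.n_cells, spec.n_frames))
    for cid, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        n_steps = spec.n_frames - 1
        if cid < n_immobile:
            xs[cid] = rng.uniform(-spec.jitter, spec.jitter, size=spec.n_frames)
            ys[cid] = rng.uniform(-spec.jitter, spec.jitter, size=spec.n_frames)
        else:
            aligned = rng.uniform(size=n_steps) < abs(spec.bias)
            theta = rng.uniform(0.0, 2.0 * math.pi, size=n_steps)
            theta[aligned] = 0.0 if spec.bias >= 0 else math.pi
            lengths = _step_lengths(rng, spec, n_steps)
            xs[cid, 0] = ys[cid, 0] = 0.0
            xs[cid, 1:] = np.cumsum(lengths * np.cos(theta))
            ys[cid, 1:] = np.cumsum(lengths * np.sin(theta))
    data = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(spec.n_cells), spec.n_frames),
            "frame": np.tile(frames, spec.n_cells),
            "x": xs.ravel(),
            "y": ys.ravel(),
        }
    )
    return TrackTable(
        data=data, frame_interval=spec.frame_interval, meta={"spec": spec}
    )


def generate_reference(
    kind: str,
    high: float,
    low: float | None = None,
    switch_step: int | None = None,
    horizon: int = 3600,
    observable: str = "directedness",
) -> ReferenceTrajectory:
    """Piecewise-constant reference: a one-switch square wave or a hold.

    ``square`` holds ``high`` for ``switch_step`` samples then ``low`` for
    the remainder (switch_step 0 degenerates to a constant at ``low``);
    ``hold`` is constant at ``high`` for the whole horizon.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if kind == "hold":
        r = np.full(horizon, float(high))
    elif kind == "square":
        if low is None or switch_step is None:
            raise ValueError("square reference needs low and switch_step")
        if not 0 <= switch_step <= horizon:
            raise ValueError("switch_step must lie in [0, horizon]")
        r = np.concatenate(
            [np.full(switch_step, float(high)), np.full(horizon - switch_step, float(low))]
        )
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    return ReferenceTrajectory(r=r, observable=observable)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir, seed: int = 11) -> dict[str, str]:
    """Write the canonical fixture files and return {filename: sha256}.

    Emits a hand-checkable 3-cell toy CSV, a biased-population CSV, the
    square-wave preset references, and a ``manifest.json`` listing every
    file with its checksum.  Deterministic for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # Toy 3-cell table with integer geometry; companion metrics computed by
    # hand live in the test suite that consumes this fixture.
    toy = pd.DataFrame(
        {
            "particle": [0] * 3 + [1] * 3 + [2] * 3,
            "frame": [0, 1, 2] * 3,
            "x": [0, 3, 6, 0, 0, 0, 0, -3, -6],
            "y": [0, 4, 8, 0, 0, 0, 0, 4, 8],
        }
    )
    toy.to_csv(out / "toy_tracks.csv", index=False)

    biased = generate_tracks(
        TrackGenSpec(n_cells=100, n_frames=25, bias=0.6, immobile_fraction=0.25,
                     seed=seed)
    )
    biased.to_csv(out / "biased_tracks.csv")

    for name, (high, low) in {"example1": (0.65, -0.65), "example2": (0.9, -0.9)}.items():
        ref = generate_reference("square", high, low, switch_step=1800, horizon=3600)
        pd.DataFrame({"step": np.arange(len(ref)), "r": ref.r}).to_csv(
            out / f"reference_{name}.csv", index=False
        )

    files = sorted(p.name for p in out.glob("*.csv"))
    manifest = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
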