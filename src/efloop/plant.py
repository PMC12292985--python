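"""Stochastic population model of cell directedness under an electric field.

The "plant" in the control loop: at each model time step every cell draws a
directedness value composed of a uniformly random motility term and a
field-induced bias, scaled by a logistic onset factor that represents the
delayed cellular response after field exposure, and clamped to the physical
range [-1, 1].  The population observable fed back to the controller is the
mean directedness (or the recruitment index) over ``n_cells`` independent
samples per step.

The published typesetting of the model equation collapses fractions, so the
exact placement of the bias-strength parameter ``s`` admits more than one
defensible reading.  :class:`PlantParams.composition` selects among them; see
``docs/methods.md`` for the rationale behind each and for which reading the
shipped closed-loop presets use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "COMPOSITIONS",
    "PlantParams",
    "Ensemble",
    "PlantSimulator",
    "saturation_exponent",
    "onset_factor",
    "bias_term",
    "clamp",
    "directedness_sample",
    "simulate_population",
    "mean_response",
    "calibrate",
]

#: Recognised readings of the model equation's ambiguous ``s`` placement.
#:
#: ``prefactor_s``      d = onset * (nu*s) * [noise + bias]
#: ``prefactor_inv_s``  d = onset * (nu/s) * [noise + bias]
#: ``bias_inv_s``       d = onset * [noise + (nu/s) * bias]
#:
#: with noise = 2*rand - 1 and bias = EF/s + sign(EF)*s*|EF|^p/(|EF|^p + 1).
COMPOSITIONS = ("prefactor_s", "prefactor_inv_s", "bias_inv_s")


@dataclass(frozen=True)
class PlantParams:
    """Parameters of the stochastic directedness model.

    Attributes
    ----------
    s : float
        Bias-strength parameter (dimensionless, default 3): how strongly a
        small field biases motion along the field axis.
    tau : float
        Response-delay parameter in model time steps (default 4); midpoint
        of the logistic onset factor.
    nu : int
        Direction flag in {-1, +1}: whether the population biases with or
        against the field axis.  Population-level constant.
    ef_max : float
        Magnitude bound on the applied field, V/cm (default 4).
    composition : str
        Reading of the ambiguous ``s`` placement; one of ``COMPOSITIONS``.
    onset_from_start : bool
        If True (default) the onset clock runs from the start of the run;
        the model does not restart its delay when the field changes sign.
    """

    s: float = 3.0
    tau: float = 4.0
    nu: int = 1
    ef_max: float = 4.0
    composition: str = "prefactor_s"
    onset_from_start: bool = True

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"bias strength s must be > 0, got {self.s}")
        if self.nu not in (-1, 1):
            raise ValueError(f"direction flag nu must be -1 or +1, got {self.nu}")
        if self.ef_max <= 0:
            raise ValueError(f"ef_max must be > 0, got {self.ef_max}")
        if self.composition not in COMPOSITIONS:
            raise ValueError(
                f"unknown composition {self.composition!r}; expected one of {COMPOSITIONS}"
            )


@dataclass
class Ensemble:
    """Matrix of directedness samples for a simulated cell population.

    ``data`` has shape (n_cells, n_steps); ``ef`` is the applied field at
    each step; ``seed`` is the RNG seed the ensemble was generated from.
    """

    data: np.ndarray
    ef: np.ndarray
    seed: int | None = None
    t0: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ef = np.asarray(self.ef, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ensemble data must be 2-D (cells x steps)")
        if self.data.shape[1] != self.ef.shape[0]:
            raise ValueError(
                f"ensemble has {self.data.shape[1]} steps but {self.ef.shape[0]} EF values"
            )

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_steps(self) -> int:
        return self.data.shape[1]


def saturation_exponent(ef: float) -> float:
    """Exponent p that saturates the influence of an increasing field.

    p = 1 when the field is off, 1/|EF| otherwise, so the saturating term
    |EF|^p/(|EF|^p + 1) approaches a plateau rather than growing without
    bound as the field strengthens.
    """
    if not math.isfinite(ef):
        raise ValueError(f"EF must be finite, got {ef}")
    if ef == 0.0:
        return 1.0
    return 1.0 / abs(ef)


def onset_factor(t: float, tau: float) -> float:
    """Logistic onset of the cellular response, 1/(1 + exp(-(t - tau))).

    Strictly increasing in t; equals 0.5 at t = tau and approaches 1 for
    t >> tau.  Models the delay before cells respond to a newly applied
    field.
    """
    return 1.0 / (1.0 + math.exp(-(t - tau)))


def bias_term(ef: float, params: PlantParams) -> float:
    """Field-induced bias EF/s + sign(EF)*s*|EF|^p/(|EF|^p + 1).

    Odd in EF and zero at EF = 0.  The first addend grows linearly with the
    field; the second saturates (via the exponent p) toward s as |EF| grows.
    """
    if ef == 0.0:
        return 0.0
    p = saturation_exponent(ef)
    a = abs(ef) ** p
    return ef / params.s + math.copysign(1.0, ef) * params.s * a / (a + 1.0)


def clamp(d_raw):
    """Restrict directedness to the physical range [-1, 1]."""
    return np.minimum(np.maximum(d_raw, -1.0), 1.0)


def _raw_sample(noise, ef: float, t: float, params: PlantParams):
    """Unclamped directedness for noise values in [-1, 1] (vectorised)."""
    on = onset_factor(t, params.tau)
    b = bias_term(ef, params)
    if params.composition == "prefactor_s":
        return on * params.nu * params.s * (noise + b)
    if params.composition == "prefactor_inv_s":
        return on * (params.nu / params.s) * (noise + b)
    # bias_inv_s: unscaled motility noise, direction/strength on the bias only
    return on * (noise + (params.nu / params.s) * b)


def directedness_sample(
    t: float,
    ef: float,
    params: PlantParams,
    rng: np.random.Generator | None = None,
    u: float | None = None,
) -> float:
    """One cell's directedness at model time t under field ef.

    The motility noise is 2u - 1 with u ~ Uniform(0, 1) drawn from ``rng``;
    pass ``u`` explicitly to pin the noise (used in deterministic tests).
    The raw value is clamped to [-1, 1].
    """
    if u is None:
        if rng is None:
            raise ValueError("provide either a seeded rng or an explicit u")
        u = rng.uniform()
    noise = 2.0 * u - 1.0
    return float(clamp(_raw_sample(noise, ef, t, params)))


def _cell_rngs(seed: int, n_cells: int) -> list[np.random.Generator]:
    """Per-cell generators from stable sub-seeding.

    Child streams are spawned from one SeedSequence so that increasing
    ``n_cells`` extends the ensemble without reshuffling the draws of
    already-existing cells.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n_cells)]


class PlantSimulator:
    """Stepwise interface to the population model for closed-loop use.

    Pre-draws each cell's uniform noise stream for up to ``max_steps`` steps
    (the noise is independent of the applied field, so this is identical to
    drawing per step) and advances one model time step per :meth:`step` call.
    Model time starts at ``t = 1`` on the first step.
    """

    def __init__(
        self,
        params: PlantParams,
        n_cells: int,
        seed: int,
        max_steps: int,
    ) -> None:
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.params = params
        self.n_cells = n_cells
        self.seed = seed
        # (n_cells, max_steps) uniforms; row i is cell i's private stream.
        self._u = np.empty((n_cells, max_steps))
        for i, rng in enumerate(_cell_rngs(seed, n_cells)):
            self._u[i] = rng.uniform(size=max_steps)
        self._t = 0

    @property
    def t(self) -> int:
        """Model time of the most recent step (0 before the first step)."""
        return self._t

    def step(self, ef: float) -> np.ndarray:
        """Advance one model step at field ``ef``; return per-cell directedness."""
        if abs(ef) > self.params.ef_max + 1e-12:
            raise ValueError(
                f"|EF| = {abs(ef):.4g} exceeds ef_max = {self.params.ef_max}; "
                "saturate the control signal before applying it"
            )
        if self._t >= self._u.shape[1]:
            raise RuntimeError("PlantSimulator exhausted its pre-drawn noise stream")
        noise = 2.0 * self._u[:, self._t] - 1.0
        self._t += 1
        return clamp(_raw_sample(noise, ef, float(self._t), self.params))


def simulate_population(
    ef_sequence: Sequence[float],
    n_cells: int,
    params: PlantParams,
    seed: int,
) -> Ensemble:
    """Simulate ``n_cells`` independent cells over a prescribed EF sequence.

    Each cell draws fresh noise at every step (no within-cell temporal
    autocorrelation).  Reproducible: the same seed yields a bit-identical
    ensemble, and cell i's draws do not depend on n_cells.
    """
    ef = np.asarray(ef_sequence, dtype=float)
    sim = PlantSimulator(params, n_cells, seed, max_steps=len(ef))
    data = np.column_stack([sim.step(e) for e in ef]) if len(ef) else np.empty((n_cells, 0))
    return Ensemble(data=data, ef=ef, seed=seed)


def mean_response(ensemble: Ensemble):
    """Per-step mean, sample std (ddof=1), and 95% CI half-width.

    The half-width is the normal approximation 1.96 * std / sqrt(n).
    """
    mean = ensemble.data.mean(axis=0)
    if ensemble.n_cells > 1:
        std = ensemble.data.std(axis=0, ddof=1)
    else:
        std = np.zeros(ensemble.n_steps)
    ci = 1.96 * std / math.sqrt(ensemble.n_cells)
    return mean, std, ci


def calibrate(
    observed: dict[float, np.ndarray],
    s_grid: Sequence[float],
    tau_grid: Sequence[float],
    base_params: PlantParams | None = None,
    n_cells: int = 2000,
    seed: int = 0,
) -> tuple[PlantParams, float]:
    """Grid-search (s, tau) against observed mean-directedness series.

    ``observed`` maps a constant EF value to the mean-directedness series
    measured under that field.  For every grid point the model is simulated
    at large ``n_cells`` with a fixed seed (matched across grid points so
    the comparison is noise-paired) and the summed squared error between the
    simulated and observed mean series is accumulated over all EF values.
    Returns the best-fitting parameter set and its loss.  Note an EF = 0
    series carries no information about s; ties are broken by grid order.
    """
    if base_params is None:
        base_params = PlantParams()
    best: tuple[PlantParams, float] | None = None
    for s in s_grid:
        for tau in tau_grid:
            params = PlantParams(
                s=float(s),
                tau=float(tau),
                nu=base_params.nu,
                ef_max=base_params.ef_max,
                composition=base_params.composition,
                onset_from_start=base_params.onset_from_start,
            )
            loss = 0.0
            for ef_value, series in observed.items():
                series = np.asarray(series, dtype=float)
                ens = simulate_population(
                    np.full(len(series), float(ef_value)), n_cells, params, seed
                )
                mean, _, _ = mean_response(ens)
                loss += float(np.sum((mean - series) ** 2))
            if best is None or loss < best[1]:
                best = (params, loss)
    assert best is not None, "empty calibration grid"
    return best
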