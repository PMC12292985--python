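"""Adaptive RBF-network controller, projection anti-windup, and PID baseline.

The controller is a single hidden layer of Gaussian radial-basis units with
a linear output: u(z) = sum_i W_i * exp(-||z - c_i||^2 / beta_i^2).  Weights
adapt online by gradient descent on the squared tracking error.  When the
commanded output exceeds the actuator bounds the standard update law keeps
integrating the error and the weights wind up; the projected update law adds
a term that restrains weight growth in the saturated regime so the command
returns promptly to the admissible range when the reference changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RBFNetwork",
    "UpdateConfig",
    "PIDState",
    "center_grid",
    "init_network",
    "activations",
    "control_output",
    "saturate",
    "update_standard",
    "update_projected",
    "build_regressor",
    "dump_network",
    "load_network",
    "pid_step",
    "ef_from_current",
    "REGRESSOR_SCHEMES",
]


@dataclass
class RBFNetwork:
    """Gaussian RBF network state: centers (M, N), widths, and weights (M,).

    ``beta`` may be a scalar shared by all neurons (the usual configuration)
    or a length-M vector of per-neuron widths.
    """

    centers: np.ndarray
    beta: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.beta = np.broadcast_to(
            np.asarray(self.beta, dtype=float), (self.centers.shape[0],)
        ).copy()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.centers.shape[0] != self.weights.shape[0]:
            raise ValueError(
                f"{self.centers.shape[0]} centers but {self.weights.shape[0]} weights"
            )
        if np.any(self.beta <= 0):
            raise ValueError("all widths beta must be > 0")

    @property
    def m(self) -> int:
        """Number of hidden neurons."""
        return self.centers.shape[0]

    @property
    def n(self) -> int:
        """Input dimension."""
        return self.centers.shape[1]


@dataclass(frozen=True)
class UpdateConfig:
    """Learning-rate and bound configuration for the weight-update laws.

    gamma is the unsaturated learning rate; gamma_a/alpha_a act when the raw
    command exceeds UL, gamma_b/alpha_b when it falls below LL.  Ts is the
    sampling time in seconds.  ``projection`` selects the reading of the
    projection term: "vector" applies the shared scalar (W^T Phi)/||W|| to
    every weight (default); "per_weight" uses each weight's own
    W_i^2 Phi_i / |W_i| instead.
    """

    gamma: float
    gamma_a: float = 0.0
    gamma_b: float = 0.0
    alpha_a: float = 0.0
    alpha_b: float = 0.0
    UL: float = np.inf
    LL: float = -np.inf
    Ts: float = 1.0
    projection: str = "vector"

    def __post_init__(self) -> None:
        for name in ("gamma", "gamma_a", "gamma_b", "alpha_a", "alpha_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.LL < self.UL:
            raise ValueError(f"need LL < UL, got [{self.LL}, {self.UL}]")
        if self.Ts <= 0:
            raise ValueError("Ts must be > 0")
        if self.projection not in ("vector", "per_weight"):
            raise ValueError(f"unknown projection mode {self.projection!r}")


@dataclass
class PIDState:
    """Positional-form PID state.

    Integral clamping (anti-windup) is off by default, mirroring the
    windup-prone baseline the adaptive controller is compared against.
    """

    kp: float
    ki: float = 0.0
    kd: float = 0.0
    integral: float = 0.0
    prev_error: float = 0.0
    integral_limit: float | None = None


def center_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Arithmetic grid lo, lo+step, ..., hi inclusive (endpoint-safe)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def init_network(
    m: int,
    n: int,
    center_levels: np.ndarray,
    weight_scale: float,
    rng: np.random.Generator,
    beta: float = 1.0,
) -> RBFNetwork:
    """Build an RBF network with centers c_i = l_i * (1, ..., 1).

    ``center_levels`` is the arithmetic grid l of length M; each center is a
    constant vector at its level.  Weights are independent uniform draws on
    [0, weight_scale] (one draw per weight), so ``weight_scale = 0`` gives
    an exactly-zero initial network.
    """
    levels = np.asarray(center_levels, dtype=float)
    if levels.shape[0] != m:
        raise ValueError(f"center grid has {levels.shape[0]} levels, expected M = {m}")
    centers = np.repeat(levels[:, None], n, axis=1)
    weights = weight_scale * rng.uniform(size=m) if weight_scale else np.zeros(m)
    return RBFNetwork(centers=centers, beta=np.full(m, beta), weights=weights)


def activations(z: np.ndarray, net: RBFNetwork) -> np.ndarray:
    """Gaussian activations Phi_i = exp(-||z - c_i||^2 / beta_i^2)."""
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != net.n:
        raise ValueError(f"regressor has dimension {z.shape[0]}, network expects {net.n}")
    d2 = np.sum((net.centers - z) ** 2, axis=1)
    return np.exp(-d2 / net.beta**2)


def control_output(net: RBFNetwork, phi: np.ndarray) -> float:
    """Network output u = sum_i W_i Phi_i."""
    return float(net.weights @ phi)


def saturate(u_raw: float, LL: float, UL: float) -> float:
    """Clip the command to the actuator range [LL, UL]; idempotent."""
    return float(min(max(u_raw, LL), UL))


def update_standard(net: RBFNetwork, e: float, phi: np.ndarray, cfg: UpdateConfig) -> None:
    """Gradient update W_i <- W_i + gamma * e * Phi_i (in place)."""
    net.weights += cfg.gamma * e * phi


def _projection_term(net: RBFNetwork, phi: np.ndarray, u_raw: float) -> np.ndarray:
    """The restraining direction W * (W^T Phi)/||W|| (or per-weight variant)."""
    if np.any(~np.isfinite(net.weights)):
        raise FloatingPointError("non-finite weights entering projected update")
    norm = float(np.linalg.norm(net.weights))
    # u_raw = W^T Phi = 0 lies inside any LL < 0 < UL, so a saturated branch
    # with all-zero weights is unreachable; guard against it regardless.
    assert norm > 0.0, "saturated update branch reached with zero weight vector"
    return net.weights * (u_raw / norm)


def _projection_term_per_weight(net: RBFNetwork, phi: np.ndarray) -> np.ndarray:
    """Per-coordinate reading W_i^2 Phi_i / |W_i| = |W_i| * sign-consistent."""
    out = np.zeros_like(net.weights)
    nz = net.weights != 0.0
    out[nz] = net.weights[nz] ** 2 * phi[nz] / np.abs(net.weights[nz])
    return out


def update_projected(
    net: RBFNetwork,
    e: float,
    phi: np.ndarray,
    u_raw: float,
    cfg: UpdateConfig,
) -> None:
    """Projection-operator update law (in place).

    Branches on the *unsaturated* command u_raw: when it exceeds UL (or
    undershoots LL) the learning rate switches to gamma_a (gamma_b) and a
    restraining term proportional to alpha_a (alpha_b) pushes the weight
    vector back along itself, scaled by the shared factor (W^T Phi)/||W||.
    Inside the bounds the update is identical to the standard law.
    sign(0) = 0: a zero error applies no projection push.
    """
    sgn = float(np.sign(e))
    if u_raw > cfg.UL:
        if cfg.projection == "vector":
            proj = _projection_term(net, phi, u_raw)
        else:
            proj = _projection_term_per_weight(net, phi)
        net.weights += cfg.gamma_a * e * phi - sgn * cfg.alpha_a * proj * e
    elif u_raw < cfg.LL:
        if cfg.projection == "vector":
            proj = _projection_term(net, phi, u_raw)
        else:
            proj = _projection_term_per_weight(net, phi)
        net.weights += cfg.gamma_b * e * phi + sgn * cfg.alpha_b * proj * e
    else:
        net.weights += cfg.gamma * e * phi


#: Regressor layouts: each entry is a list of (series, lag) pairs, where
#: series "r" is the reference and "y" the plant output, and lag k means
#: the value k samples before the current one (lag 0 = current sample).
REGRESSOR_SCHEMES: dict[str, list[tuple[str, int]]] = {
    # z(n) = [r(n), y(n-1), y(n-2), y(n-3), y(n-4), y(n-5)]
    "r_y5": [("r", 0), ("y", 1), ("y", 2), ("y", 3), ("y", 4), ("y", 5)],
    # z(n) = [r(n), y(n-1), r(n-1), y(n-2), r(n-2), y(n-3)]
    "ry_interleaved": [("r", 0), ("y", 1), ("r", 1), ("y", 2), ("r", 2), ("y", 3)],
}


def build_regressor(
    ref_history: list[float] | np.ndarray,
    out_history: list[float] | np.ndarray,
    scheme: str = "r_y5",
    scale: float = 1.0,
    offset: float = 0.0,
) -> np.ndarray:
    """Assemble the network input z(n) from reference and output history.

    Histories are ordered oldest-first.  ``ref_history`` ends at the
    current reference sample r(n); ``out_history`` ends at the most recent
    measured output y(n-1) (the current output does not exist yet when the
    command is computed).  Lags not yet available at run start are padded
    with 0.  The assembled vector is mapped affinely, ``scale * z +
    offset``, onto the network's center span before use: the directedness
    presets use scale 1 with offset +1 (directedness in [-1, 1] lands
    exactly on the [0, 2] center grid), the recruitment-index preset scales
    percent-range signals down onto its [-5, 5] grid.
    """
    layout = REGRESSOR_SCHEMES[scheme]
    series = {"r": np.asarray(ref_history, dtype=float),
              "y": np.asarray(out_history, dtype=float)}
    z = np.zeros(len(layout))
    for k, (name, lag) in enumerate(layout):
        arr = series[name]
        # r's last element has lag 0, y's last element has lag 1
        idx = arr.shape[0] - lag - (1 if name == "r" else 0)
        if idx >= 0:
            z[k] = arr[idx]
    return scale * z + offset


def pid_step(state: PIDState, e: float, Ts: float) -> float:
    """Positional PID: u = kp*e + ki*I + kd*(e - e_prev)/Ts, I <- I + e*Ts.

    Returns the raw (unsaturated) command and mutates ``state``.  If
    ``integral_limit`` is set the accumulator is clamped to +/- that value;
    by default it is unbounded (windup-prone, as in the baseline).
    """
    state.integral += e * Ts
    if state.integral_limit is not None:
        lim = abs(state.integral_limit)
        state.integral = min(max(state.integral, -lim), lim)
    u = state.kp * e + state.ki * state.integral + state.kd * (e - state.prev_error) / Ts
    state.prev_error = e
    return float(u)


def dump_network(net: RBFNetwork, path) -> None:
    """Write the network state as CSV (neuron,center_1..center_N,beta,weight)."""
    import pandas as pd

    cols = {f"center_{j + 1}": net.centers[:, j] for j in range(net.n)}
    df = pd.DataFrame({"neuron": np.arange(net.m), **cols,
                       "beta": net.beta, "weight": net.weights})
    # %.17g guarantees the float64 state round-trips exactly through text
    df.to_csv(path, index=False, float_format="%.17g")


def load_network(path) -> RBFNetwork:
    """Rebuild an :class:`RBFNetwork` from a state dump written by dump_network."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    center_cols = sorted(
        (c for c in df.columns if c.startswith("center_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return RBFNetwork(
        centers=df[center_cols].to_numpy(),
        beta=df["beta"].to_numpy(),
        weights=df["weight"].to_numpy(),
    )


def ef_from_current(current: float, cross_section: float, conductivity: float) -> float:
    """Uniform-field estimate EF = I / (A * sigma) for an Ohmic medium.

    current in amperes, cross_section in cm^2, conductivity in S/cm;
    returns V/cm.  Linear in the current.
    """
    if cross_section <= 0 or conductivity <= 0:
        raise ValueError("cross_section and conductivity must be > 0")
    return current / (cross_section * conductivity)
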