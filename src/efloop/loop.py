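"""Closed-loop reference tracking: controller + stochastic plant + metrics.

One control sample drives one plant step: the controller reads the current
reference and the recent plant outputs, emits a command, the command is
clipped to the actuator range and applied as the field strength, the plant
returns the population observable (mean directedness or recruitment index
over the simulated cells), and the tracking error updates the controller.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
import numpy as np
import pandas as pd

from . import control as ctl
from .plant import PlantParams, PlantSimulator

__all__ = [
    "ReferenceTrajectory",
    "RunResult",
    "MetricsReport",
    "NNControllerSpec",
    "PIDControllerSpec",
    "run_simulation",
    "tracking_metrics",
    "normalized_metrics",
    "fall_time",
    "compare_controllers",
    "metrics_report",
]

RUN_COLUMNS = ["step", "time_s", "r", "y", "u_raw", "u_sat", "e", "w_norm"]


@dataclass(frozen=True)
class ReferenceTrajectory:
    """A per-step target series for the plant observable.

    ``observable`` is "directedness" (targets in [-1, 1]) or
    "recruitment_index" (targets in percent, [-100, 100]).
    """

    r: np.ndarray
    observable: str = "directedness"

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if self.observable not in ("directedness", "recruitment_index"):
            raise ValueError(f"unknown observable {self.observable!r}")
        bound = 1.0 if self.observable == "directedness" else 100.0
        if np.any(np.abs(self.r) > bound):
            raise ValueError(f"reference exceeds |r| <= {bound} for {self.observable}")

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class RunResult:
    """Time-indexed record of one closed-loop run."""

    data: pd.DataFrame
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RUN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"RunResult missing columns {missing}")

    @property
    def Ts(self) -> float:
        return float(self.meta.get("Ts", 1.0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "RunResult":
        return cls(data=pd.read_csv(path), meta=meta)


@dataclass(frozen=True)
class NNControllerSpec:
    """Everything needed to build the adaptive RBF controller for a run."""

    cfg: ctl.UpdateConfig
    law: str = "projected"  # "projected" | "standard"
    m: int = 201
    n: int = 6
    center_lo: float = 0.0
    center_hi: float = 2.0
    center_step: float = 0.01
    beta: float = 1.0
    weight_scale: float = 1e-4
    regressor_scheme: str = "r_y5"
    regressor_scale: float = 1.0
    regressor_offset: float = 0.0

    def build(self, rng: np.random.Generator) -> ctl.RBFNetwork:
        levels = ctl.center_grid(self.center_lo, self.center_hi, self.center_step)
        return ctl.init_network(self.m, self.n, levels, self.weight_scale, rng,
                                beta=self.beta)


@dataclass(frozen=True)
class PIDControllerSpec:
    """PID baseline configuration."""

    kp: float
    ki: float = 0.0
    kd: float = 0.0
    UL: float = math.inf
    LL: float = -math.inf
    Ts: float = 1.0
    integral_limit: float | None = None


def _observable(samples: np.ndarray, kind: str, ri_threshold: float = 0.01) -> float:
    """Population observable from one step's per-cell directedness values."""
    if kind == "directedness":
        return float(samples.mean())
    above = int(np.sum(samples > ri_threshold))
    below = int(np.sum(samples < -ri_threshold))
    return (above - below) / samples.size * 100.0


def _config_hash(*parts) -> str:
    blob = json.dumps([repr(p) for p in parts], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_simulation(
    plant_params: PlantParams,
    controller_spec: NNControllerSpec | PIDControllerSpec,
    reference: ReferenceTrajectory,
    n_cells: int = 100,
    seed: int = 0,
    current_to_ef: tuple[float, float] | None = None,
    preset_name: str = "",
) -> RunResult:
    """Run one closed-loop reference-tracking experiment.

    Per step: build the regressor from the current reference and the output
    history, compute the raw command, clip it to the actuator bounds, apply
    it to the plant (one plant step, ``n_cells`` fresh samples), read the
    population observable, and update the controller with e = r - y.

    ``current_to_ef`` = (cross_section_cm2, conductivity_S_per_cm) declares
    that the actuator variable is a current in amperes; the clipped command
    is converted to a field via the Ohmic relation before driving the plant.
    The controller's RNG stream (weight init) is derived from ``seed`` and
    is independent of the plant noise.
    """
    horizon = len(reference)
    if horizon < 1:
        raise ValueError("reference trajectory is empty")
    is_pid = isinstance(controller_spec, PIDControllerSpec)
    Ts = controller_spec.Ts if is_pid else controller_spec.cfg.Ts
    LL = controller_spec.LL if is_pid else controller_spec.cfg.LL
    UL = controller_spec.UL if is_pid else controller_spec.cfg.UL

    ss = np.random.SeedSequence(seed)
    plant_seed_seq, ctrl_seed_seq = ss.spawn(2)
    plant_seed = int(plant_seed_seq.generate_state(1)[0] % (2**31))
    sim = PlantSimulator(plant_params, n_cells, plant_seed, max_steps=horizon)

    if is_pid:
        pid = ctl.PIDState(kp=controller_spec.kp, ki=controller_spec.ki,
                           kd=controller_spec.kd,
                           integral_limit=controller_spec.integral_limit)
        net = None
    else:
        if controller_spec.law not in ("projected", "standard"):
            raise ValueError(f"unknown update law {controller_spec.law!r}")
        net = controller_spec.build(np.random.Generator(np.random.PCG64(ctrl_seed_seq)))

    r = reference.r
    y_hist: list[float] = []
    rows = np.empty((horizon, len(RUN_COLUMNS)))
    e_prev = 0.0
    for k in range(horizon):
        if is_pid:
            # PID acts on the previous step's error (no measurement yet at k=0)
            u_raw = ctl.pid_step(pid, e_prev, Ts)
            phi = None
        else:
            z = ctl.build_regressor(r[: k + 1], y_hist,
                                    scheme=controller_spec.regressor_scheme,
                                    scale=controller_spec.regressor_scale,
                                    offset=controller_spec.regressor_offset)
            phi = ctl.activations(z, net)
            u_raw = ctl.control_output(net, phi)
        u_sat = ctl.saturate(u_raw, LL, UL)
        ef = (
            ctl.ef_from_current(u_sat, *current_to_ef)
            if current_to_ef is not None
            else u_sat
        )
        samples = sim.step(ef)
        y = _observable(samples, reference.observable)
        e = r[k] - y
        if not (math.isfinite(u_raw) and math.isfinite(y)):
            raise FloatingPointError(
                f"non-finite quantity at step {k}: u_raw={u_raw}, y={y}"
            )
        if is_pid:
            e_prev = e
            w_norm = 0.0
        else:
            if controller_spec.law == "projected":
                ctl.update_projected(net, e, phi, u_raw, controller_spec.cfg)
            else:
                ctl.update_standard(net, e, phi, controller_spec.cfg)
            w_norm = float(np.linalg.norm(net.weights))
        y_hist.append(y)
        rows[k] = (k, k * Ts, r[k], y, u_raw, u_sat, e, w_norm)

    data = pd.DataFrame(rows, columns=RUN_COLUMNS)
    meta = {
        "seed": seed,
        "preset": preset_name,
        "Ts": Ts,
        "LL": LL,
        "UL": UL,
        "n_cells": n_cells,
        "law": "pid" if is_pid else controller_spec.law,
        "observable": reference.observable,
        "config_hash": _config_hash(plant_params, controller_spec),
    }
    return RunResult(data=data, meta=meta)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

MAPE_EPS = 1e-9


def tracking_metrics(run: RunResult) -> tuple[float, float, float]:
    """(MSE, RMSE, MAPE%) of the tracking error e = r - y.

    MAPE averages |e/r| * 100 over the steps where |r| exceeds a small
    guard (MAPE_EPS) to avoid division by a zero reference.
    """
    e = run.data["e"].to_numpy()
    r = run.data["r"].to_numpy()
    mse = float(np.mean(e**2))
    ok = np.abs(r) > MAPE_EPS
    mape = float(np.mean(np.abs(e[ok] / r[ok])) * 100.0) if ok.any() else math.nan
    return mse, math.sqrt(mse), mape


def normalized_metrics(run: RunResult) -> tuple[float, float, float]:
    """(nMSE, nRMSE, nMAPE): dimensionless variants of the error metrics.

    nMSE = sum(e^2)/sum(r^2) and nRMSE its square root, so a controller
    that never moves the plant (y = 0) scores nMSE = 1 exactly.  nMAPE is
    MAPE divided by the MAPE of that same zero-output controller (which is
    100%), keeping all three equal to 1 for the do-nothing baseline.
    """
    e = run.data["e"].to_numpy()
    r = run.data["r"].to_numpy()
    denom = float(np.sum(r**2))
    if denom == 0.0:
        return math.nan, math.nan, math.nan
    nmse = float(np.sum(e**2)) / denom
    _, _, mape = tracking_metrics(run)
    return nmse, math.sqrt(nmse), mape / 100.0


def fall_time(
    run: RunResult,
    upper_frac: float = 0.9,
    lower_frac: float = 0.1,
    plateau_window: float = 0.1,
) -> float:
    """Minutes for the output pulse to fall from its peak to its lowest value.

    Locates the reference's single high->low transition and measures the
    descent of y between its pre-switch plateau (mean of y over the last
    ``plateau_window`` fraction of the high phase) and its own post-switch
    floor (mean of y over the last ``plateau_window`` fraction of the low
    phase): the time between the first post-switch samples at which y has
    descended to ``upper_frac`` and ``lower_frac`` of that span.  Using the
    output's own floor rather than the reference target keeps the metric
    defined when the target is unattainable (the saturated examples).  A
    one-sample drop is reported as one sampling period.  Returns NaN (with
    no exception) if the output never reaches the lower threshold.
    """
    r = run.data["r"].to_numpy()
    y = run.data["y"].to_numpy()
    drops = np.nonzero(np.diff(r) < 0)[0]
    if drops.size == 0:
        raise ValueError("reference has no high->low switch")
    switch = int(drops[0]) + 1  # first index at the low value
    n_floor = max(1, int(round(plateau_window * (len(y) - switch))))
    low = float(np.mean(y[-n_floor:]))
    n_plateau = max(1, int(round(plateau_window * switch)))
    plateau = float(np.mean(y[switch - n_plateau : switch]))
    span = plateau - low
    if span <= 0:
        return math.nan
    hi_level = low + upper_frac * span
    lo_level = low + lower_frac * span
    post = y[switch:]
    below_hi = np.nonzero(post <= hi_level)[0]
    if below_hi.size == 0:
        return math.nan
    t_hi = int(below_hi[0])
    below_lo = np.nonzero(post[t_hi:] <= lo_level)[0]
    if below_lo.size == 0:
        return math.nan
    steps = max(int(below_lo[0]), 1)
    return steps * run.Ts / 60.0


def improvement(old: float, new: float) -> float:
    """Percentage improvement (old - new)/old * 100; positive = new better."""
    return (old - new) / old * 100.0


def metrics_report(run: RunResult, with_fall_time: bool = True) -> dict[str, float]:
    """All scalar metrics for one run, as a plain dict."""
    mse, rmse, mape = tracking_metrics(run)
    nmse, nrmse, nmape = normalized_metrics(run)
    out = {
        "mse": mse, "rmse": rmse, "mape": mape,
        "nmse": nmse, "nrmse": nrmse, "nmape": nmape,
    }
    if with_fall_time:
        try:
            out["fall_time_min"] = fall_time(run)
        except ValueError:
            out["fall_time_min"] = math.nan
    return out


@dataclass
class MetricsReport:
    """Per-run metrics plus pairwise improvement rows, as DataFrames."""

    per_run: pd.DataFrame
    improvements: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_run.to_csv(path, index=False)


def compare_controllers(results: dict[str, RunResult]) -> MetricsReport:
    """Tabulate metrics for several runs and pairwise improvements.

    Improvements are reported for every ordered pair (old, new) in the
    order the runs are given: improvement% = (metric_old - metric_new) /
    metric_old * 100, so positive numbers mean the ``new`` run is better.
    """
    rows = []
    for name, run in results.items():
        rows.append({"run": name, **metrics_report(run)})
    per_run = pd.DataFrame(rows).set_index("run")

    imp_rows = []
    names = list(results)
    for i, old in enumerate(names):
        for new in names[i + 1 :]:
            row = {"old": old, "new": new}
            for metric in ("mse", "rmse", "mape", "fall_time_min"):
                o, n = per_run.loc[old, metric], per_run.loc[new, metric]
                row[metric] = improvement(o, n) if o and not math.isnan(o) else math.nan
            imp_rows.append(row)
    improvements = pd.DataFrame(imp_rows)
    return MetricsReport(per_run=per_run.reset_index(), improvements=improvements)
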