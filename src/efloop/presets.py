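"""Shipped experiment presets and the TOML config loader.

Presets mirror the published parameter tables: three in-silico examples
(directedness tracking against the stochastic plant, EF bounds +/-4 V/cm)
and the in-vitro-shaped configurations (recruitment-index tracking with a
current actuator bounded at +/-0.95 mA).  Config files live in
``efloop/configs/`` and can be copied and edited; ``load_config`` accepts
any path to a file with the same structure.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import loop
from .control import UpdateConfig
from .loop import NNControllerSpec, PIDControllerSpec, ReferenceTrajectory, RunResult
from .plant import PlantParams
from .synth import generate_reference

__all__ = ["PRESET_NAMES", "load_config", "build_preset", "run_preset", "Preset"]

PRESET_NAMES = ("example1", "example2", "example3", "invitro_nn", "invitro_pid")


@dataclass
class Preset:
    """A fully-specified closed-loop experiment ready to run."""

    name: str
    plant: PlantParams
    reference: ReferenceTrajectory
    nn: NNControllerSpec | None
    pid: PIDControllerSpec | None
    n_cells: int
    compare_laws: bool
    current_to_ef: tuple[float, float] | None = None

    def controller(self, law: str) -> NNControllerSpec | PIDControllerSpec:
        if law == "pid":
            if self.pid is None:
                raise ValueError(f"preset {self.name} has no PID controller block")
            return self.pid
        if self.nn is None:
            raise ValueError(f"preset {self.name} has no NN controller block")
        return NNControllerSpec(
            **{**self.nn.__dict__, "law": law}  # dataclass is frozen; rebuild
        )


def _config_path(name: str):
    return resources.files("efloop.configs").joinpath(f"{name}.toml")


def load_config(source) -> dict:
    """Parse a preset TOML file (path or shipped preset name)."""
    if isinstance(source, str) and source in PRESET_NAMES:
        with _config_path(source).open("rb") as fh:
            return tomllib.load(fh)
    with open(Path(source), "rb") as fh:
        return tomllib.load(fh)


def build_preset(source, horizon: int | None = None, n_cells: int | None = None) -> Preset:
    """Materialise a :class:`Preset` from a config file or shipped name.

    ``horizon`` and ``n_cells`` override the config's run block (used to
    scale experiments down in tests).
    """
    cfg = load_config(source)
    name = cfg.get("name", str(source))
    run = cfg.get("run", {})
    horizon = horizon or int(run.get("horizon", 3600))
    n_cells = n_cells or int(run.get("n_cells", 100))

    plant = PlantParams(**cfg.get("plant", {}))

    ref_cfg = cfg["reference"]
    switch = ref_cfg.get("switch_step")
    if switch is None and ref_cfg.get("kind") == "square":
        switch = horizon // 2
    reference = generate_reference(
        kind=ref_cfg.get("kind", "square"),
        high=ref_cfg["high"],
        low=ref_cfg.get("low"),
        switch_step=switch,
        horizon=horizon,
        observable=ref_cfg.get("observable", "directedness"),
    )

    nn = None
    if "nn" in cfg.get("controller", {}):
        c = dict(cfg["controller"]["nn"])
        update = UpdateConfig(
            gamma=c.pop("gamma"),
            gamma_a=c.pop("gamma_a", 0.0),
            gamma_b=c.pop("gamma_b", 0.0),
            alpha_a=c.pop("alpha_a", 0.0),
            alpha_b=c.pop("alpha_b", 0.0),
            UL=c.pop("UL"),
            LL=c.pop("LL"),
            Ts=c.pop("Ts", 1.0),
            projection=c.pop("projection", "vector"),
        )
        nn = NNControllerSpec(cfg=update, **c)

    pid = None
    if "pid" in cfg.get("controller", {}):
        pid = PIDControllerSpec(**cfg["controller"]["pid"])

    actuator = cfg.get("actuator")
    current_to_ef = None
    if actuator is not None:
        current_to_ef = (actuator["cross_section_cm2"], actuator["conductivity_S_per_cm"])

    return Preset(
        name=name,
        plant=plant,
        reference=reference,
        nn=nn,
        pid=pid,
        n_cells=n_cells,
        compare_laws=bool(run.get("compare_laws", nn is not None)),
        current_to_ef=current_to_ef,
    )


def run_preset(
    name: str,
    seed: int = 0,
    horizon: int | None = None,
    n_cells: int | None = None,
    laws: tuple[str, ...] | None = None,
) -> tuple[dict[str, RunResult], loop.MetricsReport]:
    """Run a shipped preset and evaluate it.

    For presets that compare the two NN update laws, both are run on the
    same seed (identical plant noise and weight initialisation) unless
    ``laws`` narrows the selection.  Returns the runs keyed by law plus a
    metrics report mirroring the error/fall-time table layout.
    """
    preset = build_preset(name, horizon=horizon, n_cells=n_cells)
    if laws is None:
        if preset.pid is not None and preset.nn is None:
            laws = ("pid",)
        elif preset.compare_laws:
            laws = ("standard", "projected")
        else:
            laws = ("projected",)
    results: dict[str, RunResult] = {}
    for law in laws:
        results[law] = loop.run_simulation(
            preset.plant,
            preset.controller(law),
            preset.reference,
            n_cells=preset.n_cells,
            seed=seed,
            current_to_ef=preset.current_to_ef,
            preset_name=preset.name,
        )
    return results, loop.compare_controllers(results)
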