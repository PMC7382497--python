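"""Run configuration, validation and scenario presets.

A run config bundles the model parameters, the initial state, the engine
choice, the horizon, and an intervention schedule.  Configs can be built
in code, loaded from YAML/JSON, or taken from the named presets that
encode the standard scenarios (fitness-neutral drive, full/partial
sterility drives, imperfect homing, forced-fraction and phase scans,
and ten-yearly cull/release management programmes).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from .interventions import Intervention, InterventionSchedule
from .model_core import QUEEN_CLASSES, ModelParams, PopulationState

ENGINES = ("deterministic", "stochastic")
KINDS = ("simulate", "phase_scan", "forced_fraction")

#: Initial-state sentinel: start from the wild-type equilibrium density.
WT_EQUILIBRIUM = "wt-equilibrium"


@dataclass
class RunConfig:
    """A fully specified, validated model run."""

    params: ModelParams = field(default_factory=ModelParams)
    initial: str | dict[str, float] = WT_EQUILIBRIUM
    engine: str = "deterministic"
    kind: str = "simulate"
    generations: int = 50
    replicates: int = 1
    seed: int = 0
    schedule: InterventionSchedule = field(default_factory=InterventionSchedule)
    scan: dict[str, Any] = field(default_factory=dict)
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}, got {self.engine!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.initial, dict):
            unknown = set(self.initial) - set(QUEEN_CLASSES) - {"z"}
            if unknown:
                raise ValueError(f"unknown initial-state keys: {sorted(unknown)}")
        elif self.initial != WT_EQUILIBRIUM:
            raise ValueError(
                f"initial must be {WT_EQUILIBRIUM!r} or a class-density mapping"
            )

    def initial_state(self) -> PopulationState:
        """Materialise the configured initial summer census."""
        from .analysis import wt_equilibrium

        if self.initial == WT_EQUILIBRIUM:
            return PopulationState.wild_type(wt_equilibrium(self.params))
        assert isinstance(self.initial, dict)
        return PopulationState(
            **{k: float(v) for k, v in self.initial.items() if k in QUEEN_CLASSES},
            z=float(self.initial.get("z", 1.0)),
        )

    def to_metadata(self) -> dict[str, Any]:
        """JSON-serialisable record sufficient to reproduce the run."""
        return {
            "params": dataclasses.asdict(self.params),
            "initial": self.initial,
            "engine": self.engine,
            "kind": self.kind,
            "generations": self.generations,
            "replicates": self.replicates,
            "seed": self.seed,
            "schedule": [dataclasses.asdict(ev) for ev in self.schedule.events],
            "scan": self.scan,
            "preset": self.preset,
        }


_TOP_KEYS = {
    "params",
    "initial",
    "engine",
    "kind",
    "generations",
    "replicates",
    "seed",
    "schedule",
    "scan",
    "preset",
}
_EVENT_KEYS = {"kind", "magnitude", "generation", "period", "start", "target_class"}


def _build_schedule(raw: Any) -> InterventionSchedule:
    if raw is None:
        return InterventionSchedule()
    if not isinstance(raw, list):
        raise ValueError("schedule must be a list of event mappings")
    events = []
    for i, item in enumerate(raw):
        if not isinstance(item, dict):
            raise ValueError(f"schedule entry {i} must be a mapping")
        unknown = set(item) - _EVENT_KEYS
        if unknown:
            raise ValueError(f"schedule entry {i}: unknown keys {sorted(unknown)}")
        events.append(Intervention(**item))
    return InterventionSchedule(tuple(events))


def config_from_dict(raw: dict[str, Any] | None) -> RunConfig:
    """Build a validated RunConfig from parsed YAML/JSON data.

    Unknown keys are rejected by name; parameter values are validated
    against the model invariants; unspecified parameters take the
    published default values (m=2.5, s=0.02, n=1500, λ=560, b=0,
    release density 100).
    """
    raw = dict(raw or {})
    if base := raw.pop("preset", None):
        cfg = preset(base)
        base_dict = cfg.to_metadata()
    else:
        base_dict = None

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    params_raw = raw.pop("params", {}) or {}
    if not isinstance(params_raw, dict):
        raise ValueError("params must be a mapping")
    param_fields = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(params_raw) - param_fields
    if unknown:
        raise ValueError(f"unknown params keys: {sorted(unknown)}")

    if base_dict is not None:
        merged_params = {**base_dict["params"], **params_raw}
        kwargs: dict[str, Any] = {
            "initial": base_dict["initial"],
            "engine": base_dict["engine"],
            "kind": base_dict["kind"],
            "generations": base_dict["generations"],
            "replicates": base_dict["replicates"],
            "seed": base_dict["seed"],
            "scan": base_dict["scan"],
            "preset": base,
        }
        schedule = (
            _build_schedule(raw.pop("schedule"))
            if "schedule" in raw
            else _build_schedule(base_dict["schedule"])
        )
    else:
        merged_params = params_raw
        kwargs = {}
        schedule = _build_schedule(raw.pop("schedule", None))

    kwargs.update(raw)
    return RunConfig(params=ModelParams(**merged_params), schedule=schedule, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping at the top level")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _one_off(params: ModelParams, generations: int = 50) -> RunConfig:
    return RunConfig(
        params=params,
        generations=generations,
        schedule=InterventionSchedule.one_off_release(params.release_density),
    )


def _ten_yearly(
    params: ModelParams,
    cull: bool,
    release: bool,
    generations: int = 100,
) -> RunConfig:
    schedule = InterventionSchedule()
    if cull:
        schedule = schedule + InterventionSchedule.repeated_cull(0.95, period=10)
    if release:
        schedule = schedule + InterventionSchedule.repeated_release(
            params.release_density, period=10
        )
    return RunConfig(params=params, generations=generations, schedule=schedule)


def _fig3a() -> RunConfig:
    return RunConfig(
        params=ModelParams(h=1.0, p=1.0),
        kind="forced_fraction",
        scan={"fraction_step": 0.01, "m_values": [1.0, 2.5, 5.0]},
    )


def _fig3b() -> RunConfig:
    return RunConfig(
        params=ModelParams(h=1.0, p=1.0),
        kind="forced_fraction",
        scan={"fraction_step": 0.01, "b_values": [0.0, 0.5, 1.0, 2.0]},
    )


def _fig4a() -> RunConfig:
    return RunConfig(
        params=ModelParams(h=1.0, p=0.5),
        kind="phase_scan",
        generations=500,
        scan={"h_step": 0.01, "p_step": 0.01},
    )


_PRESET_BUILDERS: dict[str, Callable[[], RunConfig]] = {
    # One-off release scenarios: drive variants.
    "fig2a": lambda: _one_off(ModelParams(h=0.0, p=1.0)),  # plain sterility gene
    "fig2b": lambda: _one_off(ModelParams(h=1.0, p=0.0)),  # fitness-neutral drive
    "fig2c": lambda: _one_off(ModelParams(h=1.0, p=1.0)),  # full-sterility drive
    "fig2d": lambda: _one_off(ModelParams(h=1.0, p=0.3)),  # partial sterility
    "fig2e": lambda: _one_off(ModelParams(h=0.8, p=0.0)),  # imperfect homing
    "fig2f": lambda: _one_off(ModelParams(h=0.8, p=1.0)),
    "fig2g": lambda: _one_off(ModelParams(h=0.8, p=0.3)),
    # Forced carrier-fraction suppression curves.
    "fig3a": _fig3a,
    "fig3b": _fig3b,
    # Partial-sterility phase behaviour and combined management.
    "fig4a": _fig4a,
    "fig4b": lambda: _ten_yearly(
        ModelParams(h=0.8, p=0.9), cull=True, release=True
    ),
    "fig4b-once": lambda: _one_off(ModelParams(h=0.8, p=0.9), generations=100),
    "fig4b-cull-once": lambda: RunConfig(
        params=ModelParams(h=0.8, p=0.9),
        generations=100,
        schedule=InterventionSchedule(
            (
                Intervention("cull", 0.95, generation=0),
                Intervention("release", 100.0, generation=0),
            )
        ),
    ),
    "fig4b-repeat": lambda: _ten_yearly(
        ModelParams(h=0.8, p=0.9), cull=False, release=True
    ),
    "fig4b-cull-repeat": lambda: _ten_yearly(
        ModelParams(h=0.8, p=0.9), cull=True, release=True
    ),
    # Ten-yearly management programmes (complete drone sterility construct).
    "fig5a": lambda: _ten_yearly(ModelParams(h=1.0, p=1.0), cull=True, release=False),
    "fig5b": lambda: _ten_yearly(ModelParams(h=1.0, p=1.0), cull=False, release=True),
    "fig5c": lambda: _ten_yearly(ModelParams(h=1.0, p=1.0), cull=True, release=True),
    "fig5d": lambda: _ten_yearly(ModelParams(h=0.8, p=1.0), cull=True, release=True),
    "fig5e": lambda: _ten_yearly(ModelParams(h=0.95, p=1.0), cull=True, release=True),
}


def preset_names() -> list[str]:
    return sorted(_PRESET_BUILDERS)


def preset(name: str) -> RunConfig:
    """Return the RunConfig for a named scenario preset."""
    try:
        builder = _PRESET_BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    cfg = builder()
    cfg.preset = name
    return cfg
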