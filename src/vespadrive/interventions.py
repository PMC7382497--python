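"""Timed management events: carrier-queen releases and population culls.

Events can be one-off (``generation``) or repeating (``period``/``start``),
and are unrolled against a horizon by :func:`expand_schedule`.  Within a
single time index culls are applied before releases, so queens released
"immediately following" a cull are not themselves poisoned.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

from .model_core import QUEEN_CLASSES, PopulationState

if TYPE_CHECKING:  # pragma: no cover
    pass

RELEASE = "release"
CULL = "cull"
#: Default class for released queens: homozygous carriers already fertilised
#: by wild-type drones.  With complete drone sterility (p = 1) this is the
#: only release class whose nests produce gynes, letting the construct
#: persist after release.
DEFAULT_RELEASE_CLASS = "q_ii_w"


@dataclass(frozen=True)
class Intervention:
    """A single management event.

    ``magnitude`` is queens km⁻² for a release and the kill fraction in
    [0, 1] for a cull.  Exactly one of ``generation`` (one-off) or
    ``period`` (repeat every ``period`` generations from ``start``) must
    be given.
    """

    kind: str
    magnitude: float
    generation: int | None = None
    period: int | None = None
    start: int = 0
    target_class: str = DEFAULT_RELEASE_CLASS

    def __post_init__(self) -> None:
        if self.kind not in (RELEASE, CULL):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.kind == CULL and self.magnitude > 1:
            raise ValueError("cull kill fraction must lie in [0, 1]")
        if (self.generation is None) == (self.period is None):
            raise ValueError("give exactly one of 'generation' or 'period'")
        if self.generation is not None and self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.period is not None and self.period < 1:
            raise ValueError("period must be >= 1")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.kind == RELEASE and self.target_class not in QUEEN_CLASSES:
            raise ValueError(
                f"unknown release class {self.target_class!r}; "
                f"expected one of {QUEEN_CLASSES}"
            )

    def occurrences(self, horizon: int) -> list[int]:
        """Time indices (0-based from the trajectory start) up to horizon."""
        if self.generation is not None:
            return [self.generation] if self.generation <= horizon else []
        assert self.period is not None
        return list(range(self.start, horizon + 1, self.period))

    def __str__(self) -> str:  # compact event tag for trajectory tables
        if self.kind == RELEASE:
            return f"release:{self.magnitude:g}@{self.target_class}"
        return f"cull:{self.magnitude:g}"


@dataclass(frozen=True)
class InterventionSchedule:
    """An ordered collection of (possibly repeating) interventions."""

    events: tuple[Intervention, ...] = ()

    # -- convenience constructors --------------------------------------
    @classmethod
    def one_off_release(
        cls,
        density: float,
        generation: int = 0,
        target_class: str = DEFAULT_RELEASE_CLASS,
    ) -> "InterventionSchedule":
        return cls(
            (
                Intervention(
                    RELEASE, density, generation=generation, target_class=target_class
                ),
            )
        )

    @classmethod
    def repeated_release(
        cls,
        density: float,
        period: int,
        start: int = 0,
        target_class: str = DEFAULT_RELEASE_CLASS,
    ) -> "InterventionSchedule":
        return cls(
            (
                Intervention(
                    RELEASE, density, period=period, start=start,
                    target_class=target_class,
                ),
            )
        )

    @classmethod
    def repeated_cull(
        cls, kill_fraction: float, period: int, start: int = 0
    ) -> "InterventionSchedule":
        return cls((Intervention(CULL, kill_fraction, period=period, start=start),))

    def __add__(self, other: "InterventionSchedule") -> "InterventionSchedule":
        return InterventionSchedule(self.events + other.events)

    def __bool__(self) -> bool:
        return bool(self.events)


def apply_release(
    state: PopulationState,
    density: float,
    target_class: str = DEFAULT_RELEASE_CLASS,
) -> PopulationState:
    """Add released queens to one class; all other fields unchanged.

    Released queens are added to the summer census directly (they are
    introduced queens, not competing gynes, so the establishment factor
    g does not apply to them in the release year).
    """
    if density < 0:
        raise ValueError("release density must be >= 0")
    if target_class not in QUEEN_CLASSES:
        raise ValueError(
            f"unknown release class {target_class!r}; expected one of {QUEEN_CLASSES}"
        )
    return replace(state, **{target_class: getattr(state, target_class) + density})


def apply_cull(state: PopulationState, kill_fraction: float) -> PopulationState:
    """Multiply every queen class by (1 − kill fraction); z, generation kept."""
    if not 0.0 <= kill_fraction <= 1.0:
        raise ValueError(f"kill fraction must lie in [0, 1], got {kill_fraction!r}")
    keep = 1.0 - kill_fraction
    return replace(
        state, **{name: getattr(state, name) * keep for name in QUEEN_CLASSES}
    )


def apply_event(state: PopulationState, event: Intervention) -> PopulationState:
    if event.kind == RELEASE:
        return apply_release(state, event.magnitude, event.target_class)
    return apply_cull(state, event.magnitude)


def expand_schedule(
    schedule: InterventionSchedule, horizon: int
) -> list[tuple[int, Intervention]]:
    """Unroll repeating events into explicit (time index, event) pairs.

    Sorted by time; within a time index culls come before releases
    (released queens are not hit by a same-year cull), and otherwise the
    schedule's own event order is preserved.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    expanded: list[tuple[int, Intervention]] = []
    for seq, ev in enumerate(schedule.events):
        for t in ev.occurrences(horizon):
            expanded.append((t, ev, seq))  # type: ignore[arg-type]
    expanded.sort(key=lambda item: (item[0], 0 if item[1].kind == CULL else 1, item[2]))
    return [(t, ev) for t, ev, _ in expanded]
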