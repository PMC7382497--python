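"""Deterministic annual recursion for a haplodiploid gene-drive wasp population.

The model tracks summer queen (= nest) densities of the common wasp
*Vespula vulgaris* in a well-mixed 1 km² patch, on a yearly time step.
Queens are diploid (genotypes ``ww``, ``wi``, ``ii``, where ``w`` is the
wild-type allele and ``i`` the drive-modified allele) and drones are
haploid (``w`` or ``i``), so together with the effective mate class of
each queen (mated to ``w`` or ``i`` drones the previous autumn) there are
six queen classes.  One step of the recursion covers: autumn gyne and
drone production, random mating of gynes with the drone pool, overwinter
survival and spring nest-site competition, yielding the next summer's
census.

The drive construct targets spermatogenesis: a carrier drone's mating
transfers no viable sperm with probability ``p`` (complete drone
sterility at ``p = 1``), and heterozygous daughters of fertile matings
are converted to homozygous carriers with homing probability ``h``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - typing only
    import pandas as pd

    from .interventions import Intervention, InterventionSchedule

logger = logging.getLogger(__name__)

#: Names of the six queen classes: queen genotype × effective mate class.
QUEEN_CLASSES: tuple[str, ...] = (
    "q_ww_w",
    "q_ww_i",
    "q_wi_w",
    "q_wi_i",
    "q_ii_w",
    "q_ii_i",
)


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the annual recursion.

    Parameters
    ----------
    h : float
        Homing (heterozygote-to-homozygote conversion) probability, in [0, 1].
    p : float
        Drone sterility: probability that a mating with a carrier drone
        transfers *no* viable sperm, in [0, 1].
    c : float
        Relative mating competitiveness of carrier drones, in [0, 1].
    m : float
        Mean number of matings per gyne (polyandry), used as a real-valued
        exponent.  Default 2.5 (queens mate with 2–3 drones).
    s : float
        Overwinter gyne survival proportion, in (0, 1].  Default 0.02.
    n : float
        Nest-site competition factor, nests km⁻².  Default 1500.
    lam : float
        Potential gynes produced per nest (λ).  Default 560.
    b : float
        Sperm-load fecundity exponent: per-nest gyne output is scaled by
        Z**b where Z is the viable-sperm load of the current queens.
        Default 0 (no sperm-load effect on fecundity).
    release_density : float
        Carrier queens introduced per release event, queens km⁻².
        Default 100.
    """

    h: float = 0.0
    p: float = 0.0
    c: float = 1.0
    m: float = 2.5
    s: float = 0.02
    n: float = 1500.0
    lam: float = 560.0
    b: float = 0.0
    release_density: float = 100.0

    def __post_init__(self) -> None:
        _check_unit("h", self.h)
        _check_unit("p", self.p)
        _check_unit("c", self.c)
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m!r}")
        if not 0.0 < self.s <= 1.0:
            raise ValueError(f"s must lie in (0, 1], got {self.s!r}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n!r}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam!r}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b!r}")
        if self.release_density < 0:
            raise ValueError(
                f"release_density must be >= 0, got {self.release_density!r}"
            )

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationState:
    """Summer queen census: six class densities (nests km⁻²) plus sperm load.

    ``z`` is the viable-sperm-load factor of *this* queen generation, set
    by the drone pool they mated with last autumn; it is 1 for an
    all-wild-type founding state.
    """

    q_ww_w: float = 0.0
    q_ww_i: float = 0.0
    q_wi_w: float = 0.0
    q_wi_i: float = 0.0
    q_ii_w: float = 0.0
    q_ii_i: float = 0.0
    z: float = 1.0
    generation: int = 0

    def __post_init__(self) -> None:
        for name in QUEEN_CLASSES:
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        _check_unit("z", self.z)

    # -- derived census quantities -------------------------------------
    @property
    def densities(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in QUEEN_CLASSES)

    @property
    def total(self) -> float:
        """Total queen (= nest) density, nests km⁻²."""
        return sum(self.densities)

    @property
    def carrier_queens(self) -> float:
        """Density of queens carrying at least one drive allele (wi or ii)."""
        return self.q_wi_w + self.q_wi_i + self.q_ii_w + self.q_ii_i

    @property
    def carrier_fraction(self) -> float:
        """Fraction of queens carrying the drive allele; 0 for an empty state."""
        tot = self.total
        return self.carrier_queens / tot if tot > 0 else 0.0

    @property
    def allele_frequency(self) -> float:
        """Drive-allele frequency among queen genotypes; 0 for an empty state."""
        tot = self.total
        if tot == 0:
            return 0.0
        i_dose = 0.5 * (self.q_wi_w + self.q_wi_i) + self.q_ii_w + self.q_ii_i
        return i_dose / tot

    def with_(self, **kwargs) -> "PopulationState":
        return replace(self, **kwargs)

    @classmethod
    def wild_type(cls, density: float, generation: int = 0) -> "PopulationState":
        """All-wild-type founding state at the given nest density."""
        return cls(q_ww_w=density, z=1.0, generation=generation)


@dataclass(frozen=True)
class DronePool:
    """Relative densities of wild-type and carrier drones (proportional units)."""

    d_w: float
    d_i: float

    def __post_init__(self) -> None:
        if self.d_w < 0 or self.d_i < 0:
            raise ValueError("drone densities must be >= 0")


@dataclass(frozen=True)
class StepDetails:
    """Intermediate quantities of one annual step (for logging/diagnostics)."""

    f: float  #: proportion of gynes successfully fertilised
    j: float  #: proportion of fertile matings passing on the wild-type allele
    z_next: float  #: sperm-load factor stored on the next generation
    sigma_g: float  #: total autumn gyne density (fertilised or not)
    g: float  #: density-dependent overwinter survival factor


# ---------------------------------------------------------------------------
# Elementary operations of the recursion
# ---------------------------------------------------------------------------

def drone_pool(state: PopulationState) -> DronePool:
    """Autumn drone production by allele, proportional to queen classes.

    Haploid drones inherit a single maternal allele: ``ww`` queens give
    ``w`` drones, ``ii`` queens give ``i`` drones, and ``wi`` queens give
    each in equal measure.  The proportionality constant is taken as 1
    since only drone ratios enter the mating functions.
    """
    d_w = state.q_ww_w + state.q_ww_i + 0.5 * (state.q_wi_w + state.q_wi_i)
    d_i = 0.5 * (state.q_wi_w + state.q_wi_i) + state.q_ii_w + state.q_ii_i
    return DronePool(d_w=d_w, d_i=d_i)


def fertilisation_probability(drones: DronePool, params: ModelParams) -> float:
    """Proportion of gynes successfully fertilised.

    A gyne mates ``m`` times at random in a pool where carrier drones
    compete with weight ``c``; each carrier mating transfers no viable
    sperm with probability ``p``.  Fertilisation fails only if every
    mating is sterile, so f = 1 − (p·c·D_i / (D_w + c·D_i))**m.
    """
    weighted = drones.d_w + params.c * drones.d_i
    if weighted == 0:
        logger.warning("degenerate drone pool (no competitive drones): f = 0")
        return 0.0
    frac_sterile = params.p * params.c * drones.d_i / weighted
    return 1.0 - frac_sterile ** params.m


def wt_transmission(drones: DronePool, params: ModelParams) -> float:
    """Proportion of *fertile* matings that pass on the wild-type allele.

    j = D_w / (D_w + c(1−p)D_i).  If no viable sperm exists at all the
    convention j = 1 is returned; the split is then multiplied by a zero
    production term in :func:`step`, so the value is moot.
    """
    viable = drones.d_w + params.c * (1.0 - params.p) * drones.d_i
    if viable == 0:
        logger.debug("no viable sperm in pool: returning j = 1 by convention")
        return 1.0
    return drones.d_w / viable


def sperm_load(drones: DronePool, params: ModelParams) -> float:
    """Viable-sperm-load factor Z of the *next* queen generation.

    Z = (D_w + c(1−p)D_i) / (D_w + cD_i): the population-level fraction
    of the sperm received by queens that is viable.  Returned value is
    stored on the next generation's state and (raised to ``b``) scales
    its per-nest gyne output.
    """
    weighted = drones.d_w + params.c * drones.d_i
    if weighted == 0:
        return 1.0  # no mating occurred; moot because f = 0
    return (drones.d_w + params.c * (1.0 - params.p) * drones.d_i) / weighted


def gyne_production(state: PopulationState, params: ModelParams) -> float:
    """Total autumn gyne density ΣG (gynes km⁻²), fertilised or not.

    ΣG = λ Z**b (Q_ww_w + Q_wi_w + Q_ii_w + (1−p)(Q_ww_i + Q_wi_i + Q_ii_i)).
    Queens mated to carrier drones head smaller nests: their output
    carries the factor (1−p).  ``state.z`` is the sperm load of the
    current queens.
    """
    q_w = state.q_ww_w + state.q_wi_w + state.q_ii_w
    q_i = state.q_ww_i + state.q_wi_i + state.q_ii_i
    return params.lam * state.z ** params.b * (q_w + (1.0 - params.p) * q_i)


def survival_factor(sigma_g: float, params: ModelParams) -> float:
    """Density-dependent overwinter survival and nest-founding factor.

    g = s / (1 + sΣG/n).  All gynes — fertilised or not — compete for
    nest sites, so ΣG here is the *total* gyne density; the fertilisation
    proportion f is applied separately in the recursion.
    """
    if sigma_g < 0:
        raise ValueError(f"sigma_g must be >= 0, got {sigma_g!r}")
    return params.s / (1.0 + params.s * sigma_g / params.n)


def step_details(
    state: PopulationState, params: ModelParams
) -> tuple[PopulationState, StepDetails]:
    """One annual step, returning the next census and its intermediates.

    Within a step the order of events is: autumn gyne production (scaled
    by the current queens' stored sperm load), drone production, random
    mating of gynes (f, j, next Z), then density-dependent overwinter
    survival (g).  Offspring genotype brackets collect the maternal
    contributions with homing applied to heterozygous daughters; each
    bracket is multiplied by λZ**b·f·g and split into the two effective
    mate classes with weights {j, 1−j} (algebraically identical to the
    (1−j)/j ratio form, but defined when j → 0).
    """
    d = drone_pool(state)
    f = fertilisation_probability(d, params) if state.total > 0 else 0.0
    j = wt_transmission(d, params)
    z_next = sperm_load(d, params)
    sigma_g = gyne_production(state, params)
    g = survival_factor(sigma_g, params)

    h, p = params.h, params.p
    base = params.lam * state.z ** params.b * f * g

    bracket_ww = state.q_ww_w + 0.5 * state.q_wi_w
    bracket_wi = (1.0 - h) * (
        (1.0 - p) * (state.q_ww_i + 0.5 * state.q_wi_i)
        + 0.5 * state.q_wi_w
        + state.q_ii_w
    )
    bracket_ii = (1.0 - p) * (
        h * state.q_ww_i + 0.5 * (1.0 + h) * state.q_wi_i + state.q_ii_i
    ) + h * (0.5 * state.q_wi_w + state.q_ii_w)

    nxt = PopulationState(
        q_ww_w=base * j * bracket_ww,
        q_ww_i=base * (1.0 - j) * bracket_ww,
        q_wi_w=base * j * bracket_wi,
        q_wi_i=base * (1.0 - j) * bracket_wi,
        q_ii_w=base * j * bracket_ii,
        q_ii_i=base * (1.0 - j) * bracket_ii,
        z=z_next,
        generation=state.generation + 1,
    )
    return nxt, StepDetails(f=f, j=j, z_next=z_next, sigma_g=sigma_g, g=g)


def step(state: PopulationState, params: ModelParams) -> PopulationState:
    """One annual step of the deterministic recursion (see :func:`step_details`)."""
    nxt, _ = step_details(state, params)
    return nxt


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """An ordered sequence of summer censuses plus per-step diagnostics.

    ``states`` has length ``generations + 1`` (the initial, possibly
    intervention-adjusted, census is included).  ``details[t]`` describes
    the transition from ``states[t]`` to ``states[t + 1]``.  ``events``
    lists the interventions applied, as ``(time index, event)`` pairs.
    """

    states: list[PopulationState]
    details: list[StepDetails]
    params: ModelParams
    events: list[tuple[int, "Intervention"]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[PopulationState]:
        return iter(self.states)

    @property
    def totals(self) -> list[float]:
        return [s.total for s in self.states]

    @property
    def carrier_fractions(self) -> list[float]:
        return [s.carrier_fraction for s in self.states]

    @property
    def allele_frequencies(self) -> list[float]:
        return [s.allele_frequency for s in self.states]

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    def to_dataframe(self) -> "pd.DataFrame":
        """Per-generation summary table (one row per summer census)."""
        import pandas as pd

        events_by_t: dict[int, list[str]] = {}
        for t, ev in self.events:
            events_by_t.setdefault(t, []).append(str(ev))
        rows = []
        for idx, s in enumerate(self.states):
            det = self.details[idx] if idx < len(self.details) else None
            rows.append(
                {
                    "generation": s.generation,
                    **{name: getattr(s, name) for name in QUEEN_CLASSES},
                    "total": s.total,
                    "carrier_queen_fraction": s.carrier_fraction,
                    "allele_frequency": s.allele_frequency,
                    "z": s.z,
                    "f": det.f if det else float("nan"),
                    "j": det.j if det else float("nan"),
                    "g": det.g if det else float("nan"),
                    "sigma_g": det.sigma_g if det else float("nan"),
                    "events": ";".join(events_by_t.get(idx, [])),
                }
            )
        return pd.DataFrame(rows)


def simulate(
    initial: PopulationState,
    params: ModelParams,
    generations: int,
    schedule: "InterventionSchedule | None" = None,
) -> Trajectory:
    """Run the deterministic recursion for a number of generations.

    Interventions in ``schedule`` are applied at their scheduled time
    indices (0 = the initial census) *before* that year's census is
    recorded and stepped; within one time index culls precede releases.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    from .interventions import apply_event, expand_schedule

    events_by_t: dict[int, list] = {}
    if schedule is not None:
        for t, ev in expand_schedule(schedule, generations):
            events_by_t.setdefault(t, []).append(ev)

    states: list[PopulationState] = []
    details: list[StepDetails] = []
    applied: list[tuple[int, "Intervention"]] = []
    state = initial
    for t in range(generations + 1):
        for ev in events_by_t.get(t, ()):
            state = apply_event(state, ev)
            applied.append((t, ev))
        states.append(state)
        if t < generations:
            state, det = step_details(state, params)
            details.append(det)
    return Trajectory(states=states, details=details, params=params, events=applied)
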