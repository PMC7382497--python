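"""Integer-state stochastic twin of the deterministic recursion.

Captures demographic stochasticity and gene drift in a finite (default
1 km²) area by sampling each stage of the annual cycle so that its
expectation matches the corresponding deterministic factor:

* per-nest gyne output ~ Poisson(λZ**b) for wild-mated queens and
  Poisson(λZ**b·(1−p)) for carrier-mated queens;
* offspring genotype (including homing conversion) ~ multinomial with
  the deterministic per-mother probabilities;
* each gyne mates with 2 or 3 drones with equal probability (mean 2.5),
  partners drawn by competitiveness-weighted sampling from the drone
  pool; fertilisation fails only if every mating is sterile;
* the effective mate class of a fertilised gyne ~ Bernoulli(j);
* overwinter survival + nest-site competition ~ Binomial(g) with g
  evaluated at the realised total gyne count (all gynes compete).

Drone abundances are taken proportional to queen-class counts, as in
the deterministic model.  With fractional mean polyandry the integer
mate counts make the realised fertilisation probability differ slightly
from the deterministic f = 1 − q**m (it equals 1 − (q² + q³)/2); the
two coincide whenever no sterile matings occur (p = 0 or no carrier
drones).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

from .interventions import CULL, RELEASE, Intervention, InterventionSchedule, \
    expand_schedule
from .model_core import QUEEN_CLASSES, ModelParams, PopulationState

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

_GENOTYPES = ("ww", "wi", "ii")


@dataclass(frozen=True)
class IntegerState:
    """Integer queen counts for the six classes in a fixed area (1 km²)."""

    q_ww_w: int = 0
    q_ww_i: int = 0
    q_wi_w: int = 0
    q_wi_i: int = 0
    q_ii_w: int = 0
    q_ii_i: int = 0
    z: float = 1.0
    generation: int = 0

    def __post_init__(self) -> None:
        for name in QUEEN_CLASSES:
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError(f"z must lie in [0, 1], got {self.z!r}")

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(int(getattr(self, name)) for name in QUEEN_CLASSES)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def carrier_fraction(self) -> float:
        tot = self.total
        if tot == 0:
            return 0.0
        return (self.q_wi_w + self.q_wi_i + self.q_ii_w + self.q_ii_i) / tot

    @property
    def allele_frequency(self) -> float:
        tot = self.total
        if tot == 0:
            return 0.0
        return (0.5 * (self.q_wi_w + self.q_wi_i) + self.q_ii_w + self.q_ii_i) / tot

    def to_density_state(self, area_km2: float = 1.0) -> PopulationState:
        """View the counts as densities over the modelled area."""
        return PopulationState(
            **{name: getattr(self, name) / area_km2 for name in QUEEN_CLASSES},
            z=self.z,
            generation=self.generation,
        )

    @classmethod
    def from_density_state(
        cls, state: PopulationState, area_km2: float = 1.0
    ) -> "IntegerState":
        return cls(
            **{
                name: int(round(getattr(state, name) * area_km2))
                for name in QUEEN_CLASSES
            },
            z=state.z,
            generation=state.generation,
        )


def _offspring_genotype_probs(params: ModelParams) -> dict[str, tuple[float, float, float]]:
    """Per-mother-class (ww, wi, ii) daughter genotype probabilities.

    Homing converts a heterozygous daughter to homozygous with
    probability h.  Classes mated to carrier drones pass the paternal
    ``i`` allele to every daughter.
    """
    h = params.h
    return {
        "q_ww_w": (1.0, 0.0, 0.0),
        "q_wi_w": (0.5, 0.5 * (1.0 - h), 0.5 * h),
        "q_ii_w": (0.0, 1.0 - h, h),
        "q_ww_i": (0.0, 1.0 - h, h),
        "q_wi_i": (0.0, 0.5 * (1.0 - h), 0.5 * (1.0 + h)),
        "q_ii_i": (0.0, 0.0, 1.0),
    }


def stochastic_step(
    state: IntegerState, params: ModelParams, rng: np.random.Generator
) -> IntegerState:
    """One annual step with demographic stochasticity and gene drift.

    The zero state is absorbing.  Identical RNG streams give identical
    results.
    """
    if state.total == 0:
        return replace(state, generation=state.generation + 1)

    counts = dict(zip(QUEEN_CLASSES, state.counts))
    d_w = counts["q_ww_w"] + counts["q_ww_i"] + 0.5 * (
        counts["q_wi_w"] + counts["q_wi_i"]
    )
    d_i = 0.5 * (counts["q_wi_w"] + counts["q_wi_i"]) + counts["q_ii_w"] + counts[
        "q_ii_i"
    ]

    zb = state.z ** params.b
    geno_probs = _offspring_genotype_probs(params)

    # Autumn gyne production and daughter genotypes, aggregated per class.
    gynes_by_genotype = np.zeros(3, dtype=np.int64)
    sigma_g = 0
    for name, n_nests in counts.items():
        if n_nests == 0:
            continue
        mean = params.lam * zb * (
            (1.0 - params.p) if name.endswith("_i") else 1.0
        )
        n_gynes = int(rng.poisson(mean * n_nests))
        sigma_g += n_gynes
        if n_gynes:
            gynes_by_genotype += rng.multinomial(n_gynes, geno_probs[name])

    if sigma_g == 0:
        return IntegerState(z=1.0, generation=state.generation + 1)

    # Autumn mating: each gyne takes 2 or 3 mates (equal odds) from the
    # competitiveness-weighted drone pool; a mating is sterile iff the
    # partner is a carrier and transfers no viable sperm.
    weighted = d_w + params.c * d_i
    if weighted == 0:
        return IntegerState(z=1.0, generation=state.generation + 1)
    q_sterile = params.p * params.c * d_i / weighted
    prob_fertilised = 1.0 - 0.5 * (q_sterile**2 + q_sterile**3)

    viable = d_w + params.c * (1.0 - params.p) * d_i
    j = d_w / viable if viable > 0 else 1.0
    z_next = viable / weighted

    # Winter survival and spring nest-site competition: all gynes compete.
    g = params.s / (1.0 + params.s * sigma_g / params.n)

    new_counts: dict[str, int] = {}
    for geno, n_gynes in zip(_GENOTYPES, gynes_by_genotype):
        fertilised = int(rng.binomial(n_gynes, prob_fertilised)) if n_gynes else 0
        mated_w = int(rng.binomial(fertilised, j)) if fertilised else 0
        mated_i = fertilised - mated_w
        new_counts[f"q_{geno}_w"] = int(rng.binomial(mated_w, g)) if mated_w else 0
        new_counts[f"q_{geno}_i"] = int(rng.binomial(mated_i, g)) if mated_i else 0

    return IntegerState(**new_counts, z=z_next, generation=state.generation + 1)


@dataclass
class StochasticResult:
    """Replicate trajectories of the stochastic engine plus summaries.

    ``counts`` has shape (replicates, generations + 1, 6) in the order
    of :data:`~vespadrive.model_core.QUEEN_CLASSES`.
    """

    counts: np.ndarray
    z: np.ndarray
    params: ModelParams
    base_seed: int

    @property
    def totals(self) -> np.ndarray:
        """(replicates, generations + 1) total queen counts."""
        return self.counts.sum(axis=2)

    @property
    def carrier_fractions(self) -> np.ndarray:
        tot = self.totals
        carriers = self.counts[:, :, 2:].sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, carriers / np.maximum(tot, 1), 0.0)
        return frac

    @property
    def allele_frequencies(self) -> np.ndarray:
        tot = self.totals
        dose = 0.5 * self.counts[:, :, 2:4].sum(axis=2) + self.counts[:, :, 4:].sum(
            axis=2
        )
        return np.where(tot > 0, dose / np.maximum(tot, 1), 0.0)

    @property
    def extinction_probability(self) -> float:
        """Fraction of replicates that hit the zero state by the horizon."""
        return float(np.mean(self.totals.min(axis=1) == 0))

    def summary(self) -> "pd.DataFrame":
        """Per-generation mean/quantile summary across replicates."""
        import pandas as pd

        tot = self.totals
        cf = self.carrier_fractions
        gens = np.arange(tot.shape[1])
        return pd.DataFrame(
            {
                "generation": gens,
                "total_mean": tot.mean(axis=0),
                "total_q05": np.quantile(tot, 0.05, axis=0),
                "total_q50": np.quantile(tot, 0.50, axis=0),
                "total_q95": np.quantile(tot, 0.95, axis=0),
                "carrier_fraction_mean": cf.mean(axis=0),
                "carrier_fraction_q05": np.quantile(cf, 0.05, axis=0),
                "carrier_fraction_q95": np.quantile(cf, 0.95, axis=0),
                "extinct_fraction": (tot == 0).mean(axis=0),
            }
        )


def _apply_integer_event(
    state: IntegerState, event: Intervention, rng: np.random.Generator
) -> IntegerState:
    if event.kind == RELEASE:
        n = int(round(event.magnitude))
        return replace(
            state, **{event.target_class: getattr(state, event.target_class) + n}
        )
    assert event.kind == CULL
    keep = 1.0 - event.magnitude
    survivors = {
        name: int(rng.binomial(int(getattr(state, name)), keep))
        for name in QUEEN_CLASSES
    }
    return replace(state, **survivors)


def stochastic_simulate(
    initial: IntegerState,
    params: ModelParams,
    generations: int,
    replicates: int = 1,
    schedule: InterventionSchedule | None = None,
    base_seed: int = 0,
) -> StochasticResult:
    """Run seeded replicate simulations of the integer-state model.

    Each replicate uses its own ``numpy`` generator seeded with
    ``base_seed + replicate index``, so runs are reproducible at the
    trajectory level and replicates are independent.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    events_by_t: dict[int, list[Intervention]] = {}
    if schedule is not None:
        for t, ev in expand_schedule(schedule, generations):
            events_by_t.setdefault(t, []).append(ev)

    counts = np.zeros((replicates, generations + 1, 6), dtype=np.int64)
    zs = np.zeros((replicates, generations + 1), dtype=float)
    for r in range(replicates):
        rng = np.random.default_rng(base_seed + r)
        state = initial
        for t in range(generations + 1):
            for ev in events_by_t.get(t, ()):
                state = _apply_integer_event(state, ev, rng)
            counts[r, t] = state.counts
            zs[r, t] = state.z
            if t < generations:
                state = stochastic_step(state, params, rng)
    return StochasticResult(counts=counts, z=zs, params=params, base_seed=base_seed)
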