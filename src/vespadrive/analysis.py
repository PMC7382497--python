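"""Derived quantities and experiment drivers.

Equilibria, the analytic eradication threshold for carrier abundance,
forced-carrier-fraction suppression curves, infiltration timing,
suppression metrics, and (h, p) phase scans over drive parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import brentq

from .interventions import InterventionSchedule
from .model_core import (
    ModelParams,
    PopulationState,
    Trajectory,
    simulate,
    step,
)

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

#: Deterministic quasi-extinction threshold: less than one nest in the
#: modelled square kilometre counts as eradicated.
QUASI_EXTINCTION_DENSITY = 1.0


# ---------------------------------------------------------------------------
# Equilibria and analytic thresholds
# ---------------------------------------------------------------------------

def wt_equilibrium(params: ModelParams, method: str = "closed_form") -> float:
    """Non-trivial fixed point of the wild-type-only recursion, nests km⁻².

    The wild-type model reduces to Q' = sλQ / (1 + sλQ/n), a
    Beverton–Holt-type map whose positive fixed point is
    ``n(sλ − 1)/(sλ)`` when sλ > 1 and 0 otherwise.  ``method`` may be
    ``"closed_form"`` or ``"iterate"`` (fixed-point iteration of the
    full six-class recursion from a small founding population).
    """
    s_lam = params.s * params.lam
    if method == "closed_form":
        if s_lam <= 1.0:
            return 0.0
        return params.n * (s_lam - 1.0) / s_lam
    if method == "iterate":
        state = PopulationState.wild_type(1.0)
        prev = state.total
        for _ in range(100_000):
            state = step(state, params)
            tot = state.total
            if abs(tot - prev) <= 1e-12 * max(tot, 1.0):
                break
            prev = tot
        return 0.0 if state.total < 1e-9 else state.total
    raise ValueError(f"unknown method {method!r}")


def low_density_growth_factor(carrier_fraction: float, params: ModelParams) -> float:
    """Per-generation growth factor of a population pinned at a carrier
    fraction, evaluated where density dependence vanishes (g → s).

    With all carriers homozygous for a complete-sterility construct the
    drone pool has carrier share φ = c·d/((1−d) + c·d), the sperm load
    is Z = (1−d)/((1−d) + c·d), and the factor is sλ·(1 − φ**m)·Z**b.
    """
    d = carrier_fraction
    if not 0.0 <= d <= 1.0:
        raise ValueError("carrier fraction must lie in [0, 1]")
    denom = (1.0 - d) + params.c * d
    if denom == 0:
        return 0.0
    phi = params.c * d / denom
    z = (1.0 - d) / denom
    return params.s * params.lam * (1.0 - phi**params.m) * z**params.b


def critical_carrier_fraction(params: ModelParams, tol: float = 1e-6) -> float:
    """Smallest carrier fraction at which the population cannot replace itself.

    Assumes complete drone sterility (p = 1) among carriers.  For
    ``b = 0`` and ``c = 1`` the condition sλ(1 − d**m) < 1 gives the
    closed form d* = (1 − 1/(sλ))**(1/m); otherwise the low-density
    growth factor is bracketed to ``tol`` by root finding.
    """
    s_lam = params.s * params.lam
    if s_lam <= 1.0:
        return 0.0  # below replacement even with no carriers
    if params.b == 0 and params.c == 1.0:
        return (1.0 - 1.0 / s_lam) ** (1.0 / params.m)
    return float(
        brentq(
            lambda d: low_density_growth_factor(d, params) - 1.0,
            1e-12,
            1.0 - 1e-12,
            xtol=tol,
        )
    )


# ---------------------------------------------------------------------------
# Forced carrier-fraction suppression (imposed population composition)
# ---------------------------------------------------------------------------

def _pin_carrier_fraction(
    state: PopulationState, fraction: float
) -> PopulationState:
    """Rescale queen classes to an imposed carrier fraction.

    Total density and the within-group mate-class mix are preserved.
    Carriers are held *homozygous* for the construct (heterozygous mass
    is folded into the ``ii`` classes), matching the assumption behind
    the analytic critical-fraction threshold; a group with no mass is
    seeded in the wild-drone-mated class.
    """
    total = state.total
    if total == 0:
        return state
    carriers = state.carrier_queens
    wild = state.q_ww_w + state.q_ww_i
    target_c = fraction * total
    target_w = (1.0 - fraction) * total

    if carriers > 0:
        share_w = (state.q_wi_w + state.q_ii_w) / carriers
    else:
        share_w = 1.0
    fields: dict[str, float] = {
        "q_wi_w": 0.0,
        "q_wi_i": 0.0,
        "q_ii_w": target_c * share_w,
        "q_ii_i": target_c * (1.0 - share_w),
    }
    if wild > 0:
        scale = target_w / wild
        fields["q_ww_w"] = state.q_ww_w * scale
        fields["q_ww_i"] = state.q_ww_i * scale
    else:
        fields["q_ww_w"] = target_w
        fields["q_ww_i"] = 0.0
    return state.with_(**fields)


def forced_fraction_equilibrium(
    carrier_fraction: float,
    params: ModelParams,
    max_generations: int = 5000,
    tol: float = 1e-9,
    quasi_extinction: float = QUASI_EXTINCTION_DENSITY,
) -> float:
    """Long-run total density when the carrier queen fraction is pinned.

    Each generation the dynamics run one step and the census is then
    rescaled so the carrier fraction equals the imposed value (total
    density preserved); only the total evolves.  Returns 0 once the
    density falls below the quasi-extinction threshold; at fraction 0
    this is exactly :func:`wt_equilibrium`.
    """
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier fraction must lie in [0, 1]")
    if carrier_fraction == 0.0:
        return wt_equilibrium(params)

    state = _pin_carrier_fraction(
        PopulationState.wild_type(max(wt_equilibrium(params), 1.0)), carrier_fraction
    )
    prev = state.total
    for _ in range(max_generations):
        state = _pin_carrier_fraction(step(state, params), carrier_fraction)
        tot = state.total
        if tot < quasi_extinction:
            return 0.0
        if abs(tot - prev) <= tol * max(tot, 1.0):
            return tot
        prev = tot
    return state.total


# ---------------------------------------------------------------------------
# Trajectory metrics
# ---------------------------------------------------------------------------

def infiltration_time(trajectory: Trajectory, threshold: float) -> int | None:
    """First generation at which the carrier queen fraction reaches a threshold.

    ``threshold = 0`` means the first generation with any carriers;
    returns ``None`` if the threshold is never reached by the horizon.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    for state in trajectory.states:
        if threshold == 0.0:
            if state.carrier_queens > 0:
                return state.generation
        elif state.carrier_fraction >= threshold:
            return state.generation
    return None


@dataclass(frozen=True)
class SuppressionSummary:
    """Outcome metrics of a trajectory relative to an uncontrolled baseline."""

    baseline: float
    min_density: float
    long_run_density: float
    suppression_pct: float
    eradicated: bool
    time_to_eradication: int | None


def suppression_metrics(
    trajectory: Trajectory,
    baseline: float,
    quasi_extinction: float = QUASI_EXTINCTION_DENSITY,
    tail: int = 10,
) -> SuppressionSummary:
    """Summarise suppression achieved along a trajectory.

    The long-run density is the mean total over the last ``tail``
    censuses (0 if eradicated), and suppression % is
    100·(1 − long-run/baseline).  Eradication is declared at the first
    census below the quasi-extinction threshold.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    totals = trajectory.totals
    t_erad = next(
        (s.generation for s in trajectory.states if s.total < quasi_extinction), None
    )
    eradicated = t_erad is not None
    long_run = 0.0 if eradicated else float(np.mean(totals[-tail:]))
    return SuppressionSummary(
        baseline=baseline,
        min_density=min(totals),
        long_run_density=long_run,
        suppression_pct=100.0 * (1.0 - long_run / baseline),
        eradicated=eradicated,
        time_to_eradication=t_erad,
    )


# ---------------------------------------------------------------------------
# Drive-release experiments and phase scans
# ---------------------------------------------------------------------------

def release_into_equilibrium(
    params: ModelParams,
    generations: int,
    release_density: float | None = None,
) -> Trajectory:
    """Simulate a one-off carrier-queen release into the wild-type equilibrium."""
    density = params.release_density if release_density is None else release_density
    initial = PopulationState.wild_type(wt_equilibrium(params))
    schedule = InterventionSchedule.one_off_release(density, generation=0)
    return simulate(initial, params, generations, schedule)


@dataclass
class ScanResult:
    """Grid of drive-parameter combinations with per-cell outcome metrics."""

    data: "pd.DataFrame"
    axes: dict[str, np.ndarray] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _cell_outcome(
    params: ModelParams,
    horizon: int,
    infiltration_threshold: float,
    quasi_extinction: float,
    baseline: float,
) -> dict:
    traj = release_into_equilibrium(params, horizon)
    t_spread = infiltration_time(traj, infiltration_threshold)
    summary = suppression_metrics(traj, baseline, quasi_extinction)
    return {
        "spread": t_spread is not None,
        "t_spread": t_spread,
        "eradicated": summary.eradicated,
        "t_eradication": summary.time_to_eradication,
        "suppression_pct": summary.suppression_pct,
        "min_density": summary.min_density,
        "final_density": traj.final.total,
    }


def phase_scan(
    h_grid: Sequence[float],
    p_grid: Sequence[float],
    params: ModelParams,
    horizon: int = 200,
    infiltration_threshold: float = 0.9,
    quasi_extinction: float = QUASI_EXTINCTION_DENSITY,
) -> ScanResult:
    """Release experiment over an (h, p) grid of homing and sterility levels.

    Each cell releases ``params.release_density`` homozygous carrier
    queens into the wild-type equilibrium and records whether the drive
    infiltrates more than ``infiltration_threshold`` of the queens,
    whether the population is eradicated, and the suppression achieved
    relative to the uncontrolled equilibrium.
    """
    import pandas as pd

    h_grid = np.asarray(sorted(h_grid), dtype=float)
    p_grid = np.asarray(sorted(p_grid), dtype=float)
    baseline = wt_equilibrium(params)
    rows = []
    for h in h_grid:
        for p in p_grid:
            cell = params.with_(h=float(h), p=float(p))
            rows.append(
                {
                    "h": float(h),
                    "p": float(p),
                    **_cell_outcome(
                        cell, horizon, infiltration_threshold,
                        quasi_extinction, baseline,
                    ),
                }
            )
    return ScanResult(
        data=pd.DataFrame(rows), axes={"h": h_grid, "p": p_grid}
    )


def minimal_eradication_sterility(
    params: ModelParams,
    h: float = 1.0,
    p_step: float = 0.01,
    horizon: int = 500,
    quasi_extinction: float = QUASI_EXTINCTION_DENSITY,
) -> float | None:
    """Smallest sterility p (on a grid) whose drive eradicates the population.

    Scans p upward from one grid step; a cell counts as eradicating when
    the total density falls below the quasi-extinction threshold within
    the horizon after a standard release at homing rate ``h``.
    """
    n_steps = int(round(1.0 / p_step))
    for k in range(1, n_steps):
        p = k * p_step
        traj = release_into_equilibrium(params.with_(h=h, p=p), horizon)
        if any(s.total < quasi_extinction for s in traj.states):
            return p
    return None


def minimal_spreading_homing(
    params: ModelParams,
    p: float,
    h_step: float = 0.01,
    horizon: int = 500,
    infiltration_threshold: float = 0.9,
) -> float | None:
    """Smallest homing rate h (on a grid) at which the drive still spreads.

    Spread means the carrier queen fraction exceeds the infiltration
    threshold at some point within the horizon after a standard release
    at sterility ``p``.
    """
    n_steps = int(round(1.0 / h_step))
    for k in range(1, n_steps + 1):
        h = min(k * h_step, 1.0)
        traj = release_into_equilibrium(params.with_(h=h, p=p), horizon)
        if any(s.carrier_fraction > infiltration_threshold for s in traj.states):
            return h
    return None
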