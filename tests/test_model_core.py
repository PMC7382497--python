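"""Unit and property tests for the deterministic annual recursion."""
import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vespadrive import (
    ModelParams,
    PopulationState,
    DronePool,
    drone_pool,
    fertilisation_probability,
    gyne_production,
    simulate,
    sperm_load,
    step,
    step_details,
    survival_factor,
    wt_equilibrium,
    wt_transmission,
)
from vespadrive.interventions import InterventionSchedule

# ---------------------------------------------------------------------------
# Independent oracles: finite enumeration over an explicit drone pool
# ---------------------------------------------------------------------------

def enumerate_failure_probability(n_w, n_i, p, c, m):
    """P(no viable sperm after m matings), by enumerating ordered mate tuples.

    Drones are drawn with replacement, carriers weighted by c.  A wild
    mating always transfers viable sperm, so only all-carrier tuples can
    leave a gyne unfertilised, each with probability p per mating.
    """
    pool = ["w"] * n_w + ["i"] * n_i
    weights = {"w": 1.0, "i": c}
    total_w = sum(weights[d] for d in pool)
    fail = 0.0
    for combo in itertools.product(pool, repeat=m):
        prob = math.prod(weights[d] / total_w for d in combo)
        if all(d == "i" for d in combo):
            fail += prob * p**len(combo)
    return fail


def enumerate_wt_share_of_viable_sperm(n_w, n_i, p, c):
    """Wild-type share of viable sperm over an explicit drone pool."""
    wild = n_w * 1.0
    viable = wild + n_i * c * (1.0 - p)
    return wild / viable


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

class TestDronePool:
    @pytest.mark.parametrize(
        "fields, expected",
        [
            ({"q_ww_w": 1350.0}, (1350.0, 0.0)),
            ({"q_wi_w": 10.0}, (5.0, 5.0)),
            ({"q_ww_i": 100.0, "q_ii_w": 50.0}, (100.0, 50.0)),
            ({}, (0.0, 0.0)),
        ],
    )
    def test_maternal_allele_contributions(self, fields, expected):
        d = drone_pool(PopulationState(**fields))
        assert (d.d_w, d.d_i) == pytest.approx(expected)


class TestFertilisation:
    def test_no_carrier_drones_gives_full_fertilisation(self, defaults):
        pool = DronePool(d_w=500.0, d_i=0.0)
        assert fertilisation_probability(pool, defaults.with_(p=0.7)) == 1.0

    def test_fertile_carriers_give_full_fertilisation(self, defaults):
        pool = DronePool(d_w=100.0, d_i=900.0)
        assert fertilisation_probability(pool, defaults.with_(p=0.0)) == 1.0

    def test_equal_pool_full_sterility(self, defaults):
        pool = DronePool(d_w=10.0, d_i=10.0)
        f = fertilisation_probability(pool, defaults.with_(p=1.0, c=1.0))
        assert f == pytest.approx(1.0 - 0.5**2.5, rel=1e-12)
        assert f == pytest.approx(0.8232, abs=5e-5)

    @pytest.mark.parametrize("p,c", [(1.0, 1.0), (0.6, 1.0), (0.9, 0.5)])
    def test_fractional_polyandry_bracketed_by_enumeration(self, defaults, p, c):
        """f at m=2.5 lies between the enumerated m=2 and m=3 values."""
        pool = DronePool(d_w=3.0, d_i=3.0)
        params = defaults.with_(p=p, c=c)
        f_frac = fertilisation_probability(pool, params)
        f2 = 1.0 - enumerate_failure_probability(3, 3, p, c, 2)
        f3 = 1.0 - enumerate_failure_probability(3, 3, p, c, 3)
        assert min(f2, f3) <= f_frac <= max(f2, f3)
        # and the formula agrees exactly with enumeration at integer m
        for m, f_enum in ((2, f2), (3, f3)):
            f_int = fertilisation_probability(pool, params.with_(m=m))
            assert f_int == pytest.approx(f_enum, rel=1e-12)

    def test_empty_pool_means_no_fertilisation(self, defaults):
        assert fertilisation_probability(DronePool(0.0, 0.0), defaults) == 0.0


class TestWtTransmission:
    def test_no_carrier_drones(self, defaults):
        assert wt_transmission(DronePool(10.0, 0.0), defaults.with_(p=0.3)) == 1.0

    def test_sterile_carrier_sperm_never_transmitted(self, defaults):
        assert wt_transmission(DronePool(5.0, 50.0), defaults.with_(p=1.0)) == 1.0

    def test_equal_pool_half_sterility(self, defaults):
        j = wt_transmission(DronePool(7.0, 7.0), defaults.with_(p=0.5, c=1.0))
        assert j == pytest.approx(2.0 / 3.0, rel=1e-12)

    @pytest.mark.parametrize("n_w,n_i,p,c", [(4, 2, 0.5, 1.0), (1, 5, 0.2, 0.7)])
    def test_matches_viable_sperm_share_of_finite_pool(self, defaults, n_w, n_i, p, c):
        j = wt_transmission(DronePool(float(n_w), float(n_i)), defaults.with_(p=p, c=c))
        assert j == pytest.approx(enumerate_wt_share_of_viable_sperm(n_w, n_i, p, c))

    def test_no_viable_sperm_convention(self, defaults):
        assert wt_transmission(DronePool(0.0, 10.0), defaults.with_(p=1.0)) == 1.0


class TestSpermLoad:
    @pytest.mark.parametrize(
        "pool,p,expected",
        [
            (DronePool(9.0, 0.0), 0.8, 1.0),
            (DronePool(3.0, 8.0), 0.0, 1.0),
            (DronePool(6.0, 6.0), 1.0, 0.5),
        ],
    )
    def test_viable_share_of_received_sperm(self, defaults, pool, p, expected):
        assert sperm_load(pool, defaults.with_(p=p)) == pytest.approx(expected)

    def test_empty_pool_convention(self, defaults):
        assert sperm_load(DronePool(0.0, 0.0), defaults) == 1.0


class TestGyneProduction:
    def test_wild_type_state(self, defaults):
        state = PopulationState(q_ww_w=1350.0)
        assert gyne_production(state, defaults) == pytest.approx(756000.0)

    def test_full_sterility_annihilates_carrier_mated_nests(self, defaults):
        state = PopulationState(q_ww_i=50.0, q_wi_i=20.0, q_ii_i=30.0)
        assert gyne_production(state, defaults.with_(p=1.0)) == 0.0

    def test_no_sperm_load_effect_when_b_zero(self, defaults):
        lo = gyne_production(PopulationState(q_ww_w=100.0, z=0.3), defaults)
        hi = gyne_production(PopulationState(q_ww_w=100.0, z=1.0), defaults)
        assert lo == hi

    def test_sperm_load_scales_production_when_b_positive(self, defaults):
        params = defaults.with_(b=1.0)
        lo = gyne_production(PopulationState(q_ww_w=100.0, z=0.25), params)
        hi = gyne_production(PopulationState(q_ww_w=100.0, z=1.0), params)
        assert lo == pytest.approx(0.25 * hi)


class TestSurvivalFactor:
    def test_no_competition(self, defaults):
        assert survival_factor(0.0, defaults) == pytest.approx(0.02)

    def test_half_saturation(self, defaults):
        assert survival_factor(75000.0, defaults) == pytest.approx(0.01, rel=1e-12)

    def test_equilibrium_scale_production(self, defaults):
        assert survival_factor(756000.0, defaults) == pytest.approx(
            0.02 / 11.08, rel=1e-9
        )


# ---------------------------------------------------------------------------
# The full step
# ---------------------------------------------------------------------------

class TestStep:
    def test_zero_maps_to_zero(self, defaults):
        nxt = step(PopulationState(), defaults)
        assert nxt.total == 0.0
        assert nxt.generation == 1

    def test_wild_type_fixed_point(self, defaults):
        q_star = defaults.n * (defaults.s * defaults.lam - 1) / (
            defaults.s * defaults.lam
        )
        nxt = step(PopulationState.wild_type(q_star), defaults)
        assert nxt.total == pytest.approx(q_star, rel=1e-12)
        assert nxt.q_ww_w == pytest.approx(q_star, rel=1e-12)

    def test_full_sterility_perfect_homing_preserves_allele_frequency(
        self, wt_eq_state, defaults
    ):
        params = defaults.with_(h=1.0, p=1.0, c=1.0)
        state = wt_eq_state.with_(q_ii_w=100.0)
        freq0 = state.allele_frequency
        for _ in range(25):
            state = step(state, params)
            assert state.allele_frequency == pytest.approx(freq0, rel=1e-9)


conservation_params = st.builds(
    ModelParams,
    h=st.floats(0, 1),
    p=st.floats(0, 1),
    c=st.floats(0.05, 1),
    m=st.floats(1.0, 5.0),
    b=st.floats(0.0, 2.0),
)
conservation_states = st.builds(
    PopulationState,
    q_ww_w=st.floats(0, 2000),
    q_ww_i=st.floats(0, 500),
    q_wi_w=st.floats(0, 500),
    q_wi_i=st.floats(0, 500),
    q_ii_w=st.floats(0, 500),
    q_ii_i=st.floats(0, 500),
    z=st.floats(0.01, 1.0),
)


class TestStepInvariants:
    @settings(max_examples=200, derandomize=True)
    @given(state=conservation_states, params=conservation_params)
    def test_conservation_and_mate_class_ratio(self, state, params):
        """Σ of the next census equals f·g·ΣG, and each genotype splits
        into mate classes in the ratio (1−j)/j."""
        nxt, det = step_details(state, params)
        assert nxt.total == pytest.approx(
            det.f * det.g * det.sigma_g, rel=1e-12, abs=1e-12
        )
        if det.j > 0:
            ratio = (1.0 - det.j) / det.j
            for geno in ("ww", "wi", "ii"):
                q_w = getattr(nxt, f"q_{geno}_w")
                q_i = getattr(nxt, f"q_{geno}_i")
                if q_w > 0:
                    assert q_i / q_w == pytest.approx(ratio, rel=1e-9)
        # densities stay finite and non-negative
        assert all(d >= 0 and math.isfinite(d) for d in nxt.densities)

    @staticmethod
    def _gene_pool_frequency(state):
        """Drive-allele frequency over queens' own alleles plus the stored
        sperm allele (three alleles per mated queen)."""
        dose = 2.0 * (
            0.5 * (state.q_wi_w + state.q_wi_i) + state.q_ii_w + state.q_ii_i
        ) + (state.q_ww_i + state.q_wi_i + state.q_ii_i)
        return dose / (3.0 * state.total)

    @settings(max_examples=50, derandomize=True)
    @given(h=st.floats(0.05, 1.0))
    def test_neutral_drive_gene_pool_frequency_nondecreasing(self, h):
        """For a fitness-neutral drive (p=0, c=1) homing can only convert
        w → i, so the drive-allele frequency of the full gene pool (queen
        genotypes + stored sperm) never declines.  The queen-genotype
        frequency alone dips transiently after a homozygous release
        because daughters carry just one maternal allele."""
        params = ModelParams(h=h, p=0.0, c=1.0)
        state = PopulationState.wild_type(wt_equilibrium(params)).with_(q_ii_w=100.0)
        freq = self._gene_pool_frequency(state)
        for _ in range(20):
            state = step(state, params)
            new = self._gene_pool_frequency(state)
            assert new >= freq - 1e-12
            freq = new


# ---------------------------------------------------------------------------
# Multi-generation behaviour
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_no_carriers_stays_carrier_free(self, wt_eq_state, defaults):
        traj = simulate(wt_eq_state, defaults, 50)
        assert len(traj) == 51
        assert all(f == 0.0 for f in traj.carrier_fractions)

    def test_neutral_drive_sweeps_within_ten_generations(self, defaults):
        params = defaults.with_(h=1.0, p=0.0, c=1.0)
        initial = PopulationState.wild_type(wt_equilibrium(params))
        schedule = InterventionSchedule.one_off_release(100.0, generation=0)
        traj = simulate(initial, params, 15, schedule)
        reached = [s.generation for s in traj if s.carrier_fraction >= 0.99]
        assert reached and reached[0] <= 10

    def test_neutral_sweep_matches_mating_lag_product_recursion(self, defaults):
        """With h=1, p=0 the non-carrier fraction follows
        u(t+1) = u(t)·u(t−1): carrier-free queens must both be ww and have
        mated a wild drone, and mate classes lag the drone pool by one
        generation.  (Fibonacci-exponent decay of the wild-type share.)"""
        params = defaults.with_(h=1.0, p=0.0, c=1.0)
        q0 = wt_equilibrium(params)
        initial = PopulationState.wild_type(q0).with_(q_ii_w=100.0)
        traj = simulate(initial, params, 12)
        u = [1.0 - f for f in traj.carrier_fractions]
        for t in range(2, len(u)):
            assert u[t] == pytest.approx(u[t - 1] * u[t - 2], rel=1e-9)

    def test_full_sterility_without_perfect_homing_is_lost(self, defaults):
        params = defaults.with_(h=0.8, p=1.0, c=1.0)
        initial = PopulationState.wild_type(wt_equilibrium(params)).with_(
            q_ii_w=100.0
        )
        traj = simulate(initial, params, 300)
        assert traj.final.carrier_fraction < 1e-3
        assert traj.carrier_fractions[5] > traj.final.carrier_fraction

    def test_plain_sterility_gene_without_drive_is_lost(self, defaults):
        params = defaults.with_(h=0.0, p=0.6, c=1.0)
        initial = PopulationState.wild_type(wt_equilibrium(params)).with_(
            q_ii_w=100.0
        )
        traj = simulate(initial, params, 200)
        assert traj.final.carrier_fraction < 1e-3


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h": 1.5},
            {"p": -0.1},
            {"s": 0.0},
            {"m": 0.0},
            {"lam": -5.0},
            {"b": -1.0},
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(q_ww_w=-1.0)
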