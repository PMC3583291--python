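"""Exactness, determinism and event semantics of the simulation engine."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from plaquesim import (
    HazardKind,
    ModelSpec,
    ParameterSet,
    Reaction,
    SpeciesState,
    TimedEvent,
    build_model1,
    build_model2,
    fast_forward_linear,
    simulate,
    simulate_ensemble,
)
from plaquesim.engine import LinearityContractError, default_record_times
from plaquesim.units import YEAR_SECONDS


def _frozen_spec(count=5):
    return ModelSpec(
        name="frozen",
        species=(SpeciesState("Abeta", count),
                 SpeciesState("Sink", 0, constant=True)),
        parameters=ParameterSet(k=0.0),
        reactions=(
            Reaction("deg", {"Abeta": 1}, {"Sink": 1},
                     HazardKind.FIRST_ORDER, "k"),
        ),
    )


def _toy_two_species():
    """Production/decay of A plus reversible pairing into B; small enough
    for a full chemical-master-equation solution."""
    return ModelSpec(
        name="toy",
        species=(
            SpeciesState("A", 0),
            SpeciesState("B", 0),
            SpeciesState("Source", 1, constant=True),
            SpeciesState("Sink", 0, constant=True),
        ),
        parameters=ParameterSet(k1=1.0, k2=0.5, k3=0.3, k4=0.4),
        reactions=(
            Reaction("prod", {"Source": 1}, {"Source": 1, "A": 1},
                     HazardKind.ZEROTH_ORDER, "k1"),
            Reaction("deg", {"A": 1}, {"Sink": 1},
                     HazardKind.FIRST_ORDER, "k2"),
            Reaction("pair", {"A": 2}, {"B": 1},
                     HazardKind.SECOND_ORDER_HOMODIMER, "k3"),
            Reaction("unpair", {"B": 1}, {"A": 2},
                     HazardKind.FIRST_ORDER, "k4"),
        ),
    )


class TestBasics:
    def test_all_hazards_zero_freezes_state(self):
        tr = simulate(_frozen_spec(5), t_max=1000.0, n_records=20, seed=3)
        assert np.all(tr.series("Abeta") == 5)

    def test_bitwise_determinism(self):
        spec = build_model2("declining")
        a = simulate_ensemble(spec, 5, base_seed=42, n_records=50)
        b = simulate_ensemble(spec, 5, base_seed=42, n_records=50)
        for ta, tb in zip(a, b):
            assert ta.seed == tb.seed
            np.testing.assert_array_equal(ta.counts, tb.counts)
            np.testing.assert_array_equal(ta.firing_counts, tb.firing_counts)

    def test_single_cell_ensemble_reduces_to_simulate(self):
        spec = build_model1()
        ens = simulate_ensemble(spec, 1, base_seed=7, n_records=50)
        tr = simulate(spec, seed=ens.seeds[0], n_records=50)
        np.testing.assert_array_equal(ens.trajectories[0].counts, tr.counts)

    def test_record_grid_validation(self):
        spec = build_model1()
        with pytest.raises(ValueError):
            simulate(spec, record_times=np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate(spec, t_max=10.0, record_times=np.array([5.0, 20.0]))

    def test_default_record_grid_has_500_points_over_century(self):
        g = default_record_times(100 * YEAR_SECONDS)
        assert len(g) == 500
        assert g[-1] == 100 * YEAR_SECONDS
        assert np.allclose(np.diff(g), 0.2 * YEAR_SECONDS)

    def test_firing_counts_non_decreasing_and_match_state(self):
        tr = simulate(build_model1(), seed=11)
        fire = tr.firing_counts
        assert np.all(np.diff(fire, axis=0) >= 0)
        # net count equals initial + production - degradation firings
        prod = tr.firing_series("AbetaProduction")
        deg = tr.firing_series("AbetaDegradation")
        np.testing.assert_array_equal(tr.series("Abeta"), 1 + prod - deg)


class TestEvents:
    def test_event_atomicity_pre_trigger_identical(self):
        base = build_model1()
        tau = 30 * YEAR_SECONDS
        evented = ModelSpec(
            name=base.name,
            species=base.species,
            parameters=base.parameters,
            reactions=base.reactions,
            events=(TimedEvent(tau, species_assignments={"Abeta": 500}),),
        )
        a = simulate(base, seed=9)
        b = simulate(evented, seed=9)
        pre = a.record_times < tau
        np.testing.assert_array_equal(a.counts[pre], b.counts[pre])
        # at the first grid point after the trigger the assignment is visible
        first_post = np.argmax(a.record_times >= tau)
        assert b.series("Abeta")[first_post] >= 400  # 500 minus some decay

    def test_parameter_event_changes_rate(self):
        base = build_model1()
        tau = 50 * YEAR_SECONDS
        evented = ModelSpec(
            name="switch_off",
            species=base.species,
            parameters=base.parameters,
            reactions=base.reactions,
            events=(
                TimedEvent(tau, parameter_assignments={"k_prod": 0.0,
                                                       "k_deg": 0.0}),
            ),
        )
        tr = simulate(evented, seed=13)
        post = tr.record_times >= tau
        # with both rates switched off, the count is frozen after the event
        assert np.ptp(tr.series("Abeta")[post]) == 0

    def test_event_beyond_horizon_warns_and_is_ignored(self):
        base = build_model1()
        evented = ModelSpec(
            name="late",
            species=base.species,
            parameters=base.parameters,
            reactions=base.reactions,
            events=(TimedEvent(1e12, species_assignments={"Abeta": 99}),),
        )
        with pytest.warns(UserWarning, match="after the simulation horizon"):
            tr = simulate(evented, t_max=100.0, n_records=10, seed=1)
        assert tr.series("Abeta").max() < 99


class TestExactness:
    def test_ssa_matches_cme_matrix_exponential(self):
        """Empirical SSA distribution at a fixed time vs the exact
        master-equation solution on a truncated state space (TV < 0.05)."""
        spec = _toy_two_species()
        AMAX, BMAX = 14, 7
        states = [(a, b) for a in range(AMAX + 1) for b in range(BMAX + 1)]
        sidx = {s: i for i, s in enumerate(states)}
        Q = np.zeros((len(states), len(states)))
        for (a, b) in states:
            i = sidx[(a, b)]
            moves = [
                (1.0, (a + 1, b)),
                (0.5 * a, (a - 1, b)),
                (0.3 * a * (a - 1) * 0.5, (a - 2, b + 1)),
                (0.4 * b, (a + 2, b - 1)),
            ]
            for rate, s2 in moves:
                if rate > 0 and 0 <= s2[0] <= AMAX and 0 <= s2[1] <= BMAX:
                    Q[i, sidx[s2]] += rate
                    Q[i, i] -= rate
        T = 3.0
        p0 = np.zeros(len(states))
        p0[sidx[(0, 0)]] = 1.0
        p_exact = p0 @ expm(Q * T)
        assert p_exact.sum() == pytest.approx(1.0, abs=1e-8)

        n_rep = 10_000
        emp = np.zeros(len(states))
        grid = np.array([T])
        for k in range(n_rep):
            tr = simulate(spec, t_max=T, record_times=grid, seed=1_000 + k)
            key = (int(tr.series("A")[0]), int(tr.series("B")[0]))
            if key in sidx:
                emp[sidx[key]] += 1
        emp /= n_rep
        tv = 0.5 * np.abs(emp - p_exact).sum()
        assert tv < 0.05

    def test_poisson_stationary_law(self, model1_normal_ens, model1_ad_ens):
        """Immigration-death occupancy is Poisson(k_prod/k_deg): grand mean
        and variance agree within 3 standard errors for both clearance
        rates."""
        for ens, k_deg in ((model1_normal_ens, 2.1e-5), (model1_ad_ens, 1.5e-5)):
            lam = 1.86e-5 / k_deg
            x = ens.stack("Abeta").astype(float)
            n = x.size  # 100 cells x 500 near-independent samples
            grand_mean = x.mean()
            se_mean = math.sqrt(lam / n)
            assert abs(grand_mean - lam) < 3 * se_mean
            grand_var = x.var()
            # SE of the variance of a Poisson sample: sqrt((mu4 - var^2)/n),
            # with mu4 = lam*(1 + 3*lam) for the centred fourth moment
            mu4 = lam * (1 + 3 * lam)
            se_var = math.sqrt((mu4 - lam**2) / n) if mu4 > lam**2 else math.sqrt(lam / n)
            assert abs(grand_var - lam) < 4 * se_var

    def test_enzyme_decay_matches_closed_form(self):
        """Pure first-order decay of the 1000-copy enzyme pool: ensemble mean
        at 60 years within 3 SE of 1000*exp(-k t) ~ 711."""
        spec = ModelSpec(
            name="nep_decay",
            species=(SpeciesState("Nep", 1000),
                     SpeciesState("Sink", 0, constant=True)),
            parameters=ParameterSet(k=1.8e-10),
            reactions=(
                Reaction("decay", {"Nep": 1}, {"Sink": 1},
                         HazardKind.FIRST_ORDER, "k"),
            ),
        )
        t60 = 60 * YEAR_SECONDS
        ens = simulate_ensemble(spec, 100, base_seed=5,
                                t_max=t60, n_records=10)
        finals = np.array([tr.series("Nep")[-1] for tr in ens])
        expected = 1000 * math.exp(-1.8e-10 * t60)
        se = math.sqrt(1000 * math.exp(-1.8e-10 * t60)
                       * (1 - math.exp(-1.8e-10 * t60)) / 100)
        assert abs(finals.mean() - expected) < 3 * se


class TestFastForward:
    def test_zero_dt_is_identity(self):
        spec = build_model1()
        state = {"Abeta": 3, "Source": 1, "Sink": 0}
        rng = np.random.default_rng(0)
        assert fast_forward_linear(spec, state, 0.0, rng) == state

    def test_rejects_active_nonlinear_hazard(self):
        spec = build_model2("normal")
        state = spec.initial_state()
        state.update(Abeta=5)
        with pytest.raises(LinearityContractError):
            fast_forward_linear(spec, state, 1.0, np.random.default_rng(0))

    def test_distribution_matches_exact_ssa(self):
        """Fast-forwarded immigration-death state at 10 years is
        statistically indistinguishable from step-by-step SSA
        (chi-squared two-sample test, n = 2000, alpha = 0.01)."""
        spec = build_model1()
        dt = 10 * YEAR_SECONDS
        rng = np.random.default_rng(123)
        n = 2000
        ff = np.array(
            [
                fast_forward_linear(spec, {"Abeta": 1, "Source": 1, "Sink": 0},
                                    dt, rng)["Abeta"]
                for _ in range(n)
            ]
        )
        grid = np.array([dt])
        ssa = np.array(
            [
                simulate(spec, t_max=dt, record_times=grid,
                         seed=50_000 + i).series("Abeta")[0]
                for i in range(n)
            ]
        )
        top = max(ff.max(), ssa.max())
        bins = np.arange(-0.5, top + 1.5)
        c1, _ = np.histogram(ff, bins)
        c2, _ = np.histogram(ssa, bins)
        # pool sparse tails so expected counts are adequate
        keep = (c1 + c2) >= 10
        c1 = np.append(c1[keep], c1[~keep].sum())
        c2 = np.append(c2[keep], c2[~keep].sum())
        stat, p, *_ = stats.chi2_contingency(np.vstack([c1, c2]))
        assert p > 0.01

    def test_matches_poisson_influx_from_empty(self):
        """From an empty pool the transition law is exactly
        Poisson(k_prod/k_deg * (1 - exp(-k_deg dt)))."""
        spec = build_model1()
        dt = 5 * YEAR_SECONDS
        rng = np.random.default_rng(7)
        draws = np.array(
            [
                fast_forward_linear(spec, {"Abeta": 0, "Source": 1, "Sink": 0},
                                    dt, rng)["Abeta"]
                for _ in range(4000)
            ]
        )
        lam = (1.86e-5 / 2.1e-5) * (1 - math.exp(-2.1e-5 * dt))
        assert draws.mean() == pytest.approx(lam, abs=3 * math.sqrt(lam / 4000))
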