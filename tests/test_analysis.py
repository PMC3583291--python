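"""Trajectory statistics: exceedance, correlation, plaque metrics, curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquesim.analysis import (
    correlate_mean_vs_exceedance,
    curve_shape,
    exceedance_percent,
    plaque_metrics,
    point_prevalence,
    prevalence_ci_half_width,
    prevalence_curve,
)
from plaquesim.engine import Trajectory
from plaquesim.units import YEAR_SECONDS


def make_traj(abp=None, abeta=None, seed=0):
    """Construct a synthetic trajectory on a yearly grid from raw arrays."""
    series = {}
    if abp is not None:
        series["AbP"] = np.asarray(abp, np.int64)
    if abeta is not None:
        series["Abeta"] = np.asarray(abeta, np.int64)
    n = len(next(iter(series.values())))
    names = tuple(series)
    counts = np.stack([series[s] for s in names], axis=1)
    return Trajectory(
        record_times=np.arange(1, n + 1) * YEAR_SECONDS,
        counts=counts,
        firing_counts=np.zeros((n, 0), np.int64),
        species_names=names,
        reaction_ids=(),
        seed=seed,
        model_id="synthetic",
    )


class TestExceedance:
    def test_constant_zero_and_one(self):
        assert exceedance_percent(make_traj(abeta=[0] * 10), "Abeta", 1) == 0.0
        assert (
            exceedance_percent(make_traj(abeta=[1] * 10), "Abeta", 1,
                               comparator="ge")
            == 100.0
        )
        # strict comparator: a count of exactly 1 does not exceed 1
        assert exceedance_percent(make_traj(abeta=[1] * 10), "Abeta", 1) == 0.0

    def test_empty_trajectory_rejected(self):
        tr = make_traj(abeta=[1])
        tr.counts = tr.counts[:0]
        with pytest.raises(ValueError):
            exceedance_percent(tr, "Abeta", 1)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        counts=st.lists(st.integers(0, 8), min_size=1, max_size=60),
        comparator=st.sampled_from(["gt", "ge"]),
    )
    def test_monotone_non_increasing_in_threshold(self, counts, comparator):
        tr = make_traj(abeta=counts)
        vals = [
            exceedance_percent(tr, "Abeta", thr, comparator)
            for thr in range(0, 10)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_poisson_tail_on_turnover_ensemble(self, model1_normal_ens):
        """Long-run occupancy matches the Poisson(0.886) stationary law:
        P(X >= 1) = 58.8% and P(X > 1) = 22.2%."""
        lam = 1.86e-5 / 2.1e-5
        ge1 = np.mean(
            [exceedance_percent(t, "Abeta", 1, "ge") for t in model1_normal_ens]
        )
        gt1 = np.mean(
            [exceedance_percent(t, "Abeta", 1, "gt") for t in model1_normal_ens]
        )
        assert ge1 == pytest.approx(100 * (1 - math.exp(-lam)), abs=1.0)
        assert gt1 == pytest.approx(
            100 * (1 - math.exp(-lam) * (1 + lam)), abs=1.0
        )


class TestCorrelation:
    def test_textbook_formulas_on_small_fixture(self):
        """Pearson r and the slope t-test match a direct evaluation of the
        closed-form expressions on a hand-checkable 5-point dataset."""
        abeta = [[0, 0, 1, 2, 1], [1, 2, 2, 3, 0], [0, 1, 0, 0, 1],
                 [2, 2, 3, 1, 1], [0, 0, 0, 1, 0]]
        trajs = [make_traj(abeta=row) for row in abeta]
        res = correlate_mean_vs_exceedance(trajs, threshold=1, comparator="ge")

        x = np.array([np.mean(r) for r in abeta])
        y = np.array([100 * np.mean(np.array(r) >= 1) for r in abeta])
        n = len(x)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        r_direct = sxy / math.sqrt(sxx * syy)
        slope_direct = sxy / sxx
        rss = syy - slope_direct * sxy
        se = math.sqrt(rss / (n - 2) / sxx)
        t_stat = slope_direct / se
        from scipy.stats import t as tdist

        p_direct = 2 * tdist.sf(abs(t_stat), n - 2)

        assert res.pearson_r == pytest.approx(r_direct)
        assert res.slope == pytest.approx(slope_direct)
        assert res.slope_p_value == pytest.approx(p_direct)

    def test_perfectly_linear_pairs(self):
        # cells whose exceedance is an exact affine function of the mean
        trajs = [make_traj(abeta=[1] * k + [0] * (4 - k)) for k in (0, 1, 2, 3)]
        res = correlate_mean_vs_exceedance(trajs, threshold=1, comparator="ge")
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope_p_value < 1e-10

    def test_zero_variance_flagged(self):
        trajs = [make_traj(abeta=[1, 1, 1])] * 3
        with pytest.raises(ValueError, match="zero variance"):
            correlate_mean_vs_exceedance(trajs, threshold=1)

    def test_needs_three_cells(self):
        with pytest.raises(ValueError):
            correlate_mean_vs_exceedance([make_traj(abeta=[1, 2])], 1)


class TestPlaqueMetrics:
    def test_never_exceeding_threshold(self):
        m = plaque_metrics(make_traj(abp=[0, 3, 5, 2]), 30)
        assert not m.has_plaque and m.lag_time_years is None
        assert m.max_size == 5 and m.final_size == 2

    def test_lag_is_first_crossing_time(self):
        abp = [0] * 61 + [31] + [20] * 38
        m = plaque_metrics(make_traj(abp=abp), 30)
        assert m.has_plaque
        assert m.lag_time_years == pytest.approx(62.0)  # yearly grid, 1-based

    def test_step_trajectory_sizes(self):
        m = plaque_metrics(make_traj(abp=[0, 35, 20, 40]), 30)
        assert m.lag_time_years == pytest.approx(2.0)
        assert m.max_size == 40 and m.final_size == 40

    def test_threshold_is_strict(self):
        m = plaque_metrics(make_traj(abp=[30] * 5), 30)
        assert not m.has_plaque


class TestPrevalence:
    def test_ci_formula(self):
        # 50 of 100 cells: half-width 1.96 * sqrt(50*50/100) = 9.8
        assert prevalence_ci_half_width(50.0, 100) == pytest.approx(9.8)
        assert prevalence_ci_half_width(0.0, 100) == 0.0
        assert prevalence_ci_half_width(100.0, 50) == 0.0

    def test_curve_counts_cumulative_association(self):
        trajs = [
            make_traj(abp=[0, 40, 0, 0]),  # plaque at year 2, then shrinks
            make_traj(abp=[0, 0, 0, 50]),
            make_traj(abp=[0, 0, 0, 0]),
            make_traj(abp=[31, 0, 0, 0]),
        ]
        curve = prevalence_curve(trajs, plaque_threshold=30)
        assert list(curve.percent) == [25.0, 50.0, 50.0, 75.0]
        assert np.all(np.diff(curve.percent) >= 0)
        assert curve.at_age(2.5) == 50.0
        # whereas point prevalence can decrease when plaques dissolve
        pp = point_prevalence(trajs, plaque_threshold=30)
        assert list(pp.percent) == [25.0, 25.0, 0.0, 25.0]

    def test_invariant_to_cell_order(self, model2_declining_ens):
        trajs = list(model2_declining_ens)
        fwd = prevalence_curve(trajs, plaque_threshold=30)
        rev = prevalence_curve(trajs[::-1], plaque_threshold=30)
        np.testing.assert_array_equal(fwd.percent, rev.percent)

    def test_no_plaques_gives_flat_zero(self):
        curve = prevalence_curve([make_traj(abp=[0, 0, 0])] * 3,
                                 plaque_threshold=30)
        assert np.all(curve.percent == 0) and np.all(curve.ci_half_width == 0)


class TestCurveShape:
    def _curve(self, ages, percent):
        from plaquesim.analysis import PrevalenceCurve

        percent = np.asarray(percent, float)
        return PrevalenceCurve(
            ages_years=np.asarray(ages, float),
            percent=percent,
            ci_half_width=np.zeros_like(percent),
            n_cells=100,
        )

    def test_linear_curve(self):
        ages = np.linspace(0, 100, 20)
        assert curve_shape(self._curve(ages, 0.3 * ages)).label == "linear"

    def test_exponential_curve(self):
        ages = np.linspace(0, 100, 20)
        assert (
            curve_shape(self._curve(ages, np.expm1(0.05 * ages))).label
            == "convex-increasing"
        )

    def test_flat_curve(self):
        ages = np.linspace(0, 100, 20)
        assert curve_shape(self._curve(ages, np.zeros_like(ages))).label == "flat"

    def test_needs_five_points(self):
        with pytest.raises(ValueError):
            curve_shape(self._curve([1, 2, 3], [0, 1, 2]))
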