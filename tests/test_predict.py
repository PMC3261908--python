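"""Fixed-point prediction: interpolation, intersection enumeration, Monte Carlo."""

import numpy as np
import pytest

from quorumlogic import (
    DEFAULT_LUXI_FEEDBACK,
    DEFAULT_PLF,
    EquivalenceLine,
    IOC,
    NoiseModel,
    TopologySpec,
    find_intersections,
    generate_plf_grid,
    interp_across_regulator,
    ioc_from_grid,
    loglog_interp,
    mc_predict,
    model_based_ioc,
    plf_eval,
)
from quorumlogic.ddr import steady_states_at_density
from quorumlogic.params import ConfigurationError


def brute_force_crossings(ioc: IOC, scale: float, n: int = 100_000):
    """Independent oracle: dense sign-change scan of the interpolated IOC
    against y = s x, in log space, over a range covering the flat tails."""
    lo = min(ioc.x[0] * 1e-8, np.min(ioc.y) / scale * 1e-3)
    hi = max(ioc.x[-1] * 1e8, np.max(ioc.y) / scale * 1e3)
    x = np.geomspace(lo, hi, n)
    g = np.log(loglog_interp(ioc, x)) - np.log(scale * x)
    s = np.sign(g)
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    brackets = [(x[k], x[k + 1]) for k in idx]
    exact = x[np.nonzero(g == 0)[0]]
    return brackets, exact


def random_monotone_ioc(rng: np.random.Generator) -> IOC:
    npts = rng.integers(4, 10)
    x = np.sort(10 ** rng.uniform(-1, 3, npts))
    while np.any(np.diff(x) <= 0):
        x = np.sort(10 ** rng.uniform(-1, 3, npts))
    # monotone nondecreasing outputs over ~3 decades, strictly positive
    steps = 10 ** rng.uniform(-2, 1, npts)
    y = 1e-2 * np.cumsum(steps)
    return IOC(x=x, y=y)


class TestLogLogInterp:
    def test_nodes_exact(self):
        ioc = IOC(x=[1.0, 10.0, 100.0], y=[2.0, 30.0, 50.0])
        np.testing.assert_allclose(loglog_interp(ioc, ioc.x), ioc.y, rtol=1e-14)

    def test_power_law_midpoint(self):
        ioc = IOC(x=[1.0, 100.0], y=[1.0, 100.0])
        assert loglog_interp(ioc, 10.0) == pytest.approx(10.0, rel=1e-12)

    def test_flat_extrapolation(self):
        ioc = IOC(x=[1.0, 100.0], y=[5.0, 700.0])
        assert loglog_interp(ioc, 1e-6) == pytest.approx(5.0)
        assert loglog_interp(ioc, 1e9) == pytest.approx(700.0)

    def test_empty_ioc_rejected(self):
        with pytest.raises(ConfigurationError):
            IOC(x=[], y=[])


class TestIocFromGrid:
    def test_vertical_cut_has_seven_points(self, clean_grid):
        ioc = ioc_from_grid(clean_grid, "luxR", 2)
        assert len(ioc.x) == 7
        assert ioc.axis == "luxR"

    def test_noise_free_slice_matches_model(self, clean_grid):
        ioc = ioc_from_grid(clean_grid, "luxI", 4)
        iptg = clean_grid.IPTG_levels[4]
        summary = clean_grid.replicate_summary().reset_index()
        sl = summary[summary.IPTG_uM == iptg]
        expected = plf_eval(
            sl["luxI_cfp"].to_numpy(), sl["luxR_yfp"].to_numpy(), DEFAULT_PLF
        )
        np.testing.assert_allclose(np.sort(ioc.y), np.sort(expected), rtol=1e-9)

    def test_monotone_when_noise_free(self, clean_grid):
        for k in range(6):
            ioc = ioc_from_grid(clean_grid, "luxR", k)
            assert np.all(np.diff(ioc.y) >= -1e-15)

    def test_bad_regulator_index_rejected(self, clean_grid):
        with pytest.raises(ConfigurationError):
            ioc_from_grid(clean_grid, "luxR", 99)


class TestFindIntersections:
    def test_constant_ioc_single_stable_point(self):
        ioc = IOC(x=[1.0, 10.0], y=[20.0, 20.0])
        fps = find_intersections(ioc, EquivalenceLine(scale=4.0))
        assert len(fps) == 1
        assert fps.points[0].level == pytest.approx(5.0, rel=1e-10)
        assert fps.points[0].stability == "stable"

    def test_sigmoidal_ioc_three_points_middle_unstable(self):
        # steep sigmoid crossing y = x three times
        x = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        y = np.array([0.05, 0.055, 1.0, 18.0, 20.0])
        fps = find_intersections(IOC(x=x, y=y), EquivalenceLine(scale=1.0))
        assert len(fps) == 3
        assert fps.stabilities == ["stable", "unstable", "stable"]

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 200:
            ioc = random_monotone_ioc(rng)
            scale = 10 ** rng.uniform(-2, 2)
            brackets, exact = brute_force_crossings(ioc, scale)
            if exact.size:  # grid point exactly on the line: skip degenerate draw
                continue
            fps = find_intersections(ioc, EquivalenceLine(scale=scale))
            assert len(fps) == len(brackets), (ioc.x, ioc.y, scale)
            for q, (lo, hi) in zip(fps.points, brackets):
                assert lo <= q.level <= hi
            checked += 1

    def test_stability_labels_alternate(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            ioc = random_monotone_ioc(rng)
            fps = find_intersections(ioc, 10 ** rng.uniform(-2, 2))
            labels = [q.stability for q in fps if q.stability != "unknown"]
            for a, b in zip(labels, labels[1:]):
                assert a != b
            if len(fps) % 2 == 1 and "unknown" not in fps.stabilities:
                assert fps.stabilities[0] == fps.stabilities[-1] == "stable"


class TestModelBasedIOC:
    def test_matches_grid_nodes_when_noise_free(self, clean_grid):
        topo = DEFAULT_LUXI_FEEDBACK
        ioc_grid = ioc_from_grid(clean_grid, "luxI", 3)
        summary = clean_grid.replicate_summary().reset_index()
        rbar = summary[summary.IPTG_uM == clean_grid.IPTG_levels[3]]["luxR_yfp"].iloc[0]
        ioc_model = model_based_ioc(
            DEFAULT_PLF, topo, rbar, (ioc_grid.x[0], ioc_grid.x[-1]), output_scale=1.0
        )
        from quorumlogic import loglog_interp as interp

        np.testing.assert_allclose(
            interp(ioc_model, ioc_grid.x), ioc_grid.y, rtol=1e-3
        )

    def test_saturates_at_output_scale_times_plf_ceiling(self):
        ioc = model_based_ioc(
            DEFAULT_PLF, DEFAULT_LUXI_FEEDBACK, 600.0, (1.0, 1e6), output_scale=2.0
        )
        # at saturating input the IOC reaches output_scale * f(inf, Rbar),
        # which approaches output_scale as the regulator saturates too
        assert ioc.y[-1] == pytest.approx(
            2.0 * plf_eval(1e6, 600.0, DEFAULT_PLF), rel=1e-9
        )
        big = model_based_ioc(
            DEFAULT_PLF, DEFAULT_LUXI_FEEDBACK, 1e8, (1.0, 1e8), output_scale=2.0
        )
        assert big.y[-1] == pytest.approx(2.0, rel=1e-4)

    def test_regulator_separates_iocs(self):
        lo = model_based_ioc(DEFAULT_PLF, DEFAULT_LUXI_FEEDBACK, 10.0, (1.0, 1e3))
        hi = model_based_ioc(DEFAULT_PLF, DEFAULT_LUXI_FEEDBACK, 600.0, (1.0, 1e3))
        mid = len(lo.x) // 2
        assert hi.y[mid] / lo.y[mid] >= 10.0


class TestMCPredict:
    def test_zero_noise_trials_identical(self, clean_grid):
        res = mc_predict(clean_grid, 1 / 600.0, "luxI", 3, trials=20, seed=0,
                         noise_log_sd=0.0)
        det = res.deterministic.levels
        for t in res.trials:
            np.testing.assert_allclose(t.levels, det, rtol=1e-12)

    def test_deep_monostable_fraction_zero(self, clean_grid):
        # high-regulator slice at grid density: single high intersection
        res = mc_predict(clean_grid, 1 / 600.0, "luxI", 6, trials=50, seed=1,
                         noise_log_sd=0.05)
        assert res.multistable_fraction == 0.0

    def test_near_bifurcation_fraction_intermediate_and_reproducible(self):
        # density slightly above the hysteretic window for this slice puts the
        # deterministic IOC near tangency; noise flips multistability on and off
        grid = generate_plf_grid(
            p=DEFAULT_PLF.with_density(0.06),
            noise=NoiseModel(cv=0.0, seed=0), replicates=2,
        )
        res = mc_predict(grid, 1 / 600.0, "luxI", 2, trials=200, seed=7,
                         noise_log_sd=0.25)
        res2 = mc_predict(grid, 1 / 600.0, "luxI", 2, trials=200, seed=7,
                          noise_log_sd=0.25)
        assert 0.0 < res.multistable_fraction < 1.0
        assert res.multistable_fraction == res2.multistable_fraction

    def test_ensemble_variance_collapses_as_noise_vanishes(self, clean_grid):
        spread = []
        for sd in (0.2, 0.05, 0.0125, 0.0):
            res = mc_predict(clean_grid, 1 / 600.0, "luxI", 5, trials=100, seed=3,
                             noise_log_sd=sd)
            top = np.array([t.stable_levels.max() for t in res.trials])
            spread.append(np.std(np.log(top)))
        assert spread[0] > spread[1] > spread[2] > spread[3]
        assert spread[3] < 1e-12


class TestInterpAcrossRegulator:
    def test_measured_level_returns_its_prediction(self):
        out = interp_across_regulator([1.0, 10.0], [[5.0], [50.0]], 10.0)
        np.testing.assert_allclose(out, [50.0])

    def test_power_law_midpoint(self):
        out = interp_across_regulator([1.0, 100.0], [[10.0], [1000.0]], 10.0)
        assert out[0] == pytest.approx(100.0, rel=1e-12)

    def test_branch_count_change_warns_and_interpolates_outer(self):
        with pytest.warns(UserWarning, match="branch count changes"):
            out = interp_across_regulator(
                [1.0, 100.0], [[10.0], [5.0, 500.0]], 10.0
            )
        assert out.size == 1

    def test_branchwise_matches_model_based_prediction(self):
        """Interpolated stable branches track the true steady-state family."""
        topo = DEFAULT_LUXI_FEEDBACK
        regs = np.array([40.0, 48.0, 58.0])
        preds = []
        for r in regs:
            fps = steady_states_at_density(
                topo.replace(luxR_fixed=float(r)), DEFAULT_PLF, 0.05
            )
            preds.append(fps.stable_levels)
        target = 44.0
        got = interp_across_regulator(regs, preds, target)
        truth = steady_states_at_density(
            topo.replace(luxR_fixed=target), DEFAULT_PLF, 0.05
        ).stable_levels
        assert len(got) == len(truth)
        np.testing.assert_allclose(got, truth, rtol=0.25)
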