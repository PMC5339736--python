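"""Tests for stationary oracles, collapse detection, and protocols."""

import numpy as np
import pytest

import irristoch as ir
from irristoch.analytics import (
    CollapseReport,
    StationaryDistribution,
    TailMassError,
    all_drift_negative,
    all_drift_positive,
    asymmetry_search,
    collapse_fractions,
    collapse_trap_protocol,
    detect_collapse,
    drift_profile,
    empirical_distribution,
    product_form_from_rates,
    stationary_product_form,
    summarize_population,
    total_variation,
)
from irristoch.drivers import beta_from_mean_cv, constant_driver, lognormal_from_mean_cv
from irristoch.simulator import SimConfig, Trajectory, run_trajectory


def _dist(p, scheme="bernoulli"):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.maximum(p, 1e-320)), -np.inf)
    return StationaryDistribution(p, logp, scheme)


def _fake_traj(params, year_mins, N_samples=None):
    year_mins = np.asarray(year_mins, dtype=np.int64)
    n_years = len(year_mins)
    if N_samples is None:
        N_samples = np.concatenate([[year_mins[0]], year_mins])
    N_samples = np.asarray(N_samples, dtype=np.int64)
    steps = np.arange(len(N_samples), dtype=np.int64) * 20_000
    return Trajectory(
        step=steps,
        time=steps * params.dt,
        N=N_samples,
        W_years=np.full(n_years, params.W_bar),
        T_years=np.full(n_years, params.T_bar),
        year_min=year_mins,
        year_max=N_samples[1:].copy() if len(N_samples) == n_years + 1 else year_mins,
        scheme=params.scheme,
        seed=0,
        params=params,
        record_stride=20_000,
    )


class TestProductForm:
    def test_toy_geometric_chain(self):
        # b = 2, d = 1 everywhere: masses proportional to 1, 2, 4
        b = np.array([2.0, 2.0, 2.0])
        d = np.array([1.0, 1.0, 1.0])
        p, logp = product_form_from_rates(b, d, "bernoulli")
        assert p == pytest.approx([1 / 7, 2 / 7, 4 / 7], rel=1e-14)
        assert logp == pytest.approx(np.log([1 / 7, 2 / 7, 4 / 7]), rel=1e-14)

    def test_jump_form_matches_matrix_oracle(self):
        """Forced-move invariant measure vs brute-force eigenvector."""
        rng = np.random.default_rng(3)
        n = 12
        b = rng.uniform(0.5, 3.0, n)
        d = rng.uniform(0.5, 3.0, n)
        d[0] = 0.0
        # brute force: build the forced-move transition matrix and iterate
        P = np.zeros((n, n))
        for i in range(n):
            tot = b[i] + d[i]
            if i + 1 < n:
                P[i, i + 1] = b[i] / tot
            else:
                P[i, i] += b[i] / tot  # reflect at the truncation edge
            if i > 0:
                P[i, i - 1] = d[i] / tot
        pi = np.full(n, 1.0 / n)
        for _ in range(200_000):
            pi = pi @ P
        pi /= pi.sum()
        p, _ = product_form_from_rates(b, d, "jump")
        assert p == pytest.approx(pi, abs=1e-10)

    def test_bernoulli_form_matches_matrix_oracle(self):
        rng = np.random.default_rng(4)
        n = 10
        b = rng.uniform(0.5, 3.0, n)
        d = rng.uniform(0.5, 3.0, n)
        dt = 0.05
        P = np.zeros((n, n))
        for i in range(n):
            up = b[i] * dt if i + 1 < n else 0.0
            down = d[i] * dt if i > 0 else 0.0
            if i + 1 < n:
                P[i, i + 1] = up
            if i > 0:
                P[i, i - 1] = down
            P[i, i] = 1.0 - up - down
        pi = np.full(n, 1.0 / n)
        for _ in range(200_000):
            pi = pi @ P
        pi /= pi.sum()
        p, _ = product_form_from_rates(b, d, "bernoulli")
        assert p == pytest.approx(pi, abs=1e-10)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            product_form_from_rates(np.array([-1.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            product_form_from_rates(np.array([1.0, 1.0]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            product_form_from_rates(np.array([1.0]), np.array([1.0]))


class TestStationaryDefaults:
    def test_bistable_structure(self, params, thresholds):
        dist = stationary_product_form(params)
        assert dist.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist.p >= 0)
        modes = dist.local_modes()
        assert len(modes) == 2
        low_mode, high_mode = modes
        assert 0 <= low_mode < thresholds.n_low
        assert thresholds.n_low < high_mode < params.n_cap
        # deep barrier between the basins
        barrier = dist.logp[1 : thresholds.n_low].min()
        assert dist.logp[high_mode] - barrier > 10 * np.log(10)

    def test_upper_mode_near_n_star(self, params, thresholds):
        dist = stationary_product_form(params)
        _, sd, _ = summarize_population(dist.restricted(2000, dist.n_max))
        high_mode = dist.local_modes()[-1]
        assert abs(high_mode - thresholds.n_star) <= 2 * sd

    def test_increasing_then_decreasing_in_basin(self, params, thresholds):
        dist = stationary_product_form(params)
        seg = dist.logp[thresholds.n_low : thresholds.n_star + 1]
        diffs = np.diff(seg)
        change = np.nonzero(np.diff(np.sign(diffs[diffs != 0])))[0]
        assert len(change) <= 1  # single rise/fall switch

    def test_tail_error_when_truncated_tight(self, params):
        with pytest.raises(TailMassError):
            stationary_product_form(params, N_max=7100)

    def test_upper_basin_cv_order_of_magnitude(self, params):
        dist = stationary_product_form(params)
        _, _, cv = summarize_population(dist.restricted(2000, dist.n_max))
        assert 1e-3 <= cv <= 1e-2


class TestEmpiricalDistribution:
    def test_point_mass(self, params):
        traj = _fake_traj(params, [5, 5, 5], N_samples=[5, 5, 5, 5])
        dist = empirical_distribution(traj, 1)
        assert dist.p[-1] == 1.0
        assert summarize_population(dist)[1] == 0.0

    def test_burn_in_validation(self, params):
        traj = _fake_traj(params, [5, 5, 5])
        with pytest.raises(ValueError):
            empirical_distribution(traj, 3)

    def test_oracle_equivalence_small(self, small_params):
        thr = ir.compute_thresholds(small_params)
        cfg = SimConfig(
            params=small_params,
            w_spec=constant_driver("lognormal", 1.0),
            t_spec=constant_driver("beta", 0.2),
            n_years=1000,
            N0=thr.n_star,
            seed=8,
            record_stride=1,
        )
        traj = run_trajectory(cfg)
        oracle = stationary_product_form(small_params, N_max=250)
        emp = empirical_distribution(traj, 100, N_max=250)
        assert total_variation(emp, oracle) < 0.03


class TestSummaries:
    def test_point_mass_moments(self):
        p = np.zeros(101)
        p[100] = 1.0
        assert summarize_population(_dist(p)) == (100.0, 0.0, 0.0)

    def test_two_point_moments(self):
        p = np.zeros(111)
        p[90] = p[110] = 0.5
        mean, sd, cv = summarize_population(_dist(p))
        assert (mean, sd, cv) == pytest.approx((100.0, 10.0, 0.1))

    def test_zero_mean_cv_undefined(self):
        p = np.zeros(3)
        p[0] = 1.0
        with pytest.raises(ValueError, match="cv"):
            summarize_population(_dist(p))

    def test_restricted_carries_no_mass_error(self):
        p = np.zeros(10)
        p[9] = 1.0
        with pytest.raises(ValueError):
            _dist(p).restricted(0, 3)


class TestCollapseDetection:
    def test_no_collapse(self, params):
        traj = _fake_traj(params, [7000, 6900, 7050])
        report = detect_collapse(traj, 727)
        assert not report.collapsed
        assert report.first_passage_year is None

    def test_first_passage_year(self, params):
        traj = _fake_traj(params, [7000, 6900, 0, 10])
        report = detect_collapse(traj, 727)
        assert report.collapsed
        assert report.first_passage_year == 3
        assert report.min_N == 0


class TestDriftProfile:
    def test_profile_values(self, params):
        prof = drift_profile(params, 1.0, 0.2, [500, 3333])
        assert prof[0, 1] == pytest.approx(-0.341, abs=1e-3)
        assert prof[1, 1] == pytest.approx(3.123, abs=1e-3)

    def test_sign_pattern_at_baseline(self, params, thresholds):
        prof = drift_profile(params, 1.0, 0.2, np.arange(0, 12_001))
        drift = prof[:, 1]
        positive = np.nonzero(drift > 0)[0]
        interior = positive[positive > 0]
        assert drift[0] > 0  # boundary state pushes up
        assert interior.min() == thresholds.n_low
        # pi(n_star) = pi_o exactly by calibration, so drift vanishes there
        # and is strictly negative beyond
        assert drift[thresholds.n_star] == 0.0
        assert interior.max() == thresholds.n_star - 1
        assert np.all(drift[thresholds.n_star + 1 :] < 0)

    def test_all_negative_under_drought(self, params):
        assert all_drift_negative(params, 0.7, 0.2)
        assert not all_drift_negative(params, 1.0, 0.2)

    def test_no_universal_growth(self, params):
        assert not all_drift_positive(params, 1.0, 0.2)
        assert not all_drift_positive(params, 5.0, 0.5)

    def test_asymmetry_search(self, params):
        res = asymmetry_search(
            params, W_grid=[0.5, 0.7, 1.0, 1.5], T_grid=[0.05, 0.2, 0.5, 0.95]
        )
        assert len(res["all_negative"]) > 0
        assert res["all_positive"] == []


class TestProtocols:
    def test_collapse_fraction_strong_tax_noise(self, params):
        # CV_T = 0.8: nonviable tax years arrive ~1 in 4; collapse is fast
        fr = collapse_fractions(
            params, "T", [0.8], n_reps=5, n_years=10, base_seed=2
        )
        assert fr[0.8] >= 0.8

    def test_collapse_fraction_calm_is_zero(self, params):
        fr = collapse_fractions(
            params, "W", [0.02], n_reps=5, n_years=10, base_seed=2
        )
        assert fr[0.02] == 0.0

    def test_invalid_driver_name(self, params):
        with pytest.raises(ValueError):
            collapse_fractions(params, "X", [0.1])

    def test_trap_protocol_collapse_and_no_recovery(self, params):
        calm = (constant_driver("lognormal", 1.0), constant_driver("beta", 0.2))
        storm = (lognormal_from_mean_cv(1.0, 0.2), beta_from_mean_cv(0.2, 0.8))
        res = collapse_trap_protocol(params, calm, storm, (2, 20, 5), seed=11)
        assert res.collapsed_in_storm
        assert res.report.collapsed
        assert not res.recovered
        # post-collapse calm phase hovers near zero: entry at rate m balanced
        # by incentive-driven exit far below the viability basin
        assert res.phases[2].year_max.max() < res.thresholds.n_low

    def test_trap_protocol_degenerate_storm(self, params):
        calm = (constant_driver("lognormal", 1.0), constant_driver("beta", 0.2))
        res = collapse_trap_protocol(params, calm, calm, (1, 1, 1), seed=4)
        assert not res.report.collapsed
        assert res.recovered  # vacuously
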