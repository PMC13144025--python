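import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

from dyadspark.ip3r import (build_generator, initial_state, intermodal_rates,
                            max_exit_rate, modal_gates, po_curve,
                            simulate_ensemble, stationary_distribution,
                            step_ip3r)
from dyadspark.params import IP3RParams, StabilityError

from _oracles import detailed_balance_pi


@pytest.fixture(scope="module")
def params():
    return IP3RParams()


class TestIntermodalRates:
    def test_saturated_gates_leave_floor(self, params):
        # km tiny and kh huge force m*h ~ 1, so q24 collapses to a24
        p = replace(params, km_act=1e-5, kh_base=1e7, kh_amp=0.0)
        q24, _ = intermodal_rates(1.0, 1.0, p)
        _, _, _, _, a24, _ = modal_gates(1.0, 1.0, p)
        assert q24 == pytest.approx(a24, rel=1e-6)

    def test_vanishing_drive_gate_leaves_floor(self, params):
        # zero Ca kills the m gates, so q42 collapses to a42
        _, q42 = intermodal_rates(0.0, 1.0, params)
        _, _, _, _, _, a42 = modal_gates(0.0, 1.0, params)
        assert q42 == a42

    def test_regression_fixture_at_1uM_1uM(self, params):
        # independent arithmetic with the registry constants
        gp = 1.0 / (1.0 + 0.25**2)               # p=1, k_ip3=0.25
        m = 0.5                                  # c=1, km=1: 1/(1+1)
        kh = 10.0 + 70.0 * 1.0 / (1.0 + 4.0)     # 24.0
        h = kh**3 / (kh**3 + 1.0)
        q24_expect = 20.0 * (1 - gp) + 40.0 * (1 - m * h)
        q42_expect = 0.4 * gp + 100.0 * m * h * gp
        q24, q42 = intermodal_rates(1.0, 1.0, params)
        assert q24 == pytest.approx(q24_expect, rel=1e-12)
        assert q42 == pytest.approx(q42_expect, rel=1e-12)

    def test_nonnegative_over_grid(self, params):
        for c in np.geomspace(1e-3, 1e4, 15):
            for p in (0.0, 0.05, 0.5, 5.0, 50.0):
                q24, q42 = intermodal_rates(c, p, params)
                assert q24 >= 0 and q42 >= 0

    def test_no_ip3_severs_drive_entry(self, params):
        for c in (0.01, 1.0, 100.0):
            _, q42 = intermodal_rates(c, 0.0, params)
            assert q42 == 0.0


class TestGenerator:
    def test_rows_sum_to_zero(self, params):
        Q = build_generator(3.3, 1.7, params)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_table_entries(self, params):
        Q = build_generator(1.0, 1.0, params)
        assert Q[1, 5] == 10.1          # q26
        assert Q[3, 4] == 4.14e-3       # q45
        assert Q[0, 1] == 1.14          # q12

    def test_tree_topology_only(self, params):
        Q = build_generator(2.0, 2.0, params)
        edges = {(0, 1), (1, 0), (1, 2), (2, 1), (1, 5), (5, 1),
                 (1, 3), (3, 1), (3, 4), (4, 3)}
        for i in range(6):
            for j in range(6):
                if i != j and (i, j) not in edges:
                    assert Q[i, j] == 0.0

    def test_negative_rate_rejected(self, params):
        with pytest.raises(ValueError):
            build_generator(-1.0, 1.0, params)


class TestStationary:
    def test_symmetric_toy_uniform(self):
        p = IP3RParams(q12=1, q21=1, q23=1, q32=1, q26=1, q62=1,
                       q45=1, q54=1)
        pi = stationary_distribution(build_generator(1.0, 1.0, p))
        assert np.allclose(pi, 1 / 6, atol=1e-12)

    def test_drive_restricted_closed_form(self, params):
        r1 = params.q21 / params.q12
        r3 = params.q23 / params.q32
        r6 = params.q26 / params.q62
        with pytest.warns(UserWarning, match="reducible"):
            pi = stationary_distribution(build_generator(0.0, 1.0, params))
        assert pi[5] == pytest.approx(r6 / (r1 + 1 + r3 + r6), rel=1e-12)
        assert pi[3] == 0.0 and pi[4] == 0.0

    def test_park_restricted_closed_form(self, params):
        r = params.q45 / params.q54
        with pytest.warns(UserWarning, match="reducible"):
            pi = stationary_distribution(build_generator(1.0, 0.0, params))
        assert pi[4] == pytest.approx(r / (1 + r), rel=1e-12)
        assert pi[[0, 1, 2, 5]].sum() == 0.0

    @pytest.mark.parametrize("c", [0.05, 0.5, 3.0, 30.0, 300.0])
    @pytest.mark.parametrize("p", [0.1, 1.0, 10.0])
    def test_detailed_balance_matches_null_space(self, params, c, p):
        q24, q42 = intermodal_rates(c, p, params)
        pi = stationary_distribution(build_generator(q24, q42, params))
        expect = detailed_balance_pi(params.q12, params.q21, params.q23,
                                     params.q32, params.q26, params.q62,
                                     q24, q42, params.q45, params.q54)
        assert np.max(np.abs(pi - expect)) < 1e-10


class TestStepping:
    def test_one_step_probabilities_from_state_2(self, params, rng):
        c, p, dt = 0.5, 1.0, 2e-3
        q24, q42 = intermodal_rates(c, p, params)
        Q = build_generator(q24, q42, params)
        n = 40000
        dest = np.array([step_ip3r(2, Q, dt, rng) for _ in range(n)])
        for target, rate in ((1, params.q21), (3, params.q23),
                             (6, params.q26), (4, q24)):
            pr = dt * rate
            se = np.sqrt(pr * (1 - pr) / n)
            assert np.mean(dest == target) == pytest.approx(pr, abs=3 * se)

    def test_guard_rejects_large_dt(self, params):
        Q = build_generator(50.0, 50.0, params)
        with pytest.raises(StabilityError):
            step_ip3r(2, Q, dt=0.5, rng=np.random.default_rng(0))

    def test_ensemble_matches_matrix_exponential(self, params):
        c, p, t_end, dt = 0.3, 1.0, 10.0, 5e-4
        states, _ = simulate_ensemble(10000, 2, c, p, t_end, params,
                                      seed=77, dt=dt)
        q24, q42 = intermodal_rates(c, p, params)
        Q = build_generator(q24, q42, params)
        expect = expm(Q * t_end)[1]
        counts = np.bincount(states - 1, minlength=6) / len(states)
        for s in range(6):
            se = np.sqrt(max(expect[s] * (1 - expect[s]), 1e-12) / len(states))
            assert counts[s] == pytest.approx(expect[s], abs=3 * se + 0.012)

    def test_ergodic_average_matches_stationary(self, params):
        c, p = 2.0, 1.0
        q24, q42 = intermodal_rates(c, p, params)
        pi = stationary_distribution(build_generator(q24, q42, params))
        _, open_frac = simulate_ensemble(100, 2, c, p, 300.0, params, seed=5)
        assert open_frac == pytest.approx(float(pi[4] + pi[5]), abs=0.05)


class TestPoCurve:
    def test_biphasic_at_both_ip3_levels(self, params):
        grid = np.geomspace(0.01, 1000.0, 41)
        for p in (1.0, 10.0):
            po = np.array([v for _, v in po_curve(grid, p, params=params)])
            assert po[0] < 0.2 * po.max()
            assert po[-1] < 0.2 * po.max()

    def test_peak_location_windows(self, params):
        grid = np.geomspace(0.01, 1000.0, 81)
        po1 = np.array([v for _, v in po_curve(grid, 1.0, params=params)])
        assert 1.0 <= grid[po1.argmax()] <= 10.0
        po10 = np.array([v for _, v in po_curve(grid, 10.0, params=params)])
        assert grid[po10.argmax()] <= 100.0

    def test_simulated_agrees_with_stationary(self, params):
        # single-channel 1000-ms averages carry sizable run-to-run scatter
        # (state 3 dwells ~1/q32 = 84 ms), so average a few repeats
        grid = [0.1, 3.0, 100.0]
        stat = dict(po_curve(grid, 1.0, params=params))
        reps = [dict(po_curve(grid, 1.0, duration=1000.0, mode="SIMULATED",
                              seed=s, params=params)) for s in range(8)]
        for c in grid:
            mean = np.mean([r[c] for r in reps])
            assert mean == pytest.approx(stat[c], abs=0.06)

    def test_no_ip3_never_conducts(self, params):
        simu = po_curve([0.1, 10.0], 0.0, duration=200.0, mode="SIMULATED",
                        params=params)
        assert all(v == 0.0 for _, v in simu)

    def test_inert_initial_state_without_ip3(self, params, rng):
        assert initial_state(0.1, 0.0, params, rng) == 4


def test_mode_open_probabilities(params):
    # park submode is nearly silent, drive submode conducts most of the time
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        park = stationary_distribution(build_generator(1.0, 0.0, params))
        drive = stationary_distribution(build_generator(0.0, 1.0, params))
    assert park[4] < 5e-3
    assert 0.5 < drive[5] < 0.8


def test_max_exit_rate_bounds_generator(params):
    for c in (0.01, 1.0, 500.0):
        for p in (0.05, 1.0, 20.0):
            q24, q42 = intermodal_rates(c, p, params)
            Q = build_generator(q24, q42, params)
            exits = -np.diag(Q)
            assert exits.max() <= max_exit_rate(params) + 1e-9
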