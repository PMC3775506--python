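"""Wiring rules: probabilities, selection, normalization, delays, full builds."""

import warnings

import numpy as np
import pytest

from mbpnet.connectivity import (ConnectivityParams, SynapseTable,
                                 anisotropy_statistic, assign_delays,
                                 build_network, default_connectivity,
                                 direction_based_probability,
                                 draw_isotropic_weights, isotropic_probability,
                                 latency, motion_based_probability,
                                 normalize_weights, predicted_position,
                                 select_incoming)
from mbpnet.geometry import (GridSpec, TuningProperties, assemble_population,
                             torus_distance)


class TestIsotropicProbability:
    def test_zero_distance_gives_pmax(self):
        assert isotropic_probability(0.0, 0.2, 0.013) == pytest.approx(0.013)

    def test_one_sigma(self):
        assert isotropic_probability(0.2, 0.2, 1.0) == pytest.approx(
            np.exp(-0.5))

    def test_large_sigma_random_limit(self, rng):
        # sigma >> torus diameter: probabilities uniform within 0.3%
        d = rng.random(1000) * np.sqrt(2) / 2
        p = isotropic_probability(d, 10.0, 1.0)
        assert p.max() / p.min() < 1.003


class TestLatencyAndPrediction:
    def test_latency_arithmetic(self):
        assert latency(0.2, 0.5) == pytest.approx(0.4)
        assert latency(0.0, 0.5) == 0.0

    def test_latency_times_speed_is_distance(self, rng):
        d = rng.random(500)
        s = rng.random(500) + 0.05
        np.testing.assert_allclose(latency(d, s) * s, d, atol=1e-12)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            latency(0.1, 0.0)

    def test_predicted_position_wraps(self):
        got = predicted_position(np.array([0.9, 0.5]), np.array([0.5, 0.0]),
                                 np.array(0.4))
        np.testing.assert_allclose(got, [0.1, 0.5], atol=1e-12)

    def test_zero_tau_is_identity(self):
        p = np.array([0.3, 0.8])
        np.testing.assert_array_equal(
            predicted_position(p, np.array([1.0, 2.0]), np.array(0.0)), p)

    def test_latency_minimizes_prediction_miss_when_aligned(self):
        # motion pointing straight at the target: scanning tau, the miss
        # distance is minimal exactly at the inter-neuron latency
        src, tgt = np.array([0.2, 0.5]), np.array([0.45, 0.5])
        vel = np.array([0.5, 0.0])
        tau_star = latency(torus_distance(src, tgt), 0.5)
        taus = np.linspace(0.0, 1.0, 201)
        miss = torus_distance(predicted_position(src, vel, taus), tgt)
        assert taus[np.argmin(miss)] == pytest.approx(tau_star, abs=0.005)


class TestMotionBasedProbability:
    def test_perfect_prediction_gives_pmax(self):
        # target exactly at the predicted position with identical velocity
        src, vel = np.array([0.2, 0.5]), np.array([0.5, 0.0])
        tgt = np.array([0.4, 0.5])   # ahead along motion: miss = 0
        p = motion_based_probability(src, vel, tgt, vel, 0.1, 0.1, p_max=0.7)
        assert p == pytest.approx(0.7)

    def test_one_sigma_spatial_offset(self):
        src, vel = np.array([0.2, 0.5]), np.array([0.5, 0.0])
        tgt = np.array([0.4, 0.5 + 0.1])   # sideways miss of one sigma_x
        p = motion_based_probability(src, vel, tgt, vel, 0.1, 0.1)
        # the sideways offset also changes the latency slightly; generous tol
        assert p == pytest.approx(np.exp(-0.5), rel=0.1)

    def test_anisotropy_on_three_neuron_toy(self, toy_tuning):
        pos, vel = toy_tuning.positions, toy_tuning.velocities
        ahead = motion_based_probability(pos[0], vel[0], pos[1], vel[1],
                                         0.3, 0.3)
        behind = motion_based_probability(pos[0], vel[0], pos[2], vel[2],
                                          0.3, 0.3)
        assert ahead > behind

    def test_sigma_v_infinity_matches_isotropic_on_predicted_positions(
            self, small_tuning, rng):
        idx = rng.integers(0, small_tuning.n, size=(200, 2))
        src, tgt = idx[:, 0], idx[:, 1]
        pos, vel = small_tuning.positions, small_tuning.velocities
        p = motion_based_probability(pos[src], vel[src], pos[tgt], vel[tgt],
                                     0.2, 1e12)
        d = torus_distance(pos[src], pos[tgt])
        tau = latency(d, small_tuning.speeds[src])
        miss = torus_distance(predicted_position(pos[src], vel[src], tau),
                              pos[tgt])
        np.testing.assert_allclose(p, isotropic_probability(miss, 0.2, 1.0),
                                   rtol=1e-9)


class TestDirectionBasedProbability:
    def test_aligned_pair_is_global_maximum(self):
        src, vel = np.array([0.5, 0.5]), np.array([1.0, 0.0])
        tgt = np.array([0.55, 0.5])
        p = direction_based_probability(src, vel, tgt, vel, 0.5, 0.5)
        assert p == pytest.approx(np.exp(1 / 0.25) * np.exp(1 / 0.25))

    def test_target_behind_is_spatial_minimum(self):
        src, vel = np.array([0.5, 0.5]), np.array([1.0, 0.0])
        tgt = np.array([0.45, 0.5])
        p = direction_based_probability(src, vel, tgt, vel, 0.5, 0.5)
        assert p == pytest.approx(np.exp(-1 / 0.25) * np.exp(1 / 0.25))

    def test_independent_of_speed(self):
        # the von Mises kernel ignores speed; invariance holds for pairs
        # that stay inside the radius/latency eligibility gate
        src = np.array([0.5, 0.5])
        tgt = np.array([0.55, 0.55])
        v1, v2 = np.array([0.8, 0.4]), np.array([0.2, 0.6])
        a = direction_based_probability(src, v1, tgt, v2, 0.5, 0.5)
        b = direction_based_probability(src, 2 * v1, tgt, 2 * v2, 0.5, 0.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_gate_excludes_remote_and_slow_pairs(self):
        src, vel = np.array([0.5, 0.5]), np.array([0.1, 0.0])
        far = np.array([0.9, 0.5])       # d = 0.4 > r_conn, lat = 4 s
        assert direction_based_probability(src, vel, far, vel, 0.5, 0.5) == 0.0
        near_slow = np.array([0.55, 0.5])  # d = 0.05 <= r_conn, lat = 500 ms
        assert direction_based_probability(src, vel, near_slow, vel,
                                           0.5, 0.5) == 0.0

    def test_coincident_positions_excluded(self):
        src = np.array([0.5, 0.5])
        vel = np.array([1.0, 0.0])
        assert direction_based_probability(src, vel, src, vel, 0.5, 0.5) == 0.0


class TestSelectionAndWeights:
    def test_half_percent_of_13000_is_65(self, rng):
        p = rng.random(13000)
        sel = select_incoming(p, 0.005)
        assert len(sel) == 65
        # brute-force oracle: full stable sort on (-p, index)
        oracle = np.lexsort((np.arange(13000), -p))[:65]
        np.testing.assert_array_equal(np.sort(sel), np.sort(oracle))

    def test_tie_break_by_ascending_index(self):
        sel = select_incoming(np.ones(1000), 0.065)
        np.testing.assert_array_equal(sel, np.arange(65))

    def test_short_supply_warns_and_takes_all_nonzero(self):
        p = np.zeros(100)
        p[[3, 7]] = 0.5
        with pytest.warns(UserWarning, match="positive probability"):
            sel = select_incoming(p, 0.1)
        np.testing.assert_array_equal(np.sort(sel), [3, 7])

    def test_normalize_examples(self):
        np.testing.assert_allclose(normalize_weights([0.2, 0.2], 0.2),
                                   [0.1, 0.1])
        np.testing.assert_allclose(normalize_weights([0.3, 0.1], 0.2),
                                   [0.15, 0.05])

    def test_normalized_sum_exact(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            w = normalize_weights(p, 0.3)
            assert abs(w.sum() - 0.3) < 1e-12

    def test_all_zero_probabilities_error(self):
        with pytest.raises(ValueError):
            normalize_weights(np.zeros(5), 0.2)

    def test_isotropic_weight_moments(self, rng):
        w = draw_isotropic_weights(100_000, w_sum=0.3, n_expected=65, rng=rng)
        mu = 0.3 / 65
        assert np.all(w >= 0)
        assert abs(w.mean() - mu) < 3 * 0.2 * mu / np.sqrt(len(w))
        assert w.std() / w.mean() == pytest.approx(0.2, rel=0.05)


class TestDelays:
    def test_motion_based_latency_in_ms(self):
        params = ConnectivityParams(scheme="motion_based", tau_max_mb=500.0)
        d = assign_delays(np.array([0.2]), np.array([0.5]), "motion_based",
                          params)
        assert d[0] == pytest.approx(400.0)

    def test_isotropic_moments(self, rng):
        params = ConnectivityParams(scheme="isotropic")
        d = assign_delays(np.zeros(100_000), np.ones(100_000), "isotropic",
                          params, rng)
        assert abs(d.mean() - 3.0) < 3 * 1.0 / np.sqrt(len(d))
        assert d.std() == pytest.approx(1.0, rel=0.03)

    def test_clip_floor_at_dt(self, rng):
        params = ConnectivityParams(scheme="motion_based")
        d = assign_delays(np.array([1e-6]), np.array([4.0]), "motion_based",
                          params)
        assert np.all(d >= params.dt)
        d = assign_delays(np.zeros(10_000), np.ones(10_000), "random",
                          params, rng)
        assert np.all(d >= params.dt)


@pytest.fixture(scope="module")
def fixture_populations():
    rng = np.random.default_rng(42)
    te = assemble_population(GridSpec(n_cells=25, n_speeds=8, n_angles=10),
                             2000, rng)
    ti = assemble_population(GridSpec(n_cells=9, n_speeds=5, n_angles=5),
                             400, rng)
    return te, ti


@pytest.fixture(scope="module")
def built_networks(fixture_populations):
    te, ti = fixture_populations
    out = {}
    for scheme in ("isotropic", "motion_based", "direction_based"):
        # r_conn matched to the 5x5 fixture grid spacing (0.2), mirroring
        # the full-scale ratio of eligibility radius to cell spacing
        params = default_connectivity(scheme, r_conn=0.2)
        out[scheme] = (build_network(te, ti, params,
                                     np.random.default_rng(7)), params)
    return out


class TestBuildNetwork:
    def test_anisotropic_in_degree_exact(self, built_networks,
                                         fixture_populations):
        te, _ = fixture_populations
        k = round(0.005 * te.n)
        for scheme in ("motion_based", "direction_based"):
            ee = built_networks[scheme][0]["EE"]
            np.testing.assert_array_equal(ee.in_degrees(te.n),
                                          np.full(te.n, k))

    def test_anisotropic_weight_sums_exact(self, built_networks,
                                           fixture_populations):
        te, _ = fixture_populations
        for scheme in ("motion_based", "direction_based"):
            tables, params = built_networks[scheme]
            sums = tables["EE"].incoming_weight_sums(te.n)
            np.testing.assert_allclose(sums, params.w_ee, atol=1e-9)

    def test_no_self_connections_and_delay_floor(self, built_networks):
        for scheme, (tables, params) in built_networks.items():
            for name, tab in tables.items():
                if name in ("EE", "II"):
                    assert not np.any(tab.source == tab.target)
                assert np.all(tab.delay >= params.dt - 1e-12)
                assert np.all(tab.weight >= 0)

    def test_isotropic_overall_density(self, built_networks,
                                       fixture_populations):
        te, _ = fixture_populations
        ee = built_networks["isotropic"][0]["EE"]
        n_pairs = te.n * (te.n - 1)
        phat = len(ee) / n_pairs
        se = np.sqrt(0.005 * 0.995 / n_pairs)
        assert abs(phat - 0.005) < 4 * se

    def test_direction_based_delays_capped(self, built_networks):
        ee = built_networks["direction_based"][0]["EE"]
        assert ee.delay.max() <= 100.0 + 1e-9

    def test_direction_based_reaches_beyond_own_cell(self, built_networks,
                                                     fixture_populations):
        te, _ = fixture_populations
        ee = built_networks["direction_based"][0]["EE"]
        d = torus_distance(te.positions[ee.source], te.positions[ee.target])
        assert d.max() <= 0.2 + 1e-9
        assert np.percentile(d, 90) > 0.05   # beyond jitter-scale clumps

    def test_anisotropy_statistic_separates_schemes(self, built_networks,
                                                    fixture_populations):
        te, _ = fixture_populations
        iso = anisotropy_statistic(built_networks["isotropic"][0]["EE"], te)
        mb = anisotropy_statistic(built_networks["motion_based"][0]["EE"], te)
        db = anisotropy_statistic(built_networks["direction_based"][0]["EE"],
                                  te)
        # isotropic wiring has no net forward displacement; both anisotropic
        # rules displace activity ahead of the preferred direction by at
        # least an order of magnitude more (the direction-based statistic
        # is bounded by its eligibility radius, hence the smaller scale)
        assert abs(iso) <= 0.005
        for stat in (mb, db):
            assert stat >= max(10 * abs(iso), 0.01)
        assert mb >= 0.05

    def test_anisotropic_build_deterministic(self, fixture_populations):
        te, ti = fixture_populations
        params = default_connectivity("motion_based")
        a = build_network(te, ti, params, np.random.default_rng(1))["EE"]
        b = build_network(te, ti, params, np.random.default_rng(2))["EE"]
        np.testing.assert_array_equal(a.source, b.source)
        np.testing.assert_array_equal(a.target, b.target)
        np.testing.assert_array_equal(a.weight, b.weight)
        np.testing.assert_array_equal(a.delay, b.delay)

    def test_isotropic_build_reproducible_under_seed(self, fixture_populations):
        te, ti = fixture_populations
        params = default_connectivity("isotropic")
        a = build_network(te, ti, params, np.random.default_rng(5))
        b = build_network(te, ti, params, np.random.default_rng(5))
        for name in a:
            np.testing.assert_array_equal(a[name].source, b[name].source)
            np.testing.assert_array_equal(a[name].weight, b[name].weight)


class TestSynapseTableIO:
    def test_csv_roundtrip_validates(self, tmp_path, built_networks,
                                     fixture_populations):
        te, ti = fixture_populations
        tab = built_networks["motion_based"][0]["EI"]
        path = tmp_path / "ei.csv"
        tab.to_csv(path)
        back = SynapseTable.from_csv(path, n_source=te.n, n_target=ti.n)
        np.testing.assert_array_equal(back.source, tab.source)
        np.testing.assert_allclose(back.weight, tab.weight)

    def test_loader_rejects_self_connection(self, tmp_path):
        bad = SynapseTable(np.array([3]), np.array([3]), np.array([0.1]),
                           np.array([1.0]), pathway="EE")
        path = tmp_path / "bad.csv"
        bad.to_frame().to_csv(path, index=False)
        with pytest.raises(ValueError, match="[Ss]elf"):
            SynapseTable.from_csv(path, n_source=10, n_target=10)
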