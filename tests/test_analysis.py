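"""Structure-function analyses and the two-oscillator analytic oracle."""

import numpy as np
import pytest

from phasefc import (
    Connectome,
    FCMatrix,
    SimConfig,
    bin_mean_correlation,
    ensemble_fc,
    frequency_sweep,
    generate_synthetic_connectome,
    graph_density,
    matrix_similarity_distance,
    run_ensemble,
    two_node_locked_state,
    uniform_delays,
)
from phasefc.connectome import compute_delays


class TestGraphDensity:
    def test_macaque_printed_values(self):
        assert 29 * 28 == 812
        assert round(graph_density(29, 536, directed=True)) == 66

    def test_empty_and_complete(self):
        assert graph_density(29, 0, directed=True) == 0.0
        assert graph_density(29, 812, directed=True) == 100.0

    def test_undirected_denominator(self):
        assert graph_density(4, 6, directed=False) == 100.0

    def test_overfull_raises(self):
        with pytest.raises(ValueError):
            graph_density(29, 813, directed=True)


def _connectome_with_weights(wvals: np.ndarray, mask_pairs) -> Connectome:
    n = int(max(max(i, j) for i, j in mask_pairs)) + 1
    w = np.zeros((n, n))
    for (i, j), v in zip(mask_pairs, wvals):
        w[i, j] = w[j, i] = v
    d = np.where(np.eye(n) == 0, 10.0, 0.0)
    return Connectome(weights=w, distances=d)


class TestSimilarityDistance:
    def test_zero_iff_equal_on_mask(self):
        pairs = [(0, 1), (1, 2)]
        c = _connectome_with_weights(np.array([0.4, 0.9]), pairs)
        s = np.eye(3)
        s[0, 1] = s[1, 0] = 0.4
        s[1, 2] = s[2, 1] = 0.9
        assert matrix_similarity_distance(FCMatrix(sigma=s), c) == 0.0

    def test_hand_computed_example(self):
        # sigma = {1, 0}, W = {0.., 1} over two pairs -> sqrt(2)/2
        pairs = [(0, 1), (1, 2)]
        c = _connectome_with_weights(np.array([1e-4, 1.0]), pairs)
        c.weights[0, 1] = c.weights[1, 0] = 0.0
        c.weights[0, 2] = c.weights[2, 0] = 1e-9  # keep pair masked out
        s = np.eye(3)
        s[0, 1] = s[1, 0] = 1.0
        s[1, 2] = s[2, 1] = 0.0
        fc = FCMatrix(sigma=s)
        got = matrix_similarity_distance(fc, c, mask="all")
        # over all three pairs: diff = (1, -1, ~0) -> norm sqrt(2) / 3
        assert got == pytest.approx(np.sqrt(2.0) / 3.0, rel=1e-6)
        c2 = _connectome_with_weights(np.array([1.0, 1.0]), pairs)
        s2 = np.eye(3)
        s2[0, 1] = s2[1, 0] = 1.0
        s2[1, 2] = s2[2, 1] = 0.0
        # connected pairs only: diffs (0, -1) over 2 pairs -> 1/2
        assert matrix_similarity_distance(FCMatrix(sigma=s2), c2) == pytest.approx(0.5)

    def test_two_pair_example_sqrt2_over_2(self):
        pairs = [(0, 1), (2, 3)]
        c = _connectome_with_weights(np.array([1e-9, 1.0]), pairs)
        c.weights[c.weights < 1e-5] = 0.0
        s = np.eye(4)
        s[0, 1] = s[1, 0] = 1.0
        fc = FCMatrix(sigma=s)
        # masked pairs (0,1) and (2,3): sigma = {1, 0}, W = {0, 1}
        i, j = [0, 2], [1, 3]
        diff = fc.sigma[i, j] - c.symmetric_weights()[i, j]
        assert np.linalg.norm(diff) / 2 == pytest.approx(np.sqrt(2) / 2)

    def test_metric_properties_on_mask(self):
        rng = np.random.default_rng(8)
        n_pairs = 15
        for _ in range(20):
            a, b, c3 = rng.uniform(-1, 1, (3, n_pairs))

            def d(x, y):
                return np.linalg.norm(x - y) / n_pairs

            assert d(a, a) == 0.0
            assert d(a, b) == pytest.approx(d(b, a))
            assert d(a, c3) <= d(a, b) + d(b, c3) + 1e-12

    def test_empty_mask_raises(self):
        c = Connectome(weights=np.zeros((3, 3)), distances=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="empty"):
            matrix_similarity_distance(FCMatrix(sigma=np.eye(3)), c)


class TestBinning:
    def test_single_bin_equals_global_mean(self):
        pairs = [(0, 1), (1, 2), (0, 2)]
        c = _connectome_with_weights(np.array([0.5, 0.5, 0.5]), pairs)
        s = np.eye(3)
        s[0, 1] = s[1, 0] = 0.2
        s[1, 2] = s[2, 1] = 0.6
        s[0, 2] = s[2, 0] = 0.7
        df = bin_mean_correlation(FCMatrix(sigma=s), c, by="weight", width=0.05)
        assert len(df) == 1
        assert df.iloc[0].mean_sigma == pytest.approx(0.5)
        assert df.iloc[0].n_pairs == 3

    def test_piecewise_distance_pattern(self):
        n = 6
        w = np.zeros((n, n))
        d = np.zeros((n, n))
        rng = np.random.default_rng(0)
        # edges at short (<30 mm) and long (>40 mm) distances, avoiding bin straddle
        dist_vals = [5.0, 12.0, 25.0, 44.0, 60.0, 75.0]
        pairs = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        s = np.eye(n)
        for (i, j), dv in zip(pairs, dist_vals):
            w[i, j] = w[j, i] = 0.5
            d[i, j] = d[j, i] = dv
            sv = 1.0 if dv < 30 else -1.0
            s[i, j] = s[j, i] = sv
        d[d == 0] = 100.0
        np.fill_diagonal(d, 0.0)
        c = Connectome(weights=w, distances=d)
        df = bin_mean_correlation(FCMatrix(sigma=s), c, by="distance", width=16.0)
        near = df[df.bin_center < 30.0]
        far = df[df.bin_center > 30.0]
        assert np.all(near.mean_sigma == 1.0)
        assert np.all(far.mean_sigma == -1.0)

    def test_confidence_interval_brackets_mean(self):
        rng = np.random.default_rng(2)
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        c = _connectome_with_weights(rng.uniform(0.4, 0.45, len(pairs)), pairs)
        s = np.eye(5)
        iu, ju = np.triu_indices(5, 1)
        vals = rng.uniform(-0.5, 0.5, iu.size)
        s[iu, ju] = vals
        s[ju, iu] = vals
        df = bin_mean_correlation(FCMatrix(sigma=s), c, by="weight")
        assert np.all(df.ci_low <= df.mean_sigma + 1e-12)
        assert np.all(df.mean_sigma <= df.ci_high + 1e-12)
        assert np.all(df.n_pairs >= 1)

    def test_default_widths(self):
        from phasefc.analysis import DISTANCE_BIN_WIDTH_MM, WEIGHT_BIN_WIDTH

        assert WEIGHT_BIN_WIDTH == 0.05
        assert DISTANCE_BIN_WIDTH_MM == 16.0

    def test_no_connected_pairs_raises(self):
        c = Connectome(weights=np.zeros((3, 3)), distances=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            bin_mean_correlation(FCMatrix(sigma=np.eye(3)), c)


class TestTwoNodeOracle:
    def test_zero_delay_always_in_phase(self):
        for nu in (3.0, 23.0, 51.0):
            st = two_node_locked_state(0.25, 0.0, nu)
            assert st.classification == "in_phase"

    def test_weak_coupling_low_frequency_in_phase(self):
        # Omega*tau ~ 2*pi*0.01*5 = 0.314 rad < pi/2
        st = two_node_locked_state(1e-6, 5.0, 10.0)
        assert st.classification == "in_phase"
        om = st.stable_frequencies("in_phase")[0]
        assert om * 5.0 == pytest.approx(0.314159, rel=1e-3)

    def test_weak_coupling_high_frequency_anti_phase(self):
        # Omega*tau ~ 2.20 rad, inside (pi/2, 3*pi/2)
        st = two_node_locked_state(1e-6, 5.0, 70.0)
        assert st.classification == "anti_phase"
        om = st.stable_frequencies("anti_phase")[0]
        assert om * 5.0 == pytest.approx(2.199, rel=1e-3)

    def test_strong_coupling_admits_bistability(self):
        st = two_node_locked_state(0.25, 5.0, 30.0)
        assert st.classification == "bistable"

    def test_roots_satisfy_fixed_point_equation(self):
        K, tau, nu = 0.1, 8.0, 20.0
        omega = 2 * np.pi * nu / 1000.0
        st = two_node_locked_state(K, tau, nu)
        assert st.roots
        for branch, om, _ in st.roots:
            sign = -1.0 if branch == "in_phase" else 1.0
            assert om == pytest.approx(omega + sign * K * np.sin(om * tau), abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            two_node_locked_state(-0.1, 5.0, 10.0)
        with pytest.raises(ValueError):
            two_node_locked_state(0.1, 5.0, 0.0)


class TestFrequencySweep:
    def test_single_frequency_matches_direct_ensemble(self):
        c = generate_synthetic_connectome(n=8, n_modules=2, weight_decades=2, seed=4)
        delays = compute_delays(c, 5.0)
        cfg = SimConfig(mean_freq=10.0, t_transient=0.1, t_record=0.2,
                        n_realizations=2, seed=5)
        fcs, curve = frequency_sweep(c, delays, cfg, [10.0])
        direct = ensemble_fc(run_ensemble(c, delays, cfg), mean_freq=10.0)
        np.testing.assert_allclose(fcs[10.0].sigma, direct.sigma)
        assert curve.distance_value.iloc[0] == pytest.approx(
            matrix_similarity_distance(direct, c)
        )

    def test_rejects_bad_frequency_lists(self):
        c = generate_synthetic_connectome(n=6, n_modules=2, weight_decades=2, seed=4)
        delays = compute_delays(c, 5.0)
        cfg = SimConfig(t_transient=0.1, t_record=0.1, n_realizations=1)
        with pytest.raises(ValueError):
            frequency_sweep(c, delays, cfg, [])
        with pytest.raises(ValueError):
            frequency_sweep(c, delays, cfg, [-3.0])
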