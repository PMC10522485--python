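import numpy as np
import pytest

from mhc2x.errors import (DecompositionError, DisconnectedDataError,
                          InsufficientDataError, InvalidParameterError)
from mhc2x.msm import (bootstrap_msm, cluster_microstates, estimate_msm,
                       extract_pair_distances, metastable_rates, metastable_thermo,
                       mfpt, pcca, tica)
from mhc2x.msm.estimation import MSMResult
from mhc2x.msm.pcca import UNASSIGNED
from mhc2x.synthetic import (DiscreteTrajectorySet, gen_feature_trajectory,
                             gen_markov_trajectories, stationary_distribution)

RT_300 = 8.314 * 300.0 / 1000.0


def _msm_from_matrix(T, lag=1):
    """Wrap an exact reversible matrix as an MSMResult for decomposition tests."""
    T = np.asarray(T, dtype=float)
    pi = stationary_distribution(T)
    return MSMResult(lag=lag, transition_matrix=T, stationary_distribution=pi,
                     count_matrix=T * 1000, active_set=np.arange(T.shape[0]),
                     n_states_full=T.shape[0])


class TestExtractPairDistances:
    def test_static_pair_distance(self):
        coords = np.tile(np.array([[0.0, 0, 0], [5.0, 0, 0]]), (10, 1, 1))
        ft = extract_pair_distances(coords, ["r1", "r2"], coords[0], ["r1", "r2"],
                                    "r1", radius=15.0)
        assert np.allclose(ft.data, 5.0)

    def test_feature_count_combinatorics(self):
        m = 6
        ref = np.random.default_rng(0).normal(size=(m, 3))
        coords = np.tile(ref, (4, 1, 1))
        ids = [f"r{i}" for i in range(m)]
        ft = extract_pair_distances(coords, ids, ref, ids, "r0", radius=1e6)
        assert ft.data.shape == (4, m * (m - 1) // 2)

    def test_radius_limits_selection(self):
        ref = np.array([[0.0, 0, 0], [5.0, 0, 0], [100.0, 0, 0]])
        coords = np.tile(ref, (3, 1, 1))
        ids = ["a", "b", "far"]
        ft = extract_pair_distances(coords, ids, ref, ids, "a", radius=15.0)
        assert ft.data.shape[1] == 1  # only (a, b)

    def test_sinusoidal_breathing_reproduced(self):
        t = np.linspace(0, 4 * np.pi, 200)
        d = 5.0 + np.sin(t)
        coords = np.zeros((200, 2, 3))
        coords[:, 1, 0] = d
        ft = extract_pair_distances(coords, ["a", "b"], coords[0], ["a", "b"], "a")
        assert np.allclose(ft.data[:, 0], d)

    def test_missing_anchor_rejected(self):
        coords = np.zeros((2, 2, 3))
        with pytest.raises(InvalidParameterError):
            extract_pair_distances(coords, ["a", "b"], coords[0], ["a", "b"], "zz")


class TestTica:
    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50000, 2))
        model = tica([x], lag=5)
        assert np.all(np.abs(model.eigenvalues) < 3.0 / np.sqrt(50000))

    def test_hidden_two_state_slow_axis(self):
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        ft = gen_feature_trajectory(T, [[0.0], [4.0]], 0.05, 3, 50000, 0,
                                    fast_noise_sd=1.0)
        lag = 3
        model = tica([ft.data], lag=lag, n_components=2)
        # leading eigenvalue ≈ second chain eigenvalue^lag (λ2 = 0.85)
        assert model.eigenvalues[0] == pytest.approx(0.85 ** lag, abs=0.05)
        # leading component concentrated on the slow (first) axis
        comp = model.components[:, 0]
        cosine = abs(comp[0]) / np.linalg.norm(comp)
        assert cosine > 0.99

    def test_duplicated_columns_leave_projection_unchanged(self):
        rng = np.random.default_rng(1)
        base = np.cumsum(rng.normal(size=(5000, 2)), axis=0) * 0.01 \
            + rng.normal(size=(5000, 2))
        dup = np.hstack([base, base[:, :1]])
        p1 = tica([base], lag=4, n_components=1).projections[0]
        p2 = tica([dup], lag=4, n_components=1).projections[0]
        # projections agree up to sign
        corr = np.corrcoef(p1[:, 0], p2[:, 0])[0, 1]
        assert abs(corr) > 1 - 1e-6

    def test_lag_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            tica([np.zeros((100, 2))], lag=0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidParameterError):
            tica([np.zeros((3, 10))], lag=1)


class TestClusterMicrostates:
    def test_k1_grand_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 2))
        dtrajs, centers = cluster_microstates([x], 1, seed=0)
        assert np.all(dtrajs.trajectories[0] == 0)
        assert np.allclose(centers[0], x.mean(axis=0))

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 0.3, size=(500, 2))
        b = rng.normal([8, 8], 0.3, size=(500, 2))
        x = np.vstack([a, b])
        dtrajs, _ = cluster_microstates([x], 2, seed=0)
        labels = dtrajs.trajectories[0]
        same_a = (labels[:500] == labels[0]).mean()
        same_b = (labels[500:] == labels[500]).mean()
        assert same_a > 0.99 and same_b > 0.99
        assert labels[0] != labels[500]

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(300, 3))
        d1, c1 = cluster_microstates([x], 10, seed=7)
        d2, c2 = cluster_microstates([x], 10, seed=7)
        assert np.array_equal(d1.trajectories[0], d2.trajectories[0])
        assert np.allclose(c1, c2)

    def test_k_exceeding_frames_rejected(self):
        with pytest.raises(InvalidParameterError):
            cluster_microstates([np.zeros((5, 2))], 10, seed=0)


class TestEstimateMsm:
    def test_alternating_trajectory(self):
        traj = np.tile([0, 1], 500)
        dtrajs = DiscreteTrajectorySet(trajectories=[traj], n_states=2)
        res = estimate_msm(dtrajs, lag=1)
        assert np.allclose(res.transition_matrix, [[0, 1], [1, 0]], atol=1e-10)
        assert np.allclose(res.stationary_distribution, [0.5, 0.5], atol=1e-10)

    def test_round_trip_two_state_chain(self):
        T_true = np.array([[0.9, 0.1], [0.05, 0.95]])
        dtrajs = gen_markov_trajectories(T_true, 400_000, 1, 13)
        res = estimate_msm(dtrajs, lag=1)
        assert np.max(np.abs(res.transition_matrix - T_true)) < 0.005
        assert np.max(np.abs(res.stationary_distribution
                             - np.array([1 / 3, 2 / 3]))) < 0.01

    def test_unvisited_state_dropped_with_warning(self):
        traj = np.zeros(100, dtype=int)
        dtrajs = DiscreteTrajectorySet(trajectories=[traj], n_states=2)
        with pytest.warns(UserWarning):
            res = estimate_msm(dtrajs, lag=1)
        assert np.array_equal(res.active_set, [0])

    def test_row_stochastic_and_detailed_balance(self, three_state_chain):
        dtrajs = gen_markov_trajectories(three_state_chain, 50_000, 2, 3)
        res = estimate_msm(dtrajs, lag=1)
        T, pi = res.transition_matrix, res.stationary_distribution
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(T >= 0)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-8
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_implied_timescales_lag_independent(self):
        # Markovian data: timescales stable across lags past the mixing scale
        T = np.array([[0.97, 0.03], [0.06, 0.94]])
        t_mix = -1.0 / np.log(0.91)  # ≈ 10.6 frames
        dtrajs = gen_markov_trajectories(T, 300_000, 2, 5)
        its = []
        for lag in (1, 2, 4, 8):
            res = estimate_msm(dtrajs, lag=lag)
            its.append(res.implied_timescales[0])
        assert np.all(np.abs(np.array(its) - t_mix) / t_mix < 0.10)

    def test_no_transitions_rejected(self):
        dtrajs = DiscreteTrajectorySet(trajectories=[np.array([0])], n_states=1)
        with pytest.raises(DisconnectedDataError):
            estimate_msm(dtrajs, lag=1)


class TestPcca:
    def test_two_block_memberships(self):
        eps = 1e-4
        T = np.array([
            [0.98 - eps, 0.02, eps, 0.0],
            [0.02, 0.98 - eps, 0.0, eps],
            [eps, 0.0, 0.98 - eps, 0.02],
            [0.0, eps, 0.02, 0.98 - eps],
        ])
        model = pcca(_msm_from_matrix(T), 2)
        chi = model.memberships
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-8)
        for block in ([0, 1], [2, 3]):
            cols = np.argmax(chi[block], axis=1)
            assert cols[0] == cols[1]
            assert np.all(chi[block, cols[0]] > 0.99)

    def test_identity_when_m_equals_n(self):
        T = np.array([[0.90, 0.06, 0.04],
                      [0.03, 0.95, 0.02],
                      [0.04, 0.04, 0.92]])
        # make it reversible: symmetric chain
        T = (T + T.T) / 2
        np.fill_diagonal(T, 0)
        T = T / T.sum(axis=1, keepdims=True) * 0.1
        np.fill_diagonal(T, 1 - T.sum(axis=1))
        model = pcca(_msm_from_matrix(T), 3)
        order = np.argmax(model.memberships, axis=1)
        assert sorted(order) == [0, 1, 2]
        assert np.all(model.memberships[np.arange(3), order] > 0.9)

    def test_symmetric_bridge_state_unassigned(self):
        # state 2 bridges the two blocks symmetrically → 50/50 membership
        T = np.array([
            [0.90, 0.00, 0.10],
            [0.00, 0.90, 0.10],
            [0.25, 0.25, 0.50],
        ])
        model = pcca(_msm_from_matrix(T), 2)
        assert model.memberships[2] == pytest.approx([0.5, 0.5], abs=1e-6)
        assert model.assignments[2] == UNASSIGNED

    def test_membership_rows_sum_to_one(self, three_state_chain):
        dtrajs = gen_markov_trajectories(three_state_chain, 50_000, 2, 5)
        res = estimate_msm(dtrajs, lag=1)
        model = pcca(res, 2)
        assert np.allclose(model.memberships.sum(axis=1), 1.0, atol=1e-8)

    def test_bad_n_metastable_rejected(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(InvalidParameterError):
            pcca(_msm_from_matrix(T), 5)

    def test_nonreversible_rejected(self):
        # cyclic flow violates detailed balance
        T = np.array([[0.1, 0.9, 0.0], [0.0, 0.1, 0.9], [0.9, 0.0, 0.1]])
        with pytest.raises(DecompositionError):
            pcca(_msm_from_matrix(T), 2)


class TestMetastableThermo:
    def _model(self, pops):
        """Perfectly metastable block-diagonal-ish system with given pops."""
        pops = np.asarray(pops, dtype=float)
        n = pops.size
        # Metropolis chain has stationary distribution pops
        T = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    T[i, j] = 0.1 * min(1.0, pops[j] / pops[i]) / (n - 1)
            T[i, i] = 1 - T[i].sum()
        msm = _msm_from_matrix(T)
        from mhc2x.msm.pcca import MetastableModel
        meta = MetastableModel(memberships=np.eye(n), assignments=np.arange(n),
                               n_metastable=n, crisp_cutoff=0.5)
        return msm, meta

    def test_equal_populations_zero_g(self):
        msm, meta = self._model([0.25, 0.25, 0.25, 0.25])
        th = metastable_thermo(msm, meta, 300.0)
        assert np.allclose(th["free_energies"], 0.0, atol=1e-9)

    def test_hand_computed_free_energies(self):
        msm, meta = self._model([0.90, 0.08, 0.02])
        th = metastable_thermo(msm, meta, 300.0)
        assert th["reference"] == 0
        assert th["free_energies"][1] == pytest.approx(6.04, abs=0.01)
        assert th["free_energies"][2] == pytest.approx(9.49, abs=0.01)

    def test_ordering_inverse_to_population(self):
        msm, meta = self._model([0.6, 0.3, 0.1])
        th = metastable_thermo(msm, meta, 300.0)
        assert np.all(np.diff(th["populations"]) < 0)
        assert np.all(np.diff(th["free_energies"]) > 0)


class TestMetastableRates:
    def test_two_state_mfpt_and_rate(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert mfpt(T, [1])[0] == pytest.approx(10.0)
        from mhc2x.msm.pcca import MetastableModel
        msm = _msm_from_matrix(T)
        meta = MetastableModel(memberships=np.eye(2), assignments=np.arange(2),
                               n_metastable=2, crisp_cutoff=0.5)
        rates = metastable_rates(msm, meta)["rates"]
        assert rates[0, 1] == pytest.approx(0.1)
        assert rates[1, 0] == pytest.approx(0.2)

    def test_symmetric_chain_symmetric_rates(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        from mhc2x.msm.pcca import MetastableModel
        meta = MetastableModel(memberships=np.eye(2), assignments=np.arange(2),
                               n_metastable=2, crisp_cutoff=0.5)
        rates = metastable_rates(_msm_from_matrix(T), meta)["rates"]
        assert rates[0, 1] == pytest.approx(rates[1, 0])

    def test_coarse_detailed_balance(self):
        T = np.array([[0.95, 0.05], [0.02, 0.98]])
        from mhc2x.msm.pcca import MetastableModel
        meta = MetastableModel(memberships=np.eye(2), assignments=np.arange(2),
                               n_metastable=2, crisp_cutoff=0.5)
        msm = _msm_from_matrix(T)
        th = metastable_thermo(msm, meta)
        rates = metastable_rates(msm, meta)["rates"]
        lhs = th["populations"][0] * rates[0, 1]
        rhs = th["populations"][1] * rates[1, 0]
        assert lhs == pytest.approx(rhs, rel=0.05)


class TestBootstrap:
    def test_degenerate_resampling_zero_ci(self, three_state_chain):
        base = gen_markov_trajectories(three_state_chain, 20_000, 1, 0).trajectories[0]
        dtrajs = DiscreteTrajectorySet(trajectories=[base.copy() for _ in range(10)],
                                       n_states=3)
        boot = bootstrap_msm(dtrajs, lag=1, n_metastable=3, n_boot=10, seed=0)
        assert np.all(boot["populations_ci"] < 1e-12)
        assert np.all(boot["free_energies_ci"] < 1e-9)

    def test_seed_determinism(self, three_state_chain):
        dtrajs = gen_markov_trajectories(three_state_chain, 5_000, 5, 1)
        a = bootstrap_msm(dtrajs, lag=1, n_metastable=3, n_boot=10, seed=4)
        b = bootstrap_msm(dtrajs, lag=1, n_metastable=3, n_boot=10, seed=4)
        assert np.array_equal(a["populations_ci"], b["populations_ci"])

    def test_needs_multiple_trajectories(self, three_state_chain):
        dtrajs = gen_markov_trajectories(three_state_chain, 1_000, 1, 0)
        with pytest.raises(InsufficientDataError):
            bootstrap_msm(dtrajs, lag=1, n_metastable=2, n_boot=5, seed=0)


def test_end_to_end_population_recovery(three_state_chain, feature_trajs):
    """tica → cluster → msm → pcca → thermo recovers hidden populations."""
    pi_true = stationary_distribution(three_state_chain)
    model = tica([f.data for f in feature_trajs], lag=5, n_components=2)
    dtrajs, _ = cluster_microstates(model.projections, 30, seed=0)
    res = estimate_msm(dtrajs, lag=5)
    meta = pcca(res, 3)
    th = metastable_thermo(res, meta, 300.0)
    pops = np.sort(th["populations"])[::-1]
    truth = np.sort(pi_true)[::-1]
    assert np.max(np.abs(pops - truth)) < 0.02
    g_est = -RT_300 * np.log(pops / pops[0])
    g_true = -RT_300 * np.log(truth / truth[0])
    assert np.max(np.abs(g_est - g_true)) < 0.3
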