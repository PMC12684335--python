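"""MSM estimation, coarse-graining, generators and augmentation."""

import warnings

import numpy as np
import pytest
import scipy.linalg

from nmrkin import FieldContext, cpmg, msm, synth
from nmrkin.msm import (augment_with_experiment, coarse_grain, count_matrix,
                        estimate_msm, generator_from_tmatrix,
                        implied_timescales, largest_connected_set,
                        stationary_from_generator)


from _helpers import metastable_counts


class TestCounting:
    def test_alternating_trajectory(self):
        c = count_matrix([np.array([0, 1, 0, 1, 0])], lag=1)
        np.testing.assert_array_equal(c, [[0, 2], [2, 0]])

    def test_constant_trajectory_is_diagonal(self):
        c = count_matrix([np.full(10, 2)], lag=2)
        assert c[2, 2] == 8
        assert c.sum() == 8

    def test_lag_must_fit(self):
        with pytest.raises(ValueError):
            count_matrix([np.array([0, 1])], lag=2)

    def test_matches_brute_force_tally(self, planted_network):
        d = synth.simulate_ctmc(planted_network.K, 2e-5, 5000, seed=9)
        lag = 3
        tally: dict = {}
        for a, b in zip(d[:-lag], d[lag:]):  # independent per-pair tally
            tally[(a, b)] = tally.get((a, b), 0) + 1
        c = count_matrix([d], lag=lag)
        for (a, b), n in tally.items():
            assert c[a, b] == n
        assert c.sum() == len(d) - lag


class TestEstimation:
    def test_symmetric_counts_fixed_point(self):
        c = np.array([[8.0, 2.0], [2.0, 8.0]])
        m = estimate_msm(c)
        np.testing.assert_allclose(m.transition_matrix, c / c.sum(axis=1)[:, None],
                                   atol=1e-12)

    def test_symmetric_counts_give_uniform_stationary(self):
        m = estimate_msm(np.array([[9.0, 1.0], [1.0, 9.0]]))
        np.testing.assert_allclose(m.stationary, [0.5, 0.5], atol=1e-12)

    def test_detailed_balance_to_1e10(self, planted_network):
        d = synth.simulate_ctmc(planted_network.K, 2e-5, 100000, seed=3)
        m = estimate_msm([d], lag=5, dt=2e-5)
        pi_t = m.stationary[:, None] * m.transition_matrix
        assert np.abs(pi_t - pi_t.T).max() < 1e-10

    def test_planted_stationary_recovery(self, planted_network):
        d = synth.simulate_ctmc(planted_network.K, 2e-5, 200000, seed=12)
        m = estimate_msm([d], lag=5, dt=2e-5)
        truth = planted_network.populations
        # slow inter-basin flux (~90 transitions sampled) limits the rare
        # state's precision; the two major states are tightly determined
        assert np.abs(m.stationary - truth).max() / truth.min() < 1.0
        np.testing.assert_allclose(m.stationary[1:], truth[1:], rtol=0.1)

    def test_disconnected_counts_drop_states(self):
        c = np.array([[5.0, 5.0, 0.0], [5.0, 5.0, 0.0], [0.0, 0.0, 7.0]])
        with pytest.warns(UserWarning, match="dropping states"):
            m = estimate_msm(c)
        assert m.n_states == 2
        np.testing.assert_array_equal(m.active_set, [0, 1])

    def test_largest_connected_set(self):
        c = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 9.0]])
        np.testing.assert_array_equal(largest_connected_set(c), [2])


class TestImpliedTimescales:
    def test_two_state_arithmetic(self):
        m = estimate_msm(np.array([[90.0, 10.0], [10.0, 90.0]]), lag=1, dt=1.0)
        ts = implied_timescales(m)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.8), rel=1e-10)

    def test_identity_flags_infinite(self):
        m = msm.MSM(np.eye(3), np.full(3, 1 / 3), 1, 1.0, np.arange(3))
        assert np.isinf(implied_timescales(m)).all()

    def test_invariant_under_state_relabeling(self):
        c = metastable_counts(3, seed=2)
        m1 = estimate_msm(c)
        perm = np.array([4, 7, 0, 2, 8, 1, 5, 3, 6])
        m2 = estimate_msm(c[np.ix_(perm, perm)])
        np.testing.assert_allclose(implied_timescales(m1),
                                   implied_timescales(m2), rtol=1e-8)


class TestCoarseGraining:
    @pytest.mark.parametrize("n_blocks", [2, 3, 4])
    def test_recovers_planted_blocks(self, n_blocks):
        m = estimate_msm(metastable_counts(n_blocks, seed=n_blocks))
        cm = coarse_grain(m, n_blocks)
        truth = np.repeat(np.arange(n_blocks), 3)
        # assignments must match the planted partition up to relabeling
        mapping = {}
        for micro, macro in enumerate(cm.assignments):
            key = truth[micro]
            assert mapping.setdefault(key, macro) == macro
        assert len(set(mapping.values())) == n_blocks

    def test_single_macrostate(self):
        m = estimate_msm(metastable_counts(2, seed=1))
        cm = coarse_grain(m, 1)
        assert cm.populations[0] == pytest.approx(1.0)

    def test_population_conservation(self):
        m = estimate_msm(metastable_counts(3, seed=5))
        cm = coarse_grain(m, 3)
        assert cm.populations.sum() == pytest.approx(1.0, abs=1e-10)
        for a in range(3):
            assert cm.populations[a] == pytest.approx(
                m.stationary[cm.assignments == a].sum(), abs=1e-12)

    def test_weak_gap_warns(self):
        # exactly degenerate spectrum: splitting 4 identical metastable
        # blocks into 3 has no gap between the retained and dropped modes
        m = estimate_msm(metastable_counts(4, seed=3, jitter=0.0))
        with pytest.warns(UserWarning, match="spectral gap"):
            try:
                coarse_grain(m, 3)
            except ValueError:
                pass  # merging twin blocks may legitimately lose a macrostate


class TestGenerator:
    def test_round_trip(self, planted_network):
        k = planted_network.K
        t = scipy.linalg.expm(k * 1e-4)
        res = generator_from_tmatrix(t, 1e-4)
        assert res.ok
        np.testing.assert_allclose(res.K, k, rtol=1e-6, atol=1e-8)

    def test_identity_gives_zero(self):
        res = generator_from_tmatrix(np.eye(3), 0.5)
        np.testing.assert_allclose(res.K, 0.0, atol=1e-12)

    def test_row_sums_vanish(self):
        m = estimate_msm(metastable_counts(3, seed=7))
        res = generator_from_tmatrix(m.transition_matrix, 1.0)
        assert np.abs(res.K.sum(axis=1)).max() < 1e-10

    def test_nonpositive_eigenvalue_rejected(self):
        t = np.array([[0.0, 1.0], [1.0, 0.0]])  # eigenvalue -1
        with pytest.raises(ValueError, match="logarithm undefined"):
            generator_from_tmatrix(t, 1.0)


class TestAugmentation:
    def one_block_setup(self, sigma=0.0):
        """Single connected block {partial, closed} plus matching curves."""
        cfg = synth.GeneratorConfig(seed=42, n_frames_incompetent=150000)
        blocks, macros, _, _ = synth.simulation_blocks(cfg)
        block, macro = blocks[1], macros[1] - 1  # relabel macros to 0, 1
        k_b, pops_b, _ = msm._block_coarse(block, macro)
        net = cpmg.KineticNetwork(k_b, pops_b, np.array([0.4, 0.0]),
                                  {600.0: 14.0, 950.0: 18.0})
        curves = {96: synth.simulate_dispersion(net, (600.0, 950.0),
                                                synth.DEFAULT_GRID, 0.04,
                                                sigma, seed=5, residue=96)}
        offsets = {96: np.array([0.4, 0.0])}
        return block, macro, curves, offsets, k_b, pops_b

    def test_self_consistent_block_is_a_no_op(self):
        # curves generated exactly from the simulation-derived network:
        # augmentation should not perturb the kinetics
        block, macro, curves, offsets, k_b, pops_b = self.one_block_setup()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aug = augment_with_experiment([block], [macro], curves, offsets,
                                          n_starts=3, seed=2)
        assert aug.perturbation < 1e-4
        assert aug.chi2 < 1e-3
        np.testing.assert_allclose(aug.network.populations, pops_b, rtol=0.01)
        np.testing.assert_allclose(aug.network.K, k_b, rtol=0.02, atol=1e-6)

    def test_never_worsens_experimental_chi2(self):
        block, macro, curves, offsets, *_ = self.one_block_setup(sigma=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aug = augment_with_experiment([block], [macro], curves, offsets,
                                          n_starts=3, seed=2)
        assert aug.chi2 <= aug.diagnostics["chi2_unaugmented"] + 1e-9

    def test_disconnected_blocks_without_data_fail(self):
        cfg = synth.GeneratorConfig(seed=42, n_frames_incompetent=50000,
                                    n_frames_competent=20000)
        blocks, macros, _, _ = synth.simulation_blocks(cfg)
        with pytest.raises(ValueError, match="unidentifiable"):
            augment_with_experiment(blocks, macros, {}, None)


def test_stationary_from_generator(planted_network):
    pi = stationary_from_generator(planted_network.K)
    np.testing.assert_allclose(pi, planted_network.populations, atol=1e-10)


def test_dtraj_text_round_trip(tmp_path):
    d = np.array([0, 1, 2, 1, 0, 2])
    path = tmp_path / "d.txt"
    msm.write_dtraj(d, path)
    np.testing.assert_array_equal(msm.read_dtraj(path), d)
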