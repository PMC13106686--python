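"""Contact counting, type aggregation, segment errors and MSD fits."""

import numpy as np
import pytest

import hpslab as h
from hpslab.synthetic import gen_brownian_traj, gen_power_law_msd, gen_random_frame


def brute_force_contacts(pos, box, topology):
    """Independent all-pairs double-loop oracle (pure python/numpy)."""
    n = pos.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if topology.chain_id[i] == topology.chain_id[j] and j - i == 1:
                continue
            d = pos[i] - pos[j]
            d = d - box * np.round(d / box)
            rc = 1.2 * 0.5 * (topology.sigma[i] + topology.sigma[j])
            if float(np.dot(d, d)) < rc * rc:
                pairs.append((i, j))
    return pairs


class TestContactCutoff:
    def test_printed_rule(self):
        assert h.contact_cutoff(0.5, 0.5) == pytest.approx(0.6, rel=1e-12)

    def test_symmetry_and_scaling(self):
        assert h.contact_cutoff(0.45, 0.65) == h.contact_cutoff(0.65, 0.45)
        assert h.contact_cutoff(1.0, 1.2) == pytest.approx(
            2 * h.contact_cutoff(0.5, 0.6), rel=1e-12)

    def test_positive_sigma_required(self):
        with pytest.raises(ValueError):
            h.contact_cutoff(0.0, 0.5)


class TestCountContacts:
    def test_threshold_semantics(self):
        top = h.build_system(
            [h.ChainSpec("a", "G", 1), h.ChainSpec("b", "G", 1)], (20, 20, 20))
        rc = h.contact_cutoff(top.sigma[0], top.sigma[1])
        for factor, expected in [(0.99, 1.0), (1.01, 0.0)]:
            pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + factor * rc]])
            res = h.count_contacts([(pos, top.box)], top, normalize=False)
            assert res.inter[("a", "b")] == expected

    @pytest.mark.parametrize("n_beads,seed", [(100, 0), (300, 1), (500, 2)])
    def test_matches_brute_force_oracle(self, n_beads, seed):
        top, pos = gen_random_frame(n_beads, (8.0, 8.0, 8.0), 0.2, seed=seed)
        oracle = brute_force_contacts(pos, top.box, top)
        res = h.count_contacts([(pos, top.box)], top, normalize=False)
        total = sum(res.inter.values()) + sum(res.intra.values())
        assert total == len(oracle)

    def test_distant_identical_chains(self):
        top = h.build_system([h.ChainSpec("a", "GAGAG", 2)], (40, 40, 40))
        # compact folded conformation: non-bonded |i-j| >= 2 pairs in contact
        chain = np.array([[0, 0, 0], [0.3, 0, 0], [0.3, 0.3, 0],
                          [0, 0.3, 0], [0, 0, 0.3]])
        pos = np.vstack([chain + [2, 2, 2], chain + [2, 2, 20]])
        res = h.count_contacts([(pos, top.box)], top, normalize=False)
        assert res.inter[("a", "a")] == 0
        assert res.intra["a"] > 0

    def test_normalization_by_first_species(self):
        top = h.build_system(
            [h.ChainSpec("tau", "K" * 4, 2), h.ChainSpec("ab", "E" * 4, 4)],
            (30, 30, 30))
        rng = np.random.default_rng(1)
        pos = rng.random((top.n_beads, 3)) * 3.0 + 10.0  # clustered
        raw = h.count_contacts([(pos, top.box)], top, normalize=False)
        norm = h.count_contacts([(pos, top.box)], top, normalize=True)
        assert norm.inter[("tau", "ab")] == pytest.approx(
            raw.inter[("tau", "ab")] / 2.0)
        assert norm.inter[("ab", "ab")] == pytest.approx(
            raw.inter[("ab", "ab")] / 4.0)

    def test_permutation_invariance_across_same_species_chains(self):
        top = h.build_system([h.ChainSpec("a", "KESG", 3)], (15, 15, 15))
        rng = np.random.default_rng(7)
        pos = rng.random((top.n_beads, 3)) * 4.0
        res1 = h.count_contacts([(pos, top.box)], top, normalize=False)
        # relabel chains: swap chain 0 and 2 coordinate blocks
        pos2 = pos.copy()
        pos2[0:4], pos2[8:12] = pos[8:12].copy(), pos[0:4].copy()
        res2 = h.count_contacts([(pos2, top.box)], top, normalize=False)
        assert res2.inter[("a", "a")] == res1.inter[("a", "a")]
        assert res2.intra["a"] == res1.intra["a"]


class TestAggregateContacts:
    def test_charged_pair_fixture(self):
        top = h.build_system(
            [h.ChainSpec("k", "KKKK", 1), h.ChainSpec("e", "EEEE", 1)],
            (20, 20, 20))
        # interdigitated chains: all inter contacts are charged-charged
        pos = np.zeros((8, 3))
        pos[:4, 0] = np.arange(4) * 0.38 + 1.0
        pos[4:, 0] = np.arange(4) * 0.38 + 1.19
        pos[4:, 1] = 0.3
        res = h.count_contacts([(pos, top.box)], top, normalize=False)
        tm, _ = h.aggregate_contacts(res, top)
        from hpslab.params import TYPE_CODES
        c = TYPE_CODES["charged"]
        assert tm.sum() == tm[c, c]
        assert tm[c, c] > 0

    def test_type_matrix_conserves_grand_total(self):
        top, pos = gen_random_frame(120, (6.0, 6.0, 6.0), 0.2, seed=3)
        res = h.count_contacts([(pos, top.box)], top, normalize=False)
        tm, _ = h.aggregate_contacts(res, top)
        total_inter = sum(res.inter.values())
        assert tm.sum() == pytest.approx(total_inter, rel=1e-12)

    def test_aromatics_count_as_hydrophobic(self, table):
        for aa in "FWY":
            assert table.lookup(aa).type_class == "hydrophobic"


class TestSegmentErrors:
    @staticmethod
    def _traj_from_values(values):
        """1-bead trajectory whose x coordinate encodes a scalar series."""
        top = h.build_system([h.ChainSpec("a", "G", 1)], (100, 100, 100))
        nf = len(values)
        pos = np.zeros((nf, 1, 3))
        pos[:, 0, 0] = values
        return h.Trajectory(
            times=np.arange(1, nf + 1, dtype=float),
            boxes=np.tile([100.0, 100.0, 100.0], (nf, 1)),
            positions=pos, topology=top, unwrapped=True)

    def test_constant_series(self):
        traj = self._traj_from_values([3.0] * 8)
        fn = lambda t: float(t.positions[:, 0, 0].mean())
        mean, lo, hi = h.segment_errors(traj, fn, n_segments=4)
        assert mean == lo == hi == 3.0

    def test_known_segment_extremes(self):
        # 8 frames, segments of 2: segment means are 1, 2, 3, 4
        traj = self._traj_from_values([1, 1, 2, 2, 3, 3, 4, 4])
        fn = lambda t: float(t.positions[:, 0, 0].mean())
        mean, lo, hi = h.segment_errors(traj, fn, n_segments=4)
        assert (mean, lo, hi) == (2.5, 1.0, 4.0)

    def test_spread_contains_mean(self):
        rng = np.random.default_rng(0)
        traj = self._traj_from_values(rng.random(20))
        fn = lambda t: float(t.positions[:, 0, 0].mean())
        mean, lo, hi = h.segment_errors(traj, fn, n_segments=4)
        assert lo <= mean <= hi

    def test_too_few_frames_rejected(self):
        traj = self._traj_from_values([1.0, 2.0])
        with pytest.raises(ValueError):
            h.segment_errors(traj, lambda t: 0.0, n_segments=4)


class TestComputeMsd:
    def test_static_frames_are_zero(self):
        traj = gen_brownian_traj(20, 0.0, 0.1, 50, seed=1)
        res = h.compute_msd(traj, origin_stride=5)
        np.testing.assert_allclose(res.msd, 0.0, atol=1e-20)

    def test_ballistic_closed_form(self):
        top = h.build_system([h.ChainSpec("a", "G", 1)], (1e4, 1e4, 1e4))
        v = np.array([1.5, -0.5, 2.0])
        nf = 30
        times = np.arange(nf, dtype=float) * 0.1
        pos = times[:, None, None] * v[None, None, :]
        traj = h.Trajectory(times=times, boxes=np.tile([1e4] * 3, (nf, 1)),
                            positions=pos, topology=top, unwrapped=True)
        res = h.compute_msd(traj, origin_stride=1)
        v2 = float(np.dot(v, v))
        np.testing.assert_allclose(res.msd, v2 * res.lag_times**2, rtol=1e-10)

    def test_brownian_diffusion_recovery(self):
        traj = gen_brownian_traj(1000, 0.5, dt=0.1, n_steps=200, seed=42)
        res = h.compute_msd(traj, origin_stride=10, max_lag=10.0)
        d, _ = h.fit_msd_linear(res)
        assert d == pytest.approx(0.5, rel=0.05)

    def test_wrapped_trajectory_rejected(self):
        traj = gen_brownian_traj(5, 0.1, 0.1, 20, seed=0)
        from dataclasses import replace
        wrapped = replace(traj, unwrapped=False)
        with pytest.raises(ValueError):
            h.compute_msd(wrapped)

    def test_translation_invariance(self):
        traj = gen_brownian_traj(50, 0.3, 0.1, 100, seed=5)
        res1 = h.compute_msd(traj, origin_stride=10)
        from dataclasses import replace
        shifted = replace(traj, positions=traj.positions + np.array([5.0, -3.0, 100.0]))
        res2 = h.compute_msd(shifted, origin_stride=10)
        np.testing.assert_allclose(res2.msd, res1.msd, rtol=1e-12)


class TestMsdFits:
    def test_exact_power_law_recovery(self):
        res = gen_power_law_msd(2.0, 0.5, np.linspace(0, 50, 51))
        k, alpha, _, _ = h.fit_msd_power_law(res)
        assert alpha == pytest.approx(0.5, abs=1e-8)
        assert k == pytest.approx(2.0, rel=1e-8)

    def test_loglog_regression_oracle_equivalence(self):
        res = gen_power_law_msd(1.3, 0.8, np.linspace(0, 20, 41),
                                noise=0.05, seed=3)
        k, alpha, _, _ = h.fit_msd_power_law(res)
        tau, msd = res.lag_times[1:], res.msd[1:]
        A = np.column_stack([np.ones(tau.size), np.log(tau)])
        coef, *_ = np.linalg.lstsq(A, np.log(msd), rcond=None)
        assert alpha == pytest.approx(coef[1], abs=1e-8)
        assert np.log(k) == pytest.approx(coef[0], abs=1e-8)

    def test_brownian_alpha_near_one(self):
        traj = gen_brownian_traj(1000, 0.5, dt=0.1, n_steps=200, seed=11)
        res = h.compute_msd(traj, origin_stride=10, max_lag=10.0)
        _, alpha, _, _ = h.fit_msd_power_law(res)
        assert abs(alpha - 1.0) < 0.03

    def test_linear_fit_closed_form(self):
        lags = np.linspace(0, 10, 21)
        res = h.MSDResult(lag_times=lags, msd=12.0 * lags)
        d, se = h.fit_msd_linear(res)
        assert d == pytest.approx(2.0, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_msd_gives_zero_d(self):
        lags = np.linspace(0, 10, 21)
        res = h.MSDResult(lag_times=lags, msd=np.zeros(21))
        d, _ = h.fit_msd_linear(res)
        assert d == 0.0

    def test_nonpositive_msd_rejected_by_power_law(self):
        lags = np.linspace(0, 10, 21)
        res = h.MSDResult(lag_times=lags, msd=np.zeros(21))
        with pytest.raises(ValueError):
            h.fit_msd_power_law(res)

    def test_immobile_scaffold_mobile_client_exponents(self):
        # condensate-like fixture: frozen scaffold, diffusing client
        scaffold = gen_brownian_traj(200, 1e-6, 0.1, 150, seed=2)
        client = gen_brownian_traj(200, 1.0, 0.1, 150, seed=3)
        res_c = h.compute_msd(client, origin_stride=10, max_lag=8.0)
        _, alpha_c, _, _ = h.fit_msd_power_law(res_c)
        assert abs(alpha_c - 1.0) < 0.05
        res_s = h.compute_msd(scaffold, origin_stride=10, max_lag=8.0)
        assert res_s.msd.max() < 1e-3
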