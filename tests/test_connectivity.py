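"""Pair enumeration and canonical coherence with orientation search."""

import numpy as np
import pytest

import cohdics as cd
from cohdics.connectivity import ConnectivityEstimate, ConnectivityPairs
from cohdics.csd import CSDMatrix

from conftest import random_hermitian_psd


def csd_from(mat):
    return CSDMatrix(matrix=mat, frequencies=(10.0,), tmin=0.0, tmax=0.4,
                     n_epochs=1)


def dense_grid_canonical_coherence(rows_i, rows_j, inv_matrix, n=720):
    """Brute-force oracle: build every oriented leadfield on a dense
    n x n angle grid explicitly and evaluate the coherence ratio directly."""
    thetas = np.arange(n) * np.pi / n
    l1 = np.outer(np.sin(thetas), rows_i[0]) + np.outer(np.cos(thetas), rows_i[1])
    l2 = np.outer(np.sin(thetas), rows_j[0]) + np.outer(np.cos(thetas), rows_j[1])
    a1 = l1 @ inv_matrix
    d1 = np.einsum("ts,ts->t", a1, l1).real
    d2 = np.einsum("ts,ts->t", l2 @ inv_matrix, l2).real
    num = np.abs(a1 @ l2.T) ** 2
    return float((num / np.outer(d1, d2)).max())


def random_problem(rng, n_sensors=8):
    c = random_hermitian_psd(rng, n_sensors) + 0.05 * np.eye(n_sensors)
    inv = cd.regularize_csd_inverse(csd_from(c), alpha=0.05)
    rows_i = rng.standard_normal((2, n_sensors))
    rows_j = rng.standard_normal((2, n_sensors))
    rows_i /= np.linalg.norm(rows_i, axis=1, keepdims=True)
    rows_j /= np.linalg.norm(rows_j, axis=1, keepdims=True)
    return rows_i, rows_j, inv


class TestPairEnumeration:
    def _line_space(self, xs):
        pts = [[x, 0.0, 0.0] for x in xs]
        return cd.SourceSpace(points=pts, vertex_ids=np.arange(len(xs)),
                              sphere_origin=[0, 0, 0])

    def test_collinear_threshold_case(self):
        src = self._line_space([0.0, 0.03, 0.05])
        pairs = cd.all_to_all_connectivity_pairs(src, min_dist=0.04)
        assert pairs.pairs.tolist() == [[0, 2]]

    def test_zero_threshold_gives_all_pairs(self, grid_small):
        pairs = cd.all_to_all_connectivity_pairs(grid_small, min_dist=0.0)
        n = grid_small.n_vertices
        assert pairs.n_pairs == n * (n - 1) // 2

    def test_exact_threshold_distance_is_excluded(self):
        src = self._line_space([0.0, 0.04])
        pairs = cd.all_to_all_connectivity_pairs(src, min_dist=0.04)
        assert pairs.n_pairs == 0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            pts = rng.uniform(-0.07, 0.07, (n, 3))
            src = cd.SourceSpace(points=pts, vertex_ids=np.arange(n),
                                 sphere_origin=[0, 0, 0])
            d = float(rng.uniform(0.0, 0.1))
            got = {tuple(p) for p in
                   cd.all_to_all_connectivity_pairs(src, d).pairs}
            want = {
                (i, j)
                for i in range(n) for j in range(i + 1, n)
                if np.linalg.norm(pts[i] - pts[j]) > d
            }
            assert got == want


class TestSensorCoherence:
    def test_self_coherence_is_one(self, rng):
        c = random_hermitian_psd(rng, 4) + 0.1 * np.eye(4)
        assert cd.sensor_coherence(csd_from(c), 2, 2) == pytest.approx(1.0)

    def test_zero_cross_term(self):
        c = np.diag([2.0, 3.0]).astype(complex)
        assert cd.sensor_coherence(csd_from(c), 0, 1) == 0.0

    def test_hand_computed_value(self):
        c = np.array([[2.0, 1 + 1j], [1 - 1j, 4.0]])
        assert cd.sensor_coherence(csd_from(c), 0, 1) == pytest.approx(0.25)

    def test_degenerate_power_rejected(self):
        c = np.zeros((2, 2), dtype=complex)
        with pytest.raises(ValueError):
            cd.sensor_coherence(csd_from(c), 0, 1)


class TestOrientedLeadfield:
    def test_endpoints(self, rng):
        rows = rng.standard_normal((2, 6))
        assert np.allclose(cd.oriented_leadfield(rows, 0.0), rows[1])
        assert np.allclose(cd.oriented_leadfield(rows, np.pi / 2), rows[0])

    def test_pi_shift_negates(self, rng):
        rows = rng.standard_normal((2, 6))
        th = 0.9
        assert np.allclose(cd.oriented_leadfield(rows, th + np.pi),
                           -cd.oriented_leadfield(rows, th))

    def test_norm_continuous_over_dense_grid(self, rng):
        rows = rng.standard_normal((2, 6))
        thetas = np.linspace(0, np.pi, 400)
        norms = [np.linalg.norm(cd.oriented_leadfield(rows, t))
                 for t in thetas]
        jumps = np.abs(np.diff(norms))
        assert jumps.max() < 0.1 * max(norms)


class TestCanonicalCoherence:
    def test_identical_rows_reach_unity(self, rng):
        rows, _, inv = random_problem(rng)
        coh, _, _ = cd.canonical_coherence(rows, rows, inv, n_angles=50)
        assert coh == pytest.approx(1.0, abs=1e-9)

    def test_values_in_unit_interval(self, rng):
        for _ in range(50):
            rows_i, rows_j, inv = random_problem(rng)
            coh, _, _ = cd.canonical_coherence(rows_i, rows_j, inv, 50)
            assert -1e-12 <= coh <= 1 + 1e-12

    def test_grid_matches_dense_brute_force(self, fwd_tan_small, rng):
        # random 2-dipole problems drawn from a simulated recording: the
        # 50-point angle grid resolves the peak to within 1e-3 of a
        # 720 x 720 dense scan
        vid = int(fwd_tan_small.source_space.vertex_ids[8])
        cfg = cd.SimulationConfig(active_sources=((vid, 0.5),), snr=2.0,
                                  n_epochs=50, seed=21)
        ep, _ = cd.simulate_epochs(fwd_tan_small, cfg)
        band = cd.csd_band_mean(
            cd.csd_morlet(ep, [9.0, 10.0, 11.0], 0, 0.4, 7, 20), 7, 13
        )
        inv = cd.regularize_csd_inverse(band, 0.05)
        lf = fwd_tan_small.leadfields
        l_hat = lf / np.linalg.norm(lf, axis=2, keepdims=True)
        n_src = fwd_tan_small.n_sources
        for _ in range(15):
            i, j = rng.choice(n_src, 2, replace=False)
            got, _, _ = cd.canonical_coherence(l_hat[i], l_hat[j], inv, 50)
            want = dense_grid_canonical_coherence(l_hat[i], l_hat[j],
                                                  inv.inv_matrix, n=720)
            assert got == pytest.approx(want, abs=1e-3)

    def test_scale_invariance(self, rng):
        rows_i, rows_j, inv = random_problem(rng)
        base, _, _ = cd.canonical_coherence(rows_i, rows_j, inv, 50)
        for scale in (1e-6, 3.7, 1e6):
            got, _, _ = cd.canonical_coherence(scale * rows_i, rows_j, inv, 50)
            assert got == pytest.approx(base, abs=1e-10)

    def test_pi_periodicity_of_objective(self, rng):
        # a [0, 2 pi) scan finds nothing beyond the [0, pi) grid
        rows_i, rows_j, inv = random_problem(rng)
        half, _, _ = cd.canonical_coherence(rows_i, rows_j, inv, 180)
        thetas = np.arange(360) * 2 * np.pi / 360
        best = -1.0
        for t1 in thetas[::6]:
            l1 = cd.oriented_leadfield(rows_i, t1)
            a1 = l1 @ inv.inv_matrix
            d1 = (a1 @ l1).real
            for t2 in thetas[::6]:
                l2 = cd.oriented_leadfield(rows_j, t2)
                val = abs(a1 @ l2) ** 2 / (d1 * ((l2 @ inv.inv_matrix) @ l2).real)
                best = max(best, val)
        assert best <= half + 1e-6

    def test_too_few_angles_rejected(self, rng):
        rows_i, rows_j, inv = random_problem(rng)
        with pytest.raises(ValueError):
            cd.canonical_coherence(rows_i, rows_j, inv, n_angles=1)


class TestDicsConnectivity:
    def test_vectorized_path_matches_single_pair(self, fwd_tan_small, rng):
        n = fwd_tan_small.sensor_array.n_sensors
        c = random_hermitian_psd(rng, n) + 0.05 * np.eye(n)
        csd = csd_from(c)
        pairs = cd.all_to_all_connectivity_pairs(
            fwd_tan_small.source_space, 0.04
        )
        con = cd.dics_connectivity(pairs, fwd_tan_small, csd, 0.05, 50)
        inv = cd.regularize_csd_inverse(csd, 0.05)
        lf = fwd_tan_small.leadfields
        l_hat = lf / np.linalg.norm(lf, axis=2, keepdims=True)
        vids = list(fwd_tan_small.source_space.vertex_ids)
        for k in rng.choice(pairs.n_pairs, 15, replace=False):
            i, j = pairs.pairs[k]
            coh, _, _ = cd.canonical_coherence(
                l_hat[vids.index(i)], l_hat[vids.index(j)], inv, 50
            )
            assert con.coherence[k] == pytest.approx(coh, abs=1e-10)

    def test_null_contrast_has_no_distance_trend(self, fwd_tan_small):
        # raw coherence inherently tracks leadfield overlap (field
        # spread); under the null, the condition *contrast* — which is
        # what the group statistics consume — must not depend on pair
        # distance beyond the threshold
        from scipy.stats import spearmanr
        src = fwd_tan_small.source_space
        vids = src.vertex_ids
        pairs = cd.all_to_all_connectivity_pairs(src, 0.04)
        cons = []
        for seed in (2, 3):
            cfg = cd.SimulationConfig(
                active_sources=((int(vids[5]), 0.3), (int(vids[40]), 1.0)),
                coupling=0.3, n_epochs=100, seed=seed,
            )
            ep, _ = cd.simulate_epochs(fwd_tan_small, cfg)
            band = cd.csd_band_mean(
                cd.csd_morlet(ep, [9, 10, 11], 0, 0.4, 7, 20), 7, 13
            )
            cons.append(cd.dics_connectivity(pairs, fwd_tan_small, band,
                                             0.05, 50))
        contrast = cons[0] - cons[1]
        dists = [np.linalg.norm(pairs.positions[int(a)] - pairs.positions[int(b)])
                 for a, b in pairs.pairs]
        rho = spearmanr(dists, contrast.coherence).statistic
        assert abs(rho) < 0.3


class TestContrastAndReorder:
    def _con(self, pairs, coh, **kw):
        return ConnectivityEstimate(pairs=pairs, coherence=coh, **kw)

    def _pairs(self):
        pos = {0: np.zeros(3), 1: np.array([0.05, 0, 0]),
               2: np.array([0, 0.05, 0]), 5: np.array([0, 0, 0.05]),
               7: np.array([0.05, 0.05, 0])}
        return ConnectivityPairs(
            pairs=[[0, 1], [0, 2], [1, 5], [2, 7]], min_dist=0.04,
            positions=pos,
        )

    def test_self_contrast_is_zero(self):
        pairs = self._pairs()
        a = self._con(pairs, [0.1, 0.2, 0.3, 0.4])
        out = a - a
        assert np.allclose(out.coherence, 0)
        assert out.is_contrast

    def test_contrast_bounded(self, rng):
        pairs = self._pairs()
        a = self._con(pairs, rng.uniform(0, 1, 4))
        b = self._con(pairs, rng.uniform(0, 1, 4))
        assert np.all(np.abs((a - b).coherence) <= 1)

    def test_grand_average_is_sum_over_len(self, rng):
        pairs = self._pairs()
        cons = [self._con(pairs, rng.uniform(0, 1, 4)) for _ in range(5)]
        avg = cd.connectivity_grand_average(cons)
        want = sum(c.coherence for c in cons) / 5
        assert np.allclose(avg.coherence, want)

    def test_mismatched_pairs_rejected(self):
        pairs = self._pairs()
        other = ConnectivityPairs(pairs=[[0, 1]], min_dist=0.04,
                                  positions=pairs.positions)
        with pytest.raises(ValueError):
            self._con(pairs, [0.1, 0.2, 0.3, 0.4]) - self._con(other, [0.5])

    def test_identity_mapping_unchanged(self):
        pairs = self._pairs()
        con = self._con(pairs, [0.1, 0.2, 0.3, 0.4])
        out = cd.to_common_pair_order(con, {v: v for v in (0, 1, 2, 5, 7)})
        assert np.array_equal(out.pairs.pairs, pairs.pairs)
        assert np.allclose(out.coherence, con.coherence)

    def test_swap_inducing_mapping_recanonicalizes(self):
        pos = {2: np.zeros(3), 5: np.ones(3) * 0.05}
        pairs = ConnectivityPairs(pairs=[[2, 5]], min_dist=0.0, positions=pos)
        con = self._con(pairs, [0.42])
        out = cd.to_common_pair_order(con, {2: 7, 5: 1})
        assert out.pairs.pairs.tolist() == [[1, 7]]
        assert out.coherence[0] == pytest.approx(0.42)

    def test_random_permutation_preserves_multiset(self, rng):
        pairs = self._pairs()
        con = self._con(pairs, [0.1, 0.2, 0.3, 0.4])
        vids = [0, 1, 2, 5, 7]
        for _ in range(100):
            perm = rng.permutation(100)[:5]
            mapping = {v: int(p) for v, p in zip(vids, perm)}
            out = cd.to_common_pair_order(con, mapping)
            got = {(int(a), int(b), round(float(c), 12))
                   for (a, b), c in zip(out.pairs.pairs, out.coherence)}
            want = {(min(mapping[a], mapping[b]), max(mapping[a], mapping[b]),
                     round(float(c), 12))
                    for (a, b), c in zip(pairs.pairs, con.coherence)}
            assert got == want

    def test_unmapped_vertex_rejected(self):
        pairs = self._pairs()
        con = self._con(pairs, [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            cd.to_common_pair_order(con, {0: 1, 1: 2})
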