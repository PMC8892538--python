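"""Hi-C contact loading, balancing, O/E, correlation, compartment PC1."""

import numpy as np
import pytest

from scaffotype3d import karyosim as ks
from scaffotype3d.compartments import (
    BinTable,
    CompartmentError,
    ContactMatrix,
    EigenProfile,
    compartment_profile,
    kr_balance,
    leading_eigenvector,
    load_contacts,
    observed_expected,
    orient_sign,
    pearson_correlation,
    read_bedgraph,
    write_bedgraph,
)


def dense_matrix(counts, bin_size=500_000):
    counts = np.asarray(counts, dtype=float)
    table = BinTable("s1", counts.shape[0] * bin_size, bin_size)
    return ContactMatrix(table, counts)


class TestLoadContacts:
    def test_triplets_mirrored_with_zero_diagonal(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t0\t4\n0\t1\t2\n")
        m = load_contacts(p, scaffold="s1", scaffold_length=1_000_000,
                          coverage_percentile=0)
        assert np.array_equal(m.counts, [[4, 2], [2, 0]])

    def test_one_bin_scaffold(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t0\t7\n")
        m = load_contacts(p, scaffold="s1", scaffold_length=400_000,
                          coverage_percentile=0)
        assert m.counts.shape == (1, 1)

    def test_out_of_range_bin_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t5\t1\n")
        with pytest.raises(CompartmentError, match="out of range"):
            load_contacts(p, scaffold="s1", scaffold_length=1_500_000)

    def test_hdf5_container_round_trip(self, tmp_path):
        import h5py

        n, bin_size = 6, 500_000
        rng = np.random.default_rng(0)
        upper = np.triu(rng.poisson(8, (n, n))).astype(float)
        counts = upper + np.triu(upper, 1).T
        path = tmp_path / "c.h5"
        ii, jj = np.triu_indices(n)
        with h5py.File(path, "w") as f:
            f.create_dataset("bins/chrom", data=[b"s1"] * n)
            f.create_dataset("bins/start", data=np.arange(n) * bin_size)
            f.create_dataset("bins/end", data=(np.arange(n) + 1) * bin_size)
            f.create_dataset("pixels/bin1_id", data=ii)
            f.create_dataset("pixels/bin2_id", data=jj)
            f.create_dataset("pixels/count", data=counts[ii, jj])
        m = load_contacts(path, "hdf5_container", bin_size, scaffold="s1",
                          coverage_percentile=0)
        assert np.array_equal(m.counts, counts)


def sinkhorn_oracle(mat, n_iter=20000, tol=1e-10):
    """Independent high-precision alternating row/column scaling."""
    d = np.ones(mat.shape[0])
    for _ in range(n_iter):
        s = (d[:, None] * mat * d[None, :]).sum(axis=1)
        if np.abs(s / s.mean() - 1).max() < tol:
            break
        d = d * (s.mean() / s) ** 0.5
    return d[:, None] * mat * d[None, :]


class TestKrBalance:
    def test_doubly_stochastic_is_fixed_point(self):
        m = dense_matrix([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
        out = kr_balance(m)
        assert np.allclose(out.scaling[out.bin_table.valid_mask], 1.0, atol=1e-6)

    def test_matches_independent_sinkhorn_oracle(self, rng):
        raw = rng.uniform(0.5, 4.0, (3, 3))
        raw = (raw + raw.T) / 2
        out = kr_balance(dense_matrix(raw), tol=1e-8)
        expected = sinkhorn_oracle(raw)
        assert np.allclose(out.counts, expected, atol=1e-6)
        sums = out.counts[out.bin_table.valid_mask].sum(axis=1)
        assert np.abs(sums / sums.mean() - 1).max() < 1e-6

    def test_zero_row_masked_remainder_balanced(self):
        raw = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 0]])
        out = kr_balance(dense_matrix(raw))
        assert list(out.bin_table.valid_mask) == [True, True, False]
        sums = np.nansum(out.counts[:2, :2], axis=1)
        assert np.abs(sums[0] - sums[1]) < 1e-5

    def test_row_sum_spread_within_tolerance(self, rng):
        tol = 1e-6
        for _ in range(5):
            n = int(rng.integers(5, 30))
            raw = rng.poisson(20, (n, n)).astype(float)
            raw = raw + raw.T
            out = kr_balance(dense_matrix(raw), tol=tol)
            sums = out.counts[out.bin_table.valid_mask].sum(axis=1)
            assert sums.max() / sums.min() <= 1 + 10 * tol


class TestObservedExpected:
    def test_toeplitz_becomes_ones(self):
        n = 8
        toe = np.array([[1.0 / (abs(i - j) + 1) for j in range(n)] for i in range(n)])
        oe = observed_expected(dense_matrix(toe))
        assert np.allclose(oe, 1.0)

    def test_diagonal_means_are_one(self, rng):
        raw = rng.poisson(30, (10, 10)).astype(float)
        raw = raw + raw.T
        oe = observed_expected(dense_matrix(raw))
        for s in range(10):
            vals = np.diagonal(oe, s)
            assert np.isclose(np.nanmean(vals), 1.0)

    def test_matches_per_distance_oracle(self, rng):
        n = 9
        raw = rng.uniform(1, 5, (n, n))
        raw = (raw + raw.T) / 2
        oe = observed_expected(dense_matrix(raw))
        # independent double-loop oracle
        for i in range(n):
            for j in range(n):
                s = abs(i - j)
                vals = [raw[a, b] for a in range(n) for b in range(n) if abs(a - b) == s]
                assert np.isclose(oe[i, j], raw[i, j] / np.mean(vals))

    def test_planted_checkerboard_times_decay(self):
        # lambda_ij = decay(|i-j|) * (1 + c a_i a_j) with a balanced sign
        # vector: after O/E the checkerboard factor is recovered exactly up
        # to the per-diagonal mean of the checkerboard term
        a = np.array([1, -1] * 5, dtype=float)
        c, n = 0.4, 10
        decay = lambda s: 1.0 / max(s, 1)
        lam = np.array(
            [[decay(abs(i - j)) * (1 + c * a[i] * a[j]) for j in range(n)] for i in range(n)]
        )
        oe = observed_expected(dense_matrix(lam))
        for i in range(n):
            for j in range(n):
                s = abs(i - j)
                diag_mean = np.mean([1 + c * a[k] * a[k + s] for k in range(n - s)])
                assert np.isclose(oe[i, j], (1 + c * a[i] * a[j]) / diag_mean)


class TestPearson:
    def test_matches_textbook_formula(self, rng):
        n = 6
        oe = rng.normal(1, 0.3, (n, n))
        oe = (oe + oe.T) / 2
        corr = pearson_correlation(oe)
        for i in range(n):
            for j in range(n):
                x, y = oe[i] - oe[i].mean(), oe[j] - oe[j].mean()
                expected = (x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum())
                assert abs(corr[i, j] - expected) < 1e-12

    def test_too_few_bins_rejected(self):
        with pytest.raises(CompartmentError, match="too short"):
            pearson_correlation(np.ones((2, 2)))


class TestLeadingEigenvector:
    def test_checkerboard_sign_pattern(self):
        a = np.array([1.0, 1, 1, -1, -1, 1, -1])
        corr = np.outer(a, a)
        profile = leading_eigenvector(corr)
        signs = np.sign(profile.values)
        assert np.array_equal(signs, a) or np.array_equal(signs, -a)

    def test_constant_matrix_degenerate(self):
        with pytest.raises(CompartmentError, match="degenerate"):
            leading_eigenvector(np.ones((5, 5)))

    def test_matches_dense_eigensolver_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 51))
            m = rng.normal(0, 1, (n, n))
            corr = np.corrcoef(m)
            got = leading_eigenvector(corr).values
            # independent oracle: numpy full-spectrum solve of the
            # double-centered matrix
            rm = corr.mean(axis=1, keepdims=True)
            centered = corr - rm - rm.T + corr.mean()
            w, v = np.linalg.eigh(centered)
            expected = v[:, np.argmax(w)]
            expected /= np.linalg.norm(expected)
            if np.dot(got, expected) < 0:
                expected = -expected
            assert np.abs(got - expected).max() < 1e-8

    def test_unit_norm_and_explained_fraction(self, rng):
        corr = np.corrcoef(rng.normal(0, 1, (12, 12)))
        p = leading_eigenvector(corr)
        assert np.isclose(np.linalg.norm(p.values[p.valid]), 1.0)
        assert 0 <= p.explained_fraction <= 1


class TestOrientSign:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        table = BinTable("s1", len(values) * 500_000, 500_000)
        return EigenProfile(table, values)

    def test_anchor_negation_flips(self):
        p = self._profile([0.3, -0.5, 0.2])
        anchor = self._profile([-0.3, 0.5, -0.2])
        out = orient_sign(p, anchor)
        assert np.allclose(out.values, -p.values)
        assert out.sign_anchor == "reference-correlation"

    def test_no_anchor_first_bin_positive(self):
        out = orient_sign(self._profile([-0.3, 0.1, 0.4]))
        assert out.values[0] == pytest.approx(0.3)

    def test_zero_correlation_falls_back(self):
        p = self._profile([-1.0, 0.0, 1.0])
        anchor = self._profile([1.0, 1.0, 1.0])  # zero variance -> r undefined
        with pytest.warns(UserWarning):
            out = orient_sign(p, anchor)
        assert out.sign_anchor == "first-bin-positive"
        assert out.values[0] == 1.0


class TestPipeline:
    def test_deterministic(self):
        cfg = ks.SimConfig(n_chroms=1, chrom_lengths=(20_000_000,), seed=4,
                           bin_size=500_000)
        anc, prof = ks.make_genome(cfg)
        mat = ks.simulate_hic("chr1", 20_000_000, prof["chr1"], cfg, cfg.rng())
        a = compartment_profile(mat)
        b = compartment_profile(mat)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_bedgraph_round_trip(self, tmp_path):
        cfg = ks.SimConfig(n_chroms=1, chrom_lengths=(10_000_000,), seed=9,
                           bin_size=500_000)
        anc, prof = ks.make_genome(cfg)
        mat = ks.simulate_hic("chr1", 10_000_000, prof["chr1"], cfg, cfg.rng())
        p = compartment_profile(mat)
        path = tmp_path / "eig.bedgraph"
        write_bedgraph(p, path)
        back = read_bedgraph(path, 500_000, scaffold_length=10_000_000)
        assert np.allclose(back.values[back.valid], p.values[p.valid], atol=1e-6)
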