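"""MSA feature engineering: weights, profiles, couplings, tensor layout."""

import numpy as np
import pytest

from trxgeom.containers import MSA
from trxgeom.msa_features import (
    N_CHANNELS,
    apc,
    assemble_input_tensor,
    couplings,
    featurize,
    profile_and_entropy,
    sequence_weights,
    subsample_msa,
)


def msa_of(*rows):
    return MSA(ids=[f"s{i}" for i in range(len(rows))], rows=list(rows))


class TestSequenceWeights:
    def test_identical_rows_share_weight(self):
        m = msa_of("ACDE", "ACDE", "ACDE")
        w = sequence_weights(m)
        np.testing.assert_allclose(w.w, [1 / 3] * 3)
        assert w.neff == pytest.approx(1.0)

    def test_dissimilar_rows_keep_unit_weight(self):
        m = msa_of("AAAA", "CCCC", "DDDD")
        w = sequence_weights(m)
        np.testing.assert_allclose(w.w, 1.0)
        assert w.neff == pytest.approx(3.0)

    def test_two_copies_plus_distinct(self):
        # rows 0,1 identical; row 2 at 50% identity to both (cutoff 0.8)
        # brute force: neighbor counts are (2, 2, 1) -> weights (1/2, 1/2, 1)
        m = msa_of("ACDE", "ACDE", "ACKR")
        w = sequence_weights(m, identity_cutoff=0.8)
        np.testing.assert_allclose(w.w, [0.5, 0.5, 1.0])

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            sequence_weights(msa_of("AC"), identity_cutoff=1.5)


class TestProfileAndEntropy:
    def test_conserved_column_zero_entropy(self):
        m = msa_of("A", "A", "A")
        f = profile_and_entropy(m, pseudocount=0.0)
        assert f.shape == (1, 42)
        assert f[0, 20] == pytest.approx(1.0)   # PSSM block starts at 20
        assert f[0, 41] == pytest.approx(0.0)   # entropy channel

    def test_uniform_column_max_entropy(self):
        # artificial frequencies: feed 21 rows, one per state
        rows = list("ARNDCQEGHILKMFPSTWYV") + ["-"]
        m = MSA(ids=[str(i) for i in range(21)], rows=rows)
        f = profile_and_entropy(m, pseudocount=0.0)
        assert f[0, 41] == pytest.approx(np.log(21))

    def test_single_sequence_pseudocount_closed_form(self):
        c = 0.1
        m = msa_of("A")
        f = profile_and_entropy(m, pseudocount=c)
        expected_hit = (1 + c) / (1 + 21 * c)
        expected_miss = c / (1 + 21 * c)
        assert f[0, 20] == pytest.approx(expected_hit)
        assert f[0, 21] == pytest.approx(expected_miss)
        freqs = np.array([expected_hit] + [expected_miss] * 20)
        assert f[0, 41] == pytest.approx(-(freqs * np.log(freqs)).sum())

    def test_entropy_bounds_on_real_msa(self, target48):
        f = profile_and_entropy(target48.msa)
        ent = f[:, 41]
        assert (ent >= -1e-12).all() and (ent <= np.log(21) + 1e-12).all()


class TestCouplings:
    def test_tiny_msa_matches_dense_inverse(self):
        """L=2, N=3: coupling block equals an independently built 42x42
        weighted-covariance inverse."""
        m = msa_of("AC", "AD", "CC")
        w = sequence_weights(m)
        shrink = 0.5
        got = couplings(m, w, shrinkage=shrink)

        # brute-force oracle with explicit loops
        X = m.encoded()
        wn = w.w / w.w.sum()
        onehot = np.zeros((3, 42))
        for r in range(3):
            for pos in range(2):
                onehot[r, pos * 21 + X[r, pos]] = 1.0
        mu = sum(wn[r] * onehot[r] for r in range(3))
        cov = np.zeros((42, 42))
        for r in range(3):
            d = onehot[r] - mu
            cov += wn[r] * np.outer(d, d)
        prec = np.linalg.inv(cov + shrink * np.eye(42))
        block01 = -prec[0:21, 21:42]
        np.testing.assert_allclose(
            got[0, 1, :441].reshape(21, 21), block01, atol=1e-9)

    def test_independent_columns_small_apc(self, rng):
        rows = ["".join("ARNDCQEGHILKMFPSTWYV"[rng.integers(20)]
                        for _ in range(10)) for _ in range(200)]
        m = MSA(ids=[str(i) for i in range(200)], rows=rows)
        got = couplings(m)
        assert np.abs(got[:, :, -1]).mean() <= 0.05

    def test_covarying_pair_is_apc_argmax(self, rng):
        # columns 2 and 7 jointly flip between (A,C) and (D,E)
        rows = []
        for _ in range(200):
            s = ["ARNDCQEGHI"[rng.integers(10)] for _ in range(10)]
            if rng.random() < 0.5:
                s[2], s[7] = "A", "C"
            else:
                s[2], s[7] = "D", "E"
            rows.append("".join(s))
        m = MSA(ids=[str(i) for i in range(200)], rows=rows)
        score = couplings(m)[:, :, -1]
        np.fill_diagonal(score, -np.inf)
        i, j = np.unravel_index(np.argmax(score), score.shape)
        assert {i, j} == {2, 7}

    def test_single_sequence_gives_zero_couplings(self):
        got = couplings(msa_of("ACDE"))
        assert np.all(got == 0.0)

    def test_coupling_magnitude_decreases_with_shrinkage(self, target48):
        m = target48.msa.subset(range(40))
        w = sequence_weights(m)
        mags = [np.abs(couplings(m, w, shrinkage=s)[:, :, :441]).mean()
                for s in (0.3, 1.0, 3.0, 10.0)]
        assert all(a > b for a, b in zip(mags, mags[1:]))


class TestInputTensor:
    def test_channel_count_and_layout(self, rng):
        L = 5
        f1d = rng.random((L, 42))
        f2d = rng.random((L, L, 442))
        t = assemble_input_tensor(f1d, f2d)
        assert t.shape == (L, L, 526)
        for i in range(L):
            for j in range(L):
                np.testing.assert_array_equal(t[i, j, 0:42], f1d[i])
                np.testing.assert_array_equal(t[i, j, 42:84], f1d[j])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_input_tensor(rng.random((5, 42)), rng.random((4, 4, 442)))

    def test_full_featurize_invariants(self, target48):
        t = featurize(target48.msa)
        L = target48.msa.length
        assert t.shape == (L, L, N_CHANNELS)
        # APC channel symmetric
        np.testing.assert_allclose(t[:, :, -1], t[:, :, -1].T, atol=1e-12)
        # coupling block at (i,j) is the transpose of the block at (j,i)
        blocks = t[:, :, 84:525].reshape(L, L, 21, 21)
        np.testing.assert_allclose(
            blocks, blocks.transpose(1, 0, 3, 2), atol=1e-9)


class TestAPC:
    def test_apc_removes_rank_one_background(self):
        r = np.array([1.0, 2.0, 3.0, 4.0])
        S = np.outer(r, r)
        np.fill_diagonal(S, 0.0)
        corrected = apc(S)
        off = ~np.eye(4, dtype=bool)
        # product background is strongly suppressed
        assert np.abs(corrected[off]).max() < 0.35 * np.abs(S[off]).max()


class TestSubsample:
    def test_single_row_unchanged(self, rng):
        m = msa_of("ACDE")
        assert subsample_msa(m, rng) is m

    def test_query_always_first(self, target48, rng):
        for _ in range(20):
            sub = subsample_msa(target48.msa, rng)
            assert sub.rows[0] == target48.msa.query

    def test_depth_spans_log_range(self):
        rng = np.random.default_rng(77)
        m = MSA(ids=[str(i) for i in range(1000)], rows=["A"] * 1000)
        ks = [subsample_msa(m, rng).depth for _ in range(1000)]
        assert min(ks) == 1
        assert max(ks) >= 500
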