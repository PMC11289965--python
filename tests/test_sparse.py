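"""Sparse engine: candidate semantics, rolling-space contract, guards."""

import random

import pytest

from sparsefold import (INF, fold_dense, fold_sparse, masked_energy,
                        random_constraints)
from sparsefold.sparse import INF_LIMIT


def dense_candidate_set(seq, model, P):
    """Candidate cells derived from dense matrices by the defining
    inequalities: branch contribution beats every decomposition in the
    external (Vd < Wp) or multiloop (VdM < WMp) context."""
    mats, _ = fold_dense(seq, model, P)
    n = len(seq)
    out = set()
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            if mats.Vd[i][j] < mats.Wp[i][j] or mats.VdM[i][j] < mats.WMp[i][j]:
                out.add((i, j))
    return out


def sparse_candidate_set(seq, model, P, strategy="standard"):
    r = fold_sparse(seq, model, strategy, P, keep_state=True)
    st = r.state
    return {(e[0], j) for j in range(1, st.n + 1) for e in st.cand[j]}, r


class TestCandidates:
    @pytest.mark.parametrize("model", ["d0", "d1", "d2"])
    def test_candidate_set_matches_dense_inequalities(self, P, corpus, model):
        seqs = [s for s in corpus if len(s) <= 40][:8]
        for seq in seqs:
            want = dense_candidate_set(seq, model, P)
            got, _ = sparse_candidate_set(seq, model, P)
            assert got == want

    def test_worked_example_span_is_candidate(self, P):
        # inside the 19-mer context the GGGAAAACCCC span [5,15] is a
        # candidate: its (dangled) branch contribution beats decompositions
        got, r = sparse_candidate_set("AACAGGGAAAACCCCAGAA", "d1", P)
        assert (5, 15) in got
        entry = next(e for e in r.state.cand[15] if e[0] == 5)
        assert entry[1] == -240  # V, not the dangled branch value (-290)

    def test_short_spans_never_candidates(self, P, small_corpus):
        for seq in small_corpus[:5]:
            got, _ = sparse_candidate_set(seq, "d2", P)
            assert all(j - i > P.m for i, j in got)

    def test_z_below_quadratic_and_column_counts(self, P, small_corpus):
        for seq in small_corpus:
            r = fold_sparse(seq, "d1", "standard", P)
            n = len(seq)
            assert r.stats.Z < n * (n - 1) / 2
            assert sum(r.stats.per_column_candidates) == r.stats.Z

    def test_constraints_do_not_increase_z(self, P, small_corpus):
        for k, seq in enumerate(small_corpus):
            C = random_constraints(seq, seed=100 + k)
            free = fold_sparse(seq, "d1", "standard", P)
            constrained = fold_sparse(seq, "d1", "standard", P, C)
            assert constrained.stats.Z <= free.stats.Z


class TestCellEquivalence:
    @pytest.mark.parametrize("model", ["d0", "d1", "d2"])
    def test_external_row_matches_dense(self, P, corpus, model):
        """The retained sparse W(1, ·) row equals the dense W(1, ·)."""
        for seq in corpus[:6]:
            mats, _ = fold_dense(seq, model, P)
            r = fold_sparse(seq, model, "standard", P, keep_state=True)
            n = len(seq)
            assert [r.state.W1[j] for j in range(1, n + 1)] == \
                [mats.W[1][j] for j in range(1, n + 1)]

    @pytest.mark.parametrize("model", ["d0", "d1", "d2"])
    def test_wm_rows_recomputed_from_candidates_match_dense(self, P, corpus,
                                                            model):
        """Candidate-only recomputation of WM/WM2 rows reproduces the dense
        matrices cell-wise (the space-efficient traceback's foundation)."""
        from sparsefold import recompute_wm_row
        for seq in corpus[:6]:
            mats, _ = fold_dense(seq, model, P)
            r = fold_sparse(seq, model, "standard", P, keep_state=True)
            n = len(seq)
            for i0 in range(1, n, max(1, n // 7)):
                WMr, WM2r = recompute_wm_row(r.state, i0)
                for j in range(i0, n + 1):
                    assert min(WMr[j], INF) == min(mats.WM[i0][j], INF), \
                        (seq, model, i0, j)
                    assert min(WM2r[j], INF) == min(mats.WM2[i0][j], INF), \
                        (seq, model, i0, j)


class TestSpaceContract:
    def test_peak_cells_linear_in_n(self, P):
        rng = random.Random(9)
        ratios = []
        for n in (30, 60, 90, 120):
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            r = fold_sparse(seq, "d1", "standard", P)
            ratios.append(r.stats.peak_array_cells / (n + 2))
        # rolling storage: a bounded number of length-(n+2) arrays
        assert all(rat <= P.big_m + 8 for rat in ratios)
        # the per-length constant does not grow with n
        assert max(ratios) - min(ratios) <= 2

    def test_stats_reported(self, P):
        r = fold_sparse("GGGAAAACCCC", "d1", "standard", P)
        d = r.stats.as_dict()
        assert d["candidates"] > 0
        assert d["trace_arrows_peak"] >= 0
        assert 0 <= d["z_fraction_of_quadratic"] < 1


class TestMaskedEnergy:
    def test_zero_mask_passes_energy(self):
        assert masked_energy(1, 1, -33) == -33

    def test_blocked_side_adds_infinity(self):
        assert masked_energy(0, 1, -33) >= INF - 33
        assert masked_energy(1, 0, -33) >= INF - 33
        assert masked_energy(0, 0, -33) >= INF - 33

    def test_equivalent_to_branching_logic(self):
        rng = random.Random(0)
        for _ in range(1000):
            e = rng.randint(-8000, 8000)
            for left in (0, 1):
                for right in (0, 1):
                    branching = e if (left and right) else INF + e
                    assert masked_energy(left, right, e) == branching


class TestDegenerate:
    def test_unpairable_sequence(self, P):
        for strategy in ("trace", "standard", "triplet"):
            r = fold_sparse("AAAA", "d2", strategy, P)
            assert r.mfe == 0.0
            assert r.structure.to_dotbracket() == "...."
            assert r.stats.Z == 0

    def test_single_base(self, P):
        r = fold_sparse("G", "d2", "standard", P)
        assert r.mfe == 0.0

    def test_inf_guard_headroom(self, P):
        # INF absorbs additions well past any finite loop energy
        assert INF + INF > 0
        assert INF - (1 << 21) == INF_LIMIT
        assert masked_energy(0, 0, 0) + masked_energy(0, 0, 0) < 4 * INF
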