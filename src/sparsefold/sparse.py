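"""Candidate-list sparsified MFE folding with O(n + Z + T) auxiliary space.

The forward pass processes rows i = n..1 (j ascending within a row) and
keeps only: per-row W / WM / WM2 arrays, the last M+2 rows of V (the
interior-loop window), the candidate lists, and the trace arrows.  No
quadratic table is ever allocated; peak cell counts are recorded in the
fold statistics.

A span [i, j] becomes a *candidate* when its closed (branch) contribution
beats every decomposition in at least one usage context — external loop or
multiloop.  Only candidates are enumerated at split points, which is what
removes the cubic-time inner minimizations; the interior-loop scan over a
bounded window is the one part sparsification cannot remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cases import D0, D1, D2, CONSUMED, branch_case, ml_closing_cases, \
    normalize_model
from .constraints import ConstraintSet
from .energy import (EnergyParams, INF, default_params, encode_sequence,
                     hairpin_energy, interior_energy, normalize_sequence,
                     _ptype)
from .sparse_traceback import (TraceArrowStore, encode, decode,
                               gc_trace_arrows, trace)
from .structure import SecondaryStructure

#: additions of INF sentinels stay above this guard; finite loop energies
#: stay far below it
INF_LIMIT = INF - (1 << 21)


def masked_energy(left_ok: int, right_ok: int, e: int, inf: int = INF) -> int:
    """Branch-free constraint guard for the interior-loop scan.

    ``left_ok``/``right_ok`` are 0/1 flags for the two unpaired regions of
    the loop.  Returns ``e`` when both flags are 1, otherwise at least
    ``inf``:  ``(flag - 1)`` is 0 or -1 (all bits set), so the OR of the two
    is 0 exactly when both regions are free, and AND-ing with ``inf`` turns
    the -1 mask into the infinity that is then added to ``e``.
    """
    return e + (((left_ok - 1) | (right_ok - 1)) & inf)


@dataclass
class FoldStats:
    """Sparsity and space accounting of one sparse fold."""

    n: int
    model: str
    strategy: str
    Z: int = 0
    T: int = 0                      # peak live trace arrows
    ed_trace_arrows: int = 0
    arrows_created: int = 0
    arrows_removed: int = 0
    arrows_live_end: int = 0
    per_column_candidates: list = field(default_factory=list)
    peak_array_cells: int = 0
    candidate_payload_ints: int = 0

    @property
    def z_fraction(self) -> float:
        """Z relative to the n(n-1)/2 cells of one triangular matrix."""
        denom = self.n * (self.n - 1) / 2
        return self.Z / denom if denom else 0.0

    def as_dict(self) -> dict:
        return {
            "n": self.n, "model": self.model, "strategy": self.strategy,
            "candidates": self.Z, "trace_arrows_peak": self.T,
            "ed_trace_arrows": self.ed_trace_arrows,
            "arrows_created": self.arrows_created,
            "arrows_removed": self.arrows_removed,
            "arrows_live_end": self.arrows_live_end,
            "peak_array_cells": self.peak_array_cells,
            "candidate_payload_ints": self.candidate_payload_ints,
            "z_fraction_of_quadratic": self.z_fraction,
        }


@dataclass
class FoldResult:
    mfe: float                     # kcal/mol
    structure: SecondaryStructure
    stats: FoldStats
    state: "SparseState" = None


@dataclass
class SparseState:
    """Everything the space-efficient traceback needs from the forward pass."""

    seq: str
    s: list
    n: int
    model: str
    strategy: str
    P: EnergyParams
    C: ConstraintSet | None
    cand: list
    cand_starts: list
    arrows: TraceArrowStore
    ed_arrows: dict
    W1: list
    mfe_int: int
    contrib_w: object
    contrib_wm: object
    stats: FoldStats


class SparseFolder:
    """Forward pass of the sparsified recursions (one instance per fold)."""

    def __init__(self, seq: str, model: str = D2, strategy: str = "standard",
                 P: EnergyParams | None = None,
                 C: ConstraintSet | None = None):
        self.seq = normalize_sequence(seq)
        self.model = normalize_model(model)
        strategy = str(strategy).lower()
        if strategy not in ("trace", "standard", "triplet"):
            raise ValueError(f"unknown strategy {strategy!r}")
        self.strategy = strategy
        self.P = P if P is not None else default_params()
        self.C = C
        self.s = encode_sequence(self.seq)
        self.n = len(self.seq)
        if C is not None and C.n != self.n:
            raise ValueError("constraint length does not match sequence")
        self.pref = C.paired_prefix() if C is not None else None
        self.cand = [[] for _ in range(self.n + 2)]
        self.cand_starts = [set() for _ in range(self.n + 2)]
        self.arrows = TraceArrowStore()
        self.ed_arrows = {}
        self.vband = {}
        self.wm2_prev = None    # WM2 row i+1
        self.wm2_prev2 = None   # WM2 row i+2
        self.stats = FoldStats(self.n, self.model, self.strategy)
        self.stats.per_column_candidates = [0] * (self.n + 1)
        self.stats.candidate_payload_ints = 1 if self.model != D1 else 3
        self._empty = [INF] * (self.n + 2)

    # -- candidate contributions -----------------------------------------

    def contrib_w(self, entry, j):
        """External-loop contribution of candidate entry in column j."""
        k, v = entry[0], entry[1]
        model = self.model
        if model == D1:
            f = entry[2]
            if self.strategy == "trace":
                return f
            d = f & 3
            val = (f - d) >> 2
            if self.strategy == "standard" or val >= INF_LIMIT:
                return val
            case = branch_case(self.s, self.n, self.P, self.C, model,
                               "ext", k, j, d)
            return INF if case is None else val + case[2]
        if v >= INF_LIMIT:
            return INF
        case = branch_case(self.s, self.n, self.P, self.C, model,
                           "ext", k, j, 0)
        return INF if case is None else v + case[2] + case[3]

    def contrib_wm(self, entry, j):
        """Multiloop contribution (incl. branch/unpaired penalties)."""
        k, v = entry[0], entry[1]
        model = self.model
        if model == D1:
            f = entry[3]
            if self.strategy == "trace":
                return f
            d = f & 3
            val = (f - d) >> 2
            if self.strategy == "standard" or val >= INF_LIMIT:
                return val
            case = branch_case(self.s, self.n, self.P, self.C, model,
                               "ml", k, j, d)
            return INF if case is None else val + case[2]
        if v >= INF_LIMIT:
            return INF
        case = branch_case(self.s, self.n, self.P, self.C, model,
                           "ml", k, j, 0)
        return INF if case is None else v + case[2] + case[3]

    # -- interior loop ----------------------------------------------------

    def il_candidate_min(self, i, j):
        """Best interior loop closed by i.j with a *candidate* inner pair.

        Uses the candidate's stored V value (never the dangled branch
        contribution) — the inner pair of an interior loop carries no
        dangles.  Returns (energy, inner pair or None).
        """
        s, P, M, m = self.s, self.P, self.P.big_m, self.P.m
        pref = self.pref
        best, bpq = INF, None
        pmax = min(i + M + 1, j - m - 2)
        for q in range(j - 1, max(i + m + 2, j - M - 1) - 1, -1):
            right_ok = 1
            if pref is not None:
                right_ok = 1 if pref[j - 1] - pref[q] == 0 else 0
            for entry in reversed(self.cand[q]):
                p = entry[0]
                if p > pmax:
                    break
                if p <= i or (p - i - 1) + (j - q - 1) > M:
                    continue
                v = entry[1]
                if v >= INF_LIMIT:
                    continue
                e = interior_energy(s, i, j, p, q, P)
                if pref is not None:
                    left_ok = 1 if pref[p - 1] - pref[i] == 0 else 0
                    e = masked_energy(left_ok, right_ok, e)
                tot = e + v
                if tot < best:
                    best, bpq = tot, (p, q)
        if best >= INF_LIMIT:
            return INF, None
        return best, bpq

    def il_noncandidate_scan(self, i, j):
        """Best interior loop with a non-candidate inner pair.

        V values come from the rolling (M+2)-row band; the winner (when it
        beats the candidate minimum) gets a trace arrow, since its trace
        cannot be recomputed from candidates later.  Returns
        (energy, inner pair or None, inner V).
        """
        s, P, M, m = self.s, self.P, self.P.big_m, self.P.m
        pref = self.pref
        cand_starts = self.cand_starts
        best, bp, bq, bv = INF, 0, 0, INF
        pmax = min(i + M + 1, j - m - 2)
        for p in range(i + 1, pmax + 1):
            row = self.vband.get(p)
            if row is None:
                break
            left_ok = 1
            if pref is not None:
                left_ok = 1 if pref[p - 1] - pref[i] == 0 else 0
            rem = M - (p - i - 1)
            qmin = max(p + m + 1, j - 1 - rem)
            starts = cand_starts
            for q in range(j - 1, qmin - 1, -1):
                v = row[q]
                if v >= INF_LIMIT or p in starts[q]:
                    continue
                e = interior_energy(s, i, j, p, q, P)
                if pref is not None:
                    right_ok = 1 if pref[j - 1] - pref[q] == 0 else 0
                    e = masked_energy(left_ok, right_ok, e)
                tot = e + v
                if tot < best:
                    best, bp, bq, bv = tot, p, q, v
        if best >= INF_LIMIT:
            return INF, None, INF
        return best, (bp, bq), bv

    # -- V ----------------------------------------------------------------

    def compute_V(self, i, j):
        """Closed-span energy V(i, j): hairpin, interior loop (candidate
        minimum plus non-candidate window scan), or multiloop closing.
        Registers a trace arrow when the optimum is an interior loop to a
        non-candidate inner pair."""
        s, P, C = self.s, self.P, self.C
        if j - i <= P.m or not _ptype(s[i], s[j]):
            return INF
        if C is not None and not C.pair_allowed(i, j):
            return INF
        hp = INF
        if C is None or C.region_unpaired_ok(i + 1, j - 1):
            hp = hairpin_energy(s, i, j, P)
        ilc, _ilc_pq = self.il_candidate_min(i, j)
        iln, iln_pq, iln_v = self.il_noncandidate_scan(i, j)
        ml = INF
        for wi, wj, add, _code in ml_closing_cases(s, self.n, P, C,
                                                   self.model, i, j):
            row = self.wm2_prev if wi == i + 1 else self.wm2_prev2
            if row is None:
                continue
            w2 = row[wj]
            if w2 < INF_LIMIT and w2 + add < ml:
                ml = w2 + add
        v = min(hp, ilc, iln, ml)
        if iln < hp and iln < ilc and iln < ml and iln < INF_LIMIT:
            self.arrows.add(i, j, iln_pq[0], iln_pq[1], iln_v)
        return v

    # -- branch contributions of the fresh cell ---------------------------

    def _fresh_branch(self, i, j, v_ij, v_row, context):
        """Best dangle case of span [i, j] at creation time.

        Returns (value, dangle code, dangle-table part).  V values of
        shifted pairs come from the current row and the V band.
        """
        best, bd, bdng = INF, 0, 0
        prev = self.vband.get(i + 1, self._empty)
        for d in range(4 if self.model == D1 else 1):
            case = branch_case(self.s, self.n, self.P, self.C, self.model,
                               context, i, j, d)
            if case is None:
                continue
            pi, pj, dng, rest, _ = case
            if pi == i:
                v = v_ij if pj == j else v_row[pj]
            else:
                v = prev[pj]
            if v >= INF_LIMIT:
                continue
            tot = v + dng + rest
            if tot < best:
                best, bd, bdng = tot, d, dng
        return best, bd, bdng

    # -- candidate promotion ----------------------------------------------

    def is_candidate(self, wb, wmb, wp, wmp) -> bool:
        """The sparsification criterion: the closed contribution strictly
        beats every decomposition in the external or the multiloop context."""
        return wb < wp or wmb < wmp

    def _promote(self, i, j, wb, d_w, dng_w, wmb, d_wm, dng_wm, v):
        cand_j = self.cand[j]
        if self.model != D1:
            cand_j.append((i, v))
        elif self.strategy == "trace":
            cand_j.append((i, v, wb, wmb))
            self.ed_arrows[(i, j)] = (d_w, d_wm)
        elif self.strategy == "standard":
            cand_j.append((i, v, encode(min(wb, INF), d_w),
                           encode(min(wmb, INF), d_wm)))
        else:  # triplet: store the un-dangled values
            uw = wb - dng_w if wb < INF_LIMIT else INF
            uwm = wmb - dng_wm if wmb < INF_LIMIT else INF
            cand_j.append((i, v, encode(uw, d_w), encode(uwm, d_wm)))
        self.cand_starts[j].add(i)
        self.stats.Z += 1
        self.stats.per_column_candidates[j] += 1
        if self.model == D1:
            # keep arrows at dangle-shifted achiever cells alive
            for d, val in ((d_w, wb), (d_wm, wmb)):
                if d and val < INF_LIMIT:
                    self.arrows.incref((i + (d & 1), j - (d >> 1)))

    # -- main loop ---------------------------------------------------------

    def run(self) -> SparseState:
        n, P, C = self.n, self.P, self.C
        m, c = P.m, P.ml_base
        M = P.big_m
        unp = (lambda k: True) if C is None else C.position_unpaired_ok
        reg = (lambda a, b: True) if C is None else C.region_unpaired_ok
        W_row = None
        for i in range(n, 0, -1):
            V_row = [INF] * (n + 2)
            W_row = [0] * (n + 2)
            WM_row = [INF] * (n + 2)
            WM2_row = [INF] * (n + 2)
            cand, contrib_w, contrib_wm = self.cand, self.contrib_w, self.contrib_wm
            for j in range(i, n + 1):
                v = self.compute_V(i, j)
                V_row[j] = v
                wb, d_w, dng_w = self._fresh_branch(i, j, v, V_row, "ext")
                wmb, d_wm, dng_wm = self._fresh_branch(i, j, v, V_row, "ml")
                # sparse W^p
                wp = INF
                if unp(j):
                    wp = W_row[j - 1]
                for entry in cand[j]:
                    cw = contrib_w(entry, j)
                    if cw >= INF_LIMIT:
                        continue
                    t = W_row[entry[0] - 1] + cw
                    if t < wp:
                        wp = t
                W_row[j] = wb if wb < wp else wp
                # sparse WM2 and WM^p
                wm2 = INF
                if unp(j) and WM2_row[j - 1] < INF_LIMIT:
                    wm2 = WM2_row[j - 1] + c
                wmp = INF
                if unp(j) and WM_row[j - 1] < INF_LIMIT:
                    wmp = WM_row[j - 1] + c
                for entry in cand[j]:
                    k = entry[0]
                    cwm = contrib_wm(entry, j)
                    if cwm >= INF_LIMIT:
                        continue
                    left = WM_row[k - 1]
                    if left < INF_LIMIT:
                        t = left + cwm
                        if t < wm2:
                            wm2 = t
                    if reg(i, k - 1):
                        t = c * (k - i) + cwm
                        if t < wmp:
                            wmp = t
                WM2_row[j] = wm2
                if wm2 < wmp:
                    wmp = wm2
                WM_row[j] = wmb if wmb < wmp else wmp
                if self.is_candidate(wb, wmb, wp, wmp):
                    self._promote(i, j, wb, d_w, dng_w, wmb, d_wm, dng_wm, v)
            # roll the windows
            self.vband[i] = V_row
            self.vband.pop(i + M + 2, None)
            self.wm2_prev2 = self.wm2_prev
            self.wm2_prev = WM2_row
            if i + M + 1 <= n:
                gc_trace_arrows(self.arrows, i + M + 1, self._is_cand_cell)
            cells = (len(self.vband) + 5) * (n + 2)
            if cells > self.stats.peak_array_cells:
                self.stats.peak_array_cells = cells
        st = self.stats
        st.T = self.arrows.peak
        st.ed_trace_arrows = len(self.ed_arrows)
        st.arrows_created = self.arrows.created
        st.arrows_removed = self.arrows.removed
        st.arrows_live_end = len(self.arrows)
        return SparseState(self.seq, self.s, n, self.model, self.strategy,
                           P, C, self.cand, self.cand_starts, self.arrows,
                           self.ed_arrows, W_row, W_row[n],
                           self.contrib_w, self.contrib_wm, st)

    def _is_cand_cell(self, key):
        return key[0] in self.cand_starts[key[1]]


def fold_sparse(seq: str, model: str = D2, strategy: str = "standard",
                P: EnergyParams | None = None,
                C: ConstraintSet | None = None,
                keep_state: bool = False) -> FoldResult:
    """Sparsified MFE fold: energy, traced structure, sparsity statistics.

    The MFE equals the dense reference exactly for every dangle model and
    strategy; the structure re-evaluates to the MFE under the
    loop-decomposition evaluator.
    """
    folder = SparseFolder(seq, model, strategy, P, C)
    state = folder.run()
    if state.mfe_int >= INF_LIMIT:
        raise ValueError("hard constraints admit no structure")
    structure = trace(state)
    result = FoldResult(state.mfe_int / 100.0, structure, state.stats,
                        state if keep_state else None)
    return result
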