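"""Dense Zuker-style reference implementation.

O(n^3) time, O(n^2) space energy minimization with all matrices
materialized, used as the internal correctness oracle for the sparse
engine.  Supports all three dangle models and hard constraints, and
provides a conventional deterministic traceback.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cases import D0, D1, D2, branch_cases, ml_closing_cases, normalize_model
from .constraints import ConstraintSet
from .energy import (EnergyParams, INF, default_params, encode_sequence,
                     hairpin_energy, interior_energy, normalize_sequence,
                     _ptype)
from .structure import SecondaryStructure


@dataclass
class DenseMatrices:
    """Full DP tables, 1-based; index [i][j].

    ``Vd``/``VdM`` are the external-loop / multiloop branch contributions of
    span [i, j] (V of the possibly shifted pair plus dangle and terminal
    terms; VdM also carries the branch penalty and unpaired charges), so
    that W = min(Wp, Vd) and WM = min(WMp, VdM) hold cell-wise.
    """

    n: int
    model: str
    W: list
    Wp: list
    V: list
    Vd: list
    VdM: list
    WM: list
    WMp: list
    WM2: list

    def dump(self, name: str) -> str:
        """Tab-separated text dump of one matrix (debugging aid, small n)."""
        mat = getattr(self, name)
        rows = []
        for i in range(1, self.n + 1):
            rows.append("\t".join(
                "INF" if mat[i][j] >= INF else str(mat[i][j])
                for j in range(1, self.n + 1)))
        return "\n".join(rows)


def _mk(n):
    return [[INF] * (n + 2) for _ in range(n + 2)]


def fold_dense(seq: str, model: str = D2, P: EnergyParams | None = None,
               C: ConstraintSet | None = None):
    """Fill all matrices bottom-up; returns (DenseMatrices, mfe in kcal/mol).

    mfe = W(1, n).  Under d0 the branch contribution reduces to V plus the
    terminal non-GC penalty; under d2 it always carries the both-sides
    dangle term; under d1 it is the four-case minimum over shifted pairs.
    """
    model = normalize_model(model)
    seq = normalize_sequence(seq)
    if P is None:
        P = default_params()
    s = encode_sequence(seq)
    n = len(seq)
    if C is not None and C.n != n:
        raise ValueError("constraint length does not match sequence")

    m, M, c = P.m, P.big_m, P.ml_base
    W, Wp = _mk(n), _mk(n)
    V, Vd, VdM = _mk(n), _mk(n), _mk(n)
    WM, WMp, WM2 = _mk(n), _mk(n), _mk(n)

    def unp(k):
        return C is None or C.position_unpaired_ok(k)

    def reg(a, b):
        return C is None or C.region_unpaired_ok(a, b)

    for i in range(n, 0, -1):
        for j in range(i, n + 1):
            # --- V ---------------------------------------------------
            if j - i > m and _ptype(s[i], s[j]) and (
                    C is None or C.pair_allowed(i, j)):
                best = hairpin_energy(s, i, j, P) if reg(i + 1, j - 1) else INF
                pmax = min(i + M + 1, j - 1)
                for p in range(i + 1, pmax + 1):
                    if not reg(i + 1, p - 1):
                        break
                    rem = M - (p - i - 1)
                    qmin = max(p + m + 1, j - 1 - rem)
                    Vp = V[p]
                    for q in range(j - 1, qmin - 1, -1):
                        v = Vp[q]
                        if v >= INF or not reg(q + 1, j - 1):
                            continue
                        e = interior_energy(s, i, j, p, q, P) + v
                        if e < best:
                            best = e
                for wi, wj, add, _code in ml_closing_cases(s, n, P, C, model, i, j):
                    w2 = WM2[wi][wj]
                    if w2 >= INF:
                        continue
                    e = w2 + add
                    if e < best:
                        best = e
                V[i][j] = best
            # --- branch contributions -------------------------------
            vd = vdm = INF
            for pi, pj, dng, rest, _d in branch_cases(s, n, P, C, model, "ext", i, j):
                v = V[pi][pj]
                if v >= INF:
                    continue
                e = v + dng + rest
                if e < vd:
                    vd = e
            for pi, pj, dng, rest, _d in branch_cases(s, n, P, C, model, "ml", i, j):
                v = V[pi][pj]
                if v >= INF:
                    continue
                e = v + dng + rest
                if e < vdm:
                    vdm = e
            Vd[i][j] = vd
            VdM[i][j] = vdm
            # --- multiloop chain ------------------------------------
            # a zero-unpaired two-branch multiloop chain is legal at span
            # exactly 2m+3, so WM2 is computed from that span on
            if j - i >= 2 * m + 3:
                best = INF
                WMi = WM[i]
                for k in range(i + 1, j):
                    left = WMi[k - 1]
                    right = WM[k][j]
                    if left >= INF or right >= INF:
                        continue
                    e = left + right
                    if e < best:
                        best = e
                WM2[i][j] = best
            if j - i > m:
                e = WM2[i][j]
                if unp(i) and WM[i + 1][j] + c < e:
                    e = WM[i + 1][j] + c
                if unp(j) and WM[i][j - 1] + c < e:
                    e = WM[i][j - 1] + c
                WMp[i][j] = min(e, INF)
                WM[i][j] = min(WMp[i][j], VdM[i][j])
            # --- external chain -------------------------------------
            e = INF
            if unp(j):
                e = W[i][j - 1] if j - 1 >= i else 0
            Wi = W[i]
            for k in range(i + 1, j):
                left = Wi[k - 1] if k - 1 >= i else 0
                if left >= INF:
                    continue
                ek = left + W[k][j]
                if ek < e:
                    e = ek
            Wp[i][j] = min(e, INF)
            W[i][j] = min(Wp[i][j], Vd[i][j])

    mats = DenseMatrices(n, model, W, Wp, V, Vd, VdM, WM, WMp, WM2)
    return mats, W[1][n] / 100.0


class TracebackError(RuntimeError):
    pass


def traceback_dense(seq: str, mats: DenseMatrices, model: str | None = None,
                    P: EnergyParams | None = None,
                    C: ConstraintSet | None = None) -> SecondaryStructure:
    """Deterministic traceback over filled dense matrices.

    Cases are examined in the textual order of the recursions (decomposed
    cases before closed spans; interior loops by increasing p then
    decreasing q from j-1; split points in increasing k; d1 dangle cases in
    printed order), taking the first achiever.
    """
    model = normalize_model(model or mats.model)
    seq = normalize_sequence(seq)
    if P is None:
        P = default_params()
    s = encode_sequence(seq)
    n = mats.n
    m, M, c = P.m, P.big_m, P.ml_base
    W, Wp, V, Vd, VdM = mats.W, mats.Wp, mats.V, mats.Vd, mats.VdM
    WM, WMp, WM2 = mats.WM, mats.WMp, mats.WM2
    if W[1][n] >= INF:
        raise TracebackError("no admissible structure (constraints unsatisfiable)")

    def unp(k):
        return C is None or C.position_unpaired_ok(k)

    def reg(a, b):
        return C is None or C.region_unpaired_ok(a, b)

    pairs = []
    tasks = [("W", 1, n)]

    def fail(kind, i, j):
        raise TracebackError(
            f"no recursion case reproduces {kind}({i},{j})")

    def trace_branch(i, j, target, context):
        """Find the branch case of [i, j] matching the contribution."""
        for pi, pj, dng, rest, _d in branch_cases(s, n, P, C, model, context, i, j):
            if V[pi][pj] + dng + rest == target:
                pairs.append((pi, pj))
                tasks.append(("V", pi, pj))
                return True
        return False

    while tasks:
        kind, i, j = tasks.pop()
        if kind == "W":
            while j >= i:
                w = W[i][j]
                if w == 0 and Vd[i][j] > 0 and reg(i, j):
                    j = i - 1
                    break
                prev = W[i][j - 1] if j - 1 >= i else 0
                if unp(j) and w == prev:
                    j -= 1
                    continue
                done = False
                for k in range(i + 1, j):
                    left = W[i][k - 1] if k - 1 >= i else 0
                    if left + W[k][j] == w:
                        tasks.append(("W", i, k - 1))
                        tasks.append(("W", k, j))
                        done = True
                        break
                if done:
                    break
                if trace_branch(i, j, w, "ext"):
                    break
                fail("W", i, j)
            continue
        if kind == "V":
            v = V[i][j]
            if reg(i + 1, j - 1) and hairpin_energy(s, i, j, P) == v:
                continue
            found = False
            pmax = min(i + M + 1, j - 1)
            for p in range(i + 1, pmax + 1):
                if not reg(i + 1, p - 1):
                    break
                rem = M - (p - i - 1)
                qmin = max(p + m + 1, j - 1 - rem)
                for q in range(j - 1, qmin - 1, -1):
                    if V[p][q] >= INF or not reg(q + 1, j - 1):
                        continue
                    if interior_energy(s, i, j, p, q, P) + V[p][q] == v:
                        pairs.append((p, q))
                        tasks.append(("V", p, q))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for wi, wj, add, _code in ml_closing_cases(s, n, P, C, model, i, j):
                if WM2[wi][wj] + add == v:
                    tasks.append(("WM2", wi, wj))
                    found = True
                    break
            if not found:
                fail("V", i, j)
            continue
        if kind == "WM2":
            w2 = WM2[i][j]
            found = False
            for k in range(i + 1, j):
                if WM[i][k - 1] + WM[k][j] == w2:
                    tasks.append(("WM", i, k - 1))
                    tasks.append(("WM", k, j))
                    found = True
                    break
            if not found:
                fail("WM2", i, j)
            continue
        if kind == "WM":
            w = WM[i][j]
            if unp(i) and WM[i + 1][j] + c == w:
                tasks.append(("WM", i + 1, j))
                continue
            if unp(j) and WM[i][j - 1] + c == w:
                tasks.append(("WM", i, j - 1))
                continue
            if WM2[i][j] == w:
                tasks.append(("WM2", i, j))
                continue
            if trace_branch(i, j, w, "ml"):
                continue
            fail("WM", i, j)

    return SecondaryStructure.from_pairs(n, pairs)
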