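"""Space-efficient traceback for the sparse engine.

Reconstructs the MFE structure from candidate lists and trace arrows alone
(no dense matrices): multiloop chains are recomputed per row from the
candidate lists, interior loops follow stored trace arrows or a candidate
scan, and the dangle direction of each candidate branch is recovered by one
of three strategies:

* ``trace``    — a dedicated ed-trace-arrow per candidate holds the dangle
  codes for both usage contexts;
* ``standard`` — the candidate's W/WM contribution fields carry the dangle
  type in their low two bits (bit codec below);
* ``triplet``  — the contribution fields store the *un-dangled* value (the
  dangle-table energy subtracted) plus the type bits; the dangle energy is
  re-added from the context-appropriate table at every use.

Also home to the 2-bit energy/dangle codec and the reference-counted,
garbage-collected trace-arrow store.
"""

from __future__ import annotations

from .cases import D1, branch_case, branch_cases, ml_closing_cases
from .energy import INF, hairpin_energy, interior_energy
from .structure import SecondaryStructure

STRATEGIES = ("trace", "standard", "triplet")

ENCODE_LIMIT = 1 << 60  # |V| bound for the codec (far above any RNA energy)


def encode(v: int, dangle: int) -> int:
    """Pack an energy and a 2-bit dangle code into one integer.

    ``enc = 4*v + dangle`` in two's-complement arithmetic (equivalently
    ``(v << 2) | dangle`` for the stored bit pattern); the sign of ``v`` is
    preserved.  Codes: 0 none, 1 = 5', 2 = 3', 3 = both sides.
    """
    if not 0 <= dangle <= 3:
        raise ValueError(f"dangle code {dangle} out of range")
    if abs(v) >= ENCODE_LIMIT:
        raise OverflowError(f"energy {v} outside the representable range")
    return (v << 2) | dangle if v >= 0 else 4 * v + dangle


def decode(enc: int) -> tuple[int, int]:
    """Inverse of :func:`encode`: non-negative remainder mod 4 is the dangle
    code, the arithmetic right shift by two bits restores the energy."""
    dangle = enc & 3  # == enc mod 4, non-negative
    return (enc - dangle) >> 2, dangle


class TracebackError(RuntimeError):
    pass


class TraceArrowStore:
    """Reference-counted arrows from a loop-closing pair to its optimal
    non-candidate inner pair, with per-row garbage collection.

    An arrow is removable once its source row has left the interior-loop
    window of all unprocessed cells, provided nothing references it: a
    removed arrow can never lie on any optimal trace path.
    """

    def __init__(self):
        self._arrows = {}   # (i, j) -> [p, q, v_target, refcount]
        self._by_row = {}   # i -> list of (i, j)
        self.created = 0
        self.removed = 0
        self.peak = 0

    def __len__(self):
        return len(self._arrows)

    def __contains__(self, key):
        return key in self._arrows

    def get(self, key):
        return self._arrows.get(key)

    def add(self, i, j, p, q, v_target):
        self._arrows[(i, j)] = [p, q, v_target, 0]
        self._by_row.setdefault(i, []).append((i, j))
        self.created += 1
        tgt = self._arrows.get((p, q))
        if tgt is not None:
            tgt[3] += 1
        if len(self._arrows) > self.peak:
            self.peak = len(self._arrows)

    def incref(self, key):
        a = self._arrows.get(key)
        if a is not None:
            a[3] += 1

    def gc_row(self, row: int, is_candidate) -> int:
        """Remove unreferenced arrows whose source lies in ``row``.

        Called once the row can no longer be targeted by future cells.
        Removing an arrow releases its reference on the target's arrow,
        which may cascade into older rows (already past their GC point).
        """
        removed = 0
        for key in self._by_row.pop(row, []):
            a = self._arrows.get(key)
            if a is not None and a[3] == 0 and not is_candidate(key):
                removed += self._remove(key, is_candidate)
        return removed

    def _remove(self, key, is_candidate) -> int:
        p, q, _v, _rc = self._arrows.pop(key)
        self.removed += 1
        removed = 1
        tgt = self._arrows.get((p, q))
        if tgt is not None:
            tgt[3] -= 1
            if tgt[3] == 0 and not is_candidate((p, q)):
                removed += self._remove((p, q), is_candidate)
        return removed


def gc_trace_arrows(store: TraceArrowStore, finished_row: int,
                    is_candidate) -> int:
    """Garbage-collect arrows sourced in a row that just left the active
    interior-loop window; returns the number removed."""
    return store.gc_row(finished_row, is_candidate)


# ---------------------------------------------------------------------------
# candidate-only recomputation of multiloop chains
# ---------------------------------------------------------------------------

def recompute_wm_row(state, i0: int):
    """Rebuild the sparsified WM(i0, ·) and WM²(i0, ·) rows from the
    candidate lists alone (no dense matrices).

    The split cases only ever reference candidate contributions; the closed
    case of a *non*-candidate span never beats its decompositions, so the
    recomputed rows equal the forward-pass (and dense) values cell-wise.
    """
    s, n, P, C = state.s, state.n, state.P, state.C
    m, c = P.m, P.ml_base
    cand, cand_starts = state.cand, state.cand_starts
    contrib_wm = state.contrib_wm
    unp = (lambda k: True) if C is None else C.position_unpaired_ok
    reg = (lambda a, b: True) if C is None else C.region_unpaired_ok
    WMr = [INF] * (n + 2)
    WM2r = [INF] * (n + 2)
    for j in range(i0 + m + 1, n + 1):
        w2 = WM2r[j - 1] + c if unp(j) and WM2r[j - 1] < INF else INF
        wmp = WMr[j - 1] + c if unp(j) and WMr[j - 1] < INF else INF
        for entry in cand[j]:
            k = entry[0]
            if k <= i0:
                continue
            cwm = contrib_wm(entry, j)
            if cwm >= INF:
                continue
            if k - 1 >= i0 + m + 1 and WMr[k - 1] < INF:
                t = WMr[k - 1] + cwm
                if t < w2:
                    w2 = t
            if reg(i0, k - 1):
                t = c * (k - i0) + cwm
                if t < wmp:
                    wmp = t
        WM2r[j] = w2
        if w2 < wmp:
            wmp = w2
        closed = INF
        if i0 in cand_starts[j]:
            entry = next(e for e in cand[j] if e[0] == i0)
            closed = contrib_wm(entry, j)
        WMr[j] = min(wmp, closed)
    return WMr, WM2r


# ---------------------------------------------------------------------------
# traceback proper
# ---------------------------------------------------------------------------

def trace(state) -> SecondaryStructure:
    """Reconstruct the MFE structure from a completed sparse fold state.

    The dangle direction at each candidate is recovered per the state's
    strategy; multiloop fragment rows (WM/WM2) are recomputed on demand
    purely from candidate lists; interior-loop targets come from trace
    arrows (non-candidates) or a candidate window scan.
    """
    s, n, P, C = state.s, state.n, state.P, state.C
    model, strategy = state.model, state.strategy
    m, M, c = P.m, P.big_m, P.ml_base
    cand, cand_starts = state.cand, state.cand_starts
    arrows, ed_arrows = state.arrows, state.ed_arrows
    W1 = state.W1
    contrib_w, contrib_wm = state.contrib_w, state.contrib_wm

    if W1[n] >= INF:
        raise TracebackError("no admissible structure (constraints unsatisfiable)")

    def unp(k):
        return C is None or C.position_unpaired_ok(k)

    def reg(a, b):
        return C is None or C.region_unpaired_ok(a, b)

    def fail(kind, i, j):
        raise TracebackError(f"no recursion case reproduces {kind}({i},{j})")

    def branch_dangle(k, j, context):
        """Dangle code of candidate [k, j]'s contribution in a context."""
        if model != D1:
            return 0
        if strategy == "trace":
            dw, dwm = ed_arrows[(k, j)]
            return dw if context == "ext" else dwm
        entry = next(e for e in cand[j] if e[0] == k)
        field = entry[2] if context == "ext" else entry[3]
        return field & 3

    pairs = []
    tasks = [("W", n, 0)]
    wm_cache = {}

    def wm_rows(i0):
        if i0 not in wm_cache:
            wm_cache[i0] = recompute_wm_row(state, i0)
        return wm_cache[i0]

    def take_branch(k, j, target, context):
        """Resolve the dangle case of candidate [k, j] and queue its pair."""
        d = branch_dangle(k, j, context)
        case = branch_case(s, n, P, C, model, context, k, j, d)
        if case is None:
            fail("branch", k, j)
        pi, pj, dangle, rest, _ = case
        v_inner = target - dangle - rest
        pairs.append((pi, pj))
        tasks.append(("V", pi, pj, v_inner))

    while tasks:
        kind, a, b2, val = _pop(tasks)
        if kind == "W":
            j = a
            while j >= 1:
                w = W1[j]
                if w >= INF:
                    fail("W", 1, j)
                if unp(j) and w == W1[j - 1]:
                    j -= 1
                    continue
                done = False
                for entry in cand[j]:
                    k = entry[0]
                    cw = contrib_w(entry, j)
                    if cw < INF and W1[k - 1] + cw == w:
                        take_branch(k, j, cw, "ext")
                        j = k - 1
                        done = True
                        break
                if not done:
                    fail("W", 1, j)
            continue
        if kind == "V":
            i, j, v = a, b2, val
            arrow = arrows.get((i, j))
            if arrow is not None:
                p, q, vt, _rc = arrow
                if interior_energy(s, i, j, p, q, P) + vt == v:
                    pairs.append((p, q))
                    tasks.append(("V", p, q, vt))
                    continue
            if reg(i + 1, j - 1) and hairpin_energy(s, i, j, P) == v:
                continue
            found = False
            pmax = min(i + M + 1, j - 1)
            for q in range(j - 1, max(i + m + 2, j - M - 1) - 1, -1):
                if not reg(q + 1, j - 1):
                    break
                for entry in reversed(cand[q]):
                    p = entry[0]
                    if p > pmax:
                        break
                    if p <= i or (p - i - 1) + (j - q - 1) > M:
                        continue
                    vp = entry[1]
                    if vp >= INF or not reg(i + 1, p - 1):
                        continue
                    if interior_energy(s, i, j, p, q, P) + vp == v:
                        pairs.append((p, q))
                        tasks.append(("V", p, q, vp))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for wi, wj, add, _code in ml_closing_cases(s, n, P, C, model, i, j):
                _WMr, WM2r = wm_rows(wi)
                if WM2r[wj] + add == v:
                    tasks.append(("WM2", wi, wj))
                    found = True
                    break
            if not found:
                fail("V", i, j)
            continue
        if kind == "WM2":
            i0, j = a, b2
            WMr, WM2r = wm_rows(i0)
            while True:
                w2 = WM2r[j]
                if w2 >= INF:
                    fail("WM2", i0, j)
                if unp(j) and WM2r[j - 1] < INF and w2 == WM2r[j - 1] + c:
                    j -= 1
                    continue
                done = False
                for entry in cand[j]:
                    k = entry[0]
                    if k <= i0 or k - 1 < i0 + m + 1:
                        continue
                    cwm = contrib_wm(entry, j)
                    if cwm < INF and WMr[k - 1] < INF and WMr[k - 1] + cwm == w2:
                        take_branch(k, j, cwm, "ml")
                        tasks.append(("WM", i0, k - 1))
                        done = True
                        break
                if done:
                    break
                fail("WM2", i0, j)
            continue
        if kind == "WM":
            i0, j = a, b2
            WMr, WM2r = wm_rows(i0)
            while True:
                w = WMr[j]
                if w >= INF:
                    fail("WM", i0, j)
                if unp(j) and WMr[j - 1] < INF and w == WMr[j - 1] + c:
                    j -= 1
                    continue
                if WM2r[j] == w:
                    tasks.append(("WM2", i0, j))
                    break
                done = False
                for entry in cand[j]:
                    k = entry[0]
                    if k <= i0:
                        continue
                    cwm = contrib_wm(entry, j)
                    if cwm >= INF:
                        continue
                    if reg(i0, k - 1) and c * (k - i0) + cwm == w:
                        take_branch(k, j, cwm, "ml")
                        done = True
                        break
                if not done and i0 in cand_starts[j]:
                    entry = next(e for e in cand[j] if e[0] == i0)
                    cwm = contrib_wm(entry, j)
                    if cwm == w:
                        take_branch(i0, j, cwm, "ml")
                        done = True
                if done:
                    break
                fail("WM", i0, j)
            continue

    return SecondaryStructure.from_pairs(n, pairs)


def _pop(tasks):
    item = tasks.pop()
    if len(item) == 3:
        return item[0], item[1], item[2], None
    return item
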