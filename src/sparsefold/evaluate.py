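"""Loop-decomposition energy of a given secondary structure.

The free energy of a structure is the sum of its loop energies: hairpins,
two-loops (stack/bulge/interior), multiloops (a + b per branch incl. the
closing helix + c per unpaired base) and the external loop, with terminal
non-GC penalties at every helix end and dangle contributions per the
selected model.  Under the exclusive-dangle model every loop's dangling
ends are assigned optimally subject to exclusivity (no base serves two stem
ends), via a small chain/cycle DP over the loop's stem ends — this is the
per-structure counterpart of the recursion-level four-case minimum, so a
structure traced from the DP re-evaluates to the reported MFE exactly.
"""

from __future__ import annotations

import math

from .cases import D0, D1, D2, normalize_model
from .energy import (EnergyParams, INF, _ext_mismatch, _ptype,
                     default_params, encode_sequence, hairpin_energy,
                     interior_energy, normalize_sequence)
from .structure import SecondaryStructure


def _children(pt, i, j):
    """Pairs directly enclosed by (i, j); use i=0, j=n+1 for the top level."""
    out = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            out.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return out


def _assign_min(elems, cyclic):
    """Minimum total dangle energy over exclusive assignments.

    ``elems``: per stem end ``(lbase, rbase, opts)`` in loop order, each
    option ``(uses_left, uses_right, energy)``.  Adjacent stem ends conflict
    when they would consume the same unpaired base; for a multiloop the
    chain closes into a cycle through the closing helix.
    """
    if not elems:
        return 0
    best = math.inf
    for fl_use, fr_use, fe in elems[0][2]:
        cur = {fr_use: fe}
        for t in range(1, len(elems)):
            lb, rb, opts = elems[t]
            prev_rb = elems[t - 1][1]
            nxt = {}
            for prev_used_r, acc in cur.items():
                for ul, ur, e in opts:
                    if ul and prev_used_r and prev_rb == lb:
                        continue
                    val = acc + e
                    if val < nxt.get(ur, math.inf):
                        nxt[ur] = val
            cur = nxt
        for prev_used_r, acc in cur.items():
            if cyclic and prev_used_r and fl_use and elems[-1][1] == elems[0][0]:
                continue
            if acc < best:
                best = acc
    return 0 if best is math.inf else best


def _branch_elem(s, n, P, pt, p, q, table):
    """Stem-end dangle options for branch (p, q) in an enclosing loop."""
    tp = _ptype(s[p], s[q])
    lb, rb = p - 1, q + 1
    opts = [(False, False, 0)]
    l_free = 1 <= lb and pt[lb] == 0
    r_free = rb <= n and pt[rb] == 0
    if l_free:
        opts.append((True, False, P.dangle5[tp][s[lb]]))
    if r_free:
        opts.append((False, True, P.dangle3[tp][s[rb]]))
    if l_free and r_free:
        opts.append((True, True, table[tp][s[lb]][s[rb]]))
    return (lb, rb, opts)


def _closing_elem(s, P, pt, i, j):
    """Inner-facing dangle options of a multiloop-closing pair."""
    rt = _ptype(s[j], s[i])
    lb, rb = j - 1, i + 1  # 5'- and 3'-adjacent seen from inside the loop
    opts = [(False, False, 0)]
    l_free = pt[lb] == 0
    r_free = pt[rb] == 0
    if l_free:
        opts.append((True, False, P.dangle5[rt][s[lb]]))
    if r_free:
        opts.append((False, True, P.dangle3[rt][s[rb]]))
    if l_free and r_free and lb != rb:
        opts.append((True, True, P.mismatch_multi[rt][s[lb]][s[rb]]))
    return (lb, rb, opts)


def evaluate_structure_int(seq: str, R: SecondaryStructure, model: str = D2,
                           P: EnergyParams | None = None) -> int:
    """Integer (0.01 kcal/mol) loop-decomposition energy; INF-scale values
    mark structures the model forbids (too-short hairpins, non-complementary
    pairs, oversized interior loops)."""
    model = normalize_model(model)
    seq = normalize_sequence(seq)
    if P is None:
        P = default_params()
    s = encode_sequence(seq)
    n = len(seq)
    if R.n != n:
        raise ValueError("structure length does not match sequence")
    if R.is_crossing():
        raise ValueError("structure contains crossing pairs (pseudoknot)")
    pt = R.partner_array()
    total = 0

    # external loop
    top = _children(pt, 0, n + 1)
    for p, q in top:
        tp = _ptype(s[p], s[q])
        if tp == 0:
            return INF
        total += P.au_penalty(tp)
    if model == D2:
        for p, q in top:
            total += _ext_mismatch(s, n, P, _ptype(s[p], s[q]), p, q)
    elif model == D1:
        elems = [_branch_elem(s, n, P, pt, p, q, P.mismatch_exterior)
                 for p, q in top]
        total += _assign_min(elems, cyclic=False)

    for i, j in sorted(R.pairs):
        kids = _children(pt, i, j)
        if not kids:
            e = hairpin_energy(s, i, j, P)
            if e >= INF:
                return INF
            total += e
        elif len(kids) == 1:
            (p, q), = kids
            e = interior_energy(s, i, j, p, q, P)
            if e >= INF:
                return INF
            total += e
        else:
            tp = _ptype(s[i], s[j])
            rt = _ptype(s[j], s[i])
            if tp == 0:
                return INF
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += P.ml_closing + P.ml_intern + P.au_penalty(tp)
            total += P.ml_base * unpaired
            for p, q in kids:
                ktp = _ptype(s[p], s[q])
                if ktp == 0:
                    return INF
                total += P.ml_intern + P.au_penalty(ktp)
            if model == D2:
                total += P.mismatch_multi[rt][s[j - 1]][s[i + 1]]
                for p, q in kids:
                    total += P.mismatch_multi[_ptype(s[p], s[q])][s[p - 1]][s[q + 1]]
            elif model == D1:
                elems = [_closing_elem(s, P, pt, i, j)]
                elems += [_branch_elem(s, n, P, pt, p, q, P.mismatch_multi)
                          for p, q in kids]
                total += _assign_min(elems, cyclic=True)
    return total


def evaluate_structure(seq: str, R: SecondaryStructure | str,
                       model: str = D2,
                       P: EnergyParams | None = None) -> float:
    """Loop-decomposition energy in kcal/mol (math.inf if forbidden)."""
    if isinstance(R, str):
        R = SecondaryStructure.from_dotbracket(R)
    e = evaluate_structure_int(seq, R, model, P)
    return math.inf if e >= INF else e / 100.0
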