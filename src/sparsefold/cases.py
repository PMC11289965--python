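"""Dangle-model case generators shared by the dense and sparse engines.

A *branch* is a closed span [i, j] used inside an external loop or a
multiloop.  Depending on the dangle model its energy contribution is built
from the span's V value plus dangle, terminal-penalty, and multiloop
(branch/unpaired) terms; under the exclusive-dangle model the actual pair
may be shifted inward (i+1 and/or j-1) with the freed base dangling on it.

Each case is described by ``(pi, pj, dangle_part, rest, code)`` where
(pi, pj) is the pair whose V value enters the sum, ``dangle_part`` holds
only the dangling-end table energies, ``rest`` the remaining additive terms
(terminal non-GC penalty, and for multiloop context the branch penalty b
plus c per dangle-consumed base), and ``code`` the 2-bit dangle type
(0 none, 1 = 5', 2 = 3', 3 = both).  The total contribution of a case is
``V(pi, pj) + dangle_part + rest``.
"""

from __future__ import annotations

from .energy import EnergyParams, INF, _ext_mismatch, _ptype

D0, D1, D2 = "d0", "d1", "d2"
DANGLE_MODELS = (D0, D1, D2)

#: number of bases a d1 dangle case consumes at each end (by 2-bit code)
CONSUMED = (0, 1, 1, 2)


def normalize_model(model) -> str:
    m = str(getattr(model, "value", model)).lower()
    if m not in DANGLE_MODELS:
        raise ValueError(f"unknown dangle model {model!r}")
    return m


def branch_case(s, n, P: EnergyParams, C, model: str, context: str,
                i: int, j: int, d: int):
    """One dangle case of branch [i, j]; None when inapplicable.

    ``context`` is ``"ext"`` or ``"ml"``.  Under d0/d2 only code 0 exists.
    Dangle-consumed bases must not be forced to pair.
    """
    ml = context == "ml"
    if model == D1:
        pi, pj = i + (d & 1), j - (d >> 1)
        if pj - pi <= P.m:
            return None
        tp = _ptype(s[pi], s[pj])
        if tp == 0:
            return None
        if C is not None:
            if d & 1 and not C.position_unpaired_ok(i):
                return None
            if d >> 1 and not C.position_unpaired_ok(j):
                return None
        if d == 3:
            mm = P.mismatch_multi if ml else P.mismatch_exterior
            dangle = mm[tp][s[i]][s[j]]
        elif d == 1:
            dangle = P.dangle5[tp][s[i]]
        elif d == 2:
            dangle = P.dangle3[tp][s[j]]
        else:
            dangle = 0
        rest = P.au_penalty(tp)
        if ml:
            rest += P.ml_intern + P.ml_base * CONSUMED[d]
        return (pi, pj, dangle, rest, d)
    # d0 / d2: the pair is i.j itself
    if d != 0:
        return None
    tp = _ptype(s[i], s[j])
    if tp == 0 or j - i <= P.m:
        return None
    rest = P.au_penalty(tp)
    dangle = 0
    if model == D2:
        if ml:
            dangle = P.mismatch_multi[tp][s[i - 1] if i > 1 else 0][
                s[j + 1] if j < n else 0]
        else:
            dangle = _ext_mismatch(s, n, P, tp, i, j)
    if ml:
        rest += P.ml_intern
    return (i, j, dangle, rest, 0)


def branch_cases(s, n, P, C, model, context, i, j):
    """All applicable dangle cases of branch [i, j], in printed order."""
    out = []
    for d in range(4 if model == D1 else 1):
        case = branch_case(s, n, P, C, model, context, i, j, d)
        if case is not None:
            out.append(case)
    return out


def ml_closing_cases(s, n, P: EnergyParams, C, model: str, i: int, j: int):
    """Multiloop-closing cases for pair i.j.

    Yields ``(wi, wj, add, code)``: the closed-loop energy is
    ``WM2(wi, wj) + add``.  The closing helix pays the initiation penalty a
    plus one branch penalty b; its inner-facing dangles use the pair seen
    from inside the loop (reversed type), and dangle-consumed inner bases
    pay the multiloop unpaired penalty c.
    """
    tp = _ptype(s[i], s[j])
    if tp == 0:
        return []
    rt = _ptype(s[j], s[i])
    base = P.ml_closing + P.ml_intern + P.au_penalty(tp)
    if model == D0:
        return [(i + 1, j - 1, base, 0)]
    if model == D2:
        return [(i + 1, j - 1,
                 base + P.mismatch_multi[rt][s[j - 1]][s[i + 1]], 0)]
    out = [(i + 1, j - 1, base, 0)]
    i1_free = C is None or C.position_unpaired_ok(i + 1)
    j1_free = C is None or C.position_unpaired_ok(j - 1)
    if i1_free:
        out.append((i + 2, j - 1,
                    base + P.dangle3[rt][s[i + 1]] + P.ml_base, 1))
    if j1_free:
        out.append((i + 1, j - 2,
                    base + P.dangle5[rt][s[j - 1]] + P.ml_base, 2))
    if i1_free and j1_free:
        out.append((i + 2, j - 2,
                    base + P.mismatch_multi[rt][s[j - 1]][s[i + 1]]
                    + 2 * P.ml_base, 3))
    return out
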