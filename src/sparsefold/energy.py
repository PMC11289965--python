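"""Turner 2004 nearest-neighbour energy model.

All thermodynamic quantities used by the folding recursions live here:
parameter-file parsing, hairpin / interior-loop / multiloop / dangling-end
energies, and a loop-decomposition evaluator for whole secondary structures.

Energies are integers in units of 0.01 kcal/mol (the convention of the
Vienna parameter-file dialect); conversion to kcal/mol happens only at the
I/O boundary.  ``INF`` marks forbidden states and absorbs under addition.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence as TSequence

INF = 10_000_000  # > any reachable energy; INF+INF stays well inside int range

#: minimum number of unpaired bases in a hairpin loop
MIN_HAIRPIN_UNPAIRED = 3
#: maximum interior-loop size bound on (p-i-1) + (j-q-1)
MAX_INTERIOR_LOOP = 30
#: coefficient of the logarithmic loop-length extrapolation beyond 30 nt
LXC37 = 107.856

_NT = {"A": 1, "C": 2, "G": 3, "U": 4}
_NT_INV = {v: k for k, v in _NT.items()}

# Vienna pair-type order: CG=1 GC=2 GU=3 UG=4 AU=5 UA=6 (0 = not complementary).
# Types > 2 close with a terminal A-U/G-U penalty.
_PAIR_CODE = {
    (2, 3): 1, (3, 2): 2, (3, 4): 3, (4, 3): 4, (1, 4): 5, (4, 1): 6,
}

NUM_PAIR_TYPES = 7  # 6 canonical + the parameter files' NN row


class ParameterFileError(ValueError):
    """Raised when a parameter file cannot be parsed."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map T to U, and validate the alphabet."""
    s = seq.strip().upper().replace("T", "U")
    for pos, ch in enumerate(s, start=1):
        if ch not in _NT:
            raise ValueError(f"invalid residue {ch!r} at position {pos}")
    if not s:
        raise ValueError("empty sequence")
    return s


def encode_sequence(seq: str) -> list[int]:
    """Encode a normalized sequence as 1-based integer codes (index 0 unused)."""
    return [0] + [_NT[c] for c in seq]


def pair_type(b5: str, b3: str) -> int | None:
    """Ordered pair type of two bases, or None if not complementary.

    The six canonical ordered pairs (AU, UA, CG, GC, GU, UG) map to the
    distinct codes 5, 6, 1, 2, 3, 4 (the parameter-table row order).
    """
    try:
        code = _PAIR_CODE.get((_NT[b5.upper()], _NT[b3.upper()]), 0)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None
    return code or None


def _ptype(a: int, b: int) -> int:
    return _PAIR_CODE.get((a, b), 0)


@dataclass
class EnergyParams:
    """All Turner 2004 tables plus the model constants of the recursions.

    ``ml_closing`` (a), ``ml_intern`` (b) and ``ml_base`` (c) are the
    multiloop initialization, branch and unpaired penalties.  ``m`` is the
    minimum hairpin loop size and ``big_m`` the maximum interior-loop size.
    """

    stack: list = field(default_factory=list)
    mismatch_hairpin: list = field(default_factory=list)
    mismatch_interior: list = field(default_factory=list)
    mismatch_interior_1n: list = field(default_factory=list)
    mismatch_interior_23: list = field(default_factory=list)
    mismatch_multi: list = field(default_factory=list)
    mismatch_exterior: list = field(default_factory=list)
    dangle5: list = field(default_factory=list)
    dangle3: list = field(default_factory=list)
    int11: list = field(default_factory=list)
    int21: list = field(default_factory=list)
    int22: list = field(default_factory=list)
    hairpin_init: list = field(default_factory=list)
    bulge_init: list = field(default_factory=list)
    internal_init: list = field(default_factory=list)
    ml_closing: int = 0   # a
    ml_intern: int = 0    # b
    ml_base: int = 0      # c
    ninio: int = 0
    max_ninio: int = 0
    terminal_nonGC: int = 0
    duplex_init: int = 0
    tetraloops: dict = field(default_factory=dict)
    triloops: dict = field(default_factory=dict)
    hexaloops: dict = field(default_factory=dict)
    m: int = MIN_HAIRPIN_UNPAIRED
    big_m: int = MAX_INTERIOR_LOOP
    lxc: float = LXC37
    INF: int = INF

    # aliases matching the conventional a/b/c naming
    @property
    def a(self) -> int:
        return self.ml_closing

    @property
    def b(self) -> int:
        return self.ml_intern

    @property
    def c(self) -> int:
        return self.ml_base

    def au_penalty(self, ptype: int) -> int:
        """Terminal penalty for helix ends closed by non-GC (AU/GU) pairs."""
        return self.terminal_nonGC if ptype > 2 else 0


# ---------------------------------------------------------------------------
# parameter-file parsing (Vienna text dialect, v2.0)
# ---------------------------------------------------------------------------

def _table(values, dims, offset=0):
    """Fold a flat token list into nested lists of the given dimensions.

    ``offset`` shifts the fill position in every dimension (the canonical
    tables start at index 1; surrounding slots stay at 0).
    """
    def build(ds):
        if not ds:
            return 0
        return [build(ds[1:]) for _ in range(ds[0] + offset)]

    out = build(dims)
    it = iter(values)

    def fill(node, ds):
        if len(ds) == 1:
            for k in range(ds[0]):
                node[k + offset] = next(it)
        else:
            for k in range(ds[0]):
                fill(node[k + offset], ds[1:])

    fill(out, dims)
    return out


_SECTION_RE = re.compile(r"^#\s*(\S+)", re.M)


def _tokenize(body: str, section: str, lineno: int) -> list[int]:
    body = re.sub(r"/\*.*?\*/", " ", body, flags=re.S)
    out = []
    for tok in body.split():
        if tok in ("INF", "inf"):
            out.append(INF)
            continue
        try:
            out.append(int(tok))
        except ValueError:
            raise ParameterFileError(
                f"section {section!r} near line {lineno}: bad token {tok!r}"
            ) from None
    return out


def _special_loops(body: str, section: str, lineno: int) -> dict:
    out = {}
    body = re.sub(r"/\*.*?\*/", " ", body, flags=re.S)
    for ln in body.splitlines():
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise ParameterFileError(
                f"section {section!r} near line {lineno}: bad row {ln!r}"
            )
        out[parts[0].upper().replace("T", "U")] = int(parts[1])
    return out


# section name -> (attribute, dimensions, index offset)
_TABLE_SECTIONS = {
    "stack": ("stack", (7, 7), 1),
    "mismatch_hairpin": ("mismatch_hairpin", (7, 5, 5), (1, 0, 0)),
    "mismatch_interior": ("mismatch_interior", (7, 5, 5), (1, 0, 0)),
    "mismatch_internal": ("mismatch_interior", (7, 5, 5), (1, 0, 0)),
    "mismatch_interior_1n": ("mismatch_interior_1n", (7, 5, 5), (1, 0, 0)),
    "mismatch_internal_1n": ("mismatch_interior_1n", (7, 5, 5), (1, 0, 0)),
    "mismatch_interior_23": ("mismatch_interior_23", (7, 5, 5), (1, 0, 0)),
    "mismatch_internal_23": ("mismatch_interior_23", (7, 5, 5), (1, 0, 0)),
    "mismatch_multi": ("mismatch_multi", (7, 5, 5), (1, 0, 0)),
    "mismatch_exterior": ("mismatch_exterior", (7, 5, 5), (1, 0, 0)),
    "dangle5": ("dangle5", (7, 5), (1, 0)),
    "dangle3": ("dangle3", (7, 5), (1, 0)),
    "int11": ("int11", (7, 7, 5, 5), (1, 1, 0, 0)),
    "int21": ("int21", (7, 7, 5, 5, 5), (1, 1, 0, 0, 0)),
    "int22": ("int22", (6, 6, 4, 4, 4, 4), 1),
    "hairpin": ("hairpin_init", (31,), 0),
    "bulge": ("bulge_init", (31,), 0),
    "internal": ("internal_init", (31,), 0),
}


def _mixed_table(values, dims, offsets):
    """_table with a per-dimension offset tuple."""
    def build(ds, os):
        if not ds:
            return 0
        return [build(ds[1:], os[1:]) for _ in range(ds[0] + os[0])]

    out = build(list(dims), list(offsets))
    it = iter(values)

    def fill(node, ds, os):
        if len(ds) == 1:
            for k in range(ds[0]):
                node[k + os[0]] = next(it)
        else:
            for k in range(ds[0]):
                fill(node[k + os[0]], ds[1:], os[1:])

    fill(out, list(dims), list(offsets))
    return out


def load_turner2004(source) -> EnergyParams:
    """Parse a Vienna-dialect parameter file (or concatenated fragments).

    ``source`` may be a path, an open text file, or the file text itself.
    Enthalpy sections and unknown sections are ignored; only the 37 degree
    free-energy tables are read.  Raises :class:`ParameterFileError` naming
    the offending section and line on malformed input.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.startswith("#"):
            text = s
        else:
            with open(s, encoding="utf-8") as fh:
                text = fh.read()

    params = EnergyParams()
    seen = set()

    matches = list(_SECTION_RE.finditer(text))
    for k, mt in enumerate(matches):
        name = mt.group(1)
        if name in ("END", "#"):
            continue
        body = text[mt.end(): matches[k + 1].start() if k + 1 < len(matches) else len(text)]
        lineno = text.count("\n", 0, mt.start()) + 1
        if name in _TABLE_SECTIONS:
            attr, dims, off = _TABLE_SECTIONS[name]
            toks = _tokenize(body, name, lineno)
            want = math.prod(dims)
            if len(toks) != want:
                raise ParameterFileError(
                    f"section {name!r} near line {lineno}: "
                    f"expected {want} entries, found {len(toks)}"
                )
            if isinstance(off, tuple):
                setattr(params, attr, _mixed_table(toks, dims, off))
            else:
                setattr(params, attr, _table(toks, dims, off))
            seen.add(attr)
        elif name == "ML_params":
            toks = _tokenize(body, name, lineno)
            if len(toks) != 6:
                raise ParameterFileError(
                    f"section 'ML_params' near line {lineno}: expected 6 entries"
                )
            params.ml_base, params.ml_closing, params.ml_intern = toks[0], toks[2], toks[4]
            seen.add("ML_params")
        elif name == "NINIO":
            toks = _tokenize(body, name, lineno)
            if len(toks) != 3:
                raise ParameterFileError(
                    f"section 'NINIO' near line {lineno}: expected 3 entries"
                )
            params.ninio, params.max_ninio = toks[0], toks[2]
            seen.add("NINIO")
        elif name == "Misc":
            toks = _tokenize(body, name, lineno)
            if len(toks) < 3:
                raise ParameterFileError(
                    f"section 'Misc' near line {lineno}: expected >=3 entries"
                )
            params.duplex_init, params.terminal_nonGC = toks[0], toks[2]
            seen.add("Misc")
        elif name == "Tetraloops":
            params.tetraloops = _special_loops(body, name, lineno)
        elif name == "Triloops":
            params.triloops = _special_loops(body, name, lineno)
        elif name == "Hexaloops":
            params.hexaloops = _special_loops(body, name, lineno)
        # enthalpy and unknown sections: skipped

    required = {"stack", "mismatch_hairpin", "mismatch_interior", "dangle5",
                "dangle3", "hairpin_init", "bulge_init", "internal_init",
                "ML_params", "NINIO", "Misc"}
    missing = required - seen
    if missing:
        raise ParameterFileError(f"missing sections: {sorted(missing)}")
    return params


def default_params() -> EnergyParams:
    """Load the bundled Turner 2004 free-energy tables.

    The tables ship as two concatenable text fragments (kept individually
    small); they are joined before parsing.
    """
    pkg = resources.files(__package__) / "params"
    parts = sorted(p.name for p in pkg.iterdir() if p.name.endswith(".par"))
    text = "\n".join((pkg / name).read_text() for name in parts)
    return load_turner2004(text)


# ---------------------------------------------------------------------------
# loop energies
# ---------------------------------------------------------------------------

def hairpin_energy(s: list[int], i: int, j: int, P: EnergyParams) -> int:
    """Energy of the hairpin loop closed by pair i.j (1-based encoded seq).

    INF if the loop is shorter than the minimum size or i.j is not
    complementary.  Special tri-/tetra-/hexaloop sequences override the
    generic initiation + mismatch scheme, as in the parameter-file
    conventions.
    """
    size = j - i - 1
    tp = _ptype(s[i], s[j])
    if tp == 0 or size < P.m:
        return INF
    if size <= 30:
        e = P.hairpin_init[size]
    else:
        e = P.hairpin_init[30] + int(P.lxc * math.log(size / 30.0))
    if size == 4 and P.tetraloops:
        key = "".join(_NT_INV[s[k]] for k in range(i, j + 1))
        if key in P.tetraloops:
            return P.tetraloops[key]
    elif size == 6 and P.hexaloops:
        key = "".join(_NT_INV[s[k]] for k in range(i, j + 1))
        if key in P.hexaloops:
            return P.hexaloops[key]
    elif size == 3:
        if P.triloops:
            key = "".join(_NT_INV[s[k]] for k in range(i, j + 1))
            if key in P.triloops:
                return P.triloops[key]
        return e + P.au_penalty(tp)
    return e + P.mismatch_hairpin[tp][s[i + 1]][s[j - 1]]


def interior_energy(s: list[int], i: int, j: int, p: int, q: int,
                    P: EnergyParams) -> int:
    """Energy of the two-loop (stack, bulge or interior loop) i.j / p.q.

    Requires i < p < q < j with both pairs complementary; INF when the loop
    size exceeds the model bound.  Implements the full table hierarchy:
    stacks, bulges, 1x1/2x1/2x2/2x3/1xn special cases and the generic
    initiation + capped-asymmetry + mismatch form.
    """
    n1 = p - i - 1
    n2 = j - q - 1
    if n1 + n2 > P.big_m:
        return INF
    tp = _ptype(s[i], s[j])
    tq = _ptype(s[q], s[p])  # inner pair seen from inside the loop
    if tp == 0 or tq == 0:
        return INF
    if n1 > n2:
        nl, ns = n1, n2
    else:
        nl, ns = n2, n1
    if nl == 0:
        return P.stack[tp][tq]
    if ns == 0:  # bulge
        if nl <= 30:
            e = P.bulge_init[nl]
        else:
            e = P.bulge_init[30] + int(P.lxc * math.log(nl / 30.0))
        if nl == 1:
            e += P.stack[tp][tq]
        else:
            e += P.au_penalty(tp) + P.au_penalty(tq)
        return e
    si1, sj1 = s[i + 1], s[j - 1]
    sp1, sq1 = s[p - 1], s[q + 1]
    if ns == 1:
        if nl == 1:
            return P.int11[tp][tq][si1][sj1]
        if nl == 2:
            if n1 == 1:
                return P.int21[tp][tq][si1][sq1][sj1]
            return P.int21[tq][tp][sq1][si1][sp1]
        # 1 x n loop
        if nl + 1 <= 30:
            e = P.internal_init[nl + 1]
        else:
            e = P.internal_init[30] + int(P.lxc * math.log((nl + 1) / 30.0))
        e += min(P.max_ninio, (nl - ns) * P.ninio)
        e += P.mismatch_interior_1n[tp][si1][sj1]
        e += P.mismatch_interior_1n[tq][sq1][sp1]
        return e
    if ns == 2:
        if nl == 2:
            return P.int22[tp][tq][si1][sp1][sq1][sj1]
        if nl == 3:
            e = P.internal_init[5] + P.ninio
            e += P.mismatch_interior_23[tp][si1][sj1]
            e += P.mismatch_interior_23[tq][sq1][sp1]
            return e
    u = nl + ns
    if u <= 30:
        e = P.internal_init[u]
    else:
        e = P.internal_init[30] + int(P.lxc * math.log(u / 30.0))
    e += min(P.max_ninio, (nl - ns) * P.ninio)
    e += P.mismatch_interior[tp][si1][sj1]
    e += P.mismatch_interior[tq][sq1][sp1]
    return e


def dangle_terms(s: list[int], P: EnergyParams, kind: str,
                 pair: tuple[int, int], dangling: TSequence[int],
                 table: str = "exterior") -> int:
    """Dangling-end stacking term(s) for a helix-closing pair.

    ``kind`` is one of ``d5``/``d3``/``d53``.  For ``d53`` the mapping is
    selected by ``table``: ``"exterior"``/``"multi"`` use the corresponding
    both-sides mismatch table when both neighbours exist (falling back to
    the single-sided tables otherwise, as at sequence boundaries), and
    ``"dangle"`` forces the additive dangle5+dangle3 sum.  Both dangle
    models consult the mismatch tables for both-sides terms; they differ in
    whether the dangling bases are consumed.  Positions outside [1, n]
    contribute exactly 0.
    """
    n = len(s) - 1
    p, q = pair
    tp = _ptype(s[p], s[q])
    if tp == 0:
        return INF

    def base(pos):
        return s[pos] if 1 <= pos <= n else 0

    if kind == "d5":
        b = base(dangling[0])
        return P.dangle5[tp][b] if b else 0
    if kind == "d3":
        b = base(dangling[0])
        return P.dangle3[tp][b] if b else 0
    if kind == "d53":
        b5, b3 = base(dangling[0]), base(dangling[1])
        if table == "dangle" or not (b5 and b3):
            e = 0
            if b5:
                e += P.dangle5[tp][b5]
            if b3:
                e += P.dangle3[tp][b3]
            return e
        mm = P.mismatch_exterior if table == "exterior" else P.mismatch_multi
        return mm[tp][b5][b3]
    raise ValueError(f"unknown dangle kind {kind!r}")


def _ext_mismatch(s, n, P, tp, i, j):
    """Always-dangle term for an external branch i.j (boundary aware)."""
    b5 = s[i - 1] if i > 1 else 0
    b3 = s[j + 1] if j < n else 0
    if b5 and b3:
        return P.mismatch_exterior[tp][b5][b3]
    if b5:
        return P.dangle5[tp][b5]
    if b3:
        return P.dangle3[tp][b3]
    return 0


def energy_to_kcal(e: int) -> float:
    """Convert an internal integer energy to kcal/mol."""
    return e / 100.0
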