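"""Hard structure constraints: parsing, O(1) DP predicates, random generator.

A constraint marks each position as unconstrained, forced-unpaired, or part
of a forced base pair.  Forced pairs must be complementary for the sequence,
non-crossing, and far enough apart to be closable.  The folding engines
consult :meth:`ConstraintSet.pair_allowed` and
:meth:`ConstraintSet.region_unpaired_ok` (prefix-count based, O(1)).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .energy import MIN_HAIRPIN_UNPAIRED, encode_sequence, normalize_sequence, _ptype

UNCONSTRAINED = 0
FORCED_UNPAIRED = 1
FORCED_PAIR_OPEN = 2
FORCED_PAIR_CLOSE = 3


class ConstraintError(ValueError):
    """Raised for malformed or inconsistent constraint strings."""


@dataclass
class ConstraintSet:
    n: int
    code: list  # per-position constraint code, 1-based
    partner: list = field(default=None)  # involution; 0 = no forced partner

    def __post_init__(self):
        if self.partner is None:
            self.partner = [0] * (self.n + 1)
        for i, j in self.forced_pairs():
            if self.partner[j] != i:
                raise ConstraintError("partner map is not an involution")
        # prefix counts of forced-paired positions, for O(1) region queries
        pref = [0] * (self.n + 1)
        for k in range(1, self.n + 1):
            pref[k] = pref[k - 1] + (1 if self.partner[k] else 0)
        self._paired_prefix = pref

    def forced_pairs(self):
        return [(i, self.partner[i]) for i in range(1, self.n + 1)
                if self.partner[i] > i]

    def pair_allowed(self, i: int, j: int) -> bool:
        """May i pair with j?  False if either end is forced unpaired or
        forced to a different partner."""
        ci, cj = self.code[i], self.code[j]
        if ci == FORCED_UNPAIRED or cj == FORCED_UNPAIRED:
            return False
        if self.partner[i] not in (0, j) or self.partner[j] not in (0, i):
            return False
        return True

    def position_unpaired_ok(self, k: int) -> bool:
        return self.partner[k] == 0

    def region_unpaired_ok(self, i: int, j: int) -> bool:
        """May every base in [i, j] stay unpaired?  (True for empty regions.)"""
        if i > j:
            return True
        return self._paired_prefix[j] - self._paired_prefix[i - 1] == 0

    def paired_prefix(self) -> list:
        """Prefix counts of forced-paired positions (for branch-free checks)."""
        return self._paired_prefix

    def is_empty(self) -> bool:
        return all(c == UNCONSTRAINED for c in self.code[1:])


def parse_constraints(text: str, seq: str) -> ConstraintSet:
    """Parse a dot-bracket constraint string against a sequence.

    ``.`` unconstrained, ``x`` forced unpaired, matched ``( )`` a forced
    pair.  Forced pairs must be complementary, non-crossing (guaranteed by
    bracket matching) and span more than the minimum hairpin size.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if len(text) != n:
        raise ConstraintError(
            f"constraint length {len(text)} != sequence length {n}")
    s = encode_sequence(seq)
    code = [UNCONSTRAINED] * (n + 1)
    partner = [0] * (n + 1)
    stack = []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            pass
        elif ch == "x":
            code[pos] = FORCED_UNPAIRED
        elif ch == "(":
            stack.append(pos)
            code[pos] = FORCED_PAIR_OPEN
        elif ch == ")":
            if not stack:
                raise ConstraintError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            if _ptype(s[i], s[pos]) == 0:
                raise ConstraintError(
                    f"forced pair {i}.{pos} ({seq[i-1]}-{seq[pos-1]}) "
                    "is not complementary")
            if pos - i <= MIN_HAIRPIN_UNPAIRED:
                raise ConstraintError(
                    f"forced pair {i}.{pos} too close to form a hairpin")
            code[pos] = FORCED_PAIR_CLOSE
            partner[i], partner[pos] = pos, i
        else:
            raise ConstraintError(
                f"invalid constraint character {ch!r} at position {pos}")
    if stack:
        raise ConstraintError(f"unbalanced '(' at position {stack[-1]}")
    return ConstraintSet(n, code, partner)


def empty_constraints(n: int) -> ConstraintSet:
    return ConstraintSet(n, [UNCONSTRAINED] * (n + 1))


def constraints_to_text(C: ConstraintSet) -> str:
    out = []
    for k in range(1, C.n + 1):
        if C.partner[k] > k:
            out.append("(")
        elif 0 < C.partner[k] < k:
            out.append(")")
        elif C.code[k] == FORCED_UNPAIRED:
            out.append("x")
        else:
            out.append(".")
    return "".join(out)


def random_constraints(seq: str, seed: int) -> ConstraintSet:
    """Random pseudoknot-free forced-pair constraints for a sequence.

    Draws two random indices at a time; a draw is kept if the bases are
    complementary, far enough apart to close a hairpin, unused so far, and
    non-crossing with the pairs already kept.  The number of forced pairs is
    capped at floor(0.5 * log2(n)); sampling stops after 10x that many
    attempts.  Deterministic for a fixed seed.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if n < 8:
        raise ValueError("sequence too short for constraint generation")
    s = encode_sequence(seq)
    rng = random.Random(seed)
    cap = int(math.floor(0.5 * math.log2(n)))
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    attempts = 0
    while len(chosen) < cap and attempts < 10 * cap:
        attempts += 1
        i, j = rng.randint(1, n), rng.randint(1, n)
        if i > j:
            i, j = j, i
        if i == j or i in used or j in used:
            continue
        if _ptype(s[i], s[j]) == 0:
            continue
        if j - i <= MIN_HAIRPIN_UNPAIRED:
            continue
        if any(a < i < b < j or i < a < j < b for a, b in chosen):
            continue
        chosen.append((i, j))
        used.update((i, j))
    code = [UNCONSTRAINED] * (n + 1)
    partner = [0] * (n + 1)
    for i, j in chosen:
        code[i], code[j] = FORCED_PAIR_OPEN, FORCED_PAIR_CLOSE
        partner[i], partner[j] = j, i
    return ConstraintSet(n, code, partner)
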