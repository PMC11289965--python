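"""Secondary-structure container and dot-bracket text round-trip."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs i.j (1-based, i < j)."""

    n: int
    pairs: frozenset

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"pair {i}.{j} out of range for n={self.n}")
            if i in seen or j in seen:
                raise ValueError(f"base in pair {i}.{j} pairs more than once")
            seen.add(i)
            seen.add(j)

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "SecondaryStructure":
        return cls(n, frozenset(tuple(p) for p in pairs))

    @classmethod
    def from_dotbracket(cls, text: str) -> "SecondaryStructure":
        stack, pairs = [], []
        for pos, ch in enumerate(text, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif ch not in ".x":
                raise ValueError(f"invalid structure character {ch!r} at {pos}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return cls(len(text), frozenset(pairs))

    def to_dotbracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)

    def partner_array(self) -> list[int]:
        """1-based partner map; 0 = unpaired."""
        pt = [0] * (self.n + 1)
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt

    def is_crossing(self) -> bool:
        ps = sorted(self.pairs)
        open_stack = []
        for i, j in ps:
            while open_stack and open_stack[-1] < i:
                open_stack.pop()
            if open_stack and j > open_stack[-1]:
                return True
            open_stack.append(j)
        return False

    def __len__(self) -> int:
        return len(self.pairs)
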