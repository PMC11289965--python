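"""Deterministic generators for test inputs.

Random sequences with a given base composition, dinucleotide-preserving
shuffles (Eulerian-path construction: the output keeps the exact
dinucleotide count multiset and the first/last residue), and the small
worked-example fixtures used throughout the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .energy import normalize_sequence

_BASES = "ACGU"


@dataclass
class GeneratorConfig:
    seed: int
    length: int
    composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, U

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be positive")
        comp = tuple(float(x) for x in self.composition)
        if len(comp) != 4 or any(x < 0 for x in comp):
            raise ValueError("composition must be 4 non-negative frequencies")
        if abs(sum(comp) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        self.composition = comp


def random_sequence(cfg: GeneratorConfig) -> str:
    """I.i.d. random RNA sequence; a pure function of (seed, config)."""
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(4, size=cfg.length, p=cfg.composition)
    return "".join(_BASES[k] for k in idx)


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle preserving all dinucleotide counts and both end residues.

    Builds the dinucleotide multigraph and draws a random Eulerian path
    from the first to the last residue (shuffle edge lists, walk, retry on
    dead ends).  Deterministic for a fixed seed; homopolymers and other
    single-path graphs return the input itself.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    for _attempt in range(500):
        edges = {b: [] for b in _BASES}
        for a, b in zip(seq, seq[1:]):
            edges[a].append(b)
        for b in _BASES:
            rng.shuffle(edges[b])
        out = [seq[0]]
        cur = seq[0]
        ok = True
        for _ in range(n - 1):
            if not edges[cur]:
                ok = False
                break
            cur = edges[cur].pop()
            out.append(cur)
        if ok:
            return "".join(out)
    return seq  # exhausted retries (essentially impossible for real inputs)


def fixtures() -> dict:
    """Named worked-example fixtures with their expected outcomes.

    Energies in kcal/mol under the stated dangle model with the bundled
    parameter tables.
    """
    return {
        "worked_example": {
            "sequence": "GGGAAAACCCC",
            "model": "d1",
            "constraint": None,
            "energy": -2.9,
            "structure": "(((....))).",
        },
        "worked_example_forced": {
            "sequence": "GGGAAAACCCC",
            "model": "d1",
            "constraint": "(.........)",
            "energy": -2.4,
            "structure": "(((.....)))",
        },
        "empty": {
            "sequence": "AAAAAAAAAA",
            "model": "d2",
            "constraint": None,
            "energy": 0.0,
            "structure": "..........",
        },
    }


def write_fixture_files(directory) -> None:
    """Export the fixtures as FASTA plus a JSON expectations manifest."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fx = fixtures()
    with open(d / "fixtures.fa", "w") as fh:
        for name, rec in fx.items():
            fh.write(f">{name}\n{rec['sequence']}\n")
            if rec["constraint"]:
                fh.write(rec["constraint"] + "\n")
    with open(d / "fixtures.json", "w") as fh:
        json.dump(fx, fh, indent=2)
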