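"""Energy-model unit tests: parameter parsing, loop energies, dangles."""

import re

import pytest

from sparsefold import (INF, ParameterFileError, dangle_terms, hairpin_energy,
                        interior_energy, load_turner2004, pair_type)
from sparsefold.energy import encode_sequence, normalize_sequence


def _raw_fixture_text():
    """Concatenated bundled parameter text, independent of the parser."""
    from importlib import resources
    pkg = resources.files("sparsefold") / "params"
    names = sorted(p.name for p in pkg.iterdir() if p.name.endswith(".par"))
    return "\n".join((pkg / n).read_text() for n in names)


def _raw_section(name):
    """Line-oriented re-parse of one section of the fixture."""
    text = _raw_fixture_text()
    m = re.search(rf"^# {name}\n(.*?)(?=^# |\Z)", text, re.S | re.M)
    assert m, name
    toks = []
    for tok in m.group(1).split():
        toks.append(INF if tok == "INF" else int(tok))
    return toks


class TestParameterLoading:
    def test_multiloop_constants_match_file(self, P):
        toks = _raw_section("ML_params")
        assert (P.c, P.a, P.b) == (toks[0], toks[2], toks[4])

    def test_stack_cg_cg_matches_file(self, P):
        # first cell of the stack table is the CG/CG entry
        assert P.stack[1][1] == _raw_section("stack")[0]

    def test_dangle3_row_matches_file(self, P):
        toks = _raw_section("dangle3")
        assert P.dangle3[1][0:5] == toks[0:5]

    def test_terminal_penalty_and_ninio(self, P):
        assert P.terminal_nonGC == _raw_section("Misc")[2]
        nin = _raw_section("NINIO")
        assert (P.ninio, P.max_ninio) == (nin[0], nin[2])

    def test_malformed_section_raises_with_name(self):
        bad = "## RNAfold parameter file v2.0\n# stack\n1 2 3\n"
        with pytest.raises(ParameterFileError, match="stack"):
            load_turner2004(bad)


class TestPairType:
    def test_canonical_codes(self):
        assert pair_type("G", "C") is not None
        assert pair_type("A", "G") is None

    def test_exactly_six_of_sixteen(self):
        hits = [(a, b) for a in "ACGU" for b in "ACGU"
                if pair_type(a, b) is not None]
        assert len(hits) == 6
        assert len({pair_type(a, b) for a, b in hits}) == 6

    def test_invalid_base_errors(self):
        with pytest.raises(ValueError):
            pair_type("N", "A")


class TestHairpin:
    def test_too_small_is_inf(self, P):
        s = encode_sequence("GAAAC")
        for j in range(2, 1 + P.m + 1):
            assert hairpin_energy(s, 1, j, P) >= INF

    def test_noncanonical_closing_is_inf(self, P):
        s = encode_sequence("AAAAAA")
        assert hairpin_energy(s, 1, 6, P) >= INF

    def test_inner_hairpin_of_worked_example_is_finite(self, P):
        s = encode_sequence("GGGAAAACCCC")
        assert hairpin_energy(s, 3, 8, P) < INF

    def test_matches_external_oracle(self, P, vienna, small_corpus):
        from sparsefold.energy import _ptype
        for seq in small_corpus:
            s = encode_sequence(seq)
            fc = vienna.fold_compound(seq)
            n = len(seq)
            for i in range(1, n - 4):
                for j in range(i + P.m + 1, n + 1):
                    if _ptype(s[i], s[j]):
                        assert hairpin_energy(s, i, j, P) == fc.eval_hp_loop(i, j)


class TestInterior:
    def test_stack_is_table_entry(self, P):
        s = encode_sequence("GGCC")
        # outer G1.C4 (GC), inner G2.C3 seen from inside as (C,G) = CG
        toks = _raw_section("stack")
        assert interior_energy(s, 1, 4, 2, 3, P) == toks[(2 - 1) * 7 + (1 - 1)]

    def test_size_bound_is_inf(self, P):
        seq = "G" + "A" * (P.big_m + 1) + "GAAAC" + "C"
        s = encode_sequence(seq)
        n = len(seq)
        # left side alone exceeds M
        assert interior_energy(s, 1, n, P.big_m + 3, n - 1, P) >= INF

    def test_one_by_one_uses_int11(self, P):
        s = encode_sequence("GAGAAACAC")  # outer G1.C9 (GC), inner G3.C7
        e = interior_energy(s, 1, 9, 3, 7, P)
        # inner pair seen from inside is (C,G) = CG; both mismatches are A
        assert e == P.int11[2][1][1][1]

    def test_matches_external_oracle(self, P, vienna, small_corpus):
        from sparsefold.energy import _ptype
        for seq in small_corpus[:8]:
            s = encode_sequence(seq)
            fc = vienna.fold_compound(seq)
            n = len(seq)
            for i in range(1, n - 6):
                for j in range(i + 8, min(i + 20, n) + 1):
                    if not _ptype(s[i], s[j]):
                        continue
                    for p in range(i + 1, min(i + 4, j - 5) + 1):
                        for q in range(j - 1, max(p + 4, j - 4) - 1, -1):
                            if p < q and _ptype(s[p], s[q]):
                                assert (interior_energy(s, i, j, p, q, P)
                                        == fc.eval_int_loop(i, j, p, q))


class TestDangleTerms:
    def test_single_sided_fixture_lookup(self, P):
        s = encode_sequence("GCC")  # pair G1.C2, C3 dangling 3'
        assert dangle_terms(s, P, "d3", (1, 2), [3]) == P.dangle3[2][2]

    def test_out_of_range_contributes_zero(self, P):
        s = encode_sequence("GAAAC")
        assert dangle_terms(s, P, "d5", (1, 5), [0]) == 0
        assert dangle_terms(s, P, "d3", (1, 5), [6]) == 0

    def test_both_sides_mapping(self, P):
        s = encode_sequence("AGAAACU")
        both = dangle_terms(s, P, "d53", (2, 6), [1, 7], table="exterior")
        assert both == P.mismatch_exterior[2][1][4]
        additive = dangle_terms(s, P, "d53", (2, 6), [1, 7], table="dangle")
        assert additive == (dangle_terms(s, P, "d5", (2, 6), [1])
                            + dangle_terms(s, P, "d3", (2, 6), [7]))

    def test_pure_function_determinism(self, P):
        s = encode_sequence("GGGAAAACCCC")
        vals = {interior_energy(s, 1, 11, 2, 10, P) for _ in range(5)}
        assert len(vals) == 1


def test_normalize_accepts_t_and_case():
    assert normalize_sequence("acgt") == "ACGU"
    with pytest.raises(ValueError):
        normalize_sequence("ACGN")
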