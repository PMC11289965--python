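# Methods

## Energy model

Energies are integers in units of 0.01 kcal/mol (the Vienna parameter-file
convention); conversion to kcal/mol happens only at the I/O boundary, which
keeps the dynamic program exact and lets the traceback compare recursion
cases by integer equality.  `INF = 10⁷` marks forbidden states; it absorbs
under addition with large headroom (guards use `INF − 2²¹`), so masked
(branch-free) sums of a finite loop energy and one or two sentinels can
never be mistaken for a reachable value.

The bundled tables are the Turner 2004 free energies in the Vienna text
dialect: stacking, hairpin/bulge/interior initiations (logarithmic
extrapolation `ΔG(s) = ΔG(30) + 107.856·ln(s/30)` beyond 30 nt), the
1×1/2×1/2×2 special interior tables, per-context mismatch tables, 5′/3′
dangles, special tri-/tetra-/hexaloop bonuses, the Ninio asymmetry penalty
(per-nucleotide 0.6 kcal/mol, capped at 3.0), the terminal non-GC penalty
(0.5 kcal/mol), and the multiloop constants a = 9.3, b = −0.9, c = 0.0
kcal/mol.  Enthalpy tables are not shipped: temperature rescaling is out of
scope, and dropping them keeps each bundled file small (the tables ship as
two concatenable text parts which the loader joins).

Conventions that the recursions as usually printed leave implicit, fixed
here the way the reference folding tools apply them (and verified by exact
MFE agreement with an independent implementation on random sequences):

* the terminal non-GC penalty applies at every helix end in external
  loops, multiloops, hairpins (size-3 directly, larger sizes through the
  mismatch tables) and bulges of size ≥ 2;
* the multiloop-closing helix pays the branch penalty b in addition to the
  initiation penalty a;
* a multiloop base consumed by a dangle still pays the unpaired penalty c;
* the both-sides (5′3′) dangle term uses the context's mismatch table
  (`mismatch_exterior` / `mismatch_multi`) rather than the sum
  dangle5 + dangle3; the schema keeps the two context tables separate even
  though the bundled parameters populate them identically;
* lonely (isolated) pairs are permitted; coaxial stacking is not modelled.

Model constants: minimum hairpin loop m = 3 unpaired bases; maximum
interior-loop size M = 30 on (p−i−1)+(j−q−1).  Both are the de-facto
community defaults; the printed worked-example energies require them.

## Recursions and dangle models

`V(i,j)` is the MFE over structures closed by pair i·j; `W` over general
spans; `WM`/`WM²` over multiloop fragments with ≥ 1 / ≥ 2 branches.  The
dangle model enters only through the *branch contribution* of a closed
span used inside an external loop or multiloop:

* d0 — `V + AU-penalty` (+ b in multiloops);
* d2 — additionally the both-sides mismatch term for the bases adjacent to
  the pair (single-sided dangle at the sequence boundary);
* d1 — minimum over four cases with the pair shifted inward:
  `V(i,j)`, `V(i+1,j)+dangle5(i)`, `V(i,j−1)+dangle3(j)`,
  `V(i+1,j−1)+mismatch(i,j)`, each with its own pair's AU penalty, and in
  multiloops + b + c per consumed base.  The multiloop-closing pair has the
  analogous four inner-facing cases over `WM²(i+1..i+2, j−2..j−1)`.

`WM²` is computed from span 2m+3 on: a chain of two minimal branches with
zero unpaired bases is legal there (the textbook initialization `∞ for
j−i ≤ 2m+3` excludes it by one position).

## Sparsification

Evaluation runs row-major, i = n..1 outer and j ascending, so the per-row
arrays `W(i,·)`, `WM(i,·)`, `WM²(i,·)` provide every `·(i, k−1)` value a
split case needs, while candidate columns provide the `(k, j)` side.
Rolling state: three WM² rows (current, i+1, i+2 for the multiloop-closing
shifts), one W and one WM row, and an (M+2)-row V band for the
interior-loop window — a bounded number of length-n arrays, recorded per
fold as `peak_array_cells` and asserted linear in n by the tests.

A cell becomes a candidate iff its external contribution `< Ŵᵖ(i,j)` **or**
its multiloop contribution `< ŴMᵖ(i,j)` (strict; both sides computed from
candidate-restricted recursions).  Under d1 both inequalities use the
dangled (four-case) contributions; under d0/d2 the candidate payload is the
single V value and the contribution is recomputed at use.  The
candidate-restricted forms are

    Ŵᵖ(i,j)  = min{ W(i,j−1);  min_cand W(i,k−1) + w-contrib(k,j) }
    ŴM²(i,j) = min{ ŴM²(i,j−1)+c;  min_cand WM(i,k−1) + wm-contrib(k,j) }
    ŴMᵖ(i,j) = min{ WM(i,j−1)+c;  min_cand c·(k−i) + wm-contrib(k,j);  ŴM² }

with the multiloop branch penalty b inside `wm-contrib` (omitting it breaks
exact equivalence with the dense recursion).

The interior-loop minimization cannot be sparsified; it splits into a
candidate minimum (inner V taken from the candidate payload — never the
dangled contribution, which would shift the traced pair inward) and a
window scan over the V band for non-candidate inner pairs.  When a
non-candidate wins strictly, a trace arrow (source pair → inner pair +
its V) is stored, because that trace cannot be recomputed later.

With hard constraints, the per-pair check inside the interior scans is the
branch-free mask `e + (((left_ok−1) | (right_ok−1)) & INF)` over prefix
counts of forced-paired positions; elsewhere plain conditionals are used.

## Traceback strategies (exclusive dangles)

Candidates under d1 carry `(i, V, W-contrib, WM-contrib)`.  The dangle
type of the contribution is recovered per strategy:

* **trace** — plain contributions plus one *ed-trace-arrow* per candidate
  holding the (external, multiloop) dangle codes.  These arrows are never
  garbage-collected: any candidate can lie on the optimal path.
* **standard** — contributions stored as `enc = (value << 2) | dangle`
  (two's-complement identity `enc = 4·value + dangle`, so decoding is
  `dangle = enc mod 4`, `value = (enc − dangle)/4`, sign-exact for
  negative energies).
* **triplet** — the *un-dangled* value (dangle-table energy subtracted) is
  encoded with the type bits, and the dangle energy is re-added from the
  context-appropriate table at every forward use and during traceback.
  Identification purely by re-adding the four dangle terms and matching the
  context energy — with no type bits — is not sound: two cases can
  coincide numerically while only one has a matching inner V, so the type
  bits are kept and the re-addition realizes the strategy's point
  (robustness to diverging external/multiloop tables).  In this
  representation standard and triplet store the same number of integers
  per candidate; the distinction is the re-addition semantics, and the
  per-candidate payload width is reported in the fold statistics.

The traceback itself never touches dense matrices: the external walk uses
the retained W row of i = 1 plus candidate columns; multiloop fragments
recompute `WM(i₀,·)/WM²(i₀,·)` for the needed rows purely from candidate
lists (a non-candidate closed span can never be the unique achiever — by
the candidate criterion a decomposition then ties, and decomposed cases
are examined first); interior loops follow the stored arrow or scan the
candidate window.  Ties are broken deterministically: decomposed cases
before closed spans, split points and interior pairs in fixed scan order,
d1 dangle cases in the order none / 5′ / 3′ / both.

## Trace-arrow garbage collection

Arrows are reference-counted: creating an arrow increments the count of an
arrow at its target cell, and creating a d1 candidate increments the
arrows at its dangle-shifted achiever cells.  After finishing row i, every
unreferenced arrow sourced in row i+M+1 whose cell is not a candidate is
removed (no future cell can reach it), cascading the release to its
target.  The statistics report created / removed / live counts and the
peak T; the suite verifies the traceback still succeeds after collection
and that created = removed + live.

## Hard constraints

Per-position codes (unconstrained, forced-unpaired, forced-pair) with a
partner involution.  Forced pairs must be complementary, non-crossing and
span more than m bases.  `pair_allowed` and `region_unpaired_ok` are O(1)
via prefix counts.  The random generator draws index pairs uniformly,
keeps complementary, distant, non-crossing draws, caps the count at
⌊0.5·log₂ n⌋ and stops after 10× that many attempts — mirroring how
constraint structures are generated for benchmarking; for a fixed seed it
is deterministic.

## Synthetic data

`random_sequence` draws i.i.d. bases from a configurable composition
(default uniform — the regime the folding benchmarks probe; real RNAs have
family-specific composition and base-pairing correlations that i.i.d.
draws do not reproduce, so passing equivalence tests certify algorithmic
exactness, not biological accuracy).  `dinucleotide_shuffle` preserves the
exact dinucleotide count multiset and both end residues via a random
Eulerian path through the dinucleotide multigraph (shuffle edge lists,
walk, retry on dead ends; deterministic per seed).  The interpretation of
"dinucleotide-shifted" benchmark inputs as dinucleotide-preserving
shuffles is recorded here as a design choice.

## Whole-structure evaluation

`evaluate_structure` sums loop energies of an arbitrary pseudoknot-free
structure.  Under d1 each loop's dangles are assigned optimally subject to
exclusivity by a small chain DP over the loop's stem ends (a cycle DP for
multiloops, conditioning on the closing helix's choice) — the
per-structure counterpart of the recursion-level four-case minimum, which
is why every traced structure re-evaluates to the reported MFE exactly.
Interior loops larger than M evaluate to infinity (the model bound is part
of the model, not only of the search).

## Problem sizes and verification

The test suite folds 100 seeded random sequences of 20–60 nt (a size at
which the dense oracle is fast while all loop types, strategies and the
garbage collector are exercised; longer 70–110 nt sequences are used for
the GC and space-contract checks) across all three dangle models and all
three strategies, asserting exact integer MFE equality sparse vs dense,
candidate-set equality against the dense inequalities for n ≤ 40, and
re-evaluation of every traced structure.  When the ViennaRNA Python
bindings are available the hairpin/interior primitives and the dense MFE
are additionally checked against them exactly (these tests skip cleanly
otherwise).

## Known limitations

No coaxial stacking, no pseudoknots, no partition function or suboptimal
enumeration, no temperature rescaling, no lonely-pair suppression.  The
d1 evaluation of *arbitrary* (non-traced) structures reflects this
engine's exclusive-dangle conventions; other tools' single-structure
evaluators differ in how they assign dangles per structure even when their
MFE values agree.
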