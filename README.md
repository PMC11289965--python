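# sparsefold

Sparsified minimum-free-energy (MFE) prediction of pseudoknot-free RNA
secondary structure under the Turner 2004 nearest-neighbour energy model,
with full dangling-end support.

## The problem

An RNA sequence S = S₁…Sₙ folds into the pseudoknot-free structure that
minimizes its loop-decomposition free energy.  The classical dynamic
program (Zuker–Stiegler) computes

    W(i,j)  = min{ Wᵖ(i,j), Vᵈ(i,j) }                      (general spans)
    V(i,j)  = min{ 𝓗(i,j);  min 𝓘(i,j;p,q)+V(p,q);  WM²(i+1,j-1)+a }
    WM, WM² = multiloop chain minimizations with penalties a, b, c

in O(n³) time and O(n²) space.  *Sparsification* restricts the split-point
minimizations to **candidates** — spans [k, j] whose closed (branch)
contribution strictly beats every decomposition — and retains only O(n)
rolling arrays plus the Z candidates and T trace arrows: O(n² + nZ) time
and O(n + Z + T) space, with the MFE guaranteed identical to the dense
recursion.

Dangling ends (stacking of an unpaired base on an adjacent helix end) are
what make sparsification non-trivial.  Three standard models are
implemented:

* **d0** — dangles ignored;
* **d2** — both-sides dangle terms always added to every branch;
* **d1** (*exclusive*) — each branch takes the best of four cases
  (no dangle / 5′ / 3′ / both), with the actual pair shifted inward so no
  base serves two stem ends.

Under d1 a candidate's stored energy no longer identifies its inner pair:
the optimum of span [i, j] may pair (i+1, j), (i, j−1) or (i+1, j−1).  The
engine therefore extends candidates with their external-loop and multiloop
contributions and recovers the dangle direction during traceback by one of
three strategies: **trace** (a dedicated ed-trace-arrow per candidate),
**standard** (the dangle type bit-packed in the low two bits of the stored
contributions, `enc = (V << 2) | dangle`), and **triplet** (un-dangled
values stored; the dangle energy is re-added from the context-appropriate
table at every use).  Interior-loop optima that land on non-candidates are
remembered with reference-counted, garbage-collected trace arrows.

Hard constraints (forced pairs, forced-unpaired positions) restrict the
search space; the interior-loop constraint check is evaluated branch-free
(`e + (((left_ok-1) | (right_ok-1)) & INF)`).

A dense O(n²)-space reference implementation of the same recursions ships
alongside the sparse engine and serves as its internal correctness oracle;
the two agree exactly on every tested input.

## Worked example

```sh
$ echo GGGAAAACCCC | sparsefold -d1
GGGAAAACCCC
(((....))). (-2.90)
```

Under the exclusive-dangle model the optimum shifts the outer pair off the
3′ end: positions 1–10 close a helix of three G–C pairs over an AAAA
tetraloop and the final C dangles on it, for −2.9 kcal/mol.  Forcing the
full-span pair instead:

```sh
$ printf '>forced\nGGGAAAACCCC\n(.........)\n' | sparsefold -d1
>forced
GGGAAAACCCC
(((.....))) (-2.40)
```

gives the best *closed* structure of the span, V(1,11) = −2.4 kcal/mol —
the 0.5 kcal/mol gap is exactly the dangle the shifted optimum gains.
Sparsity statistics (`--stats`) report the candidate count Z, the peak
trace-arrow count T, and the peak rolling-array allocation:

```sh
$ echo GGGAAAACCCC | sparsefold -d1 --stats
GGGAAAACCCC
(((....))). (-2.90)
{"n": 11, "model": "d1", "strategy": "standard", "candidates": 12,
 "trace_arrows_peak": 0, ... "z_fraction_of_quadratic": 0.218...}
```

From Python:

```python
from sparsefold import fold_sparse, evaluate_structure

r = fold_sparse("GGGAAAACCCC", model="d1", strategy="standard")
r.mfe                          # -2.9
r.structure.to_dotbracket()    # '(((....))).'
evaluate_structure("GGGAAAACCCC", r.structure, "d1")   # -2.9, exact
```

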