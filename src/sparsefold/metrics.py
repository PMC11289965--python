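"""Base-pair prediction accuracy: sensitivity, PPV, F-measure."""

from __future__ import annotations

from dataclasses import dataclass

from .structure import SecondaryStructure


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    ppv: float
    f_measure: float


def compare_structures(predicted: SecondaryStructure,
                       reference: SecondaryStructure) -> Metrics:
    """Exact-pair-identity comparison of two structures over one sequence.

    sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), F = their harmonic mean;
    any ratio with a zero denominator (and F when either ratio is zero) is
    reported as 0.
    """
    if predicted.n != reference.n:
        raise ValueError("structures are over different lengths")
    tp = len(predicted.pairs & reference.pairs)
    fp = len(predicted.pairs - reference.pairs)
    fn = len(reference.pairs - predicted.pairs)
    sens = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return Metrics(tp, fp, fn, sens, ppv, f)
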