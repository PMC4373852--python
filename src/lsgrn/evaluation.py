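"""Scoring a predicted network against a gold standard.

The pair space is every ordered non-self (regulator, target) pair over the
gold universe, so negatives are implicit.  Ratios with zero denominator
are reported as 0 (flagged), so metric tables never contain missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GoldStandard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class EvalResult:
    TP: int
    FP: int
    TN: int
    FN: int
    TPR: float
    FPR: float
    PPV: float
    ACC: float
    degenerate: bool = False  # True when any ratio hit the 0/0 convention

    def as_text(self) -> str:
        return (
            f"TP={self.TP} FP={self.FP} TN={self.TN} FN={self.FN}\n"
            f"TPR={self.TPR:.4f} FPR={self.FPR:.4f} PPV={self.PPV:.4f} ACC={self.ACC:.4f}\n"
        )

    def as_tsv(self) -> str:
        return (
            "TP\tFP\tTN\tFN\tTPR\tFPR\tPPV\tACC\n"
            f"{self.TP}\t{self.FP}\t{self.TN}\t{self.FN}\t"
            f"{self.TPR:.6g}\t{self.FPR:.6g}\t{self.PPV:.6g}\t{self.ACC:.6g}\n"
        )


def confusion_counts(pred, gold: GoldStandard) -> ConfusionCounts:
    """TP/FP/TN/FN over all ordered non-self pairs of the gold universe.

    Predicted edges touching genes outside the universe are dropped with a
    warning; self-pairs are excluded from the pair space.
    """
    universe = gold.universe
    n = len(universe)
    total = n * (n - 1)
    kept = set()
    for edge in pred:
        reg, tgt = edge
        if reg not in universe or tgt not in universe:
            logger.warning("predicted edge %s->%s outside universe, dropped", reg, tgt)
            continue
        if reg == tgt:
            continue
        kept.add(edge)
    tp = len(kept & gold.edges)
    fp = len(kept) - tp
    fn = len(gold.edges) - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(counts: ConfusionCounts) -> EvalResult:
    """TPR, FPR, PPV and ACC from confusion counts (0/0 reported as 0)."""
    if counts.total == 0:
        logger.warning("empty pair space; all metrics reported as 0")
        return EvalResult(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    tpr, d1 = _ratio(counts.TP, counts.TP + counts.FN)
    fpr, d2 = _ratio(counts.FP, counts.FP + counts.TN)
    ppv, d3 = _ratio(counts.TP, counts.TP + counts.FP)
    acc = (counts.TP + counts.TN) / counts.total
    return EvalResult(
        counts.TP, counts.FP, counts.TN, counts.FN,
        tpr, fpr, ppv, acc, degenerate=d1 or d2 or d3,
    )


def roc_points(network, gold: GoldStandard, theta_grid) -> list:
    """(FPR, TPR) along a theta sweep of the weighted network.

    The binarized edge sets are nested in theta, so TPR and FPR are each
    monotone non-increasing along the grid.  Points are returned sorted by
    FPR with the (0,0) and (1,1) ROC endpoints appended.
    """
    points = []
    for theta in theta_grid:
        counts = confusion_counts(network.edges_at(theta), gold)
        m = metrics(counts)
        points.append((m.FPR, m.TPR))
    points.extend([(0.0, 0.0), (1.0, 1.0)])
    return sorted(set(points))


def write_roc(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("FPR\tTPR\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6g}\t{tpr:.6g}\n")
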