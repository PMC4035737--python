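"""Signal-peptide vs TM-segment discrimination and ROC/AUC evaluation.

A sequence is called a TM segment when its maximum window score strictly
exceeds a threshold (default tau_first = 2.7), otherwise a signal
peptide.  Discrimination quality over a labeled set is summarized by the
area under the ROC curve, computed as the Mann–Whitney concordance
probability with midrank tie handling: the probability that a randomly
chosen TM example scores above a randomly chosen SP example, ties
counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
from scipy.stats import rankdata

from pmiscale.scales import HydropathyScale
from pmiscale.windowing import WindowingParams, max_window_score

if TYPE_CHECKING:  # pragma: no cover
    from pmiscale.io import LabeledExample

#: Class labels. TM (membrane-inserted) is the positive class throughout.
SP = "SP"
TM = "TM"

#: Default decision threshold separating SP from TM/signal-anchor segments.
DEFAULT_TAU_FIRST = 2.7


@dataclass(frozen=True)
class ScoredExample:
    """A labeled example together with its maximum window score."""

    id: str
    label: str
    score: float

    def __post_init__(self) -> None:
        if self.label not in (SP, TM):
            raise ValueError(f"label must be {SP!r} or {TM!r}, got {self.label!r}")


@dataclass
class ROCResult:
    """ROC curve points (FPR, TPR) and the area under the curve."""

    points: list[tuple[float, float]]
    auc: float


def classify_segment(
    seq: str,
    scale: HydropathyScale,
    params: WindowingParams | None = None,
    tau_first: float = DEFAULT_TAU_FIRST,
) -> str:
    """TM if the maximum window score strictly exceeds tau_first, else SP.

    The comparison is strict: a score exactly equal to the threshold is
    classified SP.
    """
    score, _ = max_window_score(seq, scale, params)
    return TM if score > tau_first else SP


def auc(examples: Sequence[ScoredExample], positive_label: str = TM) -> float:
    """Mann–Whitney AUC of the scores for positive vs negative labels.

    Equals the pairwise concordance probability: over all
    (positive, negative) pairs, 1 for positive > negative, 0.5 for ties,
    divided by the number of pairs.  Computed from midranks, which is
    exact under ties.
    """
    scores = np.array([e.score for e in examples], dtype=float)
    pos = np.array([e.label == positive_label for e in examples], dtype=bool)
    return _auc_from_scores(scores, pos)


def _auc_from_scores(scores: np.ndarray, positive: np.ndarray) -> float:
    n_pos = int(positive.sum())
    n_neg = int(len(scores) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative example")
    ranks = rankdata(scores, method="average")
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(examples: Sequence[ScoredExample], positive_label: str = TM) -> list[tuple[float, float]]:
    """ROC curve as (FPR, TPR) pairs from (0,0) to (1,1)."""
    from sklearn.metrics import roc_curve

    y = np.array([e.label == positive_label for e in examples], dtype=int)
    s = np.array([e.score for e in examples], dtype=float)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def evaluate_discrimination(
    dataset: Iterable["LabeledExample"],
    scale: HydropathyScale,
    params: WindowingParams | None = None,
) -> tuple[ROCResult, list[ScoredExample]]:
    """Score every example by its maximum window score and compute ROC/AUC.

    Returns the ROC result (curve + AUC with TM as the positive class)
    and the per-example scores, in input order.  Deterministic for fixed
    inputs.
    """
    params = params or WindowingParams()
    scored = []
    for ex in dataset:
        score, _ = max_window_score(ex.record.residues, scale, params, ex.record.id)
        scored.append(ScoredExample(ex.record.id, ex.label, score))
    result = ROCResult(points=roc_points(scored), auc=auc(scored))
    return result, scored


def write_scores_tsv(scored: Sequence[ScoredExample], path, tau_first: float = DEFAULT_TAU_FIRST) -> None:
    """Export per-example scores as TSV (id, label, score, predicted_label)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("id\tlabel\tscore\tpredicted_label\n")
        for e in scored:
            pred = TM if e.score > tau_first else SP
            fh.write(f"{e.id}\t{e.label}\t{e.score:.6f}\t{pred}\n")


def write_roc_tsv(examples: Sequence[ScoredExample], path, positive_label: str = TM) -> None:
    """Export the ROC curve as TSV (threshold, fpr, tpr)."""
    from sklearn.metrics import roc_curve

    y = np.array([e.label == positive_label for e in examples], dtype=int)
    s = np.array([e.score for e in examples], dtype=float)
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for t, f, tp in zip(thr, fpr, tpr):
            fh.write(f"{t:.6f}\t{f:.6f}\t{tp:.6f}\n")
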