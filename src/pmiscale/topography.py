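"""TM-segment localization, membrane-protein calls, and topography scoring.

Localization is a greedy left-to-right scan of the window profile: the
first window whose mean strictly exceeds ``tau_first`` (default 2.7)
places the first TM segment — spanning exactly the n window residues —
and the scan resumes ``gap`` residues after the segment end (default 2),
with subsequent segments requiring only ``tau_next`` (default 2.1).  The
lower second threshold reflects the observation that the first segment
(a signal anchor) needs a stronger insertion signal than downstream
helices of a polytopic protein.

For the membrane/non-membrane call, the first segment must in addition
start within the N-terminal ``nterm_limit`` residues (default 140, the
upper end of the nascent-chain length range over which SRP binding
declines), mirroring the biology of co-translational targeting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from pmiscale.scales import HydropathyScale
from pmiscale.windowing import WindowingParams, sequence_profile

logger = logging.getLogger(__name__)

DEFAULT_TAU_FIRST = 2.7
DEFAULT_TAU_NEXT = 2.1
DEFAULT_GAP = 2
DEFAULT_NTERM_LIMIT = 140
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class TopographyParams:
    """Thresholds and geometry of the two-threshold greedy scan.

    Parameters
    ----------
    tau_first:
        Threshold (strict) for the first TM segment; also the SP/TM
        discrimination threshold.
    tau_next:
        Threshold (strict) for every subsequent segment; normally
        below ``tau_first``.
    gap:
        Minimum number of residues separating consecutive segments.
    nterm_limit:
        Maximum allowed 1-based start of the first segment when calling
        a protein membrane vs non-membrane; ``None`` disables the limit.
    limit_scan:
        When True, the N-terminal limit also truncates the *search* for
        the first segment during localization (not only the
        membrane/non-membrane call).
    windowing:
        Window length settings (n, default 23).
    """

    tau_first: float = DEFAULT_TAU_FIRST
    tau_next: float = DEFAULT_TAU_NEXT
    gap: int = DEFAULT_GAP
    nterm_limit: int | None = DEFAULT_NTERM_LIMIT
    limit_scan: bool = False
    windowing: WindowingParams = field(default_factory=WindowingParams)

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.nterm_limit is not None and self.nterm_limit < 1:
            raise ValueError("nterm_limit must be >= 1 when set")
        if self.tau_first < self.tau_next:
            logger.warning(
                "tau_first (%g) < tau_next (%g): first-segment threshold is normally the higher one",
                self.tau_first,
                self.tau_next,
            )


@dataclass(frozen=True)
class TMSegment:
    """One predicted TM segment: 1-based inclusive span, window mean, rank."""

    start: int
    end: int
    score: float
    rank: int


@dataclass
class TopographyPrediction:
    """Ordered non-overlapping TM segments plus the membrane-protein flag."""

    sequence_id: str
    segments: list[TMSegment]
    is_membrane: bool


def locate_tm_segments(
    seq: str,
    scale: HydropathyScale,
    params: TopographyParams | None = None,
    sequence_id: str = "<seq>",
) -> TopographyPrediction:
    """Greedy two-threshold localization of TM segments.

    Deterministic: the first window strictly above ``tau_first`` becomes
    segment 1; scanning resumes at ``end + gap + 1`` and subsequent
    windows need only exceed ``tau_next``.
    """
    params = params or TopographyParams()
    prof = sequence_profile(seq, scale, params.windowing, sequence_id)
    n = prof.window_length
    scores = prof.scores
    segments: list[TMSegment] = []
    pos = 0  # 0-based index into the profile
    threshold = params.tau_first
    first_limit = None
    if params.limit_scan and params.nterm_limit is not None:
        first_limit = params.nterm_limit
    while pos < len(scores):
        start = pos + 1
        if not segments and first_limit is not None and start > first_limit:
            break
        if scores[pos] > threshold:
            segments.append(TMSegment(start=start, end=start + n - 1, score=float(scores[pos]), rank=len(segments) + 1))
            pos = (start + n - 1) + params.gap  # 0-based index of residue end+gap+1
            threshold = params.tau_next
        else:
            pos += 1
    is_membrane = bool(segments)
    if segments and params.nterm_limit is not None:
        is_membrane = segments[0].start <= params.nterm_limit
    return TopographyPrediction(sequence_id, segments, is_membrane)


def predict_membrane(
    seq: str,
    scale: HydropathyScale,
    params: TopographyParams | None = None,
    sequence_id: str = "<seq>",
) -> bool:
    """Membrane-protein call: a first TM segment exists and, when the
    N-terminal limit is set, starts within it."""
    return locate_tm_segments(seq, scale, params, sequence_id).is_membrane


def _as_intervals(segments: Iterable) -> list[tuple[int, int]]:
    out = []
    for seg in segments:
        if isinstance(seg, TMSegment):
            out.append((seg.start, seg.end))
        else:
            s, e = seg[0], seg[1]
            out.append((int(s), int(e)))
    for s, e in out:
        if e < s:
            raise ValueError(f"segment end before start: ({s}, {e})")
    for (s1, e1), (s2, e2) in zip(out, out[1:]):
        if s2 <= s1:
            raise ValueError("segments must be sorted by start")
        if s2 <= e1:
            raise ValueError(f"overlapping segments ({s1},{e1}) and ({s2},{e2})")
    return out


def match_segments(
    predicted: Sequence,
    observed: Sequence,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[int, int, int, bool]:
    """One-to-one greedy matching of predicted vs annotated segments.

    Both lists must be sorted and non-overlapping.  Walking both lists
    in sequence order, a (predicted, observed) pair is a true positive
    when their overlap is at least ``min_overlap`` residues; otherwise
    the interval that ends first is discarded.  Returns
    ``(tp, fp, fn, protein_correct)`` with ``protein_correct`` true iff
    there are no false positives and no false negatives.
    """
    pred = _as_intervals(predicted)
    obs = _as_intervals(observed)
    tp = 0
    i = j = 0
    while i < len(pred) and j < len(obs):
        (ps, pe), (os_, oe) = pred[i], obs[j]
        overlap = min(pe, oe) - max(ps, os_) + 1
        if overlap >= min_overlap:
            tp += 1
            i += 1
            j += 1
        elif pe < oe:
            i += 1
        else:
            j += 1
    fp = len(pred) - tp
    fn = len(obs) - tp
    return tp, fp, fn, (fp == 0 and fn == 0)


@dataclass
class TopographyBenchmark:
    """Aggregate segment-level metrics over an annotated dataset (percent).

    ``specificity`` here is segment-level precision, TP/(TP+FP) — the
    convention of TM-helix benchmark servers — not the true-negative
    rate.
    """

    sensitivity: float
    specificity: float
    correctly_predicted: float
    tp: int
    fp: int
    fn: int
    n_proteins: int


def benchmark_topography(
    dataset: Sequence,
    scale: HydropathyScale,
    params: TopographyParams | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> TopographyBenchmark:
    """Predict topography for every annotated protein and score it.

    sensitivity = 100 * TP/(TP+FN), specificity (precision)
    = 100 * TP/(TP+FP), correctly_predicted = percent of proteins with
    neither false positives nor false negatives.  Degenerate zero
    denominators report 100 with a warning, preserving the raw counts.
    """
    params = params or TopographyParams()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("benchmark_topography requires a non-empty dataset")
    TP = FP = FN = 0
    correct = 0
    for ex in dataset:
        pred = locate_tm_segments(ex.record.residues, scale, params, ex.record.id)
        tp, fp, fn, ok = match_segments(pred.segments, ex.segments, min_overlap)
        TP += tp
        FP += fp
        FN += fn
        correct += ok
    if TP + FN == 0:
        logger.warning("no annotated segments in dataset; sensitivity reported as 100")
        sens = 100.0
    else:
        sens = 100.0 * TP / (TP + FN)
    if TP + FP == 0:
        logger.warning("no predicted segments in dataset; specificity reported as 100")
        spec = 100.0
    else:
        spec = 100.0 * TP / (TP + FP)
    return TopographyBenchmark(
        sensitivity=sens,
        specificity=spec,
        correctly_predicted=100.0 * correct / len(dataset),
        tp=TP,
        fp=FP,
        fn=FN,
        n_proteins=len(dataset),
    )


def write_predictions_tsv(predictions: Iterable[TopographyPrediction], path) -> None:
    """Export segments as TSV (sequence_id, rank, start, end, score)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sequence_id\trank\tstart\tend\tscore\n")
        for pred in predictions:
            for seg in pred.segments:
                fh.write(f"{pred.sequence_id}\t{seg.rank}\t{seg.start}\t{seg.end}\t{seg.score:.6f}\n")


def write_predictions_gff3(predictions: Iterable[TopographyPrediction], path, source: str = "pmiscale") -> None:
    """Export segments as GFF3 ``transmembrane_helix`` features (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for pred in predictions:
            for seg in pred.segments:
                attrs = f"ID={pred.sequence_id}.tm{seg.rank};rank={seg.rank}"
                fh.write(
                    f"{pred.sequence_id}\t{source}\ttransmembrane_helix\t{seg.start}\t{seg.end}"
                    f"\t{seg.score:.3f}\t.\t.\t{attrs}\n"
                )


def write_summary_tsv(predictions: Iterable[TopographyPrediction], path) -> None:
    """Export a per-protein summary TSV (sequence_id, n_segments, is_membrane)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sequence_id\tn_segments\tis_membrane\n")
        for pred in predictions:
            fh.write(f"{pred.sequence_id}\t{len(pred.segments)}\t{str(pred.is_membrane).lower()}\n")
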