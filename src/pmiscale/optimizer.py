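"""Grouped steepest-ascent local search over the 20 scale values.

A candidate solution is a full 20-value hydropathy scale.  A neighbor is
obtained by leaving each residue value of the active group unchanged or
shifting it by ±delta; all 3^|group| − 1 non-identity combinations form
the neighborhood.  The best neighbor by training AUC replaces the
current solution when it strictly improves it; otherwise the search
moves to the next (smaller) delta, and after the last delta to the next
group.  Groups are processed in order (default G1 = {F,I,L,V,W,Y},
G2 = {A,D,E,G,H,R,T}, G3 = {C,K,M,N,P,Q,S}), starting from the
Kyte–Doolittle scale.  The procedure is fully deterministic.

Neighbor evaluation is the hot loop: scoring a scale against the
training set reduces to a matrix product between per-window residue
counts and the 20 scale values, followed by a per-sequence maximum and
a rank-based AUC.  The count matrix is precomputed once per training
set; a dual-route test asserts agreement with the direct
`evaluate_discrimination` path.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from pmiscale.discrimination import TM, _auc_from_scores
from pmiscale.io import LabeledExample
from pmiscale.scales import CANONICAL_RESIDUES, HydropathyScale, builtin_scale
from pmiscale.windowing import WindowingParams

logger = logging.getLogger(__name__)

#: Default residue groups searched in order.
DEFAULT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("F", "L", "I", "V", "Y", "W"),
    ("A", "T", "D", "E", "R", "G", "H"),
    ("C", "K", "S", "M", "N", "P", "Q"),
)

#: Default decreasing step sizes; the search starts with ±3 moves.
DEFAULT_DELTA_SCHEDULE: tuple[float, ...] = (3.0, 2.0, 1.0, 0.5, 0.25, 0.1)

#: Above this group size the full 3^|G| neighborhood is replaced by
#: single-coordinate moves (2*|G| neighbors) to avoid combinatorial blow-up.
MAX_FULL_NEIGHBORHOOD = 7


class OptimizerError(RuntimeError):
    """Raised when a search phase exceeds its step cap; carries the trace."""

    def __init__(self, message: str, trace: "OptimizerTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class OptimizerConfig:
    """Search settings.

    ``groups`` must partition the 20 canonical residues; the
    ``delta_schedule`` must be positive and non-increasing.
    ``max_steps_per_phase`` caps the number of accepted moves within one
    (group, delta) phase as a safety net against pathological inputs.
    ``recycle`` repeats the whole G1→G2→G3 pass until a full pass
    accepts no move.
    """

    groups: tuple[tuple[str, ...], ...] = DEFAULT_GROUPS
    delta_schedule: tuple[float, ...] = DEFAULT_DELTA_SCHEDULE
    initial_scale: HydropathyScale = field(default_factory=lambda: builtin_scale("KD"))
    windowing: WindowingParams = field(default_factory=WindowingParams)
    max_steps_per_phase: int = 500
    recycle: bool = False

    def __post_init__(self) -> None:
        flat = [aa for g in self.groups for aa in g]
        if sorted(flat) != sorted(CANONICAL_RESIDUES):
            raise ValueError("groups must be disjoint and jointly cover the 20 canonical residues")
        deltas = tuple(float(d) for d in self.delta_schedule)
        if not deltas or any(d <= 0 for d in deltas):
            raise ValueError("delta_schedule must be non-empty and strictly positive")
        if any(b > a for a, b in zip(deltas, deltas[1:])):
            raise ValueError("delta_schedule must be non-increasing")
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))
        object.__setattr__(self, "delta_schedule", deltas)


@dataclass(frozen=True)
class TraceStep:
    """One accepted move: which group/delta, the per-residue shifts, new AUC."""

    group: tuple[str, ...]
    delta: float
    moves: tuple[tuple[str, int], ...]  # (residue, -1|+1) for shifted residues
    auc: float

    def describe(self) -> str:
        shifts = ",".join(f"{aa}{'+' if s > 0 else '-'}{abs(s) * self.delta:g}" for aa, s in self.moves)
        return shifts or "(none)"


@dataclass
class OptimizerTrace:
    """Accepted-move history; AUC is strictly increasing along ``steps``."""

    initial_auc: float
    steps: list[TraceStep] = field(default_factory=list)

    @property
    def final_auc(self) -> float:
        return self.steps[-1].auc if self.steps else self.initial_auc


def _move_combinations(k: int) -> list[tuple[int, ...]]:
    # deterministic order: per residue unchanged(0) < -delta(-1) < +delta(+1)
    return [c for c in itertools.product((0, -1, 1), repeat=k) if any(c)]


def enumerate_neighbors(scale: HydropathyScale, group: Sequence[str], delta: float) -> list[HydropathyScale]:
    """All 3^|group| − 1 non-identity ±delta combinations over the group.

    Residues are taken in alphabetical order and, per residue, moves in
    the order unchanged < −delta < +delta, so the enumeration order is
    deterministic.  Residues outside the group are untouched.
    """
    if not group:
        raise ValueError("enumerate_neighbors requires a non-empty group")
    if delta <= 0:
        raise ValueError("delta must be positive")
    residues = sorted(group)
    neighbors = []
    for combo in _move_combinations(len(residues)):
        updates = {aa: scale.values[aa] + s * delta for aa, s in zip(residues, combo) if s}
        neighbors.append(scale.replace_values(updates))
    return neighbors


class _TrainingMatrix:
    """Per-window residue counts for fast scale evaluation.

    Window k of the stacked training set contributes the row
    ``counts[k]`` (how many of each canonical residue fall in that
    window); the window mean under a scale ``h`` is ``counts @ h / n``
    (non-canonical residues count zero, matching the scoring rule).
    A per-sequence max over windows then yields the example scores.
    """

    def __init__(self, training: Sequence[LabeledExample], windowing: WindowingParams):
        n = windowing.n
        rows = []
        boundaries = [0]
        labels = []
        inv_len = []
        aa_index = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}
        for ex in training:
            seq = ex.record.residues.upper()
            L = len(seq)
            codes = np.full(L, -1, dtype=np.int8)
            for i, ch in enumerate(seq):
                codes[i] = aa_index.get(ch, -1)
            width = min(n, L)
            n_windows = max(L - n + 1, 1)
            onehot = np.zeros((L, 20), dtype=np.float32)
            valid = codes >= 0
            onehot[np.nonzero(valid)[0], codes[valid]] = 1.0
            csum = np.vstack([np.zeros((1, 20), dtype=np.float32), np.cumsum(onehot, axis=0)])
            counts = csum[width:] - csum[:-width] if L >= n else csum[-1:] - csum[:1]
            rows.append(counts)
            boundaries.append(boundaries[-1] + counts.shape[0])
            labels.append(ex.label == TM)
            inv_len.extend([1.0 / width] * counts.shape[0])
        self.counts = np.vstack(rows)
        self.starts = np.array(boundaries[:-1], dtype=np.intp)
        self.inv_len = np.array(inv_len, dtype=np.float64)
        self.positive = np.array(labels, dtype=bool)
        if not self.positive.any() or self.positive.all():
            raise ValueError("training set must contain both SP and TM examples")

    def example_scores(self, h: np.ndarray) -> np.ndarray:
        window_scores = (self.counts @ h) * self.inv_len
        return np.maximum.reduceat(window_scores, self.starts)

    def auc(self, h: np.ndarray) -> float:
        return _auc_from_scores(self.example_scores(h), self.positive)


def steepest_step(
    scale: HydropathyScale,
    group: Sequence[str],
    delta: float,
    training: Sequence[LabeledExample],
    windowing: WindowingParams | None = None,
    _matrix: _TrainingMatrix | None = None,
) -> tuple[HydropathyScale, float, tuple[tuple[str, int], ...]] | None:
    """Evaluate every neighbor; return the best strictly-improving one.

    Returns ``(best_scale, best_auc, moves)`` or ``None`` when no
    neighbor strictly exceeds the current training AUC.  Ties among
    best neighbors are broken by enumeration order.
    """
    matrix = _matrix or _TrainingMatrix(training, windowing or WindowingParams())
    residues = sorted(group)
    if len(residues) > MAX_FULL_NEIGHBORHOOD:
        logger.warning(
            "group of %d residues exceeds full-neighborhood limit %d; using single-coordinate moves",
            len(residues),
            MAX_FULL_NEIGHBORHOOD,
        )
        combos = []
        for i in range(len(residues)):
            for s in (-1, 1):
                c = [0] * len(residues)
                c[i] = s
                combos.append(tuple(c))
    else:
        combos = _move_combinations(len(residues))

    h = scale.as_array()
    current_auc = matrix.auc(h)
    idx = np.array([CANONICAL_RESIDUES.index(aa) for aa in residues])
    group_cols = matrix.counts[:, idx].astype(np.float64)
    base_window = (matrix.counts @ h) * matrix.inv_len

    best_auc = current_auc
    best_combo = None
    for combo in combos:
        shift = group_cols @ (np.asarray(combo, dtype=np.float64) * delta)
        window_scores = base_window + shift * matrix.inv_len
        scores = np.maximum.reduceat(window_scores, matrix.starts)
        a = _auc_from_scores(scores, matrix.positive)
        if a > best_auc:
            best_auc = a
            best_combo = combo
    if best_combo is None:
        return None
    moves = tuple((aa, s) for aa, s in zip(residues, best_combo) if s)
    updates = {aa: scale.values[aa] + s * delta for aa, s in moves}
    return scale.replace_values(updates), best_auc, moves


def optimize_scale(
    training: Sequence[LabeledExample],
    config: OptimizerConfig | None = None,
) -> tuple[HydropathyScale, OptimizerTrace]:
    """Run the grouped steepest-ascent search.

    For each group in order and each delta in the (decreasing) schedule,
    `steepest_step` is repeated until no neighbor improves the training
    AUC, then the next delta is tried; with ``recycle`` the whole pass
    repeats until stable.  The returned scale is a local optimum of the
    final delta's neighborhood within every group, and the trace AUC is
    strictly increasing over accepted moves.
    """
    config = config or OptimizerConfig()
    training = list(training)
    matrix = _TrainingMatrix(training, config.windowing)
    scale = config.initial_scale
    trace = OptimizerTrace(initial_auc=matrix.auc(scale.as_array()))
    improved_any = True
    passes = 0
    while improved_any:
        improved_any = False
        passes += 1
        for group in config.groups:
            for delta in config.delta_schedule:
                steps_here = 0
                while True:
                    result = steepest_step(scale, group, delta, training, config.windowing, _matrix=matrix)
                    if result is None:
                        break
                    scale, new_auc, moves = result
                    improved_any = True
                    steps_here += 1
                    trace.steps.append(TraceStep(tuple(group), delta, moves, new_auc))
                    if steps_here >= config.max_steps_per_phase:
                        raise OptimizerError(
                            f"exceeded max_steps_per_phase={config.max_steps_per_phase} "
                            f"in group {group} at delta {delta}",
                            trace,
                        )
        if not config.recycle:
            break
    final = HydropathyScale("optimized", dict(scale.values))
    logger.info(
        "local search finished: %d accepted moves over %d pass(es), training AUC %.4f -> %.4f",
        len(trace.steps),
        passes,
        trace.initial_auc,
        trace.final_auc,
    )
    return final, trace


def write_trace_tsv(trace: OptimizerTrace, path) -> None:
    """Export the accepted-move history as TSV (step, group, delta, move, auc)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("step\tgroup\tdelta\tmove\tauc\n")
        fh.write(f"0\t.\t.\tinitial\t{trace.initial_auc:.6f}\n")
        for k, step in enumerate(trace.steps, start=1):
            fh.write(f"{k}\t{''.join(step.group)}\t{step.delta:g}\t{step.describe()}\t{step.auc:.6f}\n")
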