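"""Seeded generators for SP-like and TM-like training examples.

The generators emulate the *structure* of curated SP/TM training data:

* TM examples are a hydrophobic core (19–25 residues, mimicking an
  annotated signal-anchor helix) plus up to 10 flanking residues on each
  side drawn from a polar-enriched background, with the core coordinates
  recorded as the annotated segment.
* SP examples are capped at 60 residues and follow the classic
  n/h/c-region architecture: a short basic n-region (1–5 residues with
  at least one K/R), a hydrophobic h-region of only 6–12 residues —
  shorter than a membrane-spanning helix, which is the signal the
  sliding window exploits — and polar c-region/mature-start filler.
* Whole "proteins" for topography tests alternate background loops
  (>= 25 residues) with 23-residue TM cores at known positions.

Residue compositions are configurable; the defaults separate the
classes under hydropathy scoring, mirroring the compositional bias
between signal-peptide h-regions and signal-anchor helices that the
discrimination method exploits.  All randomness flows through an
explicit numpy Generator — no ambient global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from pmiscale.discrimination import SP, TM
from pmiscale.io import LabeledExample, SequenceRecord
from pmiscale.scales import CANONICAL_RESIDUES


def _normalize_composition(comp: Mapping[str, float], name: str) -> dict[str, float]:
    vals = {aa: float(comp.get(aa, 0.0)) for aa in CANONICAL_RESIDUES}
    if set(comp) - set(CANONICAL_RESIDUES):
        raise ValueError(f"{name}: non-canonical residues {sorted(set(comp) - set(CANONICAL_RESIDUES))}")
    if any(v < 0 for v in vals.values()):
        raise ValueError(f"{name}: negative frequencies")
    total = sum(vals.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: frequencies sum to {total!r}, expected 1")
    return vals


def _spread(base: Mapping[str, float]) -> dict[str, float]:
    # distribute the remaining mass uniformly over unnamed residues
    rest = [aa for aa in CANONICAL_RESIDUES if aa not in base]
    remainder = 1.0 - sum(base.values())
    return {**{aa: v for aa, v in base.items()}, **{aa: remainder / len(rest) for aa in rest}}


#: Hydrophobic-core composition of TM examples (aliphatic/aromatic heavy).
DEFAULT_COMPOSITION_TM = _spread(
    {"I": 0.18, "L": 0.22, "F": 0.12, "V": 0.14, "A": 0.10, "G": 0.06, "W": 0.05, "Y": 0.05}
)

#: Signal-peptide h-region composition (L/A-rich, as in real h-regions).
DEFAULT_COMPOSITION_SP_H = _spread({"L": 0.35, "A": 0.25, "V": 0.15, "C": 0.05})

#: Polar-enriched background for flanks, loops and c-regions.
DEFAULT_COMPOSITION_BACKGROUND = _spread(
    {aa: 0.068 for aa in "DEKRNQSTGPH"}
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shapes and compositions of the synthetic examples.

    ``tm_core_length_range`` is inclusive (default 19–25 residues, the
    span of membrane-crossing helices); ``flank_length`` residues of
    background sequence are added on each side of a TM core;
    ``sp_total_length_max`` caps SP examples at the N-terminal stretch
    that carries the signal peptide (default 60).
    """

    seed: int = 42
    tm_core_length_range: tuple[int, int] = (19, 25)
    flank_length: int = 10
    sp_total_length_max: int = 60
    composition_tm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION_TM))
    composition_sp_h: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION_SP_H))
    composition_background: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION_BACKGROUND))

    def __post_init__(self) -> None:
        lo, hi = self.tm_core_length_range
        if not (1 <= lo <= hi):
            raise ValueError("tm_core_length_range must be positive and ordered")
        if self.flank_length < 0 or self.sp_total_length_max < 20:
            raise ValueError("flank_length must be >= 0 and sp_total_length_max >= 20")
        object.__setattr__(self, "composition_tm", _normalize_composition(self.composition_tm, "composition_tm"))
        object.__setattr__(self, "composition_sp_h", _normalize_composition(self.composition_sp_h, "composition_sp_h"))
        object.__setattr__(
            self, "composition_background", _normalize_composition(self.composition_background, "composition_background")
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _sample(comp: Mapping[str, float], length: int, rng: np.random.Generator) -> str:
    letters = np.array(list(CANONICAL_RESIDUES))
    probs = np.array([comp[aa] for aa in CANONICAL_RESIDUES])
    return "".join(rng.choice(letters, size=length, p=probs))


def generate_tm_example(config: GeneratorConfig, rng: np.random.Generator, ident: str = "tm") -> LabeledExample:
    """One TM-labeled example: hydrophobic core with background flanks.

    The annotated segment coordinates are exactly the core span.
    """
    lo, hi = config.tm_core_length_range
    core_len = int(rng.integers(lo, hi + 1))
    left = _sample(config.composition_background, config.flank_length, rng)
    core = _sample(config.composition_tm, core_len, rng)
    right = _sample(config.composition_background, config.flank_length, rng)
    seq = left + core + right
    seg = (len(left) + 1, len(left) + core_len)
    return LabeledExample(SequenceRecord(ident, f"{ident} synthetic TM segment", seq), TM, (seg,))


def generate_sp_example(config: GeneratorConfig, rng: np.random.Generator, ident: str = "sp") -> LabeledExample:
    """One SP-labeled example (<= 60 residues, n/h/c-region architecture)."""
    n_len = int(rng.integers(1, 6))
    n_region = list(_sample(config.composition_background, n_len, rng))
    n_region[int(rng.integers(0, n_len))] = "K" if rng.random() < 0.5 else "R"
    h_len = int(rng.integers(6, 13))
    h_region = _sample(config.composition_sp_h, h_len, rng)
    total = int(rng.integers(max(40, n_len + h_len + 10), config.sp_total_length_max + 1))
    tail = _sample(config.composition_background, total - n_len - h_len, rng)
    seq = "".join(n_region) + h_region + tail
    return LabeledExample(SequenceRecord(ident, f"{ident} synthetic signal peptide", seq), SP)


def generate_dataset(n_tm: int, n_sp: int, config: GeneratorConfig | None = None) -> list[LabeledExample]:
    """Exactly ``n_tm`` TM and ``n_sp`` SP examples, deterministically shuffled.

    The generator stream is seeded from ``config.seed``; two calls with
    the same configuration produce identical datasets.
    """
    config = config or GeneratorConfig()
    if n_tm < 0 or n_sp < 0:
        raise ValueError("counts must be >= 0")
    rng = config.rng()
    examples = [generate_tm_example(config, rng, f"tm_{i + 1:04d}") for i in range(n_tm)]
    examples += [generate_sp_example(config, rng, f"sp_{i + 1:04d}") for i in range(n_sp)]
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


def generate_topography_protein(
    n_segments: int,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    ident: str = "prot",
) -> LabeledExample:
    """A whole protein with ``n_segments`` 23-residue TM cores at known positions.

    Background loops of 25–45 residues alternate with the cores, so
    consecutive ground-truth segments are separated by at least 25
    residues.  Proteins with no segments carry the SP (non-membrane)
    label.
    """
    config = config or GeneratorConfig()
    if n_segments < 0:
        raise ValueError("n_segments must be >= 0")
    rng = rng if rng is not None else config.rng()
    parts = []
    segments = []
    pos = 0
    for _ in range(n_segments):
        loop = _sample(config.composition_background, int(rng.integers(25, 46)), rng)
        parts.append(loop)
        pos += len(loop)
        core = _sample(config.composition_tm, 23, rng)
        parts.append(core)
        segments.append((pos + 1, pos + 23))
        pos += 23
    tail = _sample(config.composition_background, int(rng.integers(25, 46)), rng)
    parts.append(tail)
    seq = "".join(parts)
    label = TM if segments else SP
    return LabeledExample(SequenceRecord(ident, f"{ident} synthetic protein ({n_segments} TM)", seq), label, tuple(segments))
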