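"""Amino-acid hydropathy scales.

A scale maps each of the 20 canonical residues to a dimensionless score;
the sliding-window machinery averages these scores over fixed windows.
Two scales ship built in:

``PMIscale``
    Potential Membrane Insertion scale — the translocon-insertion
    propensity scale at the core of this package.  High values mark
    residues that promote membrane insertion of a helix.

``KD``
    The Kyte–Doolittle (1982) hydropathy index, used both as a baseline
    in discrimination benchmarks and as the optimizer's starting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

#: The 20 canonical amino-acid one-letter codes, alphabetical.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}


class ScaleError(ValueError):
    """Raised for invalid scale definitions or unknown scale names."""


@dataclass(frozen=True)
class HydropathyScale:
    """A named map from canonical residue letters to scores.

    Parameters
    ----------
    name:
        Human-readable label, carried through transforms and file I/O.
    values:
        Mapping with exactly the 20 canonical one-letter keys; every
        value must be finite.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = dict(self.values)
        keys = set(vals)
        expected = set(CANONICAL_RESIDUES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            parts = []
            if missing:
                parts.append(f"missing residues {missing}")
            if extra:
                parts.append(f"unexpected keys {extra}")
            raise ScaleError(f"invalid scale '{self.name}': " + ", ".join(parts))
        for aa, v in vals.items():
            if not math.isfinite(float(v)):
                raise ScaleError(f"invalid scale '{self.name}': non-finite value for {aa!r}: {v!r}")
        object.__setattr__(self, "values", MappingProxyType({aa: float(vals[aa]) for aa in CANONICAL_RESIDUES}))

    def as_array(self) -> np.ndarray:
        """Scores as a length-20 float array in alphabetical residue order."""
        return np.array([self.values[aa] for aa in CANONICAL_RESIDUES], dtype=float)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def replace_values(self, updates: Mapping[str, float], name: str | None = None) -> "HydropathyScale":
        """Return a copy with some residue values replaced."""
        vals = dict(self.values)
        vals.update({aa: float(v) for aa, v in updates.items()})
        return HydropathyScale(name if name is not None else self.name, vals)


# Table of PMIscale values (one per residue, dimensionless).
_PMISCALE_VALUES = {
    "A": 1.8, "C": 2.1, "D": -8.5, "E": -11.5, "F": 5.8,
    "G": 1.6, "H": -0.2, "I": 6.5, "K": 0.1, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -4.6, "Q": -4.5, "R": 0.5,
    "S": -1.8, "T": 2.3, "V": 4.2, "W": 5.7, "Y": 6.1,
}

# Kyte & Doolittle (1982) hydropathy index.
_KD_VALUES = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

_BUILTINS: dict[str, HydropathyScale] = {
    "pmiscale": HydropathyScale("PMIscale", _PMISCALE_VALUES),
    "kd": HydropathyScale("KD", _KD_VALUES),
    "kyte-doolittle": HydropathyScale("KD", _KD_VALUES),
}

#: Canonical identifiers of the built-in scales.
BUILTIN_SCALE_NAMES = ("PMIscale", "KD")


def builtin_scale(name: str) -> HydropathyScale:
    """Look up a built-in scale by case-insensitive identifier.

    Raises
    ------
    ScaleError
        If ``name`` is not a registered identifier; the message lists
        the available scales.
    """
    key = name.strip().lower()
    try:
        return _BUILTINS[key]
    except KeyError:
        raise ScaleError(
            f"unknown scale {name!r}; available built-in scales: {', '.join(BUILTIN_SCALE_NAMES)}"
        ) from None


def affine_transform(scale: HydropathyScale, a: float, b: float) -> HydropathyScale:
    """Return the scale with every value v mapped to ``a*v + b``.

    ``a`` must be non-zero; with ``a > 0`` the transform preserves the
    ordering of the 20 values (window scores transform the same way,
    so rank-based quantities such as AUC are invariant).
    """
    if a == 0:
        raise ScaleError("affine_transform requires a != 0")
    vals = {aa: a * v + b for aa, v in scale.values.items()}
    return HydropathyScale(f"{scale.name}*{a:g}{b:+g}", vals)


def load_scale(path, name: str | None = None) -> HydropathyScale:
    """Read a scale from a two-column text file.

    Format: one ``LETTER<TAB>value`` row per residue (any run of
    whitespace accepted as separator), ``#`` starts a comment, blank
    lines ignored.  Floats round-trip exactly through `save_scale`.
    """
    vals: dict[str, float] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ScaleError(f"{path}:{lineno}: expected 'LETTER value', got {raw!r}")
            aa, sval = parts[0].upper(), parts[1]
            if aa in vals:
                raise ScaleError(f"{path}:{lineno}: duplicate residue {aa!r}")
            try:
                vals[aa] = float(sval)
            except ValueError:
                raise ScaleError(f"{path}:{lineno}: bad float {sval!r}") from None
    import os

    label = name if name is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return HydropathyScale(label, vals)


def save_scale(scale: HydropathyScale, path) -> None:
    """Write a scale in the two-column text format (exact float round-trip)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# hydropathy scale: {scale.name}\n")
        for aa in CANONICAL_RESIDUES:
            fh.write(f"{aa}\t{scale.values[aa]!r}\n")
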