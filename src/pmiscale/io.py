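"""Sequence and labeled-dataset I/O.

FASTA parsing is delegated to Biopython.  Labeled datasets pair a FASTA
file with a tab-separated annotation sidecar carrying the SP/TM class
and optional annotated TM-segment coordinates (1-based inclusive, one
row per segment; rows without coordinates carry the label only).

`sniff_supplementary` additionally accepts FASTA files whose headers
embed a TM/SP class token, the simplest dialect for externally
distributed benchmark sets.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pmiscale.discrimination import SP, TM

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Raised for malformed dataset files (bad labels, unmatched ids, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with identifier and free-text description."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DatasetError("sequence record with empty id")
        if not self.residues:
            raise DatasetError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())


@dataclass(frozen=True)
class LabeledExample:
    """A sequence with its SP/TM class and optional TM-segment coordinates.

    ``segments`` are 1-based inclusive (start, end) pairs, sorted and
    non-overlapping; a non-empty list requires the TM label.
    """

    record: SequenceRecord
    label: str
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.label not in (SP, TM):
            raise DatasetError(f"{self.record.id}: label must be SP or TM, got {self.label!r}")
        segs = tuple(sorted((int(s), int(e)) for s, e in self.segments))
        for s, e in segs:
            if not (1 <= s <= e):
                raise DatasetError(f"{self.record.id}: bad segment coordinates ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise DatasetError(f"{self.record.id}: overlapping annotated segments")
        if segs and self.label != TM:
            raise DatasetError(f"{self.record.id}: annotated TM segments require the TM label")
        object.__setattr__(self, "segments", segs)


def read_fasta(path) -> list[SequenceRecord]:
    """Read all records from a FASTA file, preserving order."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such FASTA file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise DatasetError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, rec.description, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, line_width: int = 60) -> None:
    """Write records as FASTA; round-trips with `read_fasta`.

    Note: an id containing whitespace is truncated at the first
    whitespace on re-read (standard FASTA header semantics).
    """
    bio = []
    for r in records:
        rec = SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        bio.append(rec)
    with open(path, "wt", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width or None)
        writer.write_file(bio)


def _parse_coord(value: str, row: str, path) -> int:
    try:
        return int(value)
    except ValueError:
        raise DatasetError(f"{path}: malformed coordinate {value!r} in row: {row}") from None


def load_labeled_dataset(fasta_path, annotation_path) -> list[LabeledExample]:
    """Join a FASTA file with its annotation TSV into labeled examples.

    The annotation file has a header row and columns ``id``, ``label``
    and optional ``tm_start``, ``tm_end``; several rows with the same id
    contribute several segments.  Every annotation row must match a
    FASTA record; offending rows are reported together.
    """
    records = {r.id: r for r in read_fasta(fasta_path)}
    labels: dict[str, str] = {}
    segments: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    errors: list[str] = []
    with open(annotation_path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_id, i_label = header.index("id"), header.index("label")
        except ValueError:
            raise DatasetError(f"{annotation_path}: header must contain 'id' and 'label' columns, got {header}")
        i_start = header.index("tm_start") if "tm_start" in header else None
        i_end = header.index("tm_end") if "tm_end" in header else None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            rid, label = parts[i_id].strip(), parts[i_label].strip().upper()
            if rid not in records:
                errors.append(f"annotation id {rid!r} absent from FASTA")
                continue
            if label not in (SP, TM):
                errors.append(f"{rid}: bad label {label!r}")
                continue
            if rid not in labels:
                labels[rid] = label
                order.append(rid)
            elif labels[rid] != label:
                errors.append(f"{rid}: conflicting labels {labels[rid]!r} and {label!r}")
                continue
            if i_start is not None and i_end is not None and len(parts) > max(i_start, i_end):
                s_raw, e_raw = parts[i_start].strip(), parts[i_end].strip()
                if s_raw and e_raw:
                    s = _parse_coord(s_raw, line, annotation_path)
                    e = _parse_coord(e_raw, line, annotation_path)
                    segments.setdefault(rid, []).append((s, e))
    if errors:
        raise DatasetError(f"{annotation_path}: {len(errors)} bad annotation rows:\n  " + "\n  ".join(errors))
    examples = []
    for rid in order:
        examples.append(LabeledExample(records[rid], labels[rid], tuple(segments.get(rid, ()))))
    return examples


def write_labeled_dataset(examples: Sequence[LabeledExample], fasta_path, annotation_path) -> None:
    """Write examples as FASTA plus annotation TSV (inverse of `load_labeled_dataset`)."""
    write_fasta([ex.record for ex in examples], fasta_path)
    with open(annotation_path, "wt", encoding="utf-8") as fh:
        fh.write("id\tlabel\ttm_start\ttm_end\n")
        for ex in examples:
            if ex.segments:
                for s, e in ex.segments:
                    fh.write(f"{ex.record.id}\t{ex.label}\t{s}\t{e}\n")
            else:
                fh.write(f"{ex.record.id}\t{ex.label}\t\t\n")


_HEADER_TOKEN = re.compile(r"(?:^|[\s|_;,=\[\(])(TM|SP)(?:$|[\s|_;,\]\)])", re.IGNORECASE)


def sniff_supplementary(path) -> list[LabeledExample]:
    """Load a labeled dataset from a file of unknown dialect.

    Recognized dialects, tried in order:

    1. FASTA + sidecar annotation TSV at ``<path>.tsv`` (or the same
       basename with a ``.tsv`` extension);
    2. FASTA whose every header contains a TM/SP class token.

    Anything else raises a `DatasetError` asking for manual conversion
    to the FASTA + annotation-TSV format.
    """
    base, _ = os.path.splitext(str(path))
    for sidecar in (f"{path}.tsv", f"{base}.tsv"):
        if os.path.exists(sidecar) and os.path.abspath(sidecar) != os.path.abspath(str(path)):
            logger.info("%s: detected FASTA + sidecar annotation dialect (%s)", path, sidecar)
            return load_labeled_dataset(path, sidecar)
    try:
        records = read_fasta(path)
    except (DatasetError, UnicodeDecodeError, ValueError) as exc:
        raise DatasetError(
            f"{path}: unrecognized dataset dialect ({exc}); convert manually to FASTA + annotation TSV"
        ) from exc
    if not records:
        raise DatasetError(f"{path}: no FASTA records found; convert manually to FASTA + annotation TSV")
    examples = []
    for rec in records:
        m = _HEADER_TOKEN.search(rec.description) or _HEADER_TOKEN.search(rec.id)
        if m is None:
            raise DatasetError(
                f"{path}: header of {rec.id!r} carries no TM/SP class token; "
                "convert manually to FASTA + annotation TSV"
            )
        examples.append(LabeledExample(rec, m.group(1).upper()))
    logger.info("%s: detected FASTA-with-class-token dialect (%d records)", path, len(examples))
    return examples
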