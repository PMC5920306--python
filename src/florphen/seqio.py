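"""Reading and writing labelled protein alignments and result tables.

Sequences travel as aligned FASTA (gap ``-``); per-sequence metadata
(functional label, clade, species) travels in a tab-separated annotation
table with columns ``id``, ``label``, ``clade``, ``species``.  Labels record
experimentally confirmed effects on flowering time: *activator* (overexpression
accelerates flowering / knock-out delays it), *repressor* (the reverse),
*neutral* (no effect), or *unknown* (the proteins under test).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlignmentShapeError, AnnotationError, DuplicateIdError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"
ALPHABET = set(AMINO_ACIDS) | {GAP, MISSING}

LABELS = frozenset({"activator", "repressor", "neutral", "unknown"})
CLADES = frozenset({"FT", "TFL1", "MFT", "unknown"})


@dataclass
class LabeledAlignment:
    """Aligned amino-acid matrix with a functional label and clade per row.

    Rows are equal-length strings over the 20 amino-acid letters plus the gap
    symbol ``-`` and the missing-data symbol ``X``.
    """

    sequence_ids: list[str]
    rows: list[str]
    labels: dict[str, str]
    clades: dict[str, str]
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence_ids:
            raise AlignmentShapeError("alignment needs at least one sequence")
        if len(self.sequence_ids) != len(set(self.sequence_ids)):
            raise DuplicateIdError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal row lengths: {sorted(lengths)}")
        for sid in self.sequence_ids:
            if sid not in self.labels or sid not in self.clades:
                raise AnnotationError(f"missing label/clade for {sid!r}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    def row(self, sequence_id: str) -> str:
        try:
            return self.rows[self.sequence_ids.index(sequence_id)]
        except ValueError:
            raise KeyError(sequence_id) from None

    def members(self, clade: str | None = None,
                labels: Iterable[str] | None = None) -> list[str]:
        """Sequence ids filtered by clade and/or a set of functional labels."""
        wanted = set(labels) if labels is not None else None
        out = []
        for sid in self.sequence_ids:
            if clade is not None and self.clades[sid] != clade:
                continue
            if wanted is not None and self.labels[sid] not in wanted:
                continue
            out.append(sid)
        return out


def _normalize_residues(seq: str) -> tuple[str, int]:
    """Uppercase and map any non-standard letter (B, Z, J, U, O, ...) to 'X'."""
    seq = seq.upper()
    n_fixed = sum(1 for c in seq if c not in ALPHABET)
    if n_fixed:
        seq = "".join(c if c in ALPHABET else MISSING for c in seq)
    return seq, n_fixed


def read_labeled_alignment(fasta_path: str | Path,
                           annotation_path: str | Path) -> LabeledAlignment:
    """Read an aligned FASTA plus its TSV annotation into a LabeledAlignment.

    Ids are matched on the FASTA header token before the first whitespace.
    Annotation rows without a FASTA record are ignored with a warning; FASTA
    records without annotation are an error.
    """
    ids: list[str] = []
    rows: list[str] = []
    n_normalized = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in ids:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r}")
        seq, fixed = _normalize_residues(str(rec.seq))
        n_normalized += fixed
        ids.append(rec.id)
        rows.append(seq)
    if not ids:
        raise AnnotationError(f"no FASTA records in {fasta_path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"FASTA records are not aligned (lengths {sorted(lengths)})")
    if n_normalized:
        logger.info("normalized %d non-standard residue(s) to 'X'", n_normalized)

    labels: dict[str, str] = {}
    clades: dict[str, str] = {}
    species: dict[str, str] = {}
    with open(annotation_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "label", "clade", "species"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise AnnotationError(
                f"annotation must have columns {sorted(required)}")
        for line in reader:
            sid = line["id"]
            if sid in labels:
                raise DuplicateIdError(f"duplicate annotation id {sid!r}")
            if line["label"] not in LABELS:
                raise AnnotationError(f"unknown label {line['label']!r} for {sid!r}")
            if line["clade"] not in CLADES:
                raise AnnotationError(f"unknown clade {line['clade']!r} for {sid!r}")
            labels[sid] = line["label"]
            clades[sid] = line["clade"]
            species[sid] = line["species"]

    missing = [sid for sid in ids if sid not in labels]
    if missing:
        raise AnnotationError(f"no annotation for sequence id(s): {missing}")
    extra = set(labels) - set(ids)
    if extra:
        logger.warning("annotation rows without FASTA record ignored: %s",
                       sorted(extra))
    keep = set(ids)
    return LabeledAlignment(
        sequence_ids=ids,
        rows=rows,
        labels={k: v for k, v in labels.items() if k in keep},
        clades={k: v for k, v in clades.items() if k in keep},
        species={k: v for k, v in species.items() if k in keep},
    )


def write_labeled_alignment(aln: LabeledAlignment, fasta_path: str | Path,
                            annotation_path: str | Path) -> None:
    """Write the alignment back out as aligned FASTA + TSV annotation."""
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for sid, row in zip(aln.sequence_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")
    with open(annotation_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "label", "clade", "species"])
        for sid in aln.sequence_ids:
            writer.writerow([sid, aln.labels[sid], aln.clades[sid],
                             aln.species.get(sid, "")])


REPORT_COLUMNS = ["id", "clade", "direction", "in_score", "out_score",
                  "ratio", "cutoff", "call"]


def write_function_report(calls: Sequence, path: str | Path) -> None:
    """Serialize FunctionCall records to TSV, in input order.

    Columns: id, clade, direction, in_score, out_score, ratio, cutoff, call.
    """
    if not calls:
        raise ValueError("write_function_report: empty call list")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for c in calls:
            writer.writerow([
                c.query_id, c.clade, c.direction,
                f"{c.in_score:.6f}", f"{c.out_score:.6f}", f"{c.ratio:.6f}",
                f"{c.cutoff:.6f}", c.call,
            ])


def read_function_report(path: str | Path) -> list[dict]:
    """Read a function report TSV back as a list of dicts (floats parsed)."""
    out: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line in reader:
            rec = dict(line)
            for k in ("in_score", "out_score", "ratio", "cutoff"):
                rec[k] = float(rec[k])
            out.append(rec)
    return out
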