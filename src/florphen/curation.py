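"""Conserved-block curation of protein alignments.

Removes poorly conserved, gap-rich columns before consensus and prevalence
analysis, in the spirit of classic block-selection tools: columns are
classified by how dominant their most frequent residue is, long stretches of
nonconserved columns are discarded, and the surviving blocks are trimmed to
well-conserved flanks and required to meet a minimum length.  The original
column indices of every kept column are recorded so downstream positions can
be mapped back.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CurationEmptyError, ParamError
from .seqio import GAP, MISSING, LabeledAlignment


@dataclass
class CurationParams:
    """Block-selection thresholds.

    min_conserved_frac: fraction of sequences the top non-gap residue must
        reach for a column to count as conserved; ``None`` uses the classic
        "more than half" rule (floor(n/2)+1 sequences).
    min_flank_frac: stricter fraction a column must reach to serve as a block
        flank.
    max_nonconserved_run: longest run of nonconserved columns kept inside a
        block; longer runs are removed outright.
    min_block_len: shortest surviving block.
    allow_gaps: when False, any column containing a gap is nonconserved.
    """

    min_conserved_frac: float | None = None
    min_flank_frac: float = 0.85
    max_nonconserved_run: int = 8
    min_block_len: int = 10
    allow_gaps: bool = True

    def __post_init__(self) -> None:
        if self.min_conserved_frac is not None and not (
                0.5 < self.min_conserved_frac <= 1):
            raise ParamError("min_conserved_frac must lie in (0.5, 1]")
        if self.min_conserved_frac is not None and (
                self.min_flank_frac < self.min_conserved_frac):
            raise ParamError("min_flank_frac must be >= min_conserved_frac")
        if self.max_nonconserved_run < 1:
            raise ParamError("max_nonconserved_run must be positive")
        if self.min_block_len < 1:
            raise ParamError("min_block_len must be positive")


@dataclass
class CuratedAlignment:
    """A LabeledAlignment restricted to kept columns.

    kept_columns are strictly increasing 1-based indices into the original
    alignment.  Labels, clades and species are those of the base alignment.
    """

    base: LabeledAlignment
    kept_columns: list[int]
    rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            self.rows = [
                "".join(r[c - 1] for c in self.kept_columns)
                for r in self.base.rows
            ]

    @property
    def sequence_ids(self) -> list[str]:
        return self.base.sequence_ids

    @property
    def labels(self) -> dict[str, str]:
        return self.base.labels

    @property
    def clades(self) -> dict[str, str]:
        return self.base.clades

    @property
    def width(self) -> int:
        return len(self.kept_columns)

    def row(self, sequence_id: str) -> str:
        return self.rows[self.base.sequence_ids.index(sequence_id)]

    def members(self, clade=None, labels=None) -> list[str]:
        return self.base.members(clade=clade, labels=labels)

    @classmethod
    def identity(cls, aln: LabeledAlignment) -> "CuratedAlignment":
        """Wrap an externally curated alignment, keeping every column."""
        return cls(base=aln, kept_columns=list(range(1, aln.length + 1)))


def classify_column(column: str, params: CurationParams) -> str:
    """Classify one column as 'nc' (nonconserved), 'c', or 'hc' (flank-grade).

    The top *non-gap* residue count is compared with the conserved and flank
    thresholds; 'X' cells are missing data and count toward neither residue
    counts nor thresholds' numerator, but the thresholds are fractions of the
    full sequence count, as in the classic tool.
    """
    n = len(column)
    if not params.allow_gaps and GAP in column:
        return "nc"
    counts = Counter(c for c in column if c not in (GAP, MISSING))
    top = max(counts.values()) if counts else 0
    if params.min_conserved_frac is None:
        thr_c = n // 2 + 1
    else:
        thr_c = math.ceil(params.min_conserved_frac * n - 1e-9)
    thr_hc = math.ceil(params.min_flank_frac * n - 1e-9)
    if top >= thr_hc:
        return "hc"
    if top >= thr_c:
        return "c"
    return "nc"


def _select_blocks(classes: list[str], params: CurationParams) -> list[int]:
    """0-based indices surviving one curation pass over classified columns."""
    n = len(classes)
    removed = [False] * n
    # drop over-long nonconserved runs
    i = 0
    while i < n:
        if classes[i] == "nc":
            j = i
            while j < n and classes[j] == "nc":
                j += 1
            if j - i > params.max_nonconserved_run:
                for k in range(i, j):
                    removed[k] = True
            i = j
        else:
            i += 1
    # contiguous candidate blocks between removed stretches
    kept: list[int] = []
    i = 0
    while i < n:
        if removed[i]:
            i += 1
            continue
        j = i
        while j < n and not removed[j]:
            j += 1
        block = list(range(i, j))
        # trim to flank-grade columns on both ends
        while block and classes[block[0]] != "hc":
            block.pop(0)
        while block and classes[block[-1]] != "hc":
            block.pop()
        if len(block) >= params.min_block_len:
            kept.extend(block)
        i = j
    return kept


def curate_alignment(aln: LabeledAlignment,
                     params: CurationParams | None = None) -> CuratedAlignment:
    """Reduce an alignment to its well-conserved blocks.

    Idempotent: because every surviving block starts and ends with a
    flank-grade column and contains no over-long nonconserved run, re-curating
    the result with the same parameters keeps all columns.
    """
    params = params or CurationParams()
    if aln.length < params.min_block_len:
        raise CurationEmptyError(
            f"alignment length {aln.length} < min_block_len {params.min_block_len}")
    columns = ["".join(r[c] for r in aln.rows) for c in range(aln.length)]
    classes = [classify_column(col, params) for col in columns]
    kept0 = _select_blocks(classes, params)
    if not kept0:
        raise CurationEmptyError("no columns survive curation; relax parameters")
    return CuratedAlignment(base=aln, kept_columns=[c + 1 for c in kept0])


def map_position(cur: CuratedAlignment, curated_index: int) -> int:
    """Map a 1-based curated column index back to the original column."""
    if not 1 <= curated_index <= cur.width:
        raise IndexError(
            f"curated index {curated_index} outside [1, {cur.width}]")
    return cur.kept_columns[curated_index - 1]


def write_column_map(cur: CuratedAlignment, path: str | Path) -> None:
    """TSV with columns curated_index, original_index."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["curated_index", "original_index"])
        for i, c in enumerate(cur.kept_columns, start=1):
            writer.writerow([i, c])
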