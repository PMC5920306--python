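"""Single-residue Y/H diagnostic for FT/TFL1-family proteins.

One alignment position — tyrosine at Arabidopsis FT residue 85, histidine at
the homologous Arabidopsis TFL1 residue 88 — strongly associates with floral
activator vs repressor behaviour.  Given a reference sequence in the
alignment and its ungapped residue index, this module finds the alignment
column and reports the query's residue there with its interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curation import CuratedAlignment
from .seqio import GAP, LabeledAlignment

#: canonical reference positions
FT_ACTIVATOR_POSITION = 85   # Y in Arabidopsis FT
TFL1_REPRESSOR_POSITION = 88  # H in Arabidopsis TFL1


@dataclass
class DiagnosticReport:
    query_id: str
    reference_id: str
    reference_position: int   # 1-based ungapped index in the reference
    aligned_column: int       # 1-based alignment column
    reference_residue: str
    query_residue: str
    interpretation: str       # activator-like | repressor-like | other
    valid: bool               # reference residue matched the expected one


def _interpret(residue: str) -> str:
    if residue == "Y":
        return "activator-like"
    if residue == "H":
        return "repressor-like"
    return "other"


def locate_diagnostic_position(aln: LabeledAlignment | CuratedAlignment,
                               reference_id: str, reference_position: int,
                               query_id: str,
                               expected_residue: str | None = None,
                               ) -> DiagnosticReport:
    """Report the query residue at the reference's n-th ungapped position.

    Walks the reference row counting non-gap residues to find the alignment
    column of residue ``reference_position``, then reads the query's symbol
    at that column.  If ``expected_residue`` is given and the reference does
    not carry it there, the report is flagged invalid.  Deterministic and
    independent of all other sequences in the alignment.
    """
    ref_row = aln.row(reference_id)
    query_row = aln.row(query_id)
    seen = 0
    aligned_column = None
    for i, sym in enumerate(ref_row):
        if sym != GAP:
            seen += 1
            if seen == reference_position:
                aligned_column = i + 1
                break
    if aligned_column is None:
        raise IndexError(
            f"reference {reference_id!r} has only {seen} residues, "
            f"position {reference_position} requested")
    ref_res = ref_row[aligned_column - 1]
    query_res = query_row[aligned_column - 1]
    valid = expected_residue is None or ref_res == expected_residue
    return DiagnosticReport(
        query_id=query_id, reference_id=reference_id,
        reference_position=reference_position, aligned_column=aligned_column,
        reference_residue=ref_res, query_residue=query_res,
        interpretation=_interpret(query_res), valid=valid)
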