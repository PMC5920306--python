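"""Group consensus sequences, group-unique positions, and match fractions.

Within one clade (FT-like or TFL1-like), a consensus sequence is built for
each functional group (activators, repressors, flowering-neutral proteins).
Columns at which one group's consensus residue occurs in no other group's
consensus are that group's *unique positions*; a query of unknown function is
then scored by the fraction of those positions at which it carries exactly
the unique residue (e.g. 10/13 against an activator-unique set).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .curation import CuratedAlignment, map_position
from .errors import (AlignmentShapeError, EmptyUniqueSetError,
                     GroupTooSmallError)
from .seqio import AMINO_ACIDS, MISSING

#: symbol used where no residue holds a strict majority
NO_CONSENSUS = "."


@dataclass
class ConsensusSequence:
    group: str
    clade: str
    residues: str  # amino acids, '-', or NO_CONSENSUS; length = curated width


@dataclass
class UniquePositionSet:
    group: str
    clade: str
    #: sorted (1-based curated column, residue) pairs unique to this group
    positions: list[tuple[int, str]]


@dataclass
class MatchFraction:
    query_id: str
    group: str
    matches: int
    total: int

    def __post_init__(self) -> None:
        if self.matches > self.total:
            raise ValueError("matches > total")

    def __str__(self) -> str:
        return f"{self.query_id} vs {self.group}: {self.matches}/{self.total}"


def build_group_consensus(cur: CuratedAlignment, clade: str, group: str,
                          majority_frac: float = 0.5) -> ConsensusSequence:
    """Majority-rule consensus over the clade members of one functional group.

    At each column the symbol (gap counted as a symbol, 'X' cells ignored as
    missing data) held by a strict majority (> majority_frac of non-missing
    members) becomes the consensus; otherwise the column gets NO_CONSENSUS.
    """
    member_ids = cur.members(clade=clade, labels={group})
    if len(member_ids) < 2:
        raise GroupTooSmallError(
            f"{clade}/{group}: {len(member_ids)} member(s), need >= 2")
    rows = [cur.row(sid) for sid in member_ids]
    out = []
    for c in range(cur.width):
        counts = Counter(r[c] for r in rows if r[c] != MISSING)
        n = sum(counts.values())
        if n == 0:
            out.append(NO_CONSENSUS)
            continue
        sym, top = counts.most_common(1)[0]
        out.append(sym if top > majority_frac * n else NO_CONSENSUS)
    return ConsensusSequence(group=group, clade=clade, residues="".join(out))


def find_unique_positions(consensuses: Sequence[ConsensusSequence],
                          no_consensus_blocks: bool = False,
                          ) -> list[UniquePositionSet]:
    """Columns where one group's consensus residue occurs in no other group's.

    Only standard amino-acid residues can be unique (gap and NO_CONSENSUS in
    the focal group never are).  A gap or NO_CONSENSUS in *another* group
    counts as "the residue does not occur there" and so does not block
    uniqueness; set ``no_consensus_blocks=True`` to make a NO_CONSENSUS column
    in any other group disqualify the position (the stricter reading, since a
    majority-free group may still contain the residue).
    """
    if len(consensuses) < 2:
        raise ValueError("need at least two consensus sequences")
    lengths = {len(c.residues) for c in consensuses}
    if len(lengths) != 1:
        raise AlignmentShapeError("consensus length mismatch")
    clades = {c.clade for c in consensuses}
    if len(clades) != 1:
        raise AlignmentShapeError("consensuses from different clades")
    width = lengths.pop()
    out = []
    for focal in consensuses:
        others = [c for c in consensuses if c is not focal]
        positions: list[tuple[int, str]] = []
        for col in range(width):
            res = focal.residues[col]
            if res not in AMINO_ACIDS:
                continue
            blocked = False
            for o in others:
                other_res = o.residues[col]
                if other_res == res:
                    blocked = True
                elif no_consensus_blocks and other_res == NO_CONSENSUS:
                    blocked = True
            if not blocked:
                positions.append((col + 1, res))
        out.append(UniquePositionSet(group=focal.group, clade=focal.clade,
                                     positions=positions))
    return out


def match_fraction(query_id: str, cur: CuratedAlignment,
                   ups: UniquePositionSet) -> MatchFraction:
    """Fraction of a group's unique positions at which the query matches.

    'X' cells in the query count toward the denominator but never match.
    """
    if not ups.positions:
        raise EmptyUniqueSetError(f"no unique positions for group {ups.group!r}")
    row = cur.row(query_id)
    matches = sum(1 for col, res in ups.positions if row[col - 1] == res)
    return MatchFraction(query_id=query_id, group=ups.group,
                         matches=matches, total=len(ups.positions))


def write_unique_positions(sets: Sequence[UniquePositionSet],
                           cur: CuratedAlignment, path: str | Path) -> None:
    """TSV: group, curated_column, original_column, residue."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group", "curated_column", "original_column", "residue"])
        for ups in sets:
            for col, res in ups.positions:
                writer.writerow([ups.group, col, map_position(cur, col), res])
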