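"""Prevalence-based activator/repressor ratio scoring and classification.

The core statistic: for a clade (FT-like or TFL1-like) and a direction
(activator or repressor), two per-column residue-prevalence profiles are
built — one from the group with the focal confirmed function (the in-group),
one from confirmed proteins of the complementary function(s) (the
out-group).  A query sequence receives at every curated column the frequency
of its residue in each profile (1 if the residue occurs in every group
member, 0 if in none); the column values are averaged into an in-score and
an out-score, and their quotient is the *activator ratio* (or *repressor
ratio*).  A cut-off on the ratio is calibrated empirically so that no known
non-member is called a member, with the fewest possible misses of known
members; queries at or above the cut-off are called members.

`FunctionScoreModel` wraps the procedure statsmodels-style: build it from a
curated labelled alignment, `fit()` computes leave-one-out ratios for every
sequence of confirmed function, the class means and their two-sample test,
and the calibrated cut-off; the returned `FunctionScoreResults` classifies
queries and prints a summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .curation import CuratedAlignment
from .errors import (CalibrationImpossibleError, DivisionByZeroScoreError,
                     GroupTooSmallError, NoScorableColumnsError)
from .seqio import MISSING

KNOWN_LABELS = ("activator", "repressor", "neutral")


def direction_labels(direction: str) -> tuple[set[str], set[str]]:
    """In-group / out-group label sets for a scoring direction.

    Non-members are the confirmed proteins of the same clade that do not have
    the focal function: for the activator direction the out-group is
    {repressor, neutral}, and symmetrically for the repressor direction.
    Unknown-function sequences belong to neither profile.
    """
    if direction not in ("activator", "repressor"):
        raise ValueError(f"direction must be activator|repressor, got {direction!r}")
    in_labels = {direction}
    out_labels = set(KNOWN_LABELS) - in_labels
    return in_labels, out_labels


@dataclass
class PrevalenceProfile:
    """Per-column relative frequency of each symbol within a functional group.

    Gap '-' is an ordinary symbol; 'X' cells are missing data and excluded
    from the column denominator.  A column where every member is missing has
    an empty table entry and is unscorable.
    """

    labels: frozenset
    clade: str
    member_ids: list[str]
    table: list[dict[str, float]]

    @property
    def width(self) -> int:
        return len(self.table)


@dataclass
class RatioScore:
    query_id: str
    clade: str
    direction: str
    in_score: float
    out_score: float
    ratio: float
    n_columns_used: int


@dataclass
class FunctionCall:
    query_id: str
    clade: str
    direction: str
    in_score: float
    out_score: float
    ratio: float
    cutoff: float
    call: str  # member | non-member


def build_prevalence_profile(cur: CuratedAlignment, clade: str,
                             labels: Iterable[str],
                             exclude_ids: Iterable[str] = ()) -> PrevalenceProfile:
    """Column-wise symbol frequencies among the clade members with the labels."""
    labels = frozenset(labels)
    exclude = set(exclude_ids)
    member_ids = [sid for sid in cur.members(clade=clade, labels=labels)
                  if sid not in exclude]
    if len(member_ids) < 2:
        raise GroupTooSmallError(
            f"{clade}/{sorted(labels)}: {len(member_ids)} member(s), need >= 2")
    rows = [cur.row(sid) for sid in member_ids]
    table: list[dict[str, float]] = []
    for c in range(cur.width):
        counts: dict[str, int] = {}
        for r in rows:
            sym = r[c]
            if sym != MISSING:
                counts[sym] = counts.get(sym, 0) + 1
        denom = sum(counts.values())
        table.append({s: k / denom for s, k in counts.items()} if denom else {})
    return PrevalenceProfile(labels=labels, clade=clade,
                             member_ids=member_ids, table=table)


def _scorable_columns(row: str, profiles: Sequence[PrevalenceProfile]) -> list[int]:
    return [c for c in range(len(row))
            if row[c] != MISSING and all(p.table[c] for p in profiles)]


def _score_over(row: str, profile: PrevalenceProfile, cols: Sequence[int]) -> float:
    return sum(profile.table[c].get(row[c], 0.0) for c in cols) / len(cols)


def score_sequence(query_id: str, cur: CuratedAlignment,
                   profile: PrevalenceProfile) -> tuple[float, int]:
    """Mean prevalence of the query's residues under one profile.

    Columns where the query holds 'X' (or the profile is empty) are excluded
    from the mean; an unobserved residue scores 0.  Returns (score, n_used).
    """
    row = cur.row(query_id)
    cols = _scorable_columns(row, [profile])
    if not cols:
        raise NoScorableColumnsError(query_id)
    return _score_over(row, profile, cols), len(cols)


def compute_ratio(query_id: str, cur: CuratedAlignment,
                  in_profile: PrevalenceProfile,
                  out_profile: PrevalenceProfile,
                  leave_one_out: bool = True,
                  direction: str | None = None) -> RatioScore:
    """In-score / out-score ratio for one query.

    With leave-one-out on (default), a sequence never contributes to a
    profile it is scored against: if the query is a member of either profile
    that profile is rebuilt without it.  Both scores are averaged over the
    same column set (query non-missing, both profiles non-empty).
    """
    if in_profile.clade != out_profile.clade:
        raise ValueError("profiles from different clades")
    if in_profile.width != out_profile.width:
        raise ValueError("profile width mismatch")
    if leave_one_out:
        if query_id in in_profile.member_ids:
            in_profile = build_prevalence_profile(
                cur, in_profile.clade, in_profile.labels, exclude_ids={query_id})
        if query_id in out_profile.member_ids:
            out_profile = build_prevalence_profile(
                cur, out_profile.clade, out_profile.labels, exclude_ids={query_id})
    row = cur.row(query_id)
    cols = _scorable_columns(row, [in_profile, out_profile])
    if not cols:
        raise NoScorableColumnsError(query_id)
    in_score = _score_over(row, in_profile, cols)
    out_score = _score_over(row, out_profile, cols)
    if out_score == 0:
        raise DivisionByZeroScoreError(
            f"out-group score is 0 for {query_id!r}")
    return RatioScore(query_id=query_id, clade=in_profile.clade,
                      direction=direction or "|".join(sorted(in_profile.labels)),
                      in_score=in_score, out_score=out_score,
                      ratio=in_score / out_score, n_columns_used=len(cols))


def group_mean_ratios(cur: CuratedAlignment, clade: str, direction: str,
                      leave_one_out: bool = True):
    """Mean ratio of known members vs known non-members, with a test.

    Returns (member_mean, nonmember_mean, TestResult, ratios) where ratios
    maps sequence id -> RatioScore for every confirmed-function sequence in
    the clade.  The class difference is tested with the normality/equal-
    variance-gated two-sample comparison (two-sided).
    """
    from .qpcr import compare_groups  # local import avoids a module cycle

    in_labels, out_labels = direction_labels(direction)
    members = cur.members(clade=clade, labels=in_labels)
    nonmembers = cur.members(clade=clade, labels=out_labels)
    if len(members) < 2 or len(nonmembers) < 2:
        raise GroupTooSmallError(
            f"{clade}/{direction}: need >=2 members and >=2 non-members")
    in_profile = build_prevalence_profile(cur, clade, in_labels)
    out_profile = build_prevalence_profile(cur, clade, out_labels)
    ratios = {}
    for sid in members + nonmembers:
        ratios[sid] = compute_ratio(sid, cur, in_profile, out_profile,
                                    leave_one_out=leave_one_out,
                                    direction=direction)
    mvals = [ratios[s].ratio for s in members]
    nvals = [ratios[s].ratio for s in nonmembers]
    test = compare_groups(mvals, nvals, direction=None)
    return (sum(mvals) / len(mvals), sum(nvals) / len(nvals), test, ratios)


def calibrate_cutoff(labeled_ratios: Sequence[tuple[float, bool]],
                     granularity: float = 0.01) -> float:
    """Smallest grid cut-off with zero false member calls.

    The cut-off is the smallest multiple of ``granularity`` strictly greater
    than every non-member ratio; with the inclusive decision rule
    (ratio >= cutoff -> member) this yields zero known non-members called
    member and the fewest possible known members called non-member under
    that constraint.
    """
    members = [r for r, is_m in labeled_ratios if is_m]
    nonmembers = [r for r, is_m in labeled_ratios if not is_m]
    if not members or not nonmembers:
        raise ValueError("need both member and non-member ratios")
    if max(members) < min(nonmembers):
        raise CalibrationImpossibleError(
            "every member ratio lies below every non-member ratio")
    top_nonmember = max(nonmembers)
    k = math.floor(top_nonmember / granularity + 1e-9) + 1
    return round(k * granularity, 10)


def classify(ratio_score: RatioScore, cutoff: float) -> FunctionCall:
    """Member iff ratio >= cutoff (inclusive boundary)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return FunctionCall(
        query_id=ratio_score.query_id, clade=ratio_score.clade,
        direction=ratio_score.direction, in_score=ratio_score.in_score,
        out_score=ratio_score.out_score, ratio=ratio_score.ratio,
        cutoff=cutoff, call="member" if ratio_score.ratio >= cutoff
        else "non-member")


class FunctionScoreModel:
    """Prevalence-ratio classifier for one clade and direction.

    Parameters
    ----------
    curated : CuratedAlignment
        Curated labelled alignment; confirmed-function sequences of the given
        clade form the training classes, unknown-function sequences are
        queries.
    clade : str
        'FT' or 'TFL1'.
    direction : str
        'activator' or 'repressor' — which function membership is scored.
    leave_one_out : bool
        Exclude each known sequence from any profile it is scored against.
    granularity : float
        Grid step of the cut-off calibration.
    """

    def __init__(self, curated: CuratedAlignment, clade: str, direction: str,
                 leave_one_out: bool = True, granularity: float = 0.01):
        direction_labels(direction)  # validates
        self.curated = curated
        self.clade = clade
        self.direction = direction
        self.leave_one_out = leave_one_out
        self.granularity = granularity

    def fit(self) -> "FunctionScoreResults":
        member_mean, nonmember_mean, test, ratios = group_mean_ratios(
            self.curated, self.clade, self.direction,
            leave_one_out=self.leave_one_out)
        in_labels, _ = direction_labels(self.direction)
        labeled = [(rs.ratio, self.curated.labels[sid] in in_labels)
                   for sid, rs in ratios.items()]
        cutoff = calibrate_cutoff(labeled, granularity=self.granularity)
        return FunctionScoreResults(
            model=self, ratios=ratios, member_mean=member_mean,
            nonmember_mean=nonmember_mean, test=test, cutoff=cutoff)


@dataclass
class FunctionScoreResults:
    """Fitted ratios, class means, their test, and the calibrated cut-off."""

    model: FunctionScoreModel
    ratios: dict[str, RatioScore]
    member_mean: float
    nonmember_mean: float
    test: "object"
    cutoff: float

    def score_query(self, query_id: str) -> RatioScore:
        m = self.model
        in_labels, out_labels = direction_labels(m.direction)
        in_profile = build_prevalence_profile(m.curated, m.clade, in_labels)
        out_profile = build_prevalence_profile(m.curated, m.clade, out_labels)
        return compute_ratio(query_id, m.curated, in_profile, out_profile,
                             leave_one_out=m.leave_one_out,
                             direction=m.direction)

    def classify_query(self, query_id: str) -> FunctionCall:
        return classify(self.score_query(query_id), self.cutoff)

    def training_calls(self) -> list[FunctionCall]:
        return [classify(rs, self.cutoff) for rs in self.ratios.values()]

    def training_accuracy(self) -> float:
        """Fraction of confirmed-function sequences called correctly
        (leave-one-out ratios against the calibrated cut-off)."""
        in_labels, _ = direction_labels(self.model.direction)
        correct = 0
        for sid, rs in self.ratios.items():
            truth = self.model.curated.labels[sid] in in_labels
            called = rs.ratio >= self.cutoff
            correct += truth == called
        return correct / len(self.ratios)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"{m.direction.capitalize()} ratio model — clade {m.clade}",
            "=" * 46,
            f"sequences scored:        {len(self.ratios)}",
            f"mean ratio, members:     {self.member_mean:.4f}",
            f"mean ratio, non-members: {self.nonmember_mean:.4f}",
            f"class test:              {self.test.method}, "
            f"p = {self.test.p_value:.4g}",
            f"calibrated cut-off:      {self.cutoff:.2f}",
            f"training accuracy:       {self.training_accuracy():.3f}",
            "-" * 46,
            f"{'id':<20}{'ratio':>8}  {'label':<10}{'call':<10}",
        ]
        for sid, rs in self.ratios.items():
            call = "member" if rs.ratio >= self.cutoff else "non-member"
            lines.append(f"{sid:<20}{rs.ratio:>8.3f}  "
                         f"{m.curated.labels[sid]:<10}{call:<10}")
        return "\n".join(lines)
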