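"""qPCR mean normalized expression (MNE) and reference-gene stability.

Expression of a target gene in one sample is quantified relative to a
reference gene from cycle-threshold (Ct) values:

    MNE = E_ref ** mean(Ct_ref) / E_target ** mean(Ct_target)

where E is the amplification efficiency (fold amplification per cycle,
2.0 for perfect doubling) and the means are over technical replicates on
the Ct scale.  MNEs of biological replicates are averaged into the
'average relative expression' with its standard error; candidate reference
genes are ranked by the stability (mean SE) of the resulting expression
values; and two-group comparisons are routed to a one-tailed t-test when
normality and equal variance hold, else to the Mann-Whitney U test.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import EmptyGroupError, SampleMismatchError
from .phenology import TestResult, mann_whitney_u

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05
EQUAL_VARIANCE_ALPHA = 0.05


@dataclass
class CtSample:
    """Technical-replicate Ct values for one gene in one sample."""
    sample_id: str
    group: str
    gene: str
    technical_cts: list[float]

    def __post_init__(self) -> None:
        finite = [c for c in self.technical_cts if math.isfinite(c)]
        if not finite:
            raise ValueError(f"{self.sample_id}/{self.gene}: no finite Ct")
        if any(c <= 0 for c in finite):
            raise ValueError(f"{self.sample_id}/{self.gene}: Ct must be > 0")

    @property
    def mean_ct(self) -> float:
        finite = [c for c in self.technical_cts if math.isfinite(c)]
        return sum(finite) / len(finite)


@dataclass
class MNEValue:
    sample_id: str
    target: str
    reference: str
    mne: float
    efficiency_target: float
    efficiency_ref: float


@dataclass
class ExpressionSummary:
    group: str
    target: str
    reference: str
    average_relative_expression: float
    se: float
    n: int


def mean_normalized_expression(target: CtSample, reference: CtSample,
                               eff_target: float = 2.0,
                               eff_ref: float = 2.0) -> MNEValue:
    """MNE of one target/reference pair in one sample."""
    if target.sample_id != reference.sample_id:
        raise SampleMismatchError(
            f"target sample {target.sample_id!r} != "
            f"reference sample {reference.sample_id!r}")
    for name, eff in (("eff_target", eff_target), ("eff_ref", eff_ref)):
        if not (1.0 < eff <= 2.0):
            raise ValueError(f"{name} must lie in (1, 2], got {eff}")
    mne = eff_ref ** reference.mean_ct / eff_target ** target.mean_ct
    return MNEValue(sample_id=target.sample_id, target=target.gene,
                    reference=reference.gene, mne=mne,
                    efficiency_target=eff_target, efficiency_ref=eff_ref)


def average_relative_expression(mnes: Sequence[MNEValue],
                                group: str) -> ExpressionSummary:
    """Mean and SE of biological-replicate MNEs for one group.

    A single replicate gets SE = 0 by convention, with a warning.
    """
    if not mnes:
        raise EmptyGroupError(f"no MNE values for group {group!r}")
    targets = {m.target for m in mnes}
    refs = {m.reference for m in mnes}
    if len(targets) != 1 or len(refs) != 1:
        raise SampleMismatchError(
            f"mixed target/reference genes in group {group!r}")
    values = np.array([m.mne for m in mnes], float)
    n = len(values)
    if n == 1:
        logger.warning("group %r has a single biological replicate; SE set to 0",
                       group)
        se = 0.0
    else:
        se = float(values.std(ddof=1) / math.sqrt(n))
    return ExpressionSummary(group=group, target=targets.pop(),
                             reference=refs.pop(),
                             average_relative_expression=float(values.mean()),
                             se=se, n=n)


def reference_stability(
        summaries: Mapping[str, Sequence[ExpressionSummary]],
        ) -> list[tuple[str, float]]:
    """Rank candidate reference genes by mean SE across groups, ascending.

    ``summaries`` maps each candidate reference gene to the per-group
    expression summaries computed against it; all candidates must cover the
    same groups.  Ties are broken alphabetically.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two candidate reference genes")
    group_sets = {ref: tuple(sorted(s.group for s in ss))
                  for ref, ss in summaries.items()}
    if len(set(group_sets.values())) != 1:
        raise SampleMismatchError(
            f"candidate references cover different groups: {group_sets}")
    ranked = [(ref, float(np.mean([s.se for s in ss])))
              for ref, ss in summaries.items()]
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked


def compare_groups(a: Sequence[float], b: Sequence[float],
                   direction: str | None) -> TestResult:
    """Two-sample comparison with the normality / equal-variance gate.

    If both groups pass Shapiro-Wilk normality and (median-centred) Levene
    equal-variance checks at alpha 0.05, a two-sample t-test is used;
    otherwise the Mann-Whitney U test.  ``direction`` is 'greater' (a > b),
    'less', or None for two-sided.  Identical constant groups are degenerate
    and return p = 1.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two observations")
    alternative = {None: "two-sided", "greater": "greater",
                   "less": "less"}[direction]
    if max(a + b) == min(a + b):
        return TestResult(statistic=0.0, p_value=1.0, n_a=len(a), n_b=len(b),
                          method="degenerate (constant data)", degenerate=True)
    parametric = True
    for sample in (a, b):
        if len(set(sample)) == 1 or len(sample) < 3:
            parametric = False
            break
        if stats.shapiro(sample).pvalue < NORMALITY_ALPHA:
            parametric = False
            break
    if parametric:
        if stats.levene(a, b, center="median").pvalue < EQUAL_VARIANCE_ALPHA:
            parametric = False
    if parametric:
        res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
        return TestResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          n_a=len(a), n_b=len(b), method="t-test")
    return mann_whitney_u(a, b, alternative=alternative)


def read_ct_table(path: str | Path) -> list[CtSample]:
    """Read a Ct TSV with columns sample_id, group, gene, ct1, ct2, ct3."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line in reader:
            cts = [float(line[k]) for k in ("ct1", "ct2", "ct3")
                   if line.get(k) not in ("", None)]
            out.append(CtSample(sample_id=line["sample_id"],
                                group=line["group"], gene=line["gene"],
                                technical_cts=cts))
    return out


def write_ct_table(samples: Sequence[CtSample], path: str | Path) -> None:
    n_tech = max(len(s.technical_cts) for s in samples)
    cols = ["sample_id", "group", "gene"] + [f"ct{i+1}" for i in range(n_tech)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for s in samples:
            cts = [f"{c:.4f}" for c in s.technical_cts]
            cts += [""] * (n_tech - len(cts))
            writer.writerow([s.sample_id, s.group, s.gene] + cts)


def mne_table(samples: Sequence[CtSample], target: str, reference: str,
              eff_target: float = 2.0, eff_ref: float = 2.0,
              ) -> list[tuple[str, MNEValue]]:
    """MNE per sample for one target/reference pair, with the sample's group.

    Samples lacking either gene are skipped with a warning.
    """
    by_sample: dict[str, dict[str, CtSample]] = {}
    groups: dict[str, str] = {}
    for s in samples:
        by_sample.setdefault(s.sample_id, {})[s.gene] = s
        groups[s.sample_id] = s.group
    out = []
    for sid, genes in by_sample.items():
        if target not in genes or reference not in genes:
            logger.warning("sample %r lacks %s or %s; skipped", sid, target,
                           reference)
            continue
        out.append((groups[sid],
                    mean_normalized_expression(genes[target], genes[reference],
                                               eff_target, eff_ref)))
    return out


def summarize_expression(samples: Sequence[CtSample], target: str,
                         reference: str, eff_target: float = 2.0,
                         eff_ref: float = 2.0) -> list[ExpressionSummary]:
    """Average relative expression per group for one target/reference pair."""
    per_group: dict[str, list[MNEValue]] = {}
    for group, mne in mne_table(samples, target, reference, eff_target, eff_ref):
        per_group.setdefault(group, []).append(mne)
    return [average_relative_expression(mnes, group)
            for group, mnes in sorted(per_group.items())]
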