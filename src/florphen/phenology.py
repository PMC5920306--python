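"""Flowering-phenology phases, rank tests, dominance, reproductive output.

Plants are inspected daily for three events: appearance of the main male
inflorescence bud, first pollen release, and first fully elongated pistil.
These define three phases — vegetative-male initiation (germination to male
bud), male maturation (bud to first pollen), vegetative-female maturation
(germination to first pistil) — and the degree of dichogamy (days between
first mature male and first mature female flower; negative when the pistil
comes first).  Group comparisons use the Mann-Whitney U test with midranks,
significance-coded after Bonferroni correction of the per-comparison alpha.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataConsistencyError, MissingEventError

#: number of group-per-group rank assignments enumerated exactly
EXACT_ENUMERATION_LIMIT = 8

SIG_LEVELS = (0.05, 0.01, 0.001)
SIG_CODES = {0.05: "*", 0.01: "**", 0.001: "***"}


@dataclass
class PhenologyRecord:
    plant_id: str
    population: str  # native | invasive | F1 (free text allowed)
    day_male_bud: int | None = None
    day_first_pollen: int | None = None
    day_first_pistil: int | None = None
    n_fruits: int | None = None
    total_fruit_weight_mg: float | None = None
    exclude_female_only: bool = False


@dataclass
class PhaseLengths:
    """Phase lengths in days; dichogamy may be negative."""
    veg_male_init: float      # ♂1: germination -> male bud
    male_maturation: float    # ♂2: male bud -> first pollen
    veg_female_maturation: float  # ♀: germination -> first pistil
    dichogamy: float          # ♀ - (♂1 + ♂2)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str
    adjusted_alpha: float | None = None
    significance_code: str | None = None
    degenerate: bool = False


@dataclass
class DominanceCall:
    trait: str
    verdict: str
    p_vs_early: float
    p_vs_late: float
    code_vs_early: str
    code_vs_late: str


def phase_lengths(rec: PhenologyRecord) -> PhaseLengths:
    """Split one plant's event days into the three phases and dichogamy."""
    for name in ("day_male_bud", "day_first_pollen", "day_first_pistil"):
        if getattr(rec, name) is None:
            raise MissingEventError(f"{rec.plant_id}: missing {name}")
    m1 = rec.day_male_bud
    m2 = rec.day_first_pollen - rec.day_male_bud
    f = rec.day_first_pistil
    return PhaseLengths(veg_male_init=m1, male_maturation=m2,
                        veg_female_maturation=f,
                        dichogamy=f - rec.day_first_pollen)


def _u_from_ranks(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, bool]:
    """(U_a, U_b, has_ties) from midranks of the pooled sample."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2
    u_b = n_a * n_b - u_a
    has_ties = len(np.unique(pooled)) < len(pooled)
    return u_a, u_b, has_ties


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U with midranks; exact p for small untied samples.

    The p-value is exact (full enumeration of the U null distribution) when
    both samples have at most EXACT_ENUMERATION_LIMIT observations and there
    are no ties; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    u_a, _, has_ties = _u_from_ranks(a, b)
    pooled = a + b
    if max(pooled) == min(pooled):
        # all observations identical: no evidence either way
        return TestResult(statistic=u_a, p_value=1.0, n_a=len(a), n_b=len(b),
                          method="mann-whitney (degenerate)", degenerate=True)
    exact = (not has_ties and len(a) <= EXACT_ENUMERATION_LIMIT
             and len(b) <= EXACT_ENUMERATION_LIMIT)
    res = stats.mannwhitneyu(a, b, alternative=alternative,
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    method = "mann-whitney (exact)" if exact else "mann-whitney (asymptotic)"
    return TestResult(statistic=float(res.statistic),
                      p_value=min(1.0, float(res.pvalue)),
                      n_a=len(a), n_b=len(b), method=method)


def bonferroni_gate(p: float, m: int,
                    alpha_levels: Sequence[float] = SIG_LEVELS) -> str:
    """Significance code at Bonferroni-corrected per-comparison alphas.

    Returns the strongest code among ns/*/**/*** for which p < alpha/m.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    code = "ns"
    for alpha in sorted(alpha_levels, reverse=True):
        if p < alpha / m:
            code = SIG_CODES[alpha]
    return code


def gated_mann_whitney(a: Sequence[float], b: Sequence[float], m: int,
                       alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U annotated with the m-corrected significance code."""
    res = mann_whitney_u(a, b, alternative=alternative)
    res.adjusted_alpha = 0.05 / m
    res.significance_code = bonferroni_gate(res.p_value, m)
    return res


def dominance_assessment(parent_early: Sequence[float],
                         parent_late: Sequence[float],
                         f1: Sequence[float], m: int = 12,
                         trait: str = "") -> DominanceCall:
    """Classify F1 inheritance of a trait from tests against both parents.

    "Equal to a parent" means failing to reject (ns after Bonferroni gating
    with the given m); "different" means any gated rejection.  Verdicts:

    - equal to the early parent, different from the late -> dominant-early
    - equal to the late parent, different from the early -> dominant-late
    - different from both, F1 mean between the parents    -> additive
    - different from both, F1 mean beyond the early/late  -> overdominant-early/-late
    - otherwise (e.g. equal to both)                      -> inconclusive
    """
    t_early = gated_mann_whitney(f1, parent_early, m)
    t_late = gated_mann_whitney(f1, parent_late, m)
    eq_early = t_early.significance_code == "ns"
    eq_late = t_late.significance_code == "ns"
    mean_f1 = float(np.mean(f1))
    mean_early = float(np.mean(parent_early))
    mean_late = float(np.mean(parent_late))
    if eq_early and not eq_late:
        verdict = "dominant-early"
    elif eq_late and not eq_early:
        verdict = "dominant-late"
    elif not eq_early and not eq_late:
        lo, hi = sorted([mean_early, mean_late])
        if lo < mean_f1 < hi:
            verdict = "additive"
        elif mean_f1 <= mean_early:
            verdict = "overdominant-early"
        elif mean_f1 >= mean_late:
            verdict = "overdominant-late"
        else:  # pragma: no cover - exhaustive above
            verdict = "inconclusive"
    else:
        verdict = "inconclusive"
    return DominanceCall(trait=trait, verdict=verdict,
                         p_vs_early=t_early.p_value, p_vs_late=t_late.p_value,
                         code_vs_early=t_early.significance_code,
                         code_vs_late=t_late.significance_code)


@dataclass
class ReproductiveSummary:
    populations: list[str]
    mean_fruits: dict[str, float]
    mean_fruit_weight_mg: dict[str, float]
    percent_reduction_fruits: float  # second population relative to the first
    fruit_test: TestResult
    weight_test: TestResult


def reproductive_output_summary(records: Sequence[PhenologyRecord],
                                reference_population: str | None = None,
                                m: int = 17) -> ReproductiveSummary:
    """Per-population fruit counts and weights, with gated comparisons.

    Mean individual fruit weight is total weight / fruit count per plant,
    averaged within each population.  Percent reduction is
    100 * (1 - mean_other / mean_reference) on fruit counts; the reference
    population defaults to 'native' when present, else the first seen.
    Comparisons use the normality/equal-variance-gated two-sample test with
    Bonferroni gating at the given m.
    """
    from .qpcr import compare_groups  # deferred: avoids import cycle

    by_pop: dict[str, list[PhenologyRecord]] = {}
    for rec in records:
        if rec.n_fruits is None or rec.total_fruit_weight_mg is None:
            raise MissingEventError(f"{rec.plant_id}: missing fruit data")
        if rec.n_fruits == 0 and rec.total_fruit_weight_mg > 0:
            raise DataConsistencyError(
                f"{rec.plant_id}: zero fruits with nonzero weight")
        by_pop.setdefault(rec.population, []).append(rec)
    pops = list(by_pop)
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {pops}")
    if reference_population is None:
        reference_population = "native" if "native" in by_pop else pops[0]
    other = next(p for p in pops if p != reference_population)
    pops = [reference_population, other]

    mean_fruits = {}
    mean_weight = {}
    fruit_lists = {}
    weight_lists = {}
    for pop in pops:
        counts = [r.n_fruits for r in by_pop[pop]]
        weights = [r.total_fruit_weight_mg / r.n_fruits
                   for r in by_pop[pop] if r.n_fruits > 0]
        mean_fruits[pop] = float(np.mean(counts))
        mean_weight[pop] = float(np.mean(weights)) if weights else math.nan
        fruit_lists[pop] = counts
        weight_lists[pop] = weights

    reduction = 100.0 * (1.0 - mean_fruits[other] / mean_fruits[reference_population])
    fruit_test = compare_groups(fruit_lists[reference_population],
                                fruit_lists[other], direction=None)
    fruit_test.adjusted_alpha = 0.05 / m
    fruit_test.significance_code = bonferroni_gate(fruit_test.p_value, m)
    weight_test = compare_groups(weight_lists[reference_population],
                                 weight_lists[other], direction=None)
    weight_test.adjusted_alpha = 0.05 / m
    weight_test.significance_code = bonferroni_gate(weight_test.p_value, m)
    return ReproductiveSummary(
        populations=pops, mean_fruits=mean_fruits,
        mean_fruit_weight_mg=mean_weight,
        percent_reduction_fruits=reduction,
        fruit_test=fruit_test, weight_test=weight_test)


PHENO_COLUMNS = ["plant_id", "population", "day_male_bud", "day_first_pollen",
                 "day_first_pistil", "n_fruits", "total_fruit_weight_mg"]


def read_phenology_table(path: str | Path) -> list[PhenologyRecord]:
    """Read the phenology TSV (missing optional fields left blank)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line in reader:
            def _int(key):
                v = line.get(key, "")
                return int(v) if v not in ("", None) else None

            def _float(key):
                v = line.get(key, "")
                return float(v) if v not in ("", None) else None

            out.append(PhenologyRecord(
                plant_id=line["plant_id"], population=line["population"],
                day_male_bud=_int("day_male_bud"),
                day_first_pollen=_int("day_first_pollen"),
                day_first_pistil=_int("day_first_pistil"),
                n_fruits=_int("n_fruits"),
                total_fruit_weight_mg=_float("total_fruit_weight_mg")))
    return out


def write_phenology_table(records: Sequence[PhenologyRecord],
                          path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PHENO_COLUMNS)
        for r in records:
            writer.writerow([
                r.plant_id, r.population,
                "" if r.day_male_bud is None else r.day_male_bud,
                "" if r.day_first_pollen is None else r.day_first_pollen,
                "" if r.day_first_pistil is None else r.day_first_pistil,
                "" if r.n_fruits is None else r.n_fruits,
                "" if r.total_fruit_weight_mg is None
                else f"{r.total_fruit_weight_mg:.3f}"])
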