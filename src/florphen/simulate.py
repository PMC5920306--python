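"""Seeded synthetic-data generators for every pipeline stage.

Three generators emulate the statistical structure of the pipeline's
inputs so every stage runs and is testable without any downloads:

- a multi-group protein family with group-diagnostic residues planted at
  known columns (the ground truth is returned alongside the alignment);
- qPCR Ct tables with biological and technical noise around per-group true
  expression levels;
- flowering-phenology cohorts whose default means are those reported for
  native and invasive common-ragweed populations, with negative-binomial
  fruit counts.

All generators are pure functions of their parameter object (which carries
the seed): the same parameters always produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParamError
from .phenology import PhenologyRecord
from .qpcr import CtSample
from .seqio import AMINO_ACIDS, GAP, MISSING, LabeledAlignment


def _default_groups() -> dict[str, int]:
    return {"activator": 15, "repressor": 15, "neutral": 15}


@dataclass
class FamilySimParams:
    """Parameters of the planted-signal protein-family generator.

    Each functional group owns ``n_signal_columns`` columns (disjoint across
    groups) at which its members carry a group-specific residue with
    probability ``signal_fidelity``; all other cells are background draws.
    Gaps and missing-data 'X' are sprinkled uniformly afterwards.
    """

    n_per_group: dict[str, int] = field(default_factory=_default_groups)
    length: int = 130
    n_signal_columns: int = 12
    signal_fidelity: float = 0.9
    background: Sequence[float] | None = None  # distribution over the 20 residues
    gap_rate: float = 0.02
    x_rate: float = 0.01
    clade: str = "FT"
    n_queries: int = 0
    query_group: str | None = None  # group whose signal the queries carry
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signal_fidelity", "gap_rate", "x_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParamError(f"{name} must lie in [0, 1]")
        if self.length < self.n_signal_columns * len(self.n_per_group):
            raise ParamError("length smaller than total signal columns")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ParamError("negative group size")
        if self.n_queries and self.query_group not in self.n_per_group:
            raise ParamError("query_group must be one of the groups")
        if self.background is not None:
            bg = np.asarray(self.background, float)
            if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
                raise ParamError("background must be 20 probabilities summing to 1")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated family: per-group signal positions."""
    #: group -> list of (1-based column, residue)
    signal: dict[str, list[tuple[int, str]]]


def simulate_protein_family(params: FamilySimParams,
                            ) -> tuple[LabeledAlignment, PlantedTruth]:
    """Draw a labelled protein family with planted group-diagnostic residues."""
    rng = np.random.default_rng(params.seed)
    groups = list(params.n_per_group)
    aa = np.array(list(AMINO_ACIDS))
    bg = (np.full(20, 1 / 20) if params.background is None
          else np.asarray(params.background, float))

    total_signal = params.n_signal_columns * len(groups)
    cols = rng.choice(params.length, size=total_signal, replace=False)
    signal: dict[str, list[tuple[int, str]]] = {}
    for gi, g in enumerate(groups):
        own = np.sort(cols[gi * params.n_signal_columns:
                           (gi + 1) * params.n_signal_columns])
        signal[g] = [(int(c) + 1, str(rng.choice(aa))) for c in own]

    ids, rows, labels, clades, species = [], [], {}, {}, {}

    def _draw_member(group: str, sid: str, label: str) -> None:
        row = rng.choice(aa, size=params.length, p=bg)
        for col, res in signal[group]:
            if rng.random() < params.signal_fidelity:
                row[col - 1] = res
        noise = rng.random(params.length)
        row[noise < params.gap_rate] = GAP
        row[(noise >= params.gap_rate)
            & (noise < params.gap_rate + params.x_rate)] = MISSING
        ids.append(sid)
        rows.append("".join(row))
        labels[sid] = label
        clades[sid] = params.clade
        species[sid] = "synthetic"

    for g in groups:
        for i in range(params.n_per_group[g]):
            _draw_member(g, f"{g}_{i:02d}", g)
    for i in range(params.n_queries):
        _draw_member(params.query_group, f"query_{i:02d}", "unknown")

    aln = LabeledAlignment(sequence_ids=ids, rows=rows, labels=labels,
                           clades=clades, species=species)
    return aln, PlantedTruth(signal=signal)


def _default_target_means() -> dict[str, dict[str, float]]:
    return {"AaFTL1": {"native": 1.0, "invasive": 4.0}}


def _default_reference_sds() -> dict[str, float]:
    return {"TUA": 0.35, "TUB": 0.12, "GAPDH": 0.55}


@dataclass
class CtSimParams:
    """Parameters of the qPCR Ct-table generator.

    Ct = base_ct - log_efficiency(true expression) + biological noise (per
    sample and gene, in cycles) + technical noise (per replicate).
    Reference genes have constant true expression 1 across groups, with a
    per-gene biological noise sd so stability ranking has a planted winner.
    """

    groups: tuple[str, ...] = ("native", "invasive")
    target_means: dict[str, dict[str, float]] = field(
        default_factory=_default_target_means)
    reference_sds: dict[str, float] = field(default_factory=_default_reference_sds)
    target_bio_sd: float = 0.30
    tech_sd: float = 0.15
    n_bio: int = 4
    n_tech: int = 3
    efficiency: float = 2.0
    base_ct: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tech < 1 or self.n_bio < 1:
            raise ParamError("n_bio and n_tech must be >= 1")
        if not (1.0 < self.efficiency <= 2.0):
            raise ParamError("efficiency must lie in (1, 2]")
        for name in ("target_bio_sd", "tech_sd"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.reference_sds.values()):
            raise ParamError("reference sds must be >= 0")
        for gene, means in self.target_means.items():
            for g in self.groups:
                if g not in means:
                    raise ParamError(f"no mean for {gene}/{g}")
                if means[g] <= 0:
                    raise ParamError("expression means must be > 0")


def simulate_ct_table(params: CtSimParams) -> list[CtSample]:
    """Draw a Ct table for all targets and reference genes."""
    rng = np.random.default_rng(params.seed)
    log_e = np.log(params.efficiency)
    out: list[CtSample] = []
    for group in params.groups:
        for i in range(params.n_bio):
            sid = f"{group}_{i:02d}"
            gene_levels: list[tuple[str, float, float]] = []
            for gene, means in params.target_means.items():
                gene_levels.append((gene, means[group], params.target_bio_sd))
            for gene, sd in params.reference_sds.items():
                gene_levels.append((gene, 1.0, sd))
            for gene, level, sd in gene_levels:
                true_ct = params.base_ct - np.log(level) / log_e
                bio = rng.normal(0.0, sd) if sd > 0 else 0.0
                cts = [float(true_ct + bio +
                             (rng.normal(0.0, params.tech_sd)
                              if params.tech_sd > 0 else 0.0))
                       for _ in range(params.n_tech)]
                out.append(CtSample(sample_id=sid, group=group, gene=gene,
                                    technical_cts=cts))
    return out


def _default_populations() -> dict[str, dict[str, float]]:
    # default means: phase means (days) and fruit counts/weights reported for
    # native/invasive ragweed cohorts; sds are realistic daily-scoring spreads
    return {
        "native": dict(m1_mean=66.8, m1_sd=6.0, m2_mean=12.9, m2_sd=3.0,
                       dich_mean=2.2, dich_sd=2.0, n=20,
                       fruit_mean=381.0, fruit_dispersion=5.0,
                       fruit_weight_mean_mg=5.5, fruit_weight_sd_mg=1.0),
        "invasive": dict(m1_mean=34.8, m1_sd=6.0, m2_mean=11.7, m2_sd=3.0,
                         dich_mean=6.2, dich_sd=2.0, n=36,
                         fruit_mean=91.0, fruit_dispersion=5.0,
                         fruit_weight_mean_mg=6.3, fruit_weight_sd_mg=1.0),
        "F1": dict(m1_mean=34.3, m1_sd=6.0, m2_mean=9.3, m2_sd=3.0,
                   dich_mean=1.6, dich_sd=2.0, n=111,
                   fruit_mean=300.0, fruit_dispersion=5.0,
                   fruit_weight_mean_mg=5.5, fruit_weight_sd_mg=1.0),
    }


@dataclass
class PhenoSimParams:
    """Parameters of the phenology-cohort generator.

    Event days are built additively from rounded normal draws — male bud day
    from the vegetative-male-initiation mean, pollen from the male-maturation
    mean, pistil from the dichogamy mean — reproducing the integer tie
    structure of daily scoring.  Fruit counts are negative binomial
    (overdispersed), per-plant mean fruit weight is truncated normal.
    """

    populations: dict[str, dict[str, float]] = field(
        default_factory=_default_populations)
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"m1_mean", "m1_sd", "m2_mean", "m2_sd", "dich_mean",
                    "dich_sd", "n", "fruit_mean", "fruit_dispersion",
                    "fruit_weight_mean_mg", "fruit_weight_sd_mg"}
        for pop, p in self.populations.items():
            missing = required - set(p)
            if missing:
                raise ParamError(f"{pop}: missing {sorted(missing)}")
            if p["m1_mean"] <= 0 or p["m2_mean"] < 0:
                raise ParamError(f"{pop}: phase means must be positive")
            if p["n"] < 1:
                raise ParamError(f"{pop}: n must be >= 1")
            if any(p[k] < 0 for k in ("m1_sd", "m2_sd", "dich_sd",
                                      "fruit_weight_sd_mg")):
                raise ParamError(f"{pop}: sds must be >= 0")
            if p["fruit_mean"] < 0 or p["fruit_dispersion"] <= 0:
                raise ParamError(f"{pop}: invalid fruit parameters")


def simulate_phenology(params: PhenoSimParams) -> list[PhenologyRecord]:
    """Draw phenology cohorts for every configured population."""
    rng = np.random.default_rng(params.seed)
    out: list[PhenologyRecord] = []
    for pop, p in params.populations.items():
        for i in range(int(p["n"])):
            bud = max(1, round(rng.normal(p["m1_mean"], p["m1_sd"])))
            m2 = max(0, round(rng.normal(p["m2_mean"], p["m2_sd"])))
            pollen = bud + m2
            dich = round(rng.normal(p["dich_mean"], p["dich_sd"]))
            pistil = max(1, pollen + dich)
            mu, k = p["fruit_mean"], p["fruit_dispersion"]
            fruits = (int(rng.negative_binomial(k, k / (k + mu)))
                      if mu > 0 else 0)
            w = max(0.05, rng.normal(p["fruit_weight_mean_mg"],
                                     p["fruit_weight_sd_mg"]))
            out.append(PhenologyRecord(
                plant_id=f"{pop}_{i:03d}", population=pop,
                day_male_bud=bud, day_first_pollen=pollen,
                day_first_pistil=pistil, n_fruits=fruits,
                total_fruit_weight_mg=round(fruits * w, 3)))
    return out
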