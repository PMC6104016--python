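"""Benchmark metrics: per-rank accuracy, over-prediction, cosine consistency,
Shannon diversity, and the clade-exclusion benchmark driver.

Accuracy follows the TP/UN/ALL convention for read classifiers:

    sensitivity = TP / ALL
    precision   = TP / (ALL - UN)
    accuracy    = (sensitivity + precision) / 2

where TP counts reads whose predicted taxon at a rank equals the truth taxon,
UN counts unclassified reads, and ALL is the total. Reads whose *truth*
lineage is NA at the evaluated rank are excluded from ALL there: an NA = NA
match would be vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _sp_cosine

from .classify import Assignment, ClassifyConfig, classify
from .reference import ReferenceDatabase, exclude_clade
from .taxonomy import EVAL_RANKS, NA, TaxLineage, lineages_from_frame


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts behind the accuracy triple at one rank."""

    rank: str
    ALL: int
    UN: int
    TP: int

    def __post_init__(self):
        if not 0 <= self.TP <= self.ALL - self.UN <= self.ALL:
            raise ValueError(
                f"invalid confusion counts: TP={self.TP}, UN={self.UN}, ALL={self.ALL}"
            )


class AccuracyTriple(NamedTuple):
    sensitivity: float
    precision: float
    accuracy: float
    degenerate: bool = False


class OverPrediction(NamedTuple):
    value: float
    degenerate: bool = False


def accuracy_triple(cs: ConfusionSummary) -> AccuracyTriple:
    """sensitivity = TP/ALL, precision = TP/(ALL-UN), accuracy = their mean.

    If every read is unclassified (ALL == UN) precision is undefined; it is
    reported as 0 with the degenerate flag set, keeping tables numeric.
    """
    if cs.ALL <= 0:
        raise ValueError("ALL must be positive")
    sens = cs.TP / cs.ALL
    if cs.ALL == cs.UN:
        return AccuracyTriple(sens, 0.0, sens / 2, degenerate=True)
    prec = cs.TP / (cs.ALL - cs.UN)
    return AccuracyTriple(sens, prec, (sens + prec) / 2)


def confusion_summary(
    assignments: Iterable[Assignment],
    truth: Mapping[str, TaxLineage],
    rank: str,
) -> ConfusionSummary:
    """Tally TP/UN/ALL at one rank against per-read truth lineages.

    Reads with NA truth at ``rank`` are dropped from ALL; prediction NA never
    counts as a match.
    """
    all_n = un = tp = 0
    for a in assignments:
        t = truth[a.read_id]
        if t.name_at(rank) == NA:
            continue
        all_n += 1
        if not a.classified:
            un += 1
        elif a.lineage.matches_at(t, rank):
            tp += 1
    if all_n == 0:
        raise ValueError(f"no reads with known truth at rank {rank!r}")
    return ConfusionSummary(rank=rank, ALL=all_n, UN=un, TP=tp)


def over_prediction_rate(
    predicted: Mapping[str, float] | Sequence[str],
    expected_taxa: Iterable[str],
    min_proportion: float = 0.0,
) -> OverPrediction:
    """Fraction of predicted taxa absent from the expected composition.

    ``predicted`` is a taxon -> proportion mapping (or a bare taxon list);
    the unclassified sentinel and NA are not taxa. Taxa below
    ``min_proportion`` are ignored. Zero predicted taxa is reported as 0 with
    the degenerate flag.
    """
    if isinstance(predicted, Mapping) or isinstance(predicted, pd.Series):
        items = {t for t, p in dict(predicted).items() if p >= min_proportion}
    else:
        items = set(predicted)
    items -= {NA}
    if not items:
        return OverPrediction(0.0, degenerate=True)
    expected = set(expected_taxa) - {NA}
    return OverPrediction(len(items - expected) / len(items))


def cosine_consistency(
    predicted: Mapping[str, float], expected: Mapping[str, float]
) -> float:
    """Cosine similarity between two taxon-proportion profiles, aligned on the
    union of taxa (missing taxa count as 0)."""
    p = pd.Series(dict(predicted), dtype=float)
    e = pd.Series(dict(expected), dtype=float)
    taxa = sorted(set(p.index) | set(e.index))
    u = p.reindex(taxa, fill_value=0.0).to_numpy()
    v = e.reindex(taxa, fill_value=0.0).to_numpy()
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValueError("cosine consistency undefined for a zero profile")
    return float(1.0 - _sp_cosine(u, v))


def shannon_index(profile: Mapping[str, float] | Sequence[float]) -> float:
    """H = -sum p_i ln p_i over a proportion profile; 0-proportions drop out."""
    if isinstance(profile, Mapping) or isinstance(profile, pd.Series):
        p = np.asarray(list(dict(profile).values()), dtype=float)
    else:
        p = np.asarray(profile, dtype=float)
    if p.size == 0:
        raise ValueError("empty profile")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("profile must be non-negative proportions summing to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() + 0.0)  # + 0.0 normalises -0.0


def profile_from_lineages(
    lineages: Iterable[TaxLineage], rank: str
) -> pd.Series:
    """Taxon proportions at ``rank`` over a set of lineages, NA dropped."""
    names = [lin.name_at(rank) for lin in lineages if lin.name_at(rank) != NA]
    if not names:
        return pd.Series(dtype=float)
    counts = pd.Series(names).value_counts().sort_index()
    return counts / counts.sum()


def run_clade_exclusion_benchmark(
    db: ReferenceDatabase,
    reads: Sequence[tuple[str, str]],
    truth: pd.DataFrame,
    levels: Sequence[str] = ("none", "species", "genus", "family", "order", "class"),
    ranks: Sequence[str] = EVAL_RANKS,
    config: ClassifyConfig | None = None,
) -> pd.DataFrame:
    """Full clade-exclusion grid: for each exclusion level, rebuild the
    reference without the query clade, classify, and score every rank.

    ``truth`` is the simulator's truth table (read_id, genome_id, seven rank
    columns, strand, start). Returns a tidy frame with one row per
    (level, rank): sensitivity, precision, accuracy, over_prediction,
    cosine, shannon, and the database size used.
    """
    truth_lineages = lineages_from_frame(truth, "read_id")
    query_taxa = list({lin.to_tuple(): lin for lin in truth_lineages.values()}.values())
    rows = []
    for level in levels:
        sub_db = exclude_clade(db, query_taxa, level)
        result = classify(reads, sub_db, config)
        for rank in ranks:
            cs = confusion_summary(result.assignments, truth_lineages, rank)
            tri = accuracy_triple(cs)
            predicted = result.profiles.get(rank, pd.Series(dtype=float))
            expected = profile_from_lineages(truth_lineages.values(), rank)
            over = over_prediction_rate(predicted, expected.index)
            cos = (
                cosine_consistency(predicted, expected)
                if len(predicted) and len(expected) else np.nan
            )
            shannon = shannon_index(predicted) if len(predicted) else np.nan
            rows.append(
                (level, rank, len(sub_db), tri.sensitivity, tri.precision,
                 tri.accuracy, over.value, cos, shannon)
            )
    return pd.DataFrame(
        rows,
        columns=["level", "rank", "n_genomes", "sensitivity", "precision",
                 "accuracy", "over_prediction", "cosine", "shannon"],
    )
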