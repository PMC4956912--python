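"""Ranking-quality metrics and the method-comparison harness.

Relevance can be graded (the 0–4 judgment scale: 4 definite expertise …
0 none) or binary.  NDCG uses the exponential-gain, log2-discount form:

    DCG@K = sum_{r=1..K} (2^{g_r} - 1) / log2(r + 1),
    NDCG@K = DCG@K / IDCG@K  (0 when IDCG is 0),

with the ideal list obtained by sorting grades descending.  Binary
metrics (P@10, R-precision, MAP) follow the standard IR definitions.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import (
    AggregationResult,
    RankedList,
    aggregate_rankings,
    borda_baseline,
    rank_by_feature,
)
from .features import FeatureMatrix
from .synthetic import PlantedTruth

logger = logging.getLogger(__name__)


class JudgmentSource(str, enum.Enum):
    planted = "planted"
    reviews = "reviews"
    judgments = "judgments"


@dataclass
class RelevanceJudgments:
    """Doctor → relevance grade for one category (binary or graded)."""

    category_id: str
    relevance: dict[str, int]
    source: JudgmentSource = JudgmentSource.judgments

    def __post_init__(self) -> None:
        if not self.relevance:
            raise ValueError("no doctors judged")
        if any(g < 0 for g in self.relevance.values()):
            raise ValueError("relevance grades must be >= 0")

    def binarize(self, threshold: int = 3) -> "RelevanceJudgments":
        """Grades >= threshold become relevant (1), the rest 0."""
        return RelevanceJudgments(
            category_id=self.category_id,
            relevance={d: int(g >= threshold) for d, g in self.relevance.items()},
            source=self.source,
        )


def _grades_in_rank_order(
    ranking: RankedList, judgments: RelevanceJudgments
) -> np.ndarray:
    return np.array(
        [judgments.relevance.get(d, 0) for d in ranking.doctor_ids], dtype=float
    )


def _dcg(grades: np.ndarray) -> float:
    if grades.size == 0:
        return 0.0
    discounts = np.log2(np.arange(2, grades.size + 2))
    return float(((2.0**grades - 1.0) / discounts).sum())


def ndcg_at_k(ranking: RankedList, judgments: RelevanceJudgments, k: int) -> float:
    """Normalized discounted cumulative gain at cutoff ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    grades = _grades_in_rank_order(ranking, judgments)
    ideal = np.sort(
        np.array(list(judgments.relevance.values()), dtype=float)
    )[::-1]
    dcg = _dcg(grades[:k])
    idcg = _dcg(ideal[:k])
    return dcg / idcg if idcg > 0 else 0.0


def precision_at_k(
    ranking: RankedList, judgments: RelevanceJudgments, k: int = 10
) -> float:
    """Fraction of the top-``k`` ranked doctors that are relevant
    (judgments must be binary)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    grades = _grades_in_rank_order(ranking, judgments)
    return float((grades[:k] > 0).sum() / k)


def r_precision(ranking: RankedList, judgments: RelevanceJudgments) -> float:
    """Precision at rank R, with R the number of relevant doctors."""
    r = sum(1 for g in judgments.relevance.values() if g > 0)
    if r == 0:
        logger.warning("r_precision undefined: no relevant doctors; returning 0")
        return 0.0
    grades = _grades_in_rank_order(ranking, judgments)
    return float((grades[:r] > 0).sum() / r)


def average_precision(ranking: RankedList, judgments: RelevanceJudgments) -> float:
    """Mean of precision values at each relevant rank."""
    grades = _grades_in_rank_order(ranking, judgments)
    rel = grades > 0
    total = int(sum(1 for g in judgments.relevance.values() if g > 0))
    if total == 0:
        return 0.0
    hits = np.cumsum(rel)
    precisions = hits[rel] / (np.nonzero(rel)[0] + 1)
    return float(precisions.sum() / total)


def mean_average_precision(
    rankings: Mapping[str, RankedList], judgments: Mapping[str, RelevanceJudgments]
) -> float:
    """Mean over categories of average precision."""
    if not rankings:
        raise ValueError("no categories to evaluate")
    aps = [average_precision(rankings[c], judgments[c]) for c in rankings]
    return float(np.mean(aps))


def build_ground_truth(
    judgment_scores: Mapping[str, float],
    top_n: int = 30,
    category_id: str = "",
) -> RelevanceJudgments:
    """Binary ground truth from averaged judgment scores: doctors are
    ranked by score (ties broken by doctor_id) and the top ``top_n`` are
    marked relevant."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    order = sorted(judgment_scores, key=lambda d: (-judgment_scores[d], d))
    top = set(order[:top_n])
    return RelevanceJudgments(
        category_id=category_id,
        relevance={d: int(d in top) for d in judgment_scores},
        source=JudgmentSource.judgments,
    )


def judgments_from_truth(
    truth: PlantedTruth,
    category_id: str,
    quantiles: Sequence[float] = (0.5, 0.75, 0.9, 0.97),
) -> RelevanceJudgments:
    """Graded 0–4 judgments from planted quality quantile bins."""
    j = truth.category_ids.index(category_id)
    q = truth.quality[:, j]
    edges = np.quantile(q, quantiles)
    grades = np.searchsorted(edges, q, side="right")
    return RelevanceJudgments(
        category_id=category_id,
        relevance={d: int(g) for d, g in zip(truth.doctor_ids, grades)},
        source=JudgmentSource.planted,
    )


def judgments_from_reviews(
    reviews,
    category_id: str,
    relevant_level: int = 8,
    irrelevant_level: int = 1,
) -> RelevanceJudgments:
    """Binary relevance from review logs: mean level >= relevant_level is
    relevant, <= irrelevant_level irrelevant, intermediate doctors are
    excluded (review levels are observed to pile up at the extremes)."""
    sums: dict[str, list[int]] = {}
    for r in reviews:
        if r.disease_id == category_id:
            sums.setdefault(r.doctor_id, []).append(r.level)
    relevance = {}
    for d, levels in sums.items():
        mean = float(np.mean(levels))
        if mean >= relevant_level:
            relevance[d] = 1
        elif mean <= irrelevant_level:
            relevance[d] = 0
    return RelevanceJudgments(
        category_id=category_id, relevance=relevance, source=JudgmentSource.reviews
    )


def compare_methods(
    matrices: Mapping[str, FeatureMatrix],
    judgments: Mapping[str, RelevanceJudgments],
    k_grid: Sequence[int] = (5, 10, 20),
    binarize_threshold: int = 3,
    include_single_features: bool = True,
) -> pd.DataFrame:
    """Score the aggregate, the Borda baseline, and every single feature.

    Returns a tidy table (method, metric, K, value) with NDCG@K per K in
    ``k_grid`` plus P@10, R-precision and MAP, each averaged across
    categories.
    """
    methods: dict[str, dict[str, RankedList]] = {"aggregate": {}, "borda": {}}
    for cat, mat in matrices.items():
        result: AggregationResult = aggregate_rankings(mat)
        methods["aggregate"][cat] = result.final_ranking
        methods["borda"][cat] = borda_baseline(mat)
        if include_single_features:
            for name in mat.feature_names:
                methods.setdefault(f"feature:{name}", {})[cat] = rank_by_feature(
                    mat, name
                )

    binary = {c: j.binarize(binarize_threshold) for c, j in judgments.items()}
    rows = []
    for method, rankings in methods.items():
        cats = list(rankings)
        for k in k_grid:
            vals = [ndcg_at_k(rankings[c], judgments[c], k) for c in cats]
            rows.append(
                {"method": method, "metric": "ndcg", "K": k, "value": float(np.mean(vals))}
            )
        p10 = [precision_at_k(rankings[c], binary[c], 10) for c in cats]
        rows.append({"method": method, "metric": "p@10", "K": 10, "value": float(np.mean(p10))})
        rp = [r_precision(rankings[c], binary[c]) for c in cats]
        rows.append(
            {"method": method, "metric": "r-precision", "K": None, "value": float(np.mean(rp))}
        )
        rows.append(
            {
                "method": method,
                "metric": "map",
                "K": None,
                "value": mean_average_precision(rankings, binary),
            }
        )
    return pd.DataFrame(rows, columns=["method", "metric", "K", "value"])
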