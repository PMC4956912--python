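"""Consistency-weighted unsupervised rank aggregation.

Each feature column of a (z-normalized) feature matrix induces a ranked
list pi_i over the doctors.  The aggregation alternates between

* the weighted mean ranking  pi_bar(d) = sum_i w_i * pi_i(d),
* per-feature consistencies  sigma_i = (1/n) sum_d (pi_i(d) - pi_bar(d))^2,
* weights minimizing         J(w) = sum_i w_i^2 * sigma_i  on the simplex,

whose KKT solution is w_i proportional to 1/sigma_i: features that agree
with the consensus ranking (small sigma) earn large weights, features
that deviate are suppressed.  No ground-truth ranking is needed at any
point.  The final score of a doctor is the weighted feature sum
F(d, c) = sum_i w_i f_i(d, c), and the output ranking sorts F
descending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FeatureMatrix


@dataclass
class RankedList:
    """An ordering of doctors; ranks start at 1 (best) and ties receive
    the average of the positions they cover."""

    doctor_ids: list[str]
    ranks: dict[str, float]
    source: str = "aggregate"

    def __post_init__(self) -> None:
        n = len(self.doctor_ids)
        total = sum(self.ranks.values())
        if abs(total - n * (n + 1) / 2) > 1e-6:
            raise ValueError(
                f"invalid average-rank assignment: ranks sum to {total}, "
                f"expected {n * (n + 1) / 2}"
            )

    def rank_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.ranks[d] for d in order])


def _ranked_list_from_scores(
    scores: np.ndarray, doctor_ids: Sequence[str], source: str
) -> RankedList:
    ranks = rankdata(-np.asarray(scores, dtype=float), method="average")
    order = sorted(range(len(doctor_ids)), key=lambda i: (ranks[i], doctor_ids[i]))
    return RankedList(
        doctor_ids=[doctor_ids[i] for i in order],
        ranks={doctor_ids[i]: float(ranks[i]) for i in range(len(doctor_ids))},
        source=source,
    )


def rank_by_feature(matrix: FeatureMatrix, feature: int | str) -> RankedList:
    """Ranked list induced by one feature column (descending scores,
    average ranks on ties)."""
    idx = matrix.feature_names.index(feature) if isinstance(feature, str) else feature
    return _ranked_list_from_scores(
        matrix.values[:, idx], matrix.doctor_ids, matrix.feature_names[idx]
    )


def mean_ranking(
    lists: Sequence[RankedList], weights: Sequence[float]
) -> dict[str, float]:
    """Weighted average ranking pi_bar(d) = sum_i w_i * pi_i(d)."""
    if not lists:
        raise ValueError("mean_ranking: no ranked lists")
    doctors = set(lists[0].ranks)
    for rl in lists[1:]:
        if set(rl.ranks) != doctors:
            raise ValueError("ranked lists cover different doctor sets")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(lists):
        raise ValueError(f"{len(lists)} lists but {len(w)} weights")
    return {
        d: float(sum(wi * rl.ranks[d] for wi, rl in zip(w, lists))) for d in doctors
    }


def consistency(list_i: RankedList, mean: Mapping[str, float]) -> float:
    """Mean squared deviation of a feature's ranking from the consensus:
    sigma_i = (1/n) sum_d (pi_i(d) - pi_bar(d))^2."""
    if set(list_i.ranks) != set(mean):
        raise ValueError("doctor sets differ between list and mean ranking")
    n = len(mean)
    return float(
        sum((list_i.ranks[d] - mean[d]) ** 2 for d in mean) / n
    )


def solve_weights(
    sigmas: Sequence[float],
    method: str = "closed_form",
    max_iter: int = 10000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize J(w) = sum_i w_i^2 sigma_i over the probability simplex.

    ``closed_form``: the KKT solution w_i ∝ 1/sigma_i; if any sigma is 0
    the whole mass is split uniformly over the zero-sigma features (their
    contribution to J is free).  ``projected_gradient``: iterative
    descent with Euclidean simplex projection; agrees with the closed
    form wherever all sigmas are positive.
    """
    s = np.asarray(sigmas, dtype=float)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("sigmas must be a non-empty 1-d sequence")
    if (s < 0).any():
        raise ValueError(f"negative consistency values: {s[s < 0]}")
    m = len(s)
    if method == "closed_form":
        zero = s <= 0
        w = np.zeros(m)
        if zero.any():
            w[zero] = 1.0 / zero.sum()
        else:
            inv = 1.0 / s
            w = inv / inv.sum()
        return w
    if method == "projected_gradient":
        w = np.full(m, 1.0 / m)
        step = 1.0 / (2.0 * s.max() + 1e-12)
        for _ in range(max_iter):
            grad = 2.0 * s * w
            new = _project_simplex(w - step * grad)
            if np.max(np.abs(new - w)) < tol:
                w = new
                break
            w = new
        return w
    raise ValueError(f"unknown method {method!r}")


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / (np.arange(len(v)) + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


@dataclass
class AggregationResult:
    """Learned weights, consistencies and the final ranking for one
    category."""

    category_id: str
    feature_names: list[str]
    weights: np.ndarray
    sigmas: np.ndarray
    mean_ranks: dict[str, float]
    scores: dict[str, float]
    final_ranking: RankedList
    iterations: int
    converged: bool
    baseline: Optional[RankedList] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w, s = np.asarray(self.weights), np.asarray(self.sigmas)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        # smaller sigma => larger weight
        pos = s > 0
        order = np.argsort(s[pos], kind="stable")
        wp = w[pos][order]
        if wp.size and (np.diff(wp) > 1e-9).any():
            raise ValueError("weight/consistency monotonicity violated")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "category_id": self.category_id,
                    "feature_names": self.feature_names,
                    "weights": self.weights.tolist(),
                    "sigmas": self.sigmas.tolist(),
                    "iterations": self.iterations,
                    "converged": self.converged,
                },
                indent=1,
            )
        )

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [self.final_ranking.ranks[d] for d in self.final_ranking.doctor_ids],
                "doctor_id": self.final_ranking.doctor_ids,
                "score": [self.scores[d] for d in self.final_ranking.doctor_ids],
            }
        )


def aggregate_rankings(
    matrix: FeatureMatrix,
    tol: float = 1e-6,
    max_iter: int = 10000,
    method: str = "closed_form",
) -> AggregationResult:
    """Consistency-weighted aggregation of the per-feature rankings.

    The consensus pi_bar is the plain (unweighted) average ranking;
    re-weighting the consensus by the learned weights looks natural but
    makes the scheme collapse onto whichever single feature the consensus
    drifts towards (its sigma falls to zero and its weight to one), so
    the consistencies are measured against the neutral consensus once and
    the weights solved from them.  ``tol``/``max_iter`` control the
    projected-gradient solver when ``method="projected_gradient"``.
    """
    n, m = matrix.values.shape
    if n == 0:
        raise ValueError("aggregate_rankings: no doctors")
    lists = [rank_by_feature(matrix, i) for i in range(m)]
    mean = mean_ranking(lists, np.full(m, 1.0 / m))
    sig = np.array([consistency(rl, mean) for rl in lists])
    w = solve_weights(sig, method=method, max_iter=max_iter, tol=tol)
    iterations = 1
    converged = True

    scores_vec = matrix.values @ w
    final = _ranked_list_from_scores(scores_vec, matrix.doctor_ids, "aggregate")
    return AggregationResult(
        category_id=matrix.category_id,
        feature_names=list(matrix.feature_names),
        weights=w,
        sigmas=sig,
        mean_ranks=mean,
        scores={d: float(s) for d, s in zip(matrix.doctor_ids, scores_vec)},
        final_ranking=final,
        iterations=iterations,
        converged=converged,
    )


def top_k(result: AggregationResult, k: int) -> list[str]:
    """First min(k, n) doctors of the final ranking; ties broken by
    doctor_id (already encoded in the list order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return result.final_ranking.doctor_ids[:k]


def borda_baseline(matrix: FeatureMatrix) -> RankedList:
    """Unweighted mean-rank (Borda) consensus across all features."""
    n, m = matrix.values.shape
    if n == 0:
        raise ValueError("borda_baseline: no doctors")
    lists = [rank_by_feature(matrix, i) for i in range(m)]
    mean = mean_ranking(lists, np.full(m, 1.0 / m))
    scores = np.array([-mean[d] for d in matrix.doctor_ids])
    return _ranked_list_from_scores(scores, matrix.doctor_ids, "borda")
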