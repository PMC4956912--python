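"""End-to-end glue: corpus -> labels -> features -> aggregation."""

from __future__ import annotations

from typing import Optional, Sequence

import networkx as nx

from .aggregate import AggregationResult, aggregate_rankings
from .corpus import build_coauthorship_network
from .features import FeatureMatrix, build_feature_matrix, znormalize
from .labels import LabelMatrix, PropagationConfig, propagate_labels
from .models import Corpus


def propagate_corpus_labels(
    corpus: Corpus, config: Optional[PropagationConfig] = None
) -> LabelMatrix:
    """Propagate the corpus seed labels over its coauthorship network.

    Doctors without publications are kept as isolated nodes so the label
    matrix covers every doctor.
    """
    graph: nx.Graph = build_coauthorship_network(corpus.publications)
    graph.add_nodes_from(corpus.doctor_ids)
    return propagate_labels(
        graph,
        corpus.seed_labels,
        config=config,
        category_ids=corpus.category_ids,
        doctor_ids=corpus.doctor_ids,
    )


def category_feature_matrix(
    corpus: Corpus,
    category_id: str,
    labels: Optional[LabelMatrix] = None,
    prop_config: Optional[PropagationConfig] = None,
    normalized: bool = True,
) -> FeatureMatrix:
    if labels is None:
        labels = propagate_corpus_labels(corpus, prop_config)
    matrix = build_feature_matrix(corpus, category_id, labels)
    return znormalize(matrix) if normalized else matrix


def rank_category(
    corpus: Corpus,
    category_id: str,
    prop_config: Optional[PropagationConfig] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    labels: Optional[LabelMatrix] = None,
) -> AggregationResult:
    """Full per-category ranking: labels -> features -> normalize ->
    consistency-weighted aggregation."""
    if category_id not in corpus.category_ids:
        raise KeyError(
            f"unknown category {category_id!r}; known: {corpus.category_ids}"
        )
    matrix = category_feature_matrix(corpus, category_id, labels, prop_config)
    return aggregate_rankings(matrix, tol=tol, max_iter=max_iter)


def all_feature_matrices(
    corpus: Corpus,
    prop_config: Optional[PropagationConfig] = None,
    categories: Optional[Sequence[str]] = None,
) -> dict[str, FeatureMatrix]:
    labels = propagate_corpus_labels(corpus, prop_config)
    cats = list(categories) if categories is not None else corpus.category_ids
    return {c: category_feature_matrix(corpus, c, labels) for c in cats}
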