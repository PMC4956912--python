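"""Semi-supervised expertise labelling by graph diffusion.

A few doctors carry manually assigned expertise labels per disease
category; the rest inherit scores by diffusing those seeds over the
coauthorship network (optionally a convex combination of several
networks).  The update is the classic normalized-adjacency diffusion
with restart,

    L  <-  alpha * S @ L + (1 - alpha) * Y,

with S = D^{-1/2} A D^{-1/2} and Y the (sparse) seed matrix.  Seed rows
are re-clamped after every sweep by default, matching a workflow where
manual labels are trusted exactly.  Its fixed point solves the linear
system (I - alpha*S) L = (1 - alpha) Y, which the tests use as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .models import SeedLabel


class PropagationConfig(BaseModel):
    alpha: float = Field(default=0.85, gt=0, lt=1)
    tol: float = Field(default=1e-6, gt=0)
    max_iter: int = Field(default=1000, ge=1)
    clamp_seeds: bool = True


@dataclass
class LabelMatrix:
    """Doctors x categories expertise scores in [0, 1]."""

    doctor_ids: list[str]
    category_ids: list[str]
    values: np.ndarray
    seed_mask: np.ndarray  # boolean, same shape
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self._row = {d: i for i, d in enumerate(self.doctor_ids)}
        self._col = {c: j for j, c in enumerate(self.category_ids)}

    def lookup(self, doctor_id: str, category_id: str) -> float:
        if doctor_id not in self._row:
            raise KeyError(f"doctor {doctor_id!r} not in label matrix")
        if category_id not in self._col:
            raise KeyError(f"category {category_id!r} not in label matrix")
        return float(self.values[self._row[doctor_id], self._col[category_id]])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.doctor_ids, columns=self.category_ids
        ).to_csv(path, index_label="doctor_id")


def combine_networks(
    networks: Sequence[nx.Graph], weights: Optional[Sequence[float]] = None
) -> nx.Graph:
    """Convex combination of edge-weighted graphs over a shared node set."""
    if weights is None:
        weights = [1.0 / len(networks)] * len(networks)
    if len(weights) != len(networks):
        raise ValueError(
            f"{len(networks)} networks but {len(weights)} weights"
        )
    if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    combined = nx.Graph()
    for g, w in zip(networks, weights):
        combined.add_nodes_from(g.nodes)
        if w == 0:
            continue
        for a, b, data in g.edges(data=True):
            add = w * data.get("weight", 1.0)
            if combined.has_edge(a, b):
                combined[a][b]["weight"] += add
            else:
                combined.add_edge(a, b, weight=add)
    return combined


def _seed_matrix(
    seeds: Iterable[SeedLabel] | Mapping[tuple[str, str], float],
    doctor_ids: Sequence[str],
    category_ids: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    row = {d: i for i, d in enumerate(doctor_ids)}
    col = {c: j for j, c in enumerate(category_ids)}
    y = np.zeros((len(doctor_ids), len(category_ids)))
    mask = np.zeros_like(y, dtype=bool)
    if isinstance(seeds, Mapping):
        items = [(d, c, v) for (d, c), v in seeds.items()]
    else:
        items = [(s.doctor_id, s.category_id, s.value) for s in seeds]
    for d, c, v in items:
        if d not in row:
            raise KeyError(f"seed doctor {d!r} is not a graph node")
        if c not in col:
            raise KeyError(f"seed category {c!r} unknown")
        y[row[d], col[c]] = v
        mask[row[d], col[c]] = True
    return y, mask


def normalized_adjacency(graph: nx.Graph, nodelist: Sequence[str]):
    """Symmetrically degree-normalized adjacency D^{-1/2} A D^{-1/2};
    rows/columns of isolated nodes are zero."""
    a = nx.to_scipy_sparse_array(graph, nodelist=list(nodelist), weight="weight", format="csr")
    a = a.astype(float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    from scipy.sparse import diags

    return diags(dinv) @ a @ diags(dinv)


def propagate_labels(
    graph: nx.Graph,
    seeds: Iterable[SeedLabel] | Mapping[tuple[str, str], float],
    config: Optional[PropagationConfig] = None,
    category_ids: Optional[Sequence[str]] = None,
    doctor_ids: Optional[Sequence[str]] = None,
) -> LabelMatrix:
    """Diffuse seed labels over the graph until the maximum entry change
    drops below ``config.tol`` (or ``max_iter`` sweeps, in which case the
    result is returned with ``converged=False``)."""
    config = config or PropagationConfig()
    if graph.number_of_nodes() == 0:
        raise ValueError("propagate_labels: empty graph")
    if doctor_ids is None:
        doctor_ids = sorted(graph.nodes)
    if category_ids is None:
        if isinstance(seeds, Mapping):
            category_ids = sorted({c for _, c in seeds})
        else:
            seeds = list(seeds)
            category_ids = sorted({s.category_id for s in seeds})
    y, mask = _seed_matrix(seeds, doctor_ids, category_ids)

    s = normalized_adjacency(graph, doctor_ids)
    alpha = config.alpha
    lab = y.copy()
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        new = alpha * (s @ lab) + (1 - alpha) * y
        if config.clamp_seeds:
            new[mask] = y[mask]
        delta = float(np.max(np.abs(new - lab))) if new.size else 0.0
        lab = new
        if delta < config.tol:
            converged = True
            break
    return LabelMatrix(
        doctor_ids=list(doctor_ids),
        category_ids=list(category_ids),
        values=np.clip(lab, 0.0, 1.0),
        seed_mask=mask,
        n_iter=n_iter,
        converged=converged,
    )


def solve_propagation_exact(
    graph: nx.Graph,
    seeds: Iterable[SeedLabel] | Mapping[tuple[str, str], float],
    alpha: float = 0.85,
    category_ids: Optional[Sequence[str]] = None,
    doctor_ids: Optional[Sequence[str]] = None,
) -> LabelMatrix:
    """Direct (unclamped) fixed point: solve (I - alpha*S) L = (1-alpha) Y.

    Serves as the closed-form counterpart of :func:`propagate_labels`
    with ``clamp_seeds=False``.
    """
    if doctor_ids is None:
        doctor_ids = sorted(graph.nodes)
    if category_ids is None:
        if isinstance(seeds, Mapping):
            category_ids = sorted({c for _, c in seeds})
        else:
            seeds = list(seeds)
            category_ids = sorted({s.category_id for s in seeds})
    y, mask = _seed_matrix(seeds, doctor_ids, category_ids)
    s = normalized_adjacency(graph, doctor_ids).toarray()
    n = len(doctor_ids)
    lab = np.linalg.solve(np.eye(n) - alpha * s, (1 - alpha) * y)
    return LabelMatrix(
        doctor_ids=list(doctor_ids),
        category_ids=list(category_ids),
        values=np.clip(lab, 0.0, 1.0),
        seed_mask=mask,
        n_iter=0,
        converged=True,
    )


def read_seeds_csv(path: str | Path) -> list[SeedLabel]:
    df = pd.read_csv(path, dtype={"doctor_id": str, "category_id": str})
    return [
        SeedLabel(
            doctor_id=r["doctor_id"], category_id=r["category_id"], value=float(r["value"])
        )
        for r in df.to_dict(orient="records")
    ]
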