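"""Lineage assignment and subpopulation discovery for segmented objects.

Lineages follow a stepwise exclusive gating strategy on normalized
expression — endothelial (CD31 | MCT1 | CD105) first, then microglia
(CD45 | Iba1), then astrocytes (GFAP), with the ungated remainder labeled
neurons — mirroring cytometry practice of gating from the most specific
markers outward.  Subpopulations within a lineage are found by training a
self-organizing map on selected markers and meta-clustering its node
weights by average-linkage hierarchical clustering (the FlowSOM idiom);
the default of 11 meta-clusters matches common practice for neuronal
subset discovery.  Objects produced by threshold segmentation bypass
gating: their class is fixed by the source channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._core import ConfigurationError
from .quantify import marker_columns
from .som import SelfOrganizingMap

__all__ = ["GateStep", "GateHierarchy", "ClusterModel", "sequential_gate",
           "som_metacluster", "positivity", "embed_2d",
           "DEFAULT_GATE_HIERARCHY", "default_gate_hierarchy"]


@dataclass
class GateStep:
    lineage: str
    markers: list[str]
    combinator: str = "any"          # "any" | "all"
    thresholds: dict[str, float] = field(default_factory=dict)
    default_threshold: float = 0.5   # on [0,1]-normalized expression

    def threshold_for(self, marker: str) -> float:
        return self.thresholds.get(marker, self.default_threshold)


@dataclass
class GateHierarchy:
    """Ordered exclusive gates; first matching step wins."""

    steps: list[GateStep]
    residual: str = "neuron"


def default_gate_hierarchy(threshold: float = 0.5) -> GateHierarchy:
    return GateHierarchy(steps=[
        GateStep("endothelial", ["CD31", "MCT1", "CD105"], "any",
                 default_threshold=threshold),
        GateStep("microglia", ["CD45", "Iba1"], "any",
                 default_threshold=threshold),
        GateStep("astrocyte", ["GFAP"], "any", default_threshold=threshold),
    ], residual="neuron")


DEFAULT_GATE_HIERARCHY = default_gate_hierarchy()


@dataclass
class ClusterModel:
    grid: tuple[int, int]
    markers: list[str]
    n_meta: int
    seed: int
    node_weights: np.ndarray
    node_to_meta: np.ndarray  # meta-cluster id (1..n_meta) per SOM node


def sequential_gate(table: pd.DataFrame,
                    hierarchy: GateHierarchy | None = None) -> pd.DataFrame:
    """Assign exactly one lineage per object by ordered threshold gates."""
    hierarchy = hierarchy or default_gate_hierarchy()
    for step in hierarchy.steps:
        missing = [m for m in step.markers if m not in table.columns]
        if missing:
            raise ConfigurationError(f"gate {step.lineage!r} refers to "
                                     f"unknown markers {missing}")
    out = table.copy()
    lineage = np.full(len(out), hierarchy.residual, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for step in hierarchy.steps:
        hits = [out[m].to_numpy(dtype=float) > step.threshold_for(m)
                for m in step.markers]
        match = np.logical_and.reduce(hits) if step.combinator == "all" \
            else np.logical_or.reduce(hits)
        take = unassigned & match
        lineage[take] = step.lineage
        unassigned &= ~take
    out["lineage"] = lineage
    return out


def som_metacluster(table: pd.DataFrame, markers: Sequence[str],
                    grid: tuple[int, int] = (10, 10), n_meta: int = 11,
                    seed: int = 0, epochs: int = 10
                    ) -> tuple[pd.DataFrame, ClusterModel]:
    """SOM + linkage meta-clustering of objects on the given markers.

    Node weights are clustered by average linkage (Euclidean) and cut at
    ``n_meta``; each object inherits the meta-cluster of its best-matching
    node.  Reproducible for a fixed seed.
    """
    markers = list(markers)
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise ConfigurationError(f"unknown markers {missing}")
    n_nodes = grid[0] * grid[1]
    if not (1 <= n_meta <= n_nodes):
        raise ValueError(f"n_meta must be in [1, {n_nodes}]")
    X = table[markers].to_numpy(dtype=float)
    som = SelfOrganizingMap(grid, n_features=len(markers), seed=seed)
    som.fit(X, epochs=epochs)
    if n_meta == 1:
        node_to_meta = np.ones(n_nodes, dtype=int)
    else:
        Z = linkage(som.weights, method="average", metric="euclidean")
        node_to_meta = fcluster(Z, t=n_meta, criterion="maxclust")
    bmus = som.predict(X)
    out = table.copy()
    out["cluster_id"] = node_to_meta[bmus]
    model = ClusterModel(grid=tuple(grid), markers=markers, n_meta=n_meta,
                         seed=seed, node_weights=som.weights.copy(),
                         node_to_meta=node_to_meta)
    return out, model


def positivity(table: pd.DataFrame, marker: str, threshold: float = 0.5
               ) -> pd.Series:
    """Boolean positivity call on normalized expression (strictly above)."""
    if marker not in table.columns:
        raise ConfigurationError(f"unknown marker {marker!r}")
    return table[marker].astype(float) > threshold


def embed_2d(table: pd.DataFrame, markers: Sequence[str] | None = None,
             seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1
             ) -> np.ndarray:
    """2-D neighbor embedding of objects for visual inspection.

    Delegates to UMAP with a fixed random state; coordinates are finite and
    deterministic for a fixed seed.
    """
    import umap  # deferred: numba compilation is slow to import

    markers = list(markers) if markers is not None else marker_columns(table)
    X = table[markers].to_numpy(dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 objects to embed")
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(n_neighbors, len(X) - 1),
                        min_dist=min_dist)
    coords = reducer.fit_transform(X)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    return np.asarray(coords, dtype=float)
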