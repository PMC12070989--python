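"""Inverse-distance weighted graph construction, Gaussian feature-noise
augmentation with randomized edge thresholds, and GML serialization.

Nodes carry the 14 region features; the weight of edge (i, j) is
1 / (euclidean_distance(f_i, f_j) + epsilon).  Full graphs connect every node
pair; augmented graphs keep only pairs closer than u * D_max with
u ~ Uniform(threshold_range) and D_max the maximum pairwise distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import AugmentationError, FormatError, TableError
from .features import FEATURE_NAMES, FeatureTable, RegionFeatureVector

__all__ = [
    "LesionGraph",
    "AugmentConfig",
    "edge_weight",
    "build_full_graph",
    "perturb_features",
    "build_augmented_graph",
    "generate_augmented_set",
    "write_gml",
    "read_gml",
]

#: clipping bounds re-applied after noise injection, per feature name
_FEATURE_BOUNDS = {
    "area": (1.0, None),
    "perimeter": (1e-6, None),
    "eccentricity": (0.0, 1.0 - 1e-12),
    "solidity": (1e-12, 1.0),
    "major_axis": (1e-6, None),
    "minor_axis": (1e-6, None),
    "aspect_ratio": (1.0, None),
    "compactness": (1e-12, None),
    "circularity": (1e-12, None),
    "glcm_contrast": (0.0, None),
    "glcm_correlation": (-1.0, 1.0),
    "glcm_energy": (1e-12, 1.0),
    "glcm_homogeneity": (1e-12, 1.0),
    "mean_intensity": (0.0, 1.0),
}


@dataclass
class LesionGraph:
    """Undirected weighted graph over region feature vectors.

    ``edges`` stores (i, j, weight) with i < j over positional node indices;
    ``provenance`` records 'original' or 'augmented' plus seed and threshold u.
    """

    node_ids: list[int]
    features: np.ndarray  # (n, 14)
    edges: list[tuple[int, int, float]]
    class_label: str
    provenance: dict = field(default_factory=lambda: {"kind": "original"})

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise TableError("features must be a 2D array")
        if len(self.node_ids) != self.features.shape[0]:
            raise TableError("node_ids and features disagree in length")
        seen = set()
        for i, j, w in self.edges:
            if i == j:
                raise TableError("self-loops are not allowed in the stored edge set")
            if not (0 <= i < j < len(self.node_ids)):
                raise TableError(f"edge ({i},{j}) out of range or not i<j")
            if (i, j) in seen:
                raise TableError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
            if not (np.isfinite(w) and w > 0):
                raise TableError(f"edge ({i},{j}) weight must be positive finite, got {w}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        n = self.n_nodes
        A = np.zeros((n, n), dtype=float)
        for i, j, w in self.edges:
            A[i, j] = A[j, i] = w
        return A


@dataclass(frozen=True)
class AugmentConfig:
    """Configuration of the graph augmentation stage."""

    n_graphs_per_class: int = 500
    noise_fraction: float = 0.05
    noisy_features: tuple[str, ...] = (
        "area",
        "perimeter",
        "eccentricity",
        "mean_intensity",
        "glcm_contrast",
    )
    threshold_range: tuple[float, float] = (0.30, 0.60)
    epsilon: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.threshold_range
        if not (0 < lo < hi <= 1):
            raise AugmentationError(f"invalid threshold_range {self.threshold_range}")
        if self.noise_fraction < 0:
            raise AugmentationError("noise_fraction must be >= 0")
        unknown = set(self.noisy_features) - set(FEATURE_NAMES)
        if unknown:
            raise AugmentationError(f"unknown noisy features: {sorted(unknown)}")


# ---------------------------------------------------------------------------


def edge_weight(f_i, f_j, epsilon: float = 1e-8) -> float:
    """Inverse-distance weight 1 / (||f_i - f_j|| + epsilon)."""
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if f_i.shape != f_j.shape:
        raise TableError(f"feature vectors differ in shape: {f_i.shape} vs {f_j.shape}")
    if not (np.isfinite(f_i).all() and np.isfinite(f_j).all()):
        raise TableError("feature vectors must be finite")
    if epsilon <= 0:
        raise TableError("epsilon must be > 0")
    return 1.0 / (float(np.linalg.norm(f_i - f_j)) + epsilon)


def _table_features(table: FeatureTable) -> tuple[list[int], np.ndarray]:
    ids = [r.region_id for r in table.rows]
    if len(set(ids)) != len(ids):
        raise TableError(f"duplicate region_ids: {ids}")
    return ids, table.feature_matrix()


def build_full_graph(
    table: FeatureTable, epsilon: float = 1e-8, standardize: bool = False
) -> LesionGraph:
    """Fully connected graph: n nodes, n(n-1)/2 inverse-distance edges.

    With ``standardize`` the distances are computed on per-table z-scored
    features (stored node features stay raw); default off.
    """
    ids, X = _table_features(table)
    Xd = _zscore(X) if standardize else X
    n = len(ids)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((i, j, edge_weight(Xd[i], Xd[j], epsilon)))
    return LesionGraph(
        node_ids=ids,
        features=X,
        edges=edges,
        class_label=table.class_label,
        provenance={"kind": "original"},
    )


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _perturb_matrix(
    X: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    out = X.copy()
    if X.shape[0] < 2:
        warnings.warn("single-row table: feature std undefined, noise skipped", stacklevel=2)
        return out
    for name in cfg.noisy_features:
        j = FEATURE_NAMES.index(name)
        sigma = float(np.std(X[:, j], ddof=1))
        noise = rng.normal(0.0, cfg.noise_fraction * sigma, size=X.shape[0])
        out[:, j] = X[:, j] + noise
        lo, hi = _FEATURE_BOUNDS[name]
        out[:, j] = np.clip(out[:, j], lo, hi)
    return out


def perturb_features(
    table: FeatureTable, cfg: AugmentConfig, draw_seed: int
) -> FeatureTable:
    """Add N(0, (noise_fraction * sigma_feature)^2) noise to the configured features.

    sigma is the sample std (ddof=1) across the table's rows; other features
    are untouched and hard range floors are re-applied after perturbation.
    """
    _, X = _table_features(table)
    rng = np.random.default_rng(draw_seed)
    Xp = _perturb_matrix(X, cfg, rng)
    rows = [
        RegionFeatureVector(
            region_id=r.region_id, **dict(zip(FEATURE_NAMES, Xp[i]))
        )
        for i, r in enumerate(table.rows)
    ]
    return FeatureTable(
        class_label=table.class_label,
        rows=rows,
        image_path=table.image_path,
        mask_path=table.mask_path,
    )


def build_augmented_graph(
    table: FeatureTable, cfg: AugmentConfig, draw_seed: int
) -> LesionGraph:
    """Perturb features, then connect pairs within u * D_max of each other.

    u ~ Uniform(threshold_range) and D_max is the maximum pairwise Euclidean
    distance among the perturbed vectors; weights follow the inverse-distance
    formula.  The drawn u and seed are recorded in provenance.
    """
    ids, X = _table_features(table)
    if len(ids) < 2:
        raise AugmentationError("augmented graphs need at least 2 nodes")
    rng = np.random.default_rng(draw_seed)
    Xp = _perturb_matrix(X, cfg, rng)
    u = float(rng.uniform(*cfg.threshold_range))
    dist = squareform(pdist(Xp))
    d_max = float(dist.max())
    cutoff = u * d_max
    n = len(ids)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                edges.append((i, j, 1.0 / (dist[i, j] + cfg.epsilon)))
    return LesionGraph(
        node_ids=ids,
        features=Xp,
        edges=edges,
        class_label=table.class_label,
        provenance={"kind": "augmented", "seed": int(draw_seed), "u": u},
    )


def _graph_seed(rng_seed: int, class_idx: int, graph_idx: int) -> int:
    ss = np.random.SeedSequence((int(rng_seed), int(class_idx), int(graph_idx)))
    return int(ss.generate_state(1)[0])


def generate_augmented_set(
    tables: Sequence[FeatureTable],
    cfg: AugmentConfig | None = None,
    out_dir=None,
) -> tuple[list[LesionGraph], pd.DataFrame]:
    """Exactly ``cfg.n_graphs_per_class`` augmented graphs per class table.

    Per-graph seeds are derived deterministically from (rng_seed, class index,
    graph index).  With ``out_dir`` the graphs are written as one GML file each
    under ``<out>/<class>/`` plus a ``manifest.csv``.
    """
    cfg = cfg or AugmentConfig()
    graphs: list[LesionGraph] = []
    rows = []
    for ci, table in enumerate(tables):
        cls = table.class_label
        cls_dir = None
        if out_dir is not None:
            cls_dir = Path(out_dir) / cls
            cls_dir.mkdir(parents=True, exist_ok=True)
        for gi in range(cfg.n_graphs_per_class):
            seed = _graph_seed(cfg.rng_seed, ci, gi)
            g = build_augmented_graph(table, cfg, seed)
            graphs.append(g)
            rel = str(Path(cls) / f"{cls}_aug_{gi:04d}.gml")
            if cls_dir is not None:
                write_gml(g, Path(out_dir) / rel)
            rows.append(
                {
                    "class": cls,
                    "path": rel,
                    "provenance": "augmented",
                    "u": g.provenance["u"],
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=["class", "path", "provenance", "u", "seed"])
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return graphs, manifest


# ---------------------------------------------------------------------------
# GML I/O


def write_gml(graph: LesionGraph, path) -> None:
    g = nx.Graph()
    g.graph["class_label"] = graph.class_label
    g.graph["provenance"] = str(graph.provenance.get("kind", "original"))
    if "seed" in graph.provenance:
        g.graph["seed"] = int(graph.provenance["seed"])
    if "u" in graph.provenance:
        g.graph["u"] = float(graph.provenance["u"])
    for pos, nid in enumerate(graph.node_ids):
        attrs = {name: float(v) for name, v in zip(FEATURE_NAMES, graph.features[pos])}
        g.add_node(pos, region_id=int(nid), **attrs)
    for i, j, w in graph.edges:
        g.add_edge(i, j, weight=float(w))
    nx.write_gml(g, path)


def read_gml(path) -> LesionGraph:
    g = nx.read_gml(path, label="id")
    if "class_label" not in g.graph:
        raise FormatError(f"{path}: GML lacks a class_label graph attribute")
    provenance = {"kind": g.graph.get("provenance", "original")}
    if "seed" in g.graph:
        provenance["seed"] = int(g.graph["seed"])
    if "u" in g.graph:
        provenance["u"] = float(g.graph["u"])
    nodes = list(g.nodes())  # file order preserved by networkx
    index = {n: pos for pos, n in enumerate(nodes)}
    node_ids = []
    feats = np.zeros((len(nodes), len(FEATURE_NAMES)), dtype=float)
    for pos, n in enumerate(nodes):
        data = g.nodes[n]
        missing = [name for name in FEATURE_NAMES if name not in data]
        if missing:
            raise FormatError(f"{path}: node {n} lacks feature attributes {missing}")
        node_ids.append(int(data.get("region_id", n)))
        feats[pos] = [float(data[name]) for name in FEATURE_NAMES]
    edges = []
    for a, b, data in g.edges(data=True):
        if "weight" not in data:
            raise FormatError(f"{path}: edge ({a},{b}) lacks a weight attribute")
        i, j = sorted((index[a], index[b]))
        edges.append((i, j, float(data["weight"])))
    edges.sort()
    return LesionGraph(
        node_ids=node_ids,
        features=feats,
        edges=edges,
        class_label=str(g.graph["class_label"]),
        provenance=provenance,
    )
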