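"""Self-organizing-map subclustering: the unsupervised stage of the phenotyper.

Within one metacluster (optionally pre-split by a marker threshold, e.g.
CD163 for M1/M2 macrophages), cells are clustered on a chosen set of
functional markers: a Kohonen map is trained on the scaled expressions, each
cell is assigned to its best-matching node, and the node codebook vectors are
agglomeratively merged (average linkage, Euclidean) into a fixed number of
consensus clusters -- the FlowSOM scheme, defaulting to 9 clusters on a 10x10
grid.  Consensus clusters are then merged/annotated by hand via a merge map
and folded back into the master table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .errors import ConfigurationError, IntegrityError, ParameterError

EXCLUDE_LABEL = "exclude"


@dataclass
class SOMConfig:
    grid_rows: int = 10
    grid_cols: int = 10
    epochs: int = 10
    learning_rate: float = 0.5
    n_clusters: int = 9
    seed: int = 0
    markers: list[str] | None = None

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ParameterError("grid dimensions must be >= 1")
        if self.n_clusters < 1 or self.n_clusters > self.grid_rows * self.grid_cols:
            raise ParameterError(
                "n_clusters must be between 1 and the number of map nodes"
            )
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")


class SelfOrganizingMap:
    """Minimal deterministic online Kohonen map.

    Euclidean best-matching-unit search, Gaussian neighborhood on the grid,
    learning rate and neighborhood radius decaying linearly over the training
    schedule.  The codebook is initialized from randomly drawn data rows, and
    all randomness flows from the seed, so identical (data, config, seed)
    yields identical maps.
    """

    def __init__(self, rows: int, cols: int, n_features: int, seed: int = 0):
        self.rows = rows
        self.cols = cols
        self.n_features = n_features
        self.seed = seed
        self.codebook = np.zeros((rows * cols, n_features))
        grid = np.indices((rows, cols)).reshape(2, -1).T
        self._grid_sq_dist = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)

    def fit(self, data: np.ndarray, epochs: int = 10, learning_rate: float = 0.5) -> "SelfOrganizingMap":
        data = np.asarray(data, dtype=float)
        rng = np.random.default_rng(self.seed)
        n_nodes = self.rows * self.cols
        init_idx = rng.integers(0, len(data), size=n_nodes)
        self.codebook = data[init_idx].astype(float).copy()
        self.codebook += rng.normal(0.0, 1e-4, self.codebook.shape)

        sigma0 = max(self.rows, self.cols) / 2.0
        total_steps = epochs * len(data)
        step = 0
        for _ in range(epochs):
            for i in rng.permutation(len(data)):
                frac = step / max(total_steps - 1, 1)
                lr = learning_rate * (1.0 - frac) + 0.01 * frac
                sigma = sigma0 * (1.0 - frac) + 0.2 * frac
                x = data[i]
                bmu = int(np.argmin(((self.codebook - x) ** 2).sum(axis=1)))
                theta = np.exp(-self._grid_sq_dist[bmu] / (2.0 * sigma**2))
                self.codebook += (lr * theta)[:, None] * (x - self.codebook)
                step += 1
        return self

    def predict(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        d2 = ((data[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


@dataclass
class SubclusterResult:
    """Per-cell SOM node, consensus cluster and (after merging) label."""

    assignments: pd.DataFrame  # index = cell index of the parent subset
    codebook: np.ndarray
    node_clusters: np.ndarray  # consensus cluster id (1-based) per map node
    parent: str = ""
    branch: str | None = None
    config: SOMConfig = field(default_factory=SOMConfig)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.assignments["som_cluster"].unique())


def som_subcluster(
    subset: pd.DataFrame,
    config: SOMConfig,
    parent: str = "",
    branch: str | None = None,
) -> SubclusterResult:
    """Cluster one metacluster subset into ``config.n_clusters`` consensus
    clusters via SOM + average-linkage merging of the codebook."""
    if len(subset) == 0:
        raise ParameterError("cannot subcluster an empty subset")
    if len(subset) < config.n_clusters:
        raise ParameterError(
            f"subset has {len(subset)} cells but n_clusters={config.n_clusters}; "
            "choose a smaller n_clusters"
        )
    markers = config.markers
    if markers is None:
        raise ConfigurationError("SOMConfig.markers must list the clustering markers")
    missing = [m for m in markers if m not in subset.columns]
    if missing:
        raise ConfigurationError(f"markers not in table: {missing}")
    data = subset[markers].to_numpy(dtype=float)
    som = SelfOrganizingMap(config.grid_rows, config.grid_cols, len(markers), seed=config.seed)
    som.fit(data, epochs=config.epochs, learning_rate=config.learning_rate)
    merger = AgglomerativeClustering(
        n_clusters=config.n_clusters, linkage="average", metric="euclidean"
    )
    node_clusters = merger.fit_predict(som.codebook) + 1  # 1-based ids
    nodes = som.predict(data)
    assignments = pd.DataFrame(
        {
            "som_node": nodes,
            "som_cluster": node_clusters[nodes],
        },
        index=subset.index,
    )
    assignments["parent_metacluster"] = parent
    assignments["branch"] = branch if branch is not None else ""
    return SubclusterResult(
        assignments=assignments,
        codebook=som.codebook,
        node_clusters=node_clusters,
        parent=parent,
        branch=branch,
        config=config,
    )


def merge_annotate(result: SubclusterResult, merge_map: dict[int, str]) -> SubclusterResult:
    """Apply a cluster-id -> label map; ids sharing a label are merged.

    The map must cover every observed cluster id.  The sentinel label
    ``"exclude"`` marks cells as excluded without dropping them.
    """
    observed = {int(c) for c in result.assignments["som_cluster"].unique()}
    unmapped = sorted(observed - set(merge_map))
    if unmapped:
        raise ConfigurationError(
            f"merge map does not cover cluster ids: {unmapped}"
        )
    assignments = result.assignments.copy()
    assignments["subcluster"] = assignments["som_cluster"].map(merge_map)
    assignments["excluded"] = assignments["subcluster"] == EXCLUDE_LABEL
    return SubclusterResult(
        assignments=assignments,
        codebook=result.codebook,
        node_clusters=result.node_clusters,
        parent=result.parent,
        branch=result.branch,
        config=result.config,
    )


def integrate_subclusters(
    master: pd.DataFrame, results: list[SubclusterResult]
) -> pd.DataFrame:
    """Fold labeled subcluster results back into the master annotated table.

    Every cell keeps its metacluster; subclustered cells gain a ``subcluster``
    label and an ``excluded`` flag; cells of un-subclustered metaclusters get
    ``subcluster = None``.  A cell appearing in two results is an integrity
    error.
    """
    out = master.copy()
    out["subcluster"] = None
    out["excluded"] = False
    seen: set = set()
    for result in results:
        assignments = result.assignments
        if "subcluster" not in assignments.columns:
            raise ConfigurationError(
                "results must be merge-annotated before integration"
            )
        idx = assignments.index
        overlap = seen & set(idx)
        if overlap:
            raise IntegrityError(
                f"cells present in more than one subcluster result: "
                f"{sorted(overlap)[:10]}"
            )
        outside = set(idx) - set(out.index)
        if outside:
            raise IntegrityError(
                f"subcluster result contains cells not in the master table: "
                f"{sorted(outside)[:10]}"
            )
        seen |= set(idx)
        out.loc[idx, "subcluster"] = assignments["subcluster"]
        out.loc[idx, "excluded"] = assignments["excluded"].to_numpy()
    return out
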