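"""Dimensionality reduction and density-based cluster discovery.

The single-cell marker table is projected to two dimensions with UMAP
(optionally supervised by predefined phenotype labels, which pulls cells
of the same phenotype together) and clustered with HDBSCAN, which finds
density-based clusters of arbitrary shape and labels sparse cells as
noise (-1). Cluster-level marker profiles and phenotype-composition
tables summarize the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .profiling import SingleCellTable, zscore_matrix


@dataclass
class EmbeddingParams:
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    seed: int = 0


@dataclass
class Embedding:
    coords: np.ndarray          # (n_cells, 2)
    params: EmbeddingParams
    supervised: bool = False


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # per-cell id, -1 = noise

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def n_noise(self) -> int:
        return int((self.labels < 0).sum())


def embed(table: SingleCellTable,
          params: Optional[EmbeddingParams] = None,
          phenotype_labels: Optional[Sequence[str]] = None) -> Embedding:
    """UMAP projection of the z-scored log-intensity matrix to 2-D.

    With ``phenotype_labels``, the supervised projection is used so that
    predefined phenotypes are drawn together. Deterministic under a fixed
    seed.
    """
    import umap  # deferred: numba compilation is slow at import

    params = params or EmbeddingParams()
    if len(table) <= params.n_neighbors:
        raise ValueError(
            f"{len(table)} cells is too few for n_neighbors="
            f"{params.n_neighbors}")
    x = zscore_matrix(table).to_numpy()
    reducer = umap.UMAP(n_components=2, n_neighbors=params.n_neighbors,
                        min_dist=params.min_dist, metric=params.metric,
                        random_state=params.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if phenotype_labels is not None:
            y = pd.Categorical(list(phenotype_labels)).codes
            coords = reducer.fit_transform(x, y=y)
        else:
            coords = reducer.fit_transform(x)
    return Embedding(np.asarray(coords, dtype=np.float64), params,
                     supervised=phenotype_labels is not None)


def cluster(embedding: Embedding,
            min_cluster_size: Optional[int] = None,
            allow_single_cluster: bool = True) -> ClusterAssignment:
    """HDBSCAN on the 2-D embedding; default min_cluster_size is
    max(10, 1% of cells).

    ``allow_single_cluster`` lets the hierarchy root be selected, so a
    dataset that genuinely forms one dense group comes back as one
    cluster instead of all noise.
    """
    n = len(embedding.coords)
    if min_cluster_size is None:
        min_cluster_size = max(10, n // 100)
    if min_cluster_size > n:
        return ClusterAssignment(np.full(n, -1, dtype=int))
    labels = HDBSCAN(min_cluster_size=min_cluster_size,
                     allow_single_cluster=allow_single_cluster,
                     copy=True).fit_predict(embedding.coords)
    return ClusterAssignment(np.asarray(labels, dtype=int))


def cluster_profiles(table: SingleCellTable,
                     assignment: ClusterAssignment) -> pd.DataFrame:
    """cluster x marker mean matrix, z-scored across clusters per marker.

    Noise cells (label -1) are excluded. Raises when no clusters exist.
    """
    labels = assignment.labels
    if len(labels) != len(table):
        raise ValueError("assignment is not aligned to the table")
    if assignment.n_clusters == 0:
        raise ValueError("no clusters to profile")
    df = table.data[table.markers].copy()
    df["cluster"] = labels
    means = df[df["cluster"] >= 0].groupby("cluster").mean()
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    z = (means - mu).div(sd.where(sd > 0, 1.0), axis=1)
    z[means.columns[sd == 0]] = 0.0
    return z


def composition(assignment: ClusterAssignment,
                phenotypes: Sequence[str],
                normalize: bool = False) -> pd.DataFrame:
    """Phenotype x cluster contingency table (counts, or row-normalized
    fractions when ``normalize``). Noise cells appear in column -1."""
    labels = np.asarray(assignment.labels)
    phen = pd.Series(list(phenotypes), name="phenotype")
    if len(labels) != len(phen):
        raise ValueError("phenotype and cluster vectors differ in length")
    tab = pd.crosstab(phen, pd.Series(labels, name="cluster"))
    if normalize:
        tab = tab.div(tab.sum(axis=1), axis=0)
    return tab


def plot_embedding(embedding: Embedding, labels: Sequence, path) -> None:
    """Scatter the 2-D embedding colored by cluster or phenotype labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for lab in pd.unique(labels):
        m = labels == lab
        ax.scatter(embedding.coords[m, 0], embedding.coords[m, 1],
                   s=6, label=str(lab))
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=7, markerscale=2, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_heatmap(profiles: pd.DataFrame, path) -> None:
    """Heat map of the cluster x marker z-scored mean-intensity matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(profiles.columns) + 2,
                                    0.4 * len(profiles) + 2))
    im = ax.imshow(profiles.to_numpy(), cmap="RdBu_r", aspect="auto",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(profiles.columns)), profiles.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(profiles)),
                  [f"cluster {i}" for i in profiles.index], fontsize=8)
    fig.colorbar(im, ax=ax, label="z-scored mean intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
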