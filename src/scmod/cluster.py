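"""Clustering of cells on gene-body modification levels, and marker genes.

Cells are embedded by PCA on standardized gene-body levels, clustered either
by a shared-nearest-neighbor graph with modularity community detection or by
k-means, and optionally given a 2-D t-SNE for visualization (labels are never
derived from the embedding).  Markers are genes whose level distributions
differ between a cluster and the rest by a two-sided Wilcoxon rank-sum test
with Benjamini-Hochberg correction; genes detected (non-missing) in fewer
than ``min_pct`` of cells on both sides are not tested.  Missing levels are
excluded from tests rather than imputed — imputation would fabricate
evidence for coverage-limited data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .qc import CellQCRecord


@dataclass
class AnalysisMatrix:
    """Standardized matrix for reduction plus raw levels for marker tests."""

    X: pd.DataFrame  # cells x genes, imputed + z-scored
    raw: pd.DataFrame  # cells x genes, NaN where missing


@dataclass
class ClusterResult:
    labels: pd.Series  # cell -> cluster label (int)
    embedding: pd.DataFrame | None  # cells x (tsne1, tsne2)
    params: dict = field(default_factory=dict)


def build_matrix(
    region_levels: pd.DataFrame,
    qc: Sequence[CellQCRecord] | None = None,
    max_missing: float = 0.8,
) -> AnalysisMatrix:
    """Assemble the cells x genes analysis matrix from long-format levels.

    QC-failing cells are dropped; genes missing in more than ``max_missing``
    of remaining cells are dropped, as are zero-variance genes; remaining
    missing entries are imputed with the gene mean and each gene is z-scored
    — for the reduction step only.  Raw (unimputed) levels are retained for
    marker testing.
    """
    raw = region_levels.pivot(index="cell", columns="region_id", values="level")
    if qc is not None:
        passing = [r.cell for r in qc if r.passed]
        raw = raw.loc[raw.index.intersection(passing)]
    if raw.shape[0] < 2:
        raise ValueError(f"need at least 2 cells after QC, got {raw.shape[0]}")
    missing_frac = raw.isna().mean(axis=0)
    raw = raw.loc[:, missing_frac <= max_missing]
    spread = raw.max(axis=0, skipna=True) - raw.min(axis=0, skipna=True)
    raw = raw.loc[:, (spread > 0).fillna(False)]  # constant genes carry no signal
    X = raw.copy()
    X = X.fillna(X.mean(axis=0))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    return AnalysisMatrix(X=X, raw=raw)


def _snn_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    k_eff = min(k, len(pcs) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = [set(row[1:]) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(len(pcs)):
        for j in idx[i][1:]:
            if j <= i:
                continue
            shared = len(neigh[i] & neigh[int(j)])
            union = len(neigh[i] | neigh[int(j)])
            w = shared / union
            if w > 0:
                edges.append((i, int(j)))
                weights.append(w)
    g = igraph.Graph(n=len(pcs), edges=edges)
    g.es["weight"] = weights
    return g


def reduce_and_cluster(
    matrix: AnalysisMatrix,
    n_pcs: int = 20,
    method: str = "graph",
    k_or_resolution: float | None = None,
    seed: int = 0,
    embed: bool = True,
    n_neighbors: int = 15,
) -> ClusterResult:
    """PCA reduction followed by graph community detection or k-means.

    ``graph`` mode builds a shared-nearest-neighbor graph on the PC space
    and partitions it with Leiden modularity optimization
    (``k_or_resolution`` is the resolution, default 1.0); ``kmeans`` runs
    k-means with ``k_or_resolution`` clusters (default 2).  A 2-D t-SNE of
    the PC space is attached for plotting only.  Deterministic per seed.
    """
    X = matrix.X.to_numpy()
    n_cells, n_genes = X.shape
    if n_genes == 0:
        # all genes constant across cells: no structure, one cluster
        return ClusterResult(
            labels=pd.Series(0, index=matrix.X.index, name="cluster"),
            embedding=None,
            params={"n_pcs": 0, "method": method, "k_or_resolution": k_or_resolution,
                    "n_neighbors": n_neighbors, "seed": seed},
        )
    max_pcs = min(n_cells - 1, n_genes)
    if n_pcs > max_pcs:
        import logging

        logging.getLogger(__name__).warning("n_pcs=%d clamped to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    if method == "graph":
        resolution = 1.0 if k_or_resolution is None else float(k_or_resolution)
        g = _snn_graph(pcs, n_neighbors)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        labels = np.asarray(part.membership)
    elif method == "kmeans":
        k = 2 if k_or_resolution is None else int(k_or_resolution)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(pcs)
    else:
        raise ValueError("method must be 'graph' or 'kmeans'")
    embedding = None
    if embed:
        perplexity = min(30.0, max(2.0, (n_cells - 1) / 3))
        ts = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
        ).fit_transform(pcs)
        embedding = pd.DataFrame(ts, index=matrix.X.index, columns=["tsne1", "tsne2"])
    return ClusterResult(
        labels=pd.Series(labels, index=matrix.X.index, name="cluster"),
        embedding=embedding,
        params={
            "n_pcs": n_pcs,
            "method": method,
            "k_or_resolution": k_or_resolution,
            "n_neighbors": n_neighbors,
            "seed": seed,
        },
    )


MARKER_COLUMNS = [
    "gene",
    "cluster",
    "mean_in",
    "mean_out",
    "pct_in",
    "pct_out",
    "p_value",
    "p_adj",
    "selected",
]


def find_markers(
    raw_levels: pd.DataFrame,
    labels: pd.Series,
    cluster: int,
    min_pct: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential gene-body levels of one cluster against all other cells.

    Per gene, cells with a non-missing level enter a two-sided Wilcoxon
    rank-sum test of in-cluster vs rest.  ``pct_in``/``pct_out`` are the
    detected (non-missing) fractions; genes with ``max(pct) < min_pct`` are
    untested, as are genes with fewer than 3 detected cells on either side.
    p-values are BH-adjusted over tested genes and rows with
    ``p_adj < alpha`` are flagged selected.  Sorted by p_adj then |Δmean|.
    """
    in_mask = (labels == cluster).reindex(raw_levels.index).fillna(False).to_numpy(bool)
    if in_mask.sum() == 0:
        raise ValueError(f"cluster {cluster} is empty")
    rows = []
    for gene in raw_levels.columns:
        col = raw_levels[gene].to_numpy(float)
        inside = col[in_mask]
        outside = col[~in_mask]
        det_in = ~np.isnan(inside)
        det_out = ~np.isnan(outside)
        pct_in = det_in.mean() if len(inside) else 0.0
        pct_out = det_out.mean() if len(outside) else 0.0
        if max(pct_in, pct_out) < min_pct:
            continue
        a, b = inside[det_in], outside[det_out]
        if len(a) < 3 or len(b) < 3:
            continue
        if np.all(a == a[0]) and np.all(b == a[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((gene, cluster, float(a.mean()), float(b.mean()), pct_in, pct_out, p))
    if not rows:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    out = pd.DataFrame(
        rows, columns=["gene", "cluster", "mean_in", "mean_out", "pct_in", "pct_out", "p_value"]
    )
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["selected"] = out["p_adj"] < alpha
    out["_delta"] = (out["mean_in"] - out["mean_out"]).abs()
    out = out.sort_values(["p_adj", "_delta"], ascending=[True, False], kind="mergesort")
    return out.drop(columns="_delta").reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic two-population generator (study-condition fixture)
# ---------------------------------------------------------------------------

def simulate_population_levels(
    n_cells_a: int = 48,
    n_cells_b: int = 48,
    n_genes: int = 200,
    n_shifted: int = 30,
    level_a: float = 0.2204,
    level_b: float = 0.0929,
    shift: float = 0.15,
    mean_calls: float = 30.0,
    min_calls: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate gene-body levels for two cell populations.

    The two global levels default to hippocampal neuron vs non-neuron
    global 5hmC (22.04% vs 9.29%). All genes sit near their population's
    global level (gene-specific baselines jittered by ±0.03); ``n_shifted``
    genes additionally differ by ``shift`` between populations.  Per cell
    and gene the total call count is Poisson(``mean_calls``) and modified
    calls are binomial; entries under ``min_calls`` are missing, matching
    the gene-body aggregation rule.

    Returns (long-format region levels, truth labels, shifted gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1}" for i in range(n_genes)]
    shifted = list(rng.choice(genes, size=n_shifted, replace=False))
    jitter = rng.uniform(-0.03, 0.03, size=n_genes)
    rows = []
    cells, labels = [], []
    for pop, (n_cells, base) in enumerate([(n_cells_a, level_a), (n_cells_b, level_b)]):
        for ci in range(n_cells):
            cell = f"pop{pop}_cell{ci + 1}"
            cells.append(cell)
            labels.append(pop)
            for gi, gene in enumerate(genes):
                p = base + jitter[gi]
                if gene in shifted and pop == 1:
                    p += shift
                p = float(np.clip(p, 0.0, 1.0))
                n_total = int(rng.poisson(mean_calls))
                if n_total < min_calls:
                    continue
                n_mod = int(rng.binomial(n_total, p))
                rows.append((gene, cell, n_mod, n_total, n_mod / n_total))
    levels = pd.DataFrame(rows, columns=["region_id", "cell", "n_mod", "n_total", "level"])
    return levels, pd.Series(labels, index=cells, name="truth"), shifted
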