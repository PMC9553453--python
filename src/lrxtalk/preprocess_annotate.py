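"""Normalization, variable-gene selection, embedding, clustering and
marker-based cell-type annotation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConfigError, FormatError
from .io_core import CountMatrix, ExprMatrix

logger = logging.getLogger(__name__)

#: Default marker map used when no marker file is supplied.
DEFAULT_MARKERS: dict[str, list[str]] = {
    "tumor": ["EPCAM", "SOX4", "MDK"],
    "epithelial": ["SFTPD", "AGR3", "FOLR1"],
    "macrophage": ["CD163", "LYZ"],
    "langerhans": ["FCER1A"],
    "granulocyte": ["ELANE"],
}


def normalize_log(counts: CountMatrix, scale_factor: float = 10_000.0) -> ExprMatrix:
    """Library-size normalize to ``scale_factor`` and log2(1+x) transform.

    entry = log2(1 + scale_factor * count / cell_total). A zero-total cell is
    an error (it cannot be normalized).
    """
    if scale_factor <= 0:
        raise ConfigError("scale_factor must be positive")
    totals = counts.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [counts.cell_ids[i] for i in zero[:5]]
        raise FormatError(f"cells with zero total count: {names}")
    scaled = counts.values * (scale_factor / totals[:, None])
    return ExprMatrix(
        np.log2(1.0 + scaled), list(counts.cell_ids), list(counts.gene_symbols),
        scale_factor=scale_factor,
    )


def select_hvg(expr: ExprMatrix, n: int = 2000) -> list[str]:
    """Top ``n`` genes by variance of log expression, ties broken by symbol."""
    if n > len(expr.gene_symbols):
        raise ConfigError(
            f"requested {n} variable genes but matrix has {len(expr.gene_symbols)}"
        )
    var = expr.values.var(axis=0, ddof=0)
    order = sorted(range(len(var)), key=lambda i: (-var[i], expr.gene_symbols[i]))
    return [expr.gene_symbols[i] for i in order[:n]]


def embed_pca(expr: ExprMatrix, hvg: list[str], n_components: int = 20) -> np.ndarray:
    """PCA embedding of cells on centered, unit-scaled HVG expression."""
    hvg = [g.strip().upper() for g in hvg]
    idx = [expr.gene_index(g) for g in hvg]
    x = expr.values[:, idx]
    if n_components > min(x.shape):
        raise ConfigError(
            f"n_components={n_components} exceeds min(cells, genes)={min(x.shape)}"
        )
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ConfigError("all selected genes are constant; cannot embed")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    return pca.fit_transform(x)


def cluster_kmeans(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Plumbing k-means on the embedding; returns integer labels per cell."""
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(embedding)


def annotate_clusters(
    expr: ExprMatrix,
    clusters,
    markers: dict[str, list[str]] | None = None,
    min_score: float = 0.5,
) -> pd.DataFrame:
    """Assign a cell type to each cluster by standardized marker scores.

    Per cluster and type: score is the mean, over the type's marker genes, of
    the cluster-mean expression standardized per gene across clusters. A
    cluster is labeled with the argmax type if the max score reaches
    ``min_score``, else "unassigned". Ties break by type-name order with a
    warning. Markers absent from the matrix are skipped with a log message;
    a type with no present markers is skipped entirely.

    Returns a per-cell DataFrame with columns cell, cluster, cell_type.
    """
    markers = markers if markers is not None else DEFAULT_MARKERS
    clusters = np.asarray(clusters)
    if clusters.shape[0] != expr.n_cells:
        raise ConfigError("cluster labels must cover every cell")

    labels = pd.unique(clusters)
    cluster_means = np.vstack(
        [expr.values[clusters == c].mean(axis=0) for c in labels]
    )  # clusters x genes
    sd = cluster_means.std(axis=0, ddof=0)
    mean = cluster_means.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        zmat = np.where(sd > 0, (cluster_means - mean) / sd, 0.0)

    gene_pos = {g: i for i, g in enumerate(expr.gene_symbols)}
    type_scores: dict[str, np.ndarray] = {}
    for cell_type in sorted(markers):
        idx = []
        for g in markers[cell_type]:
            gi = gene_pos.get(g.strip().upper())
            if gi is None:
                logger.info("marker %s for type %s absent; skipped", g, cell_type)
            else:
                idx.append(gi)
        if not idx:
            logger.warning("type %s has no markers in matrix; skipped", cell_type)
            continue
        type_scores[cell_type] = zmat[:, idx].mean(axis=1)

    assignment: dict = {}
    types = sorted(type_scores)
    for ci, c in enumerate(labels):
        if not types:
            assignment[c] = "unassigned"
            continue
        scores = np.array([type_scores[t][ci] for t in types])
        best = float(scores.max())
        if best < min_score:
            assignment[c] = "unassigned"
            continue
        winners = [t for t, s in zip(types, scores) if s == best]
        if len(winners) > 1:
            logger.warning("cluster %r marker-score tie among %s", c, winners)
        assignment[c] = winners[0]

    return pd.DataFrame(
        {
            "cell": expr.cell_ids,
            "cluster": clusters,
            "cell_type": [assignment[c] for c in clusters],
        }
    )


def summarize_composition(groups) -> pd.DataFrame:
    """Tabulate group sizes with percentages to one decimal.

    ``groups`` is any per-cell label sequence (e.g. a sample_type or cell_type
    column). Percentages are 100*count/total rounded to one decimal place.
    """
    s = pd.Series(list(groups))
    if s.empty:
        raise ConfigError("empty annotation")
    counts = s.value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "group": counts.index,
            "count": counts.to_numpy(),
            "percentage": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    ).reset_index(drop=True)


def subcluster(
    expr: ExprMatrix,
    cells,
    n_subclusters: int = 4,
    n_hvg: int = 500,
    n_components: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Re-embed and k-means a cell subset (e.g. macrophages) into subtypes."""
    idx = expr.cell_indices(cells)
    sub = ExprMatrix(
        expr.values[idx], [expr.cell_ids[i] for i in idx], list(expr.gene_symbols),
        scale_factor=expr.scale_factor,
    )
    hvg = select_hvg(sub, min(n_hvg, len(sub.gene_symbols)))
    emb = embed_pca(sub, hvg, min(n_components, len(hvg), sub.n_cells))
    labels = cluster_kmeans(emb, n_subclusters, seed=seed)
    return pd.Series(labels, index=sub.cell_ids, name="subtype")
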