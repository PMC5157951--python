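"""Exploratory statistics: centered PCA of expression, Euclidean sample
clustering, replicate correlations, GO background-list construction and
contingency-table chi-square tests.

Expression enters every multivariate computation as log2(RPKM + 1); the PCA
centers each gene (mean zero across samples) but does not scale, so highly
expressed genes keep their larger variances, as is conventional for
tissue-structure overviews of bulk RNA-seq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray
    genes_used: list[str]


def pca_expression(expr: pd.DataFrame, rpkm_min: float = 1.0) -> PCAResult:
    """Centered (not scaled) PCA of log2(RPKM + 1) on expressed genes.

    Genes pass the filter when RPKM > rpkm_min in at least one sample.
    Scores are the SVD projections of the samples x genes table.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = expr.index[(expr > rpkm_min).any(axis=1)]
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes pass the expression filter")
    X = np.log2(expr.loc[keep].to_numpy(dtype=float).T + 1.0)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    var = S**2 / (S**2).sum()
    n_comp = min(X.shape) - 0
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=cols),
        variance_ratio=var,
        genes_used=list(keep),
    )


def sample_distance_clustering(
    expr: pd.DataFrame, method: str = "complete"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Euclidean distances on log2(RPKM + 1) plus a linkage matrix."""
    X = np.log2(expr.to_numpy(dtype=float).T + 1.0)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    dist = pd.DataFrame(d, index=expr.columns, columns=expr.columns)
    Z = linkage(squareform(d, checks=False), method=method)
    return dist, Z


def replicate_correlation(
    expr: pd.DataFrame,
    sample_pairs: list[tuple[str, str]],
    rpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Pearson/Spearman between replicate samples on expressed genes.

    A gene counts as expressed for a pair when its RPKM exceeds rpkm_min in
    at least one of the two samples.
    """
    rows = []
    for a, b in sample_pairs:
        sub = expr[[a, b]]
        sub = sub[(sub > rpkm_min).any(axis=1)]
        if len(sub) < 3:
            warnings.warn(f"fewer than 3 expressed genes for pair ({a}, {b})")
            rows.append((a, b, np.nan, np.nan, len(sub)))
            continue
        x = np.log2(sub[a].to_numpy() + 1.0)
        y = np.log2(sub[b].to_numpy() + 1.0)
        rows.append(
            (a, b, float(stats.pearsonr(x, y)[0]), float(stats.spearmanr(x, y)[0]), len(sub))
        )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "pearson", "spearman", "n_genes"]
    )


def build_go_background(
    de_genes: list[str],
    counts: pd.DataFrame,
    relevant_samples: list[str],
    biotypes: pd.Series | None = None,
) -> list[str]:
    """Background gene list for GO enrichment.

    The threshold is the minimum, over the differentially expressed genes,
    of their read counts summed across the relevant samples; the background
    is every (protein-coding, if biotypes given) gene with an equal or
    higher summed count — so it always contains the DE genes themselves.
    """
    if not de_genes:
        raise ValueError("empty DE gene list")
    missing = set(de_genes) - set(counts.index)
    if missing:
        raise ValueError(f"DE genes absent from count table: {sorted(missing)[:5]}")
    sums = counts[relevant_samples].sum(axis=1)
    threshold = sums.loc[list(de_genes)].min()
    background = sums.index[sums >= threshold]
    if biotypes is not None:
        coding = set(biotypes.index[biotypes == "protein_coding"])
        background = [g for g in background if g in coding or g in set(de_genes)]
    return sorted(background)


def chisq_contingency(
    table: np.ndarray | pd.DataFrame, continuity: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table.

    Returns (statistic, degrees of freedom, p-value); no continuity
    correction unless asked. Zero row or column margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _exp = stats.chi2_contingency(t, correction=continuity)
    return float(stat), int(df), float(p)


def hypergeometric_enrichment(
    focal: set[str], background: set[str], term_map: dict[str, set[str]]
) -> pd.DataFrame:
    """Plain hypergeometric term enrichment over a user-supplied gene->term
    map. Optional plumbing: this is a generic over-representation test, not
    a re-implementation of any particular GO enrichment server."""
    focal = focal & background
    rows = []
    for term, members in term_map.items():
        m = members & background
        k = len(m & focal)
        p = stats.hypergeom.sf(k - 1, len(background), len(m), len(focal))
        rows.append((term, k, len(m), float(p)))
    out = pd.DataFrame(rows, columns=["term", "n_focal", "n_background", "pvalue"])
    return out.sort_values("pvalue").reset_index(drop=True)
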