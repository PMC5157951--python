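"""Per-tissue negative-binomial GLM tests of genotype effect.

For each gene and tissue, a log-link NB GLM with offsets log(size factor)
contrasts a full model (intercept + genotype) against an intercept-only
null; the likelihood-ratio statistic is referred to chi-square with 1 df.
Because genotype is a two-level factor, the full model's likelihood
separates into two independent one-dimensional problems (one log-mean per
genotype group), which are maximized numerically with a fixed per-gene
dispersion estimated by the method of moments on size-factor-normalized
counts (floored at 1e-8, shared between full and null fits). This is a
deliberately transparent simplification of the DESeq2-style machinery: no
dispersion shrinkage, no fold-change shrinkage, no independent filtering,
no outlier handling.

P-values from all tissues are pooled into a single Benjamini-Hochberg
correction, and genes are classified up/down at strict fold-change and FDR
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
_LOG_MEAN_BOUNDS = (-30.0, 30.0)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed on all-positive genes)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; supply size factors "
            "from a pseudo-reference instead"
        )
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)  # log geometric mean
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with Var = mu + alpha * mu^2 (size r = 1/alpha)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_group(y: np.ndarray, s: np.ndarray, alpha: float) -> tuple[float, float]:
    """Maximize the NB log-likelihood over one log-mean with offsets log(s).

    Returns (beta_hat, loglik). The problem is concave in beta; a bounded
    scalar minimization is robust including for all-zero groups (beta at the
    lower bound, mu ~ 0).
    """
    if y.sum() == 0:
        beta = _LOG_MEAN_BOUNDS[0]
        return beta, _nb_loglik(y, s * np.exp(beta), alpha)
    start = np.log(y.sum() / s.sum())

    def nll(beta: float) -> float:
        return -_nb_loglik(y, s * np.exp(beta), alpha)

    res = optimize.minimize_scalar(
        nll,
        bounds=(max(start - 15.0, _LOG_MEAN_BOUNDS[0]), start + 15.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun)


def moment_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series,
    pooled_floor: bool = True,
) -> pd.Series:
    """Method-of-moments dispersion on normalized counts, pooled within group.

    alpha = max((v - m) / m^2, floor) with m the overall mean and v the
    within-group pooled variance of counts / size_factor; pooling within
    genotype keeps a real genotype effect out of the dispersion estimate.

    With few replicates the per-gene moment estimate is extremely noisy and
    underestimates the dispersion for half the genes, which would make the
    likelihood-ratio test anticonservative. ``pooled_floor`` therefore also
    floors each gene at the across-gene median estimate — a conservative
    information-sharing step in the spirit of the "maximum" sharing mode of
    early NB differential-expression methods.
    """
    q = counts.div(size_factors, axis=1)
    m = q.mean(axis=1)
    ss = pd.Series(0.0, index=counts.index)
    dof = 0
    for _g, cols in groups.groupby(groups).groups.items():
        sub = q[list(cols)]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        dof += len(cols) - 1
    if dof <= 0:
        raise ValueError("need at least 2 replicates in some group")
    v = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = alpha.replace([np.inf, -np.inf], np.nan).fillna(DISPERSION_FLOOR)
    alpha = alpha.clip(lower=DISPERSION_FLOOR)
    if pooled_floor and len(alpha) > 1:
        expressed = m > 0
        if expressed.any():
            alpha[expressed] = alpha[expressed].clip(
                lower=float(alpha[expressed].median())
            )
    return alpha


def fit_nb_lrt(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    baseline: str = "wt",
    wald: bool = False,
) -> pd.DataFrame:
    """Per-gene genotype contrast within one tissue.

    Parameters
    ----------
    counts
        genes x samples integer counts for the tissue.
    design
        one row per sample with a ``genotype`` column (two levels); indexed
        by or containing ``sample_id`` matching the count columns.
    size_factors
        per-sample scaling; median-of-ratios when omitted.
    dispersion
        per-gene NB dispersion; method-of-moments when omitted.
    baseline
        genotype level treated as reference; log2FC is (other / baseline).
    wald
        also report a Wald z test on the genotype coefficient.

    Returns a frame with baseMean, log2FoldChange, dispersion, stat, pvalue
    (NaN for all-zero genes, which are never tested).
    """
    if "sample_id" in design.columns:
        design = design.set_index("sample_id")
    design = design.loc[list(counts.columns)]
    levels = pd.unique(design["genotype"])
    if len(levels) != 2:
        raise ValueError(f"need exactly two genotype levels, got {list(levels)}")
    if baseline not in levels:
        raise ValueError(f"baseline {baseline!r} not among genotypes {list(levels)}")
    other = [lv for lv in levels if lv != baseline][0]
    groups = design["genotype"]
    if (groups.value_counts() < 2).any():
        raise ValueError("each genotype needs >= 2 replicates")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    size_factors = size_factors.loc[list(counts.columns)]
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    if dispersion is None:
        dispersion = moment_dispersion(counts, groups, size_factors)

    s = size_factors.to_numpy(dtype=float)
    is_other = (groups == other).to_numpy()
    y_all = counts.to_numpy(dtype=float)

    rows = []
    for i, gene in enumerate(counts.index):
        y = y_all[i]
        alpha = float(dispersion.loc[gene])
        base_mean = float((y / s).mean())
        if y.sum() == 0:
            rows.append((gene, base_mean, np.nan, alpha, np.nan, np.nan, np.nan))
            continue
        b0, ll0_a = _fit_group(y[~is_other], s[~is_other], alpha)
        b1, ll1_a = _fit_group(y[is_other], s[is_other], alpha)
        ll_full = ll0_a + ll1_a
        bnull, ll_null = _fit_group(y, s, alpha)
        stat = max(2.0 * (ll_full - ll_null), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        log2fc = (b1 - b0) / np.log(2.0)
        if wald:
            info0 = _fisher_info(s[~is_other], np.exp(b0), alpha)
            info1 = _fisher_info(s[is_other], np.exp(b1), alpha)
            se = np.sqrt(1.0 / info0 + 1.0 / info1)
            z = (b1 - b0) / se
            p_wald = float(2.0 * stats.norm.sf(abs(z)))
        else:
            p_wald = np.nan
        rows.append((gene, base_mean, log2fc, alpha, stat, p, p_wald))

    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "baseMean",
            "log2FoldChange",
            "dispersion",
            "stat",
            "pvalue",
            "pvalue_wald",
        ],
    ).set_index("gene_id")
    if not wald:
        out = out.drop(columns="pvalue_wald")
    return out


def _fisher_info(s: np.ndarray, m: float, alpha: float) -> float:
    mu = s * m
    return float(np.sum(mu / (1.0 + alpha * mu)))


def adjust_fdr_joint(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg over the pooled vector; NaN entries preserved."""
    p = pvalues.astype(float)
    mask = p.notna()
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    if mask.any():
        out[mask] = multipletests(vals.to_numpy(), method="fdr_bh")[1]
    return out


def classify_de(
    results: pd.DataFrame, fc_threshold: float = 1.5, fdr_threshold: float = 0.05
) -> pd.Series:
    """up / down / ns / not_tested labels at strict thresholds."""
    lfc = results["log2FoldChange"]
    fdr = results["fdr"]
    cls = pd.Series("ns", index=results.index, dtype=object)
    cls[fdr.isna() | lfc.isna()] = "not_tested"
    sig = fdr.notna() & (fdr < fdr_threshold)
    cls[sig & (2.0**lfc > fc_threshold)] = "up"
    cls[sig & (2.0**lfc < 1.0 / fc_threshold)] = "down"
    return cls


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    baseline: str = "wt",
    wald: bool = False,
) -> pd.DataFrame:
    """Full pipeline: per-tissue LRT, pooled BH across tissues, classes.

    Returns a long frame indexed by (gene_id, tissue).
    """
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id")
    frames = []
    for tissue, sub in samples.groupby("tissue", sort=False):
        res = fit_nb_lrt(
            counts[list(sub.index)], sub.reset_index(), baseline=baseline, wald=wald
        )
        res["tissue"] = tissue
        frames.append(res.reset_index())
    long = pd.concat(frames, ignore_index=True).set_index(["gene_id", "tissue"])
    long["fdr"] = adjust_fdr_joint(long["pvalue"])
    long["class"] = classify_de(long, fc_threshold, fdr_threshold)
    return long


@dataclass
class SubsetSummary:
    n_expressed: int
    n_de: int
    n_up: int
    n_down: int
    percent_up: float
    chi2_stat: float | None
    chi2_p: float | None
    table: np.ndarray | None  # rows: set/complement; cols: up/down


def subset_summary(
    results_tissue: pd.DataFrame,
    gene_set: set[str],
    expr: pd.DataFrame,
    expressed_rpkm: float = 1.0,
) -> SubsetSummary:
    """Direction-of-change summary for a gene set in one tissue.

    Expressed genes have RPKM > ``expressed_rpkm`` in at least one sample of
    the tissue (either genotype). The enrichment test is a Pearson 2x2
    chi-square, no continuity correction, of (up vs down) x (set vs
    complement) among differentially expressed genes.
    """
    expressed = set(expr.index[(expr > expressed_rpkm).any(axis=1)])
    in_set = [g for g in results_tissue.index if g in gene_set and g in expressed]
    in_comp = [
        g for g in results_tissue.index if g not in gene_set and g in expressed
    ]
    cls = results_tissue["class"]

    def updown(genes: list[str]) -> tuple[int, int]:
        sub = cls.loc[genes]
        return int((sub == "up").sum()), int((sub == "down").sum())

    up_s, down_s = updown(in_set)
    up_c, down_c = updown(in_comp)
    n_de = up_s + down_s
    pct_up = 100.0 * up_s / n_de if n_de else float("nan")

    table = np.array([[up_s, down_s], [up_c, down_c]])
    if n_de == 0 or (up_c + down_c) == 0 or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate contingency table; enrichment test skipped")
        return SubsetSummary(len(in_set), n_de, up_s, down_s, pct_up, None, None, None)
    stat, p, _df, _exp = stats.chi2_contingency(table, correction=False)
    return SubsetSummary(
        n_expressed=len(in_set),
        n_de=n_de,
        n_up=up_s,
        n_down=down_s,
        percent_up=pct_up,
        chi2_stat=float(stat),
        chi2_p=float(p),
        table=table,
    )
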