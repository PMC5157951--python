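"""Strand-aware unique-read counting, RPKM and median-scaling normalization.

Counting rules
--------------
A read is assigned to a gene iff all of the following hold:

* it is unique-mapping (NH tag absent or 1, not secondary/supplementary),
* it carries at most 2 mismatches and no small insertion or deletion,
* its *transcript* strand — derived from the alignment strand under the
  library strandedness (default ``antisense``: dUTP/TruSeq-stranded
  libraries sequence the strand antisense to the mRNA) — matches the gene's
  strand,
* at least one aligned base overlaps the gene's flattened exons, and
* exactly one gene on that strand satisfies the overlap; reads touching the
  exons of two or more overlapping same-strand genes are discarded.

Per-sample totals are the unique mapped reads over the nuclear genome,
excluding mitochondrial chromosomes.

Normalization
-------------
RPKM values are rescaled across samples by a median-scaling procedure whose
standard is the ``n_standard`` (default 100) genes with the least expression
rank variation across samples among genes whose median RPKM falls in the
central 25-75% expression window — a data-driven stand-in for stably
expressed housekeeping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import FlattenedGeneModel

MITO_CHROMOSOMES = frozenset({"chrM", "MT"})
STRANDEDNESS = ("antisense", "sense", "unstranded")


@dataclass
class CountTable:
    """Unique-read counts per gene and sample, with per-sample totals."""

    counts: pd.DataFrame  # genes x samples, integers
    totals: pd.Series  # per-sample nuclear mapped reads

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any():
            raise ValueError("totals missing for some samples")


@dataclass
class ExpressionTable:
    """RPKM values, optionally median-scale normalized."""

    rpkm: pd.DataFrame  # genes x samples
    normalized: bool = False
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale_factors is None:
            self.scale_factors = pd.Series(1.0, index=self.rpkm.columns)


@dataclass
class NormalizationStandard:
    gene_ids: list[str]
    rank_scores: pd.Series  # per eligible gene: SD of within-sample rank
    scale_factors: pd.Series | None = None
    reference: float | None = None


def _transcript_strand(alignment_strand: str, strandedness: str) -> str | None:
    if strandedness == "unstranded":
        return None
    if strandedness == "sense":
        return alignment_strand
    return "-" if alignment_strand == "+" else "+"


def _exon_trees(
    models: list[FlattenedGeneModel],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in models:
        tree = trees.setdefault((m.chromosome, m.strand), IntervalTree())
        for a, b in m.intervals:
            tree[a:b] = m.gene_id
    return trees


def count_unique_reads(
    sam_path: str,
    models: list[FlattenedGeneModel],
    strandedness: str = "antisense",
    max_mismatches: int = 2,
    mito_chromosomes: frozenset[str] = MITO_CHROMOSOMES,
) -> tuple[pd.Series, int]:
    """Count reads per gene from one SAM/BAM file.

    Returns (per-gene counts, total unique nuclear mapped reads).
    """
    if strandedness not in STRANDEDNESS:
        raise ValueError(f"strandedness must be one of {STRANDEDNESS}")
    if not models:
        raise ValueError("empty model list")
    trees = _exon_trees(models)
    chromosomes = {m.chromosome for m in models} | set(mito_chromosomes)
    counts = {m.gene_id: 0 for m in models}
    total = 0

    with pysam.AlignmentFile(sam_path, "r") as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue
            chrom = read.reference_name
            if chrom not in chromosomes:
                raise ValueError(f"read on unknown chromosome {chrom!r}")
            if chrom in mito_chromosomes:
                continue
            total += 1
            if read.has_tag("NM") and read.get_tag("NM") > max_mismatches:
                continue
            if any(op in (1, 2) for op, _n in read.cigartuples or ()):
                continue  # insertions / deletions
            astrand = "-" if read.is_reverse else "+"
            tstrand = _transcript_strand(astrand, strandedness)
            hits: set[str] = set()
            for a, b in read.get_blocks():
                if tstrand is None:
                    for s in ("+", "-"):
                        tree = trees.get((chrom, s))
                        if tree is not None:
                            hits.update(iv.data for iv in tree.overlap(a, b))
                else:
                    tree = trees.get((chrom, tstrand))
                    if tree is not None:
                        hits.update(iv.data for iv in tree.overlap(a, b))
            if len(hits) == 1:
                counts[hits.pop()] += 1
    return pd.Series(counts, name="count"), total


def count_samples(
    sam_paths: dict[str, str],
    models: list[FlattenedGeneModel],
    strandedness: str = "antisense",
) -> CountTable:
    """Count every sample's SAM file into one genes x samples table."""
    cols = {}
    totals = {}
    for sid, path in sam_paths.items():
        cols[sid], totals[sid] = count_unique_reads(path, models, strandedness)
    return CountTable(counts=pd.DataFrame(cols), totals=pd.Series(totals))


def compute_rpkm(
    counts: CountTable, models: list[FlattenedGeneModel]
) -> ExpressionTable:
    """RPKM(g, s) = count / (exonic_kb) / (total mapped reads in millions)."""
    lengths = pd.Series({m.gene_id: m.exonic_length for m in models})
    lengths = lengths.reindex(counts.counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"no flattened model for counted genes: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("exonic_length must be positive for all counted genes")
    if (counts.totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    rpkm = counts.counts.div(lengths / 1e3, axis=0).div(counts.totals / 1e6, axis=1)
    return ExpressionTable(rpkm=rpkm, normalized=False)


def select_standard_genes(
    expr: ExpressionTable,
    n_standard: int = 100,
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> NormalizationStandard:
    """Pick the rank-stable, mid-expressed normalization standard.

    Eligibility: the gene's median RPKM across samples falls within the
    [q_low, q_high] quantiles of all genes' median RPKM. Score: standard
    deviation across samples of the gene's within-sample expression rank
    (average ranks on ties). The ``n_standard`` eligible genes with the
    smallest score win; ties break lexicographically on gene_id.
    """
    rpkm = expr.rpkm
    if rpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    med = rpkm.median(axis=1)
    lo, hi = med.quantile(q_low), med.quantile(q_high)
    eligible = med.index[(med >= lo) & (med <= hi)]
    if len(eligible) < n_standard:
        raise ValueError(
            f"only {len(eligible)} genes in the {q_low}-{q_high} expression "
            f"window; need {n_standard}"
        )
    ranks = rpkm.rank(axis=0, method="average")
    scores = ranks.loc[eligible].std(axis=1, ddof=1)
    order = scores.to_frame("score").assign(gene_id=scores.index)
    order = order.sort_values(["score", "gene_id"], kind="mergesort")
    chosen = order.index[:n_standard].tolist()
    return NormalizationStandard(gene_ids=chosen, rank_scores=scores)


def median_scale_normalize(
    expr: ExpressionTable, standard: NormalizationStandard
) -> ExpressionTable:
    """Rescale each sample so the standard genes' median RPKM is constant.

    f(s) = R / m(s) with m(s) the median RPKM of the standard genes in
    sample s and R the median of the m(s) across samples.
    """
    missing = set(standard.gene_ids) - set(expr.rpkm.index)
    if missing:
        raise ValueError(f"standard genes absent from expression table: {missing}")
    m = expr.rpkm.loc[standard.gene_ids].median(axis=0)
    if (m <= 0).any():
        bad = m.index[m <= 0].tolist()
        raise ValueError(f"standard-gene median is zero in samples: {bad}")
    reference = float(m.median())
    factors = reference / m
    standard.scale_factors = factors
    standard.reference = reference
    return ExpressionTable(
        rpkm=expr.rpkm.mul(factors, axis=1),
        normalized=True,
        scale_factors=factors,
    )


def normalize_expression(
    expr: ExpressionTable, n_standard: int = 100
) -> tuple[ExpressionTable, NormalizationStandard]:
    """Convenience: select the standard, then median-scale."""
    standard = select_standard_genes(expr, n_standard=n_standard)
    return median_scale_normalize(expr, standard), standard
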