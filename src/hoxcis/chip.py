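"""Polycomb target calling from H3K27me3 / input promoter coverage.

A gene is called a putative Polycomb target when the mean H3K27me3 coverage
over its promoter, normalized per million mapped reads, is at least
``cov_min`` (default 0.1) and at least ``ratio_min`` (default 5) times the
equally normalized input coverage — both thresholds inclusive — and its
promoter is free of satellite repeats, whose artifactual H3K27me3
enrichment would otherwise produce false targets. Input coverage tracks are
assumed already deduplicated upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FlattenedGeneModel

INPUT_PSEUDOCOUNT = 0.01
PROMOTER_MODES = ("upstream2kb", "centered4kb")


@dataclass
class PromoterScore:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    chip_mean: float  # normalized per million mapped reads
    input_mean: float
    ratio: float
    satellite_overlap: bool
    is_target: bool = False


def define_promoters(
    models: list[FlattenedGeneModel],
    chrom_sizes: dict[str, int],
    mode: str = "upstream2kb",
    size: int = 2_000,
) -> pd.DataFrame:
    """Per-gene promoter intervals from the flattened model's 5' end.

    ``upstream2kb``: [TSS - size, TSS) on +, [TSS, TSS + size) on -;
    ``centered4kb``: [TSS - size, TSS + size) on both strands. Intervals are
    clipped to chromosome bounds; genes without a model are skipped.
    """
    if mode not in PROMOTER_MODES:
        raise ValueError(f"mode must be one of {PROMOTER_MODES}")
    rows = []
    for m in models:
        limit = chrom_sizes[m.chromosome]
        tss = m.tss
        if mode == "upstream2kb":
            lo, hi = (tss - size, tss) if m.strand == "+" else (tss, tss + size)
        else:
            lo, hi = tss - size, tss + size
        lo, hi = max(0, lo), min(limit, hi)
        if hi <= lo:
            continue
        rows.append((m.gene_id, m.chromosome, lo, hi, m.strand))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id")


def score_promoters(
    chip_cov: dict[str, np.ndarray],
    input_cov: dict[str, np.ndarray],
    promoters: pd.DataFrame,
    repeats: pd.DataFrame | None = None,
    chip_total: float = 1e6,
    input_total: float = 1e6,
    pseudocount: float = INPUT_PSEUDOCOUNT,
) -> list[PromoterScore]:
    """Mean normalized coverage and ChIP/input ratio per promoter.

    Coverage means are divided by the total mapped reads in millions;
    ``pseudocount`` stabilizes the ratio against empty input. A promoter is
    satellite-flagged when any repeat whose name matches "Satellite"
    (case-insensitive) intersects it.
    """
    sat = None
    if repeats is not None and len(repeats):
        mask = repeats["name"].str.contains("satellite", case=False, na=False)
        sat = repeats[mask]
    scores = []
    for gene_id, row in promoters.iterrows():
        chrom = row["chromosome"]
        if chrom not in chip_cov or chrom not in input_cov:
            raise ValueError(f"coverage track missing chromosome {chrom!r}")
        lo, hi = int(row["start"]), int(row["end"])
        chip_mean = float(chip_cov[chrom][lo:hi].mean()) / (chip_total / 1e6)
        input_mean = float(input_cov[chrom][lo:hi].mean()) / (input_total / 1e6)
        ratio = chip_mean / (input_mean + pseudocount)
        overlap = False
        if sat is not None:
            hit = sat[
                (sat["chromosome"] == chrom) & (sat["start"] < hi) & (sat["end"] > lo)
            ]
            overlap = len(hit) > 0
        scores.append(
            PromoterScore(
                gene_id=gene_id,
                chromosome=chrom,
                start=lo,
                end=hi,
                strand=row["strand"],
                chip_mean=chip_mean,
                input_mean=input_mean,
                ratio=ratio,
                satellite_overlap=overlap,
            )
        )
    return scores


def call_targets(
    scores: list[PromoterScore], ratio_min: float = 5.0, cov_min: float = 0.1
) -> set[str]:
    """Inclusive thresholds on ratio and normalized ChIP coverage."""
    targets = set()
    for s in scores:
        s.is_target = (
            s.ratio >= ratio_min and s.chip_mean >= cov_min and not s.satellite_overlap
        )
        if s.is_target:
            targets.add(s.gene_id)
    return targets


def scores_table(scores: list[PromoterScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "chromosome": s.chromosome,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "chip_mean": s.chip_mean,
                "input_mean": s.input_mean,
                "ratio": s.ratio,
                "satellite_overlap": s.satellite_overlap,
                "is_target": s.is_target,
            }
            for s in scores
        ]
    ).set_index("gene_id")
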