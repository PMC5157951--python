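"""Locus-level quantification around the deletion: named strand-specific
regions (Hotair, AHotair, LAHotair, Ghostair), coverage segmentation with a
deletion-boundary-crossing flag, and expression correlation between
neighboring genes.

Region quantification follows the same RPKM arithmetic as gene expression,
with the region length in place of the exonic length; a read contributes
when its transcript strand matches the region strand and at least one
aligned base overlaps the region. Segmentation is a maximal-run scan over
per-base normalized coverage, a deliberately simple stand-in for de novo
transcript assembly: contiguous transcription crossing the collapsed
deletion junction is the read-through signature of the deletion allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .quantify import _transcript_strand


@dataclass
class NamedRegion:
    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    role: str = "custom"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscribedSegment:
    chromosome: str
    strand: str
    start: int
    end: int
    mean_coverage: float
    crosses_boundary: bool


def regions_from_bed(bed: pd.DataFrame, chromosome_sizes: dict[str, int]) -> list[NamedRegion]:
    regions = []
    for _, row in bed.iterrows():
        if row["end"] > chromosome_sizes.get(row["chromosome"], np.inf):
            raise ValueError(f"region {row['name']} outside chromosome bounds")
        regions.append(
            NamedRegion(
                name=row["name"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                role=row["name"] if row["name"] in ("Hotair", "AHotair", "LAHotair", "Ghostair") else "custom",
            )
        )
    return regions


def count_region_reads(
    sam_path: str,
    regions: list[NamedRegion],
    strandedness: str = "antisense",
    max_mismatches: int = 2,
) -> pd.Series:
    """Strand-matched read counts per named region from one SAM file.

    Applies the same read-quality filters as gene counting (unique, <= 2
    mismatches, no indels) but no single-gene assignment rule: regions are
    quantified independently.
    """
    counts = {r.name: 0 for r in regions}
    by_chrom: dict[str, list[NamedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    with pysam.AlignmentFile(sam_path, "r") as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue
            if read.has_tag("NM") and read.get_tag("NM") > max_mismatches:
                continue
            if any(op in (1, 2) for op, _n in read.cigartuples or ()):
                continue
            cands = by_chrom.get(read.reference_name)
            if not cands:
                continue
            astrand = "-" if read.is_reverse else "+"
            tstrand = _transcript_strand(astrand, strandedness)
            blocks = read.get_blocks()
            for r in cands:
                if tstrand is not None and r.strand != tstrand:
                    continue
                if any(a < r.end and b > r.start for a, b in blocks):
                    counts[r.name] += 1
    return pd.Series(counts, name="count")


def quantify_regions(
    sam_paths: dict[str, str],
    regions: list[NamedRegion],
    totals: pd.Series,
    strandedness: str = "antisense",
    scale_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-region, per-sample RPKM; optionally rescaled by the per-sample
    normalization factors from the gene-level median-scaling step."""
    cols = {}
    for sid, path in sam_paths.items():
        k = count_region_reads(path, regions, strandedness)
        lengths = pd.Series({r.name: r.length for r in regions})
        cols[sid] = k / (lengths / 1e3) / (totals[sid] / 1e6)
    rpkm = pd.DataFrame(cols)
    if scale_factors is not None:
        rpkm = rpkm.mul(scale_factors.reindex(rpkm.columns), axis=1)
    return rpkm


def segment_transcribed(
    coverage: np.ndarray,
    chromosome: str,
    strand: str,
    min_cov: float = 0.05,
    max_gap: int = 50,
    boundary: int | tuple[int, int] | None = None,
) -> list[TranscribedSegment]:
    """Maximal runs of per-base coverage >= min_cov, merging sub-max_gap gaps.

    ``boundary`` marks the deletion: in the collapsed deletion-allele
    coordinate system it is the single junction coordinate, which a segment
    crosses when the coordinate lies strictly inside it; in wild-type
    coordinates pass the (proximal, distal) breakpoint pair, and a segment
    crosses only when it spans the entire deleted interval.
    """
    cov = np.asarray(coverage, dtype=float)
    above = cov >= min_cov
    if not above.any():
        return []
    change = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(change[~above[change]] + 1)
    ends = list(change[above[change]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(cov.size)

    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    if boundary is None:
        lo = hi = None
    elif isinstance(boundary, tuple):
        lo, hi = boundary
    else:
        lo = hi = boundary
    segments = []
    for s, e in merged:
        crosses = lo is not None and s < lo and e > hi
        segments.append(
            TranscribedSegment(
                chromosome=chromosome,
                strand=strand,
                start=int(s),
                end=int(e),
                mean_coverage=float(cov[s:e].mean()),
                crosses_boundary=crosses,
            )
        )
    return segments


def segments_table(segments: list[TranscribedSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": s.chromosome,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "mean_coverage": s.mean_coverage,
                "crosses_boundary": s.crosses_boundary,
            }
            for s in segments
        ],
        columns=["chromosome", "start", "end", "strand", "mean_coverage", "crosses_boundary"],
    )


def correlate_pair(
    expr: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    samples: list[str] | None = None,
    offset: float = 1.0,
) -> dict[str, float]:
    """Pearson and Spearman correlation of log2(RPKM + offset) across samples."""
    cols = samples if samples is not None else list(expr.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    a = np.log2(expr.loc[gene_a, cols].to_numpy(dtype=float) + offset)
    b = np.log2(expr.loc[gene_b, cols].to_numpy(dtype=float) + offset)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        warnings.warn(f"constant expression vector for {gene_a} or {gene_b}; correlation undefined")
        return {"pearson": float("nan"), "spearman": float("nan")}
    return {
        "pearson": float(stats.pearsonr(a, b)[0]),
        "spearman": float(stats.spearmanr(a, b)[0]),
    }
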