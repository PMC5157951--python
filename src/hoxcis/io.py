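"""Readers and writers for the small text formats used across the pipeline.

bedGraph and BED are 0-based half-open. Coverage is held in memory as dense
per-base numpy arrays keyed by chromosome, which is practical at the toy
genome sizes this package targets (hundreds of kilobases).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chromosome", "start", "end", "name", "score", "strand"]


def coverage_to_bedgraph(cov: dict[str, np.ndarray], path: str) -> None:
    """Write dense per-base coverage as run-length bedGraph (zero runs omitted)."""
    rows = []
    for chrom in sorted(cov):
        arr = np.asarray(cov[chrom])
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        vals = arr[starts]
        keep = vals != 0
        for s, e, v in zip(starts[keep], ends[keep], vals[keep]):
            rows.append((chrom, int(s), int(e), float(v)))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"])
    df.to_csv(path, sep="\t", header=False, index=False)


def bedgraph_to_coverage(
    path: str, chrom_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Load a bedGraph into dense per-base arrays (one per chromosome)."""
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "value"],
        comment="#",
    )
    for chrom, sub in df.groupby("chromosome"):
        if chrom not in cov:
            raise ValueError(f"bedGraph chromosome {chrom!r} absent from chrom_sizes")
        arr = cov[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            if e > arr.size:
                raise ValueError(f"bedGraph interval [{s},{e}) beyond {chrom} length")
            arr[int(s) : int(e)] += v
    return cov


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue", "genotype", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
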