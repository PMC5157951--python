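"""Gene annotation containers, flattened gene models and GTF input/output.

The counting unit of the whole pipeline is the *flattened gene model*: the
per-gene disjoint union of exon intervals from the retained transcript
isoforms. Isoform retention follows the usual biotype filtering used for
bulk RNA-seq quantification of protein-coding genes: only ``protein_coding``
isoforms contribute for protein-coding genes (``retained_intron``,
``nonsense_mediated_decay`` etc. are dropped), while every annotated isoform
is kept for non-coding genes. Individual genes (typically Hox genes, whose
annotations carry read-through isoforms) can be pinned to a single canonical
isoform.

Coordinates are 0-based half-open internally; GTF is read and written as
1-based closed, per the format.
"""

from __future__ import annotations

import contextlib
import io
import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

#: Transcript classes that contribute exons for protein-coding genes.
CODING_CLASSES = frozenset({"protein_coding"})

#: Controlled vocabulary for transcript classes (open-ended; these are the
#: ones the pipeline treats specially).
KNOWN_CLASSES = (
    "protein_coding",
    "retained_intron",
    "nonsense_mediated_decay",
    "lncRNA",
    "processed_transcript",
)


@dataclass
class Transcript:
    transcript_id: str
    transcript_class: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if a < 0 or b <= a:
                raise ValueError(
                    f"transcript {self.transcript_id}: bad exon interval [{a}, {b})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class Gene:
    gene_id: str
    name: str
    biotype: str
    chromosome: str
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """5' end of the gene span on its strand."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]  # name -> length
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chromosome not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chromosome}")
            if g.end > self.chromosomes[g.chromosome]:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chromosome}")

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class FlattenedGeneModel:
    """Disjoint, sorted exon-union intervals of a gene's retained isoforms."""

    gene_id: str
    chromosome: str
    strand: str
    intervals: list[tuple[int, int]]

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list.

    Adjacent (touching) intervals are coalesced, so the result is the minimal
    representation of the covered base set.
    """
    out: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def flatten_gene_models(
    annotation: GenomeAnnotation,
    canonical_overrides: dict[str, str] | None = None,
    coding_classes: frozenset[str] = CODING_CLASSES,
) -> list[FlattenedGeneModel]:
    """Build flattened gene models under the isoform-retention rules.

    Parameters
    ----------
    annotation
        Parsed gene annotation.
    canonical_overrides
        Map of gene_id -> transcript_id pinning a gene to one canonical
        isoform (used for Hox genes, whose annotations include read-through
        and retained-intron isoforms).
    coding_classes
        Transcript classes retained for protein-coding genes.

    Genes left with no retained transcript are excluded and logged.
    """
    canonical_overrides = canonical_overrides or {}
    for gid, tid in canonical_overrides.items():
        gene = annotation.get(gid)  # raises KeyError for unknown gene
        if tid not in {t.transcript_id for t in gene.transcripts}:
            raise ValueError(
                f"canonical override for {gid} names absent transcript {tid}"
            )

    models: list[FlattenedGeneModel] = []
    for gene in annotation.genes:
        if gene.gene_id in canonical_overrides:
            keep = [
                t
                for t in gene.transcripts
                if t.transcript_id == canonical_overrides[gene.gene_id]
            ]
        elif gene.biotype == "protein_coding":
            keep = [t for t in gene.transcripts if t.transcript_class in coding_classes]
        else:
            # non-coding genes: all annotated isoforms contribute
            keep = list(gene.transcripts)
        if not keep:
            logger.warning(
                "gene %s has no retained transcript after filtering; excluded",
                gene.gene_id,
            )
            continue
        exons = [iv for t in keep for iv in t.exons]
        models.append(
            FlattenedGeneModel(
                gene_id=gene.gene_id,
                chromosome=gene.chromosome,
                strand=gene.strand,
                intervals=merge_intervals(exons),
            )
        )
    return models


# ---------------------------------------------------------------------------
# GTF serialization
# ---------------------------------------------------------------------------

def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write exon-level GTF (1-based closed), with chromosome sizes in headers."""
    lines = []
    for name in sorted(annotation.chromosomes):
        lines.append(f"#!chromosome {name} {annotation.chromosomes[name]}")
    for gene in annotation.genes:
        for tr in gene.transcripts:
            for a, b in tr.exons:
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tr.transcript_id}"; '
                    f'gene_name "{gene.name}"; gene_biotype "{gene.biotype}"; '
                    f'transcript_biotype "{tr.transcript_class}";'
                )
                lines.append(
                    "\t".join(
                        (
                            gene.chromosome,
                            "hoxcis",
                            "exon",
                            str(a + 1),
                            str(b),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        )
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gtf(path: str) -> GenomeAnnotation:
    """Parse an exon-level GTF back into a :class:`GenomeAnnotation`."""
    chromosomes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#!chromosome"):
                _, name, length = line.split()
                chromosomes[name] = int(length)
            elif not line.startswith("#"):
                break

    # gene/transcript inference writes progress to stderr; silence it
    with contextlib.redirect_stderr(io.StringIO()):
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=False,
            disable_infer_transcripts=False,
            verbose=False,
        )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        gene_name = gf.id
        gene_biotype = "protein_coding"
        for tf in db.children(gf, featuretype="transcript"):
            exons = []
            tclass = "protein_coding"
            for ef in db.children(tf, featuretype="exon"):
                exons.append((ef.start - 1, ef.end))
                gene_name = ef.attributes.get("gene_name", [gf.id])[0]
                gene_biotype = ef.attributes.get("gene_biotype", ["protein_coding"])[0]
                tclass = ef.attributes.get("transcript_biotype", ["protein_coding"])[0]
            transcripts.append(
                Transcript(transcript_id=tf.id, transcript_class=tclass, exons=exons)
            )
        genes.append(
            Gene(
                gene_id=gf.id,
                name=gene_name,
                biotype=gene_biotype,
                chromosome=gf.seqid,
                strand=gf.strand,
                transcripts=transcripts,
            )
        )
    if not chromosomes:
        # fall back to observed extents when size headers are absent
        for g in genes:
            chromosomes[g.chromosome] = max(chromosomes.get(g.chromosome, 0), g.end)
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)
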