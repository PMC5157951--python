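"""Flattening, counting filters, RPKM arithmetic and normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoxcis.annotation import (
    FlattenedGeneModel,
    Gene,
    GenomeAnnotation,
    Transcript,
    flatten_gene_models,
    merge_intervals,
    read_gtf,
    write_gtf,
)
from hoxcis import quantify as q
from hoxcis.quantify import (
    CountTable,
    ExpressionTable,
    compute_rpkm,
    count_unique_reads,
    median_scale_normalize,
    select_standard_genes,
)


def _gene(gid, strand, transcripts, biotype="protein_coding", chrom="chr1"):
    return Gene(gid, gid, biotype, chrom, strand, transcripts)


class TestFlatten:
    def _annotation(self, genes, length=1_000_000):
        return GenomeAnnotation(chromosomes={"chr1": length}, genes=genes)

    def test_single_isoform_passthrough(self):
        g = _gene("g", "+", [Transcript("t", "protein_coding", [(100, 200), (300, 400)])])
        (m,) = flatten_gene_models(self._annotation([g]))
        assert m.intervals == [(100, 200), (300, 400)]
        assert m.exonic_length == 200

    def test_overlapping_isoforms_merge(self):
        g = _gene(
            "g",
            "+",
            [
                Transcript("t1", "protein_coding", [(100, 200)]),
                Transcript("t2", "protein_coding", [(150, 250)]),
            ],
        )
        (m,) = flatten_gene_models(self._annotation([g]))
        assert m.intervals == [(100, 250)] and m.exonic_length == 150

    def test_retained_intron_dropped_for_coding_gene(self):
        g = _gene(
            "g",
            "+",
            [
                Transcript("t1", "protein_coding", [(100, 200), (300, 400)]),
                Transcript("t2", "retained_intron", [(100, 400)]),
            ],
        )
        (m,) = flatten_gene_models(self._annotation([g]))
        assert m.intervals == [(100, 200), (300, 400)]

    def test_noncoding_gene_keeps_all_isoforms(self):
        g = _gene(
            "nc",
            "-",
            [
                Transcript("t1", "lncRNA", [(100, 200)]),
                Transcript("t2", "processed_transcript", [(500, 600)]),
            ],
            biotype="lncRNA",
        )
        (m,) = flatten_gene_models(self._annotation([g]))
        assert m.intervals == [(100, 200), (500, 600)]

    def test_canonical_override(self):
        g = _gene(
            "hox",
            "+",
            [
                Transcript("canon", "protein_coding", [(100, 200)]),
                Transcript("readthrough", "protein_coding", [(100, 900)]),
            ],
        )
        (m,) = flatten_gene_models(
            self._annotation([g]), canonical_overrides={"hox": "canon"}
        )
        assert m.intervals == [(100, 200)]

    def test_override_naming_absent_transcript_raises(self):
        g = _gene("hox", "+", [Transcript("canon", "protein_coding", [(100, 200)])])
        with pytest.raises(ValueError):
            flatten_gene_models(self._annotation([g]), canonical_overrides={"hox": "zzz"})

    def test_gene_with_no_retained_transcript_excluded(self):
        g = _gene("g", "+", [Transcript("t", "retained_intron", [(100, 200)])])
        assert flatten_gene_models(self._annotation([g])) == []

    def test_random_annotations_match_per_base_union(self):
        """Exonic length equals the per-base union size; flattening idempotent."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_tx = rng.integers(1, 5)
            transcripts = []
            for t in range(n_tx):
                n_ex = rng.integers(1, 5)
                starts = np.sort(rng.integers(0, 5_000, size=n_ex))
                exons = [(int(s), int(s + rng.integers(1, 400))) for s in starts]
                exons = merge_intervals(exons)  # transcripts need disjoint exons
                transcripts.append(Transcript(f"t{t}", "protein_coding", exons))
            g = _gene("g", "+", transcripts)
            (m,) = flatten_gene_models(self._annotation([g]))
            union = set()
            for t in transcripts:
                for a, b in t.exons:
                    union.update(range(a, b))
            assert m.exonic_length == len(union)
            assert merge_intervals(m.intervals) == m.intervals  # idempotent
            for (a1, b1), (a2, b2) in zip(m.intervals, m.intervals[1:]):
                assert b1 < a2  # disjoint and sorted

    @given(
        st.lists(
            st.tuples(st.integers(0, 3000), st.integers(1, 300)).map(
                lambda p: (p[0], p[0] + p[1])
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_merge_intervals_is_a_union(self, intervals):
        merged = merge_intervals(intervals)
        union = set()
        for a, b in intervals:
            union.update(range(a, b))
        covered = set()
        for a, b in merged:
            covered.update(range(a, b))
        assert covered == union
        assert merged == sorted(merged)

    def test_gtf_round_trip(self, dataset, tmp_path):
        path = tmp_path / "x.gtf"
        write_gtf(dataset.annotation, str(path))
        back = read_gtf(str(path))
        assert sorted(back.gene_ids) == sorted(dataset.annotation.gene_ids)
        orig = {
            m.gene_id: m for m in flatten_gene_models(dataset.annotation)
        }
        again = {m.gene_id: m for m in flatten_gene_models(back)}
        for gid, m in orig.items():
            assert again[gid].intervals == m.intervals
            assert again[gid].strand == m.strand


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

TOY_MODELS = [
    # same-strand overlapping pair
    FlattenedGeneModel("A", "chr1", "+", [(1000, 1600)]),
    FlattenedGeneModel("B", "chr1", "+", [(1400, 2000)]),
    # opposite-strand gene overlapping A
    FlattenedGeneModel("C", "chr1", "-", [(1000, 1600)]),
    FlattenedGeneModel("D", "chr1", "+", [(5000, 5500), (6000, 6500)]),
    FlattenedGeneModel("E", "chr1", "-", [(8000, 9000)]),
]


def _write_sam(path, reads):
    """reads: (name, pos, cigar, reverse, nm, extra_tags)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 20_000}, {"SN": "chrM", "LN": 16_000}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for name, chrom, pos, cigar, reverse, nm, tags in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.reference_name = chrom
            a.reference_start = pos
            a.flag = 16 if reverse else 0
            a.cigarstring = cigar
            a.mapping_quality = 50
            a.set_tag("NM", nm)
            for k, v in tags.items():
                a.set_tag(k, v)
            sam.write(a)


def _brute_force_assign(blocks, tstrand, models):
    """Independent oracle: per-base set overlap against every model."""
    hits = set()
    for m in models:
        if tstrand is not None and m.strand != tstrand:
            continue
        bases = set()
        for a, b in m.intervals:
            bases.update(range(a, b))
        for a, b in blocks:
            if bases & set(range(a, b)):
                hits.add(m.gene_id)
    return hits.pop() if len(hits) == 1 else None


class TestCounting:
    def test_filters_and_assignment_match_brute_force(self, tmp_path):
        # reads aligned on '-' correspond to '+' transcripts (antisense library)
        reads = [
            ("clean_D", "chr1", 5100, "100M", True, 0, {}),
            ("spliced_D", "chr1", 5450, "50M500N50M", True, 2, {}),
            ("mm3", "chr1", 5100, "100M", True, 3, {}),
            ("indel", "chr1", 5100, "50M2I48M", True, 0, {}),
            ("multimap", "chr1", 5100, "100M", True, 0, {"NH": 4}),
            ("overlap_AB", "chr1", 1450, "100M", True, 0, {}),  # spans A and B
            ("a_only", "chr1", 1050, "100M", True, 0, {}),
            ("strand_pick", "chr1", 1050, "100M", False, 0, {}),  # '-' transcript -> C
            ("wrong_strand_E", "chr1", 8100, "100M", True, 0, {}),  # E is '-', needs fwd aln
            ("mito", "chrM", 100, "100M", True, 0, {}),
        ]
        sam = tmp_path / "toy.sam"
        _write_sam(sam, reads)
        counts, total = count_unique_reads(str(sam), TOY_MODELS, "antisense")
        # oracle
        expected = {m.gene_id: 0 for m in TOY_MODELS}
        for name, chrom, pos, cigar, reverse, nm, tags in reads:
            if chrom == "chrM" or nm > 2 or "I" in cigar or "D" in cigar:
                continue
            if tags.get("NH", 1) > 1:
                continue
            blocks = []
            p = pos
            num = ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                else:
                    n = int(num)
                    num = ""
                    if ch == "M":
                        blocks.append((p, p + n))
                        p += n
                    elif ch == "N":
                        p += n
            tstrand = "+" if reverse else "-"
            hit = _brute_force_assign(blocks, tstrand, TOY_MODELS)
            if hit:
                expected[hit] += 1
        assert counts.to_dict() == expected
        assert expected["A"] == 1 and expected["C"] == 1 and expected["D"] == 2
        assert expected["B"] == 0 and expected["E"] == 0
        # total excludes the mitochondrial read but keeps filtered nuclear reads
        assert total == len(reads) - 1 - 1  # minus chrM, minus NH=4 multimapper

    def test_unstranded_mode_discards_opposite_strand_ambiguity(self, tmp_path):
        sam = tmp_path / "u.sam"
        _write_sam(sam, [("r", "chr1", 1050, "100M", True, 0, {})])  # overlaps A and C
        counts, _ = count_unique_reads(str(sam), TOY_MODELS, "unstranded")
        assert counts["A"] == 0 and counts["C"] == 0
        counts2, _ = count_unique_reads(str(sam), TOY_MODELS, "antisense")
        assert counts2["A"] == 1

    def test_unknown_chromosome_rejected(self, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrZ", "LN": 5000}]}
        )
        sam = tmp_path / "z.sam"
        with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
            a = pysam.AlignedSegment(header)
            a.query_name = "r"
            a.reference_name = "chrZ"
            a.reference_start = 10
            a.cigarstring = "100M"
            a.mapping_quality = 50
            fh.write(a)
        with pytest.raises(ValueError):
            count_unique_reads(str(sam), TOY_MODELS)

    def test_empty_model_list_rejected(self, tmp_path):
        sam = tmp_path / "e.sam"
        _write_sam(sam, [])
        with pytest.raises(ValueError):
            count_unique_reads(str(sam), [])

    def test_end_to_end_counts_reproduce_simulated_truth(self, dataset):
        """Counting the generated SAM recovers the simulated count table for
        genes outside the deliberately overlapping pair."""
        sid = "GT_wt_1"
        counts, total = count_unique_reads(dataset.sam(sid), dataset.models)
        truth = dataset.sim.counts[sid]
        for gid in truth.index:
            if gid in ("BG0001", "BG0002"):
                assert counts[gid] <= truth[gid]  # overlap reads are discarded
            else:
                assert counts[gid] == truth[gid], gid
        assert total >= truth.sum()


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

class TestRpkm:
    def _table(self, counts, totals):
        return CountTable(counts=counts, totals=totals)

    def test_unit_cases(self):
        counts = pd.DataFrame({"s1": [1000, 50, 0]}, index=["a", "b", "c"])
        models = [
            FlattenedGeneModel("a", "chr1", "+", [(0, 1000)]),
            FlattenedGeneModel("b", "chr1", "+", [(0, 2500)]),
            FlattenedGeneModel("c", "chr1", "+", [(0, 100)]),
        ]
        t1 = self._table(counts[["s1"]], pd.Series({"s1": 1_000_000}))
        expr = compute_rpkm(t1, models)
        assert expr.rpkm.loc["a", "s1"] == pytest.approx(1000.0)
        assert expr.rpkm.loc["c", "s1"] == 0.0
        t2 = self._table(counts[["s1"]], pd.Series({"s1": 10_000_000}))
        expr2 = compute_rpkm(t2, models)
        assert expr2.rpkm.loc["b", "s1"] == pytest.approx(2.0)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s": [30, 70]}, index=["a", "b"])
        models = [
            FlattenedGeneModel("a", "chr1", "+", [(0, 500)]),
            FlattenedGeneModel("b", "chr1", "+", [(0, 900)]),
        ]
        e1 = compute_rpkm(self._table(counts, pd.Series({"s": 10_000})), models)
        e2 = compute_rpkm(self._table(counts * 7, pd.Series({"s": 70_000})), models)
        assert np.allclose(e1.rpkm, e2.rpkm)

    def test_errors(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        models = [FlattenedGeneModel("a", "chr1", "+", [(0, 100)])]
        with pytest.raises(ValueError):
            compute_rpkm(self._table(counts, pd.Series({"s": 0})), models)
        with pytest.raises(ValueError):
            compute_rpkm(self._table(counts, pd.Series({"s": 100})), [])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestStandardSelection:
    def test_brute_force_small_case(self):
        rng = np.random.default_rng(3)
        rpkm = pd.DataFrame(
            rng.lognormal(2, 1, size=(10, 3)),
            index=[f"g{i}" for i in range(10)],
            columns=["s1", "s2", "s3"],
        )
        expr = ExpressionTable(rpkm=rpkm)
        std = select_standard_genes(expr, n_standard=3)
        med = rpkm.median(axis=1)
        lo, hi = med.quantile(0.25), med.quantile(0.75)
        eligible = [g for g in rpkm.index if lo <= med[g] <= hi]
        ranks = rpkm.rank(axis=0)
        scores = {g: float(ranks.loc[g].std(ddof=1)) for g in eligible}
        expected = sorted(eligible, key=lambda g: (scores[g], g))[:3]
        assert std.gene_ids == sorted(expected, key=lambda g: (scores[g], g))

    def test_identical_ranks_give_zero_scores(self):
        base = np.arange(1, 201, dtype=float)
        rpkm = pd.DataFrame(
            {"s1": base, "s2": base * 2, "s3": base * 0.5},
            index=[f"g{i:03d}" for i in range(200)],
        )
        std = select_standard_genes(ExpressionTable(rpkm=rpkm), n_standard=100)
        assert len(std.gene_ids) == 100
        assert (std.rank_scores.loc[std.gene_ids] == 0).all()

    def test_returns_exactly_n_standard_on_real_sized_data(self, counts_dataset):
        counts = counts_dataset.sim.counts
        models = counts_dataset.models
        expr = compute_rpkm(
            CountTable(counts=counts, totals=counts_dataset.sim.totals), models
        )
        std = select_standard_genes(expr)
        assert len(std.gene_ids) == 100

    def test_shortfall_reported(self):
        rpkm = pd.DataFrame(
            np.ones((10, 2)) * np.arange(1, 11)[:, None],
            index=[f"g{i}" for i in range(10)],
            columns=["a", "b"],
        )
        with pytest.raises(ValueError, match="need 100"):
            select_standard_genes(ExpressionTable(rpkm=rpkm), n_standard=100)


class TestMedianScaling:
    def _expr(self, rpkm):
        return ExpressionTable(rpkm=rpkm)

    def test_identity_when_samples_identical(self):
        col = np.linspace(1, 50, 200)
        rpkm = pd.DataFrame({"a": col, "b": col, "c": col}, index=[f"g{i}" for i in range(200)])
        norm, std = q.normalize_expression(self._expr(rpkm))
        assert np.allclose(norm.scale_factors, 1.0)
        assert np.allclose(norm.rpkm, rpkm)

    def test_doubled_sample_algebra(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(1, 1, 300)
        rpkm = pd.DataFrame({"A": a, "B": 2 * a, "C": a}, index=[f"g{i}" for i in range(300)])
        norm, std = q.normalize_expression(self._expr(rpkm))
        f = norm.scale_factors
        assert f["B"] == pytest.approx(f["A"] / 2)
        med = norm.rpkm.loc[std.gene_ids].median(axis=0)
        assert np.allclose(med, med.iloc[0])

    def test_post_normalization_standard_median_constant(self, counts_dataset):
        counts = counts_dataset.sim.counts
        expr = compute_rpkm(
            CountTable(counts=counts, totals=counts_dataset.sim.totals),
            counts_dataset.models,
        )
        norm, std = q.normalize_expression(expr)
        med = norm.rpkm.loc[std.gene_ids].median(axis=0)
        assert np.allclose(med, std.reference)

    def test_permuting_samples_permutes_factors(self, counts_dataset):
        counts = counts_dataset.sim.counts
        expr = compute_rpkm(
            CountTable(counts=counts, totals=counts_dataset.sim.totals),
            counts_dataset.models,
        )
        _, std1 = q.normalize_expression(expr)
        perm = list(expr.rpkm.columns[::-1])
        _, std2 = q.normalize_expression(ExpressionTable(rpkm=expr.rpkm[perm]))
        assert np.allclose(
            std1.scale_factors.sort_index(), std2.scale_factors.sort_index()
        )

    def test_zero_median_rejected(self):
        rpkm = pd.DataFrame(
            {"a": np.linspace(1, 10, 200), "b": np.zeros(200)},
            index=[f"g{i}" for i in range(200)],
        )
        std = select_standard_genes(ExpressionTable(rpkm=rpkm), n_standard=100)
        with pytest.raises(ValueError):
            median_scale_normalize(ExpressionTable(rpkm=rpkm), std)

    def test_planted_depth_factor_recovery(self):
        """Median scaling recovers planted per-sample scaling within 2%."""
        from hoxcis import simulate as sim

        cfg = sim.SimulationConfig(
            seed=7,
            n_background_genes=2000,
            chrom_length=2_000_000,
            tissues=("T3",),
            genotypes=("wt",),
            replicates_per_group=3,
            planted_effects={},
            library_size_mean=1_000_000,
            nb_dispersion=1e-9,  # technical rescaling of one RNA pool: Poisson noise
            depth_factors={"T3_wt_1": 0.5, "T3_wt_2": 1.0, "T3_wt_3": 2.0},
        )
        ann, _, _ = sim.generate_annotation(cfg)
        s = sim.simulate_counts(ann, cfg)
        models = flatten_gene_models(ann, canonical_overrides=sim.CANONICAL_OVERRIDES)
        # depth unknown to the pipeline: equal nominal totals
        expr = compute_rpkm(
            CountTable(counts=s.counts, totals=pd.Series(1e6, index=s.counts.columns)),
            models,
        )
        norm, _ = q.normalize_expression(expr)
        truth = pd.Series({"T3_wt_1": 2.0, "T3_wt_2": 1.0, "T3_wt_3": 0.5})
        ratio = norm.scale_factors / truth
        rel = (ratio / ratio["T3_wt_2"] - 1.0).abs()
        assert (rel < 0.02).all()
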