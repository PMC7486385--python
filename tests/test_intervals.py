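"""Interval data model, BED I/O, and the interval algebra vs per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcdkit import (
    DataError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    connected_union,
    merge_within,
    nearest_features,
    pairwise_intersection,
    read_intervals,
    write_intervals,
)
from hcdkit.errors import ConfigError, ParseError
from hcdkit.intervals import read_gene_models, write_gene_models

from _oracles import (
    connected_union_oracle,
    intersect_oracle,
    merge_oracle,
    random_interval_set,
)


def spans(ivs):
    return [(iv.chrom, iv.start, iv.end) for iv in ivs]


class TestGenomicInterval:
    def test_breadth_is_end_minus_start(self):
        assert GenomicInterval("chr1", 100, 200).breadth == 100

    @pytest.mark.parametrize("start,end", [(-1, 5), (10, 10), (10, 5)])
    def test_degenerate_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_bookended_intervals_do_not_overlap(self):
        a, b = GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)
        assert not a.overlaps(b)
        assert GenomicInterval("chr1", 0, 11).overlaps(b)


class TestBedIO:
    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_intervals(p, "bed3")) == 0

    def test_bed3_line_parsed_half_open(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = read_intervals(p, "bed3")
        assert (iv.chrom, iv.start, iv.end, iv.breadth) == ("chr1", 100, 200, 100)

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nbrowser position chr1\nchr1\t0\t5\n")
        assert len(read_intervals(p, "bed3")) == 1

    def test_broadpeak_roundtrip_preserves_first_columns(self, tmp_path):
        line = "chr2\t1000\t9000\tpeak_1\t250\t.\t12.5\t30.1\t27.9\n"
        p = tmp_path / "a.broadPeak"
        p.write_text(line)
        s = read_intervals(p, "broadpeak")
        (iv,) = s
        assert iv.name == "peak_1" and iv.score == 250.0
        out = tmp_path / "b.broadPeak"
        write_intervals(s, out, "broadpeak")
        got = out.read_text().split("\t")
        assert got[:3] == line.split("\t")[:3]

    def test_write_empty_set(self, tmp_path):
        p = tmp_path / "o.bed"
        write_intervals(IntervalSet(), p, "bed3")
        assert p.read_text() == ""

    def test_write_single_interval_bed3(self, tmp_path):
        p = tmp_path / "o.bed"
        write_intervals(IntervalSet([GenomicInterval("chr1", 0, 10)]), p, "bed3")
        assert p.read_text() == "chr1\t0\t10\n"

    @pytest.mark.parametrize(
        "bad", ["chr1\t10\t10\n", "chr1\tx\t20\n", "chr1\t-5\t20\n", "chr1\t100\n"]
    )
    def test_malformed_lines_name_the_line(self, tmp_path, bad):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t5\n" + bad)
        with pytest.raises(ParseError, match=":2"):
            read_intervals(p, "bed3")

    def test_unknown_dialect_is_config_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t5\n")
        with pytest.raises(ConfigError):
            read_intervals(p, "bed12")

    @given(
        seed=st.integers(0, 2**31 - 1),
        dialect=st.sampled_from(["bed3", "bed6", "broadpeak", "narrowpeak"]),
    )
    @settings(derandomize=True, max_examples=30)
    def test_roundtrip_identity_on_coordinates(self, seed, dialect, tmp_path_factory):
        rng = np.random.default_rng(seed)
        s = random_interval_set(rng, genome_len=100_000, max_n=100)
        p = tmp_path_factory.mktemp("rt") / "x.bed"
        write_intervals(s, p, dialect)
        back = read_intervals(p, dialect)
        assert spans(back.sorted()) == spans(s.sorted())


class TestGeneModels:
    def test_tss_by_strand(self):
        assert GeneModel("chr1", 100, 200, "+", "g1").tss == 100
        assert GeneModel("chr1", 100, 200, "-", "g2").tss == 199

    def test_tsv_roundtrip_with_header(self, tmp_path):
        genes = [
            GeneModel("chr1", 100, 5000, "+", "ga"),
            GeneModel("chr1", 9000, 12000, "-", "gb"),
        ]
        p = tmp_path / "genes.tsv"
        write_gene_models(genes, p)
        assert read_gene_models(p) == genes

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("chr1\t0\t10\t+\tg1\nchr1\t20\t30\t-\tg1\n")
        with pytest.raises(DataError, match="duplicate"):
            read_gene_models(p)


class TestMergeWithin:
    def test_overlapping_merge(self):
        s = IntervalSet([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 250)])
        assert spans(merge_within(s, 0)) == [("chr1", 100, 250)]

    def test_bookended_merge_at_gap_zero(self):
        s = IntervalSet([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300)])
        assert spans(merge_within(s, 0)) == [("chr1", 100, 300)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_within(IntervalSet(), -1)

    def test_against_per_base_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            s = random_interval_set(rng)
            gap = int(rng.integers(0, 500))
            got = merge_within(s, gap)
            assert spans(got) == spans(merge_oracle(s, gap, 10_000))

    @given(st.integers(0, 2**31 - 1), st.integers(0, 300))
    @settings(derandomize=True, max_examples=30)
    def test_idempotent(self, seed, gap):
        s = random_interval_set(np.random.default_rng(seed))
        once = merge_within(s, gap)
        assert spans(merge_within(once, gap)) == spans(once)


class TestPairwiseIntersection:
    def test_disjoint_sets_give_empty(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 200, 300)])
        assert len(pairwise_intersection(a, b)) == 0

    def test_partial_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150)])
        assert spans(pairwise_intersection(a, b)) == [("chr1", 50, 100)]

    def test_bookended_contact_contributes_nothing(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 100, 200)])
        assert len(pairwise_intersection(a, b)) == 0

    def test_against_per_base_oracle_and_commutative(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = random_interval_set(rng), random_interval_set(rng)
            got = pairwise_intersection(a, b)
            assert spans(got) == spans(intersect_oracle(a, b, 10_000))
            assert spans(got) == spans(pairwise_intersection(b, a))

    def test_disjoint_chromosome_namespaces_error(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("1", 0, 100)])
        with pytest.raises(DataError, match="renaming"):
            pairwise_intersection(a, b)
        b2 = b.rename_chroms({"1": "chr1"})
        assert spans(pairwise_intersection(a, b2)) == [("chr1", 0, 100)]


class TestConnectedUnion:
    def test_overlapping_pair_yields_union_span(self):
        a = IntervalSet([GenomicInterval("chr1", 100, 5000)])
        b = IntervalSet([GenomicInterval("chr1", 3000, 9000)])
        (comp,) = connected_union(a, b)
        assert (comp.span.start, comp.span.end) == (100, 9000)

    def test_single_mark_component_discarded(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 500, 600)])
        assert connected_union(a, b) == []

    def test_chain_forms_single_component(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 15, 30)])
        b = IntervalSet([GenomicInterval("chr1", 5, 20)])
        (comp,) = connected_union(a, b)
        assert (comp.span.start, comp.span.end) == (0, 30)
        assert len(comp.members_a) == 2 and len(comp.members_b) == 1

    def test_against_union_find_oracle_and_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b = random_interval_set(rng), random_interval_set(rng)
            got = [(c.span.start, c.span.end) for c in connected_union(a, b)]
            assert got == connected_union_oracle(a, b)
            swapped = [(c.span.start, c.span.end) for c in connected_union(b, a)]
            assert got == swapped


class TestNearestFeatures:
    GENES = [
        GeneModel("chr1", 500, 900, "+", "left"),
        GeneModel("chr1", 2100, 2500, "+", "right"),
        GeneModel("chr1", 1200, 1800, "+", "inside"),
    ]

    def test_contained_gene_distance_zero(self):
        q = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        hits = nearest_features(q, self.GENES)
        assert [(h.gene.gene_id, h.signed_distance, h.contained) for h in hits] == [
            ("inside", 0, True)
        ]

    def test_equidistant_ties_all_reported_in_coordinate_order(self):
        genes = [g for g in self.GENES if g.gene_id != "inside"]
        q = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        hits = nearest_features(q, genes)
        assert [(h.gene.gene_id, h.signed_distance) for h in hits] == [
            ("left", -100),
            ("right", 100),
        ]

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(12):
            s = int(rng.integers(0, 9_000))
            genes.append(GeneModel("chr1", s, s + int(rng.integers(1, 800)), "+", f"g{i}"))
        for _ in range(50):
            q = random_interval_set(rng, max_n=6)
            hits = nearest_features(q, genes)
            for iv in q.sorted():
                def gap(g):
                    if g.end <= iv.start:
                        return iv.start - g.end
                    if g.start >= iv.end:
                        return g.start - iv.end
                    return 0
                dmin = min(gap(g) for g in genes)
                expect = {g.gene_id for g in genes if gap(g) == dmin}
                got = {
                    h.gene.gene_id for h in hits if h.query.sort_key() == iv.sort_key()
                }
                assert got == expect

    def test_empty_subject_rejected(self):
        with pytest.raises(ValueError):
            nearest_features(IntervalSet([GenomicInterval("chr1", 0, 10)]), [])
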