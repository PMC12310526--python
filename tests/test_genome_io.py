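import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetscape.genome_io import (
    GenomeIOError,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    merge,
    overlap_partition,
    read_bed,
    read_bedgraph,
    read_gtf_genes,
    write_bed,
    write_bedgraph,
)

from .conftest import random_intervals
from .oracles import merge_oracle, overlap_partition_oracle


@pytest.fixture
def genome():
    return GenomeModel([("chr1", 100_000), ("chr2", 50_000)])


class TestGenomeModel:
    def test_rejects_duplicate_names_and_bad_lengths(self):
        with pytest.raises(GenomeIOError):
            GenomeModel([("chr1", 100), ("chr1", 200)])
        with pytest.raises(GenomeIOError):
            GenomeModel([("chr1", 0)])

    def test_tsv_round_trip(self, genome, tmp_path):
        p = tmp_path / "g.tsv"
        genome.to_tsv(p)
        assert GenomeModel.from_tsv(p) == genome


class TestBed:
    def test_single_line_maps_to_half_open_interval(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        ivs = read_bed(p, genome)
        assert len(ivs) == 1
        assert (ivs[0].chrom, ivs[0].start, ivs[0].end) == ("chr1", 10, 20)

    def test_empty_file_gives_empty_set(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p, genome)) == 0

    def test_unsorted_input_sorted_and_round_trips(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        lines = ["chr2\t5\t9", "chr1\t100\t200", "chr1\t10\t20"]
        p.write_text("\n".join(lines) + "\n")
        ivs = read_bed(p, genome)
        # line-sort oracle: chromosome order from the genome, then start
        assert [(iv.chrom, iv.start, iv.end) for iv in ivs] == [
            ("chr1", 10, 20), ("chr1", 100, 200), ("chr2", 5, 9),
        ]
        out = tmp_path / "b.bed"
        write_bed(ivs, out)
        again = read_bed(out, genome)
        assert [(iv.chrom, iv.start, iv.end) for iv in again] == [
            (iv.chrom, iv.start, iv.end) for iv in ivs
        ]

    def test_malformed_line_reports_line_number(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\tnope\t30\n")
        with pytest.raises(GenomeIOError, match=":2"):
            read_bed(p, genome)

    def test_unknown_chromosome_named_in_error(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t10\t20\n")
        with pytest.raises(GenomeIOError, match="chrZ"):
            read_bed(p, genome)

    def test_coordinates_beyond_chromosome_rejected(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t49000\t50001\n")
        with pytest.raises(GenomeIOError):
            read_bed(p, genome)


class TestBedgraph:
    def test_single_record_fills_bins(self, genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = read_bedgraph(p, genome, bin_size=50)
        assert track.values["chr1"][0] == pytest.approx(2.0)
        assert track.values["chr1"][1] == pytest.approx(2.0)
        assert track.values["chr1"][2:].sum() == 0

    def test_half_covered_bin_is_half_value(self, genome, tmp_path):
        # per-bp averaging oracle: 50 bp at 3.0 out of a 100 bp bin -> 1.5
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t50\t3.0\n")
        track = read_bedgraph(p, genome, bin_size=100)
        assert track.values["chr1"][0] == pytest.approx(1.5)

    def test_no_records_all_zero(self, genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("")
        track = read_bedgraph(p, genome, bin_size=1000)
        assert track.all_values().sum() == 0

    def test_negative_value_rejected(self, genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t-1.0\n")
        with pytest.raises(GenomeIOError):
            read_bedgraph(p, genome, 50)

    def test_overlapping_records_averaged_with_warning(self, genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t2.0\nchr1\t0\t100\t4.0\n")
        with pytest.warns(UserWarning, match="overlap"):
            track = read_bedgraph(p, genome, 100)
        assert track.values["chr1"][0] == pytest.approx(3.0)

    def test_write_read_round_trip_identity(self, genome, tmp_path):
        rng = np.random.default_rng(0)
        p1, p2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        recs = []
        for i in range(20):
            recs.append(f"chr1\t{i * 500}\t{(i + 1) * 500}\t{rng.uniform(0, 5):.4f}")
        p1.write_text("\n".join(recs) + "\n")
        t1 = read_bedgraph(p1, genome, 500)
        write_bedgraph(t1, p2)
        t2 = read_bedgraph(p2, genome, 500)
        for c in genome.chrom_names:
            np.testing.assert_allclose(t1.values[c], t2.values[c], rtol=1e-5)

    def test_per_bp_oracle_on_random_records(self, genome, tmp_path):
        rng = np.random.default_rng(1)
        recs, arr = [], np.zeros(genome.length("chr2"))
        cov = np.zeros(genome.length("chr2"))
        for _ in range(30):
            s = int(rng.integers(0, 49_000))
            e = s + int(rng.integers(1, 1000))
            v = float(f"{rng.uniform(0, 10):.5f}")
            recs.append(f"chr2\t{s}\t{e}\t{v}")
            arr[s:e] += v
            cov[s:e] += 1
        p = tmp_path / "a.bedgraph"
        p.write_text("\n".join(recs) + "\n")
        with pytest.warns(UserWarning):
            track = read_bedgraph(p, genome, 1000)
        per_bp = np.where(cov > 0, arr / np.maximum(cov, 1), 0.0)
        expected = per_bp.reshape(-1, 1000).mean(axis=1)
        np.testing.assert_allclose(track.values["chr2"], expected, rtol=1e-9)


class TestGtf:
    def _write(self, tmp_path, lines):
        p = tmp_path / "a.gtf"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_plus_strand_promoter_clipped_at_zero(self, genome, tmp_path):
        p = self._write(
            tmp_path, ['chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tgene_id "g1";']
        )
        ann = read_gtf_genes(p, genome, promoter_window=(2000, 500))
        prom = ann.promoters()[0]
        assert (prom.start, prom.end) == (0, 1500)

    def test_minus_strand_promoter_mirrored(self, genome, tmp_path):
        p = self._write(
            tmp_path, ['chr1\tsrc\tgene\t1001\t5000\t.\t-\t.\tgene_id "g1";']
        )
        ann = read_gtf_genes(p, genome, promoter_window=(2000, 500))
        prom = ann.promoters()[0]
        assert (prom.start, prom.end) == (4500, 7000)

    def test_duplicate_gene_id_rows_merged_to_union_extent(self, genome, tmp_path):
        p = self._write(
            tmp_path,
            [
                'chr1\tsrc\ttranscript\t1001\t3000\t.\t+\t.\tgene_id "g1";',
                'chr1\tsrc\ttranscript\t2001\t5000\t.\t+\t.\tgene_id "g1";',
            ],
        )
        ann = read_gtf_genes(p, genome)
        assert len(ann) == 1
        row = ann.genes.iloc[0]
        assert (row["start"], row["end"]) == (1000, 5000)

    def test_missing_gene_id_rejected(self, genome, tmp_path):
        p = self._write(tmp_path, ["chr1\tsrc\tgene\t1\t100\t.\t+\t.\tfoo bar;"])
        with pytest.raises(GenomeIOError, match="gene_id"):
            read_gtf_genes(p, genome)


class TestMerge:
    def test_gap_within_threshold_unions(self, genome):
        ivs = IntervalSet(
            [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 25, 30)], genome
        )
        out = merge(ivs, gap=5)
        assert [(iv.start, iv.end) for iv in out] == [(10, 30)]

    def test_gap_beyond_threshold_preserved(self, genome):
        ivs = IntervalSet(
            [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 26, 30)], genome
        )
        out = merge(ivs, gap=5)
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_bp_union_oracle(self, genome, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, genome, 100)
        gap = int(rng.integers(0, 500))
        got = [(iv.chrom, iv.start, iv.end) for iv in merge(ivs, gap)]
        assert got == merge_oracle(ivs, gap)

    @given(st.integers(0, 2**31 - 1), st.integers(0, 300))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_and_order_invariant(self, seed, gap):
        genome = GenomeModel([("chr1", 100_000), ("chr2", 50_000)])
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, genome, 40)
        once = merge(ivs, gap)
        twice = merge(once, gap)
        assert [(i.chrom, i.start, i.end) for i in once] == [
            (i.chrom, i.start, i.end) for i in twice
        ]
        perm = rng.permutation(len(ivs))
        shuffled = IntervalSet([ivs[int(i)] for i in perm], genome)
        assert [(i.chrom, i.start, i.end) for i in merge(shuffled, gap)] == [
            (i.chrom, i.start, i.end) for i in once
        ]
        # merged output is non-overlapping and sorted
        prev = None
        for iv in once:
            if prev is not None and prev.chrom == iv.chrom:
                assert iv.start > prev.end + gap
            prev = iv


class TestOverlapPartition:
    def test_identical_sets_all_shared(self, genome):
        rng = np.random.default_rng(0)
        a = random_intervals(rng, genome, 20)
        only, shared = overlap_partition(a, a)
        assert len(only) == 0 and len(shared) == len(a)

    def test_disjoint_sets_all_a_only(self, genome):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)], genome)
        b = IntervalSet([GenomicInterval("chr1", 200, 300)], genome)
        only, shared = overlap_partition(a, b)
        assert len(only) == 1 and len(shared) == 0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 500))
    @settings(max_examples=30, deadline=None)
    def test_counts_conserved_and_match_all_pairs_oracle(self, seed, min_ov):
        genome = GenomeModel([("chr1", 100_000), ("chr2", 50_000)])
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, genome, 50)
        b = random_intervals(rng, genome, 50)
        only, shared = overlap_partition(a, b, min_ov)
        assert len(only) + len(shared) == len(a)
        assert len(shared) == sum(overlap_partition_oracle(a, b, min_ov))
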