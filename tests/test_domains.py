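import numpy as np
import pandas as pd
import pytest

from hetscape.domains import (
    BGRD_DEFAULTS,
    DomainParams,
    DomainSet,
    call_bgrds,
    call_locks,
    domain_stats,
    expansion,
    genes_in_domains,
)
from hetscape.genome_io import (
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
)

from .conftest import random_annotation, small_sim_config
from .oracles import genes_in_domains_oracle


def _track(genome, bin_size, chrom_values):
    track = SignalTrack.zeros(genome, bin_size)
    for c, v in chrom_values.items():
        track.values[c] = np.asarray(v, dtype=float)
    return track


def _domset(genome, coords, params=None):
    ivs = IntervalSet([GenomicInterval(c, s, e) for c, s, e in coords], genome)
    return DomainSet(ivs, params or DomainParams())


class TestDomainParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            DomainParams(bin_size=0)
        with pytest.raises(ValueError):
            DomainParams(enrichment_threshold=0)
        with pytest.raises(ValueError):
            DomainParams(bin_size=10_000, min_length=5_000)


class TestCallLocks:
    def test_flat_zero_signal_gives_no_domains(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        track = SignalTrack.zeros(genome, 10_000)
        with pytest.warns(UserWarning, match="all-zero"):
            locks = call_locks(track)
        assert locks.n_domains == 0

    def test_noise_free_plateau_recovered_exactly(self):
        genome = GenomeModel([("chr1", 2_000_000)])
        track = SignalTrack.zeros(genome, 10_000)
        track.values["chr1"][:] = 1.0
        track.values["chr1"][10:30] += 3.0  # chr1:[100000,300000)
        locks = call_locks(track)
        assert [(d.chrom, d.start, d.end) for d in locks.domains] == [
            ("chr1", 100_000, 300_000)
        ]

    def test_planted_domains_recovered_with_noise(self, small_truth):
        truth = small_truth
        for tp in ("day1", "day2"):
            locks = call_locks(truth.tracks[tp])
            planted = truth.locks[tp]
            assert locks.n_domains == len(planted)
            jac = [
                d.overlap_bp(p) / (len(d) + len(p) - d.overlap_bp(p))
                for d, p in zip(locks.domains, planted)
            ]
            assert np.mean(jac) >= 0.9

    def test_input_normalized_mode(self):
        genome = GenomeModel([("chr1", 2_000_000)])
        sig = SignalTrack.zeros(genome, 10_000)
        inp = SignalTrack.zeros(genome, 10_000)
        sig.values["chr1"][:] = 2.0
        inp.values["chr1"][:] = 2.0
        sig.values["chr1"][50:70] = 8.0  # ratio 4 > 1.5 only here
        locks = call_locks(sig, input_track=inp)
        assert [(d.start, d.end) for d in locks.domains] == [(500_000, 700_000)]

    def test_invariant_to_chromosome_order(self):
        g1 = GenomeModel([("chrA", 2_000_000), ("chrB", 2_000_000)])
        g2 = GenomeModel([("chrB", 2_000_000), ("chrA", 2_000_000)])
        rng = np.random.default_rng(0)
        vals = {c: np.maximum(0, rng.normal(1, 0.2, 200)) for c in ("chrA", "chrB")}
        vals["chrA"][20:45] += 3
        vals["chrB"][100:140] += 3
        t1 = _track(g1, 10_000, vals)
        t2 = _track(g2, 10_000, {c: v.copy() for c, v in vals.items()})
        d1 = {(d.chrom, d.start, d.end) for d in call_locks(t1).domains}
        d2 = {(d.chrom, d.start, d.end) for d in call_locks(t2).domains}
        assert d1 == d2

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_merge_gap_and_threshold(self, seed):
        genome = GenomeModel([("chr1", 5_000_000)])
        rng = np.random.default_rng(seed)
        vals = np.maximum(0, rng.normal(1, 0.5, 500))
        # a few plateau blocks of varying strength
        for _ in range(6):
            s = int(rng.integers(0, 450))
            vals[s : s + int(rng.integers(5, 40))] += rng.uniform(0.5, 4)
        track = _track(genome, 10_000, {"chr1": vals})
        prev_n, prev_cov = None, None
        for gap in (0, 20_000, 50_000, 100_000):
            d = call_locks(track, DomainParams(merge_gap=gap))
            if prev_n is not None:
                assert d.n_domains <= prev_n
                assert d.coverage_bp >= prev_cov
            prev_n, prev_cov = d.n_domains, d.coverage_bp
        prev_cov = None
        for thr in (1.2, 1.5, 2.0, 3.0):
            d = call_locks(track, DomainParams(enrichment_threshold=thr))
            if prev_cov is not None:
                assert d.coverage_bp <= prev_cov
            prev_cov = d.coverage_bp

    def test_output_domains_sorted_nonoverlapping_min_length(self, small_truth):
        locks = call_locks(small_truth.tracks["day1"])
        prev = None
        for d in locks.domains:
            assert len(d) >= locks.params.min_length
            if prev is not None and prev.chrom == d.chrom:
                assert d.start > prev.end
            prev = d


class TestBgrds:
    def test_domain_containing_gene_kept(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        ann = GeneAnnotation(
            pd.DataFrame(
                [("g1", "chr1", "+", 100_000, 120_000)],
                columns=["gene_id", "chrom", "strand", "start", "end"],
            ),
            (2000, 500),
            genome,
        )
        doms = _domset(genome, [("chr1", 90_000, 130_000)], BGRD_DEFAULTS)
        bgrds = call_bgrds(doms, ann, 0.8)
        assert bgrds.n_domains == 1
        assert bgrds.covered_genes[0] == ["g1"]
        assert bgrds.params.domain_kind == "BGRD"

    def test_gene_desert_domain_dropped(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        ann = GeneAnnotation(
            pd.DataFrame(
                [("g1", "chr1", "+", 100_000, 120_000)],
                columns=["gene_id", "chrom", "strand", "start", "end"],
            ),
            (2000, 500),
            genome,
        )
        doms = _domset(genome, [("chr1", 500_000, 700_000)], BGRD_DEFAULTS)
        assert call_bgrds(doms, ann, 0.8).n_domains == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_bp_gene_coverage_oracle(self, seed):
        genome = GenomeModel([("chr1", 200_000)])
        rng = np.random.default_rng(seed)
        ann = random_annotation(rng, genome, 25)
        coords = []
        pos = 0
        while pos < 180_000:
            length = int(rng.integers(5_000, 30_000))
            coords.append(("chr1", pos, min(200_000, pos + length)))
            pos += length + int(rng.integers(26_000, 50_000))
        doms = _domset(genome, coords)
        frac = float(rng.uniform(0.2, 1.0))
        kept = call_bgrds(doms, ann, frac)
        oracle_genes = set(genes_in_domains_oracle(doms.domains, ann, frac))
        got_genes = {g for gids in kept.covered_genes.values() for g in gids}
        assert got_genes == oracle_genes


class TestDomainStats:
    def test_empty_set(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        st = domain_stats(_domset(genome, []), genome)
        assert st == {"n_domains": 0, "coverage_bp": 0, "coverage_fraction": 0.0}

    def test_arithmetic(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        st = domain_stats(
            _domset(genome, [("chr1", 0, 10_000), ("chr1", 50_000, 80_000)]), genome
        )
        assert st["n_domains"] == 2
        assert st["coverage_bp"] == 40_000
        assert st["coverage_fraction"] == pytest.approx(0.04)


class TestExpansion:
    def test_identical_sets_all_matched_ratio_one(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        d = _domset(genome, [("chr1", 0, 100_000), ("chr1", 300_000, 500_000)])
        rpt = expansion(d, d)
        assert rpt.n_matched == 2 and rpt.n_new == 0 and rpt.n_lost == 0
        assert rpt.median_length_ratio == 1.0

    def test_empty_day2_all_lost(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        d1 = _domset(genome, [("chr1", 0, 100_000)])
        rpt = expansion(d1, _domset(genome, []))
        assert rpt.n_lost == 1 and rpt.median_length_ratio is None

    def test_planted_expansion_factor_recovered(self):
        cfg = small_sim_config(seed=3, noise_sd=0.0)
        from hetscape.synthetic import simulate

        truth = simulate(cfg)
        d1 = call_locks(truth.tracks["day1"])
        d2 = call_locks(truth.tracks["day2"])
        rpt = expansion(d1, d2)
        assert rpt.median_length_ratio == pytest.approx(2.0, abs=0.05)
        assert rpt.n_new == 0 and rpt.n_lost == 0

    def test_merger_flagged(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        d1 = _domset(genome, [("chr1", 0, 100_000), ("chr1", 200_000, 300_000)])
        d2 = _domset(genome, [("chr1", 0, 300_000)])
        rpt = expansion(d1, d2)
        assert rpt.pairs["merger"].all()
        assert rpt.n_matched == 2 and rpt.n_new == 0


class TestGenesInDomains:
    def test_no_domains_empty(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        rng = np.random.default_rng(0)
        ann = random_annotation(rng, genome, 10)
        assert genes_in_domains(_domset(genome, []), ann) == []

    def test_half_covered_gene_boundary(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        ann = GeneAnnotation(
            pd.DataFrame(
                [("g1", "chr1", "+", 100_000, 120_000)],
                columns=["gene_id", "chrom", "strand", "start", "end"],
            ),
            (2000, 500),
            genome,
        )
        doms = _domset(genome, [("chr1", 90_000, 110_000)])  # covers exactly half
        assert genes_in_domains(doms, ann, 0.5) == ["g1"]
        assert genes_in_domains(doms, ann, 0.51) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_bp_coverage_oracle(self, seed):
        genome = GenomeModel([("chr1", 150_000), ("chr2", 100_000)])
        rng = np.random.default_rng(seed)
        ann = random_annotation(rng, genome, 30)
        coords = []
        for c in genome.chrom_names:
            pos = 0
            while pos < genome.length(c) - 30_000:
                length = int(rng.integers(2_000, 20_000))
                coords.append((c, pos, pos + length))
                pos += length + int(rng.integers(26_000, 40_000))
        doms = _domset(genome, coords)
        frac = float(rng.uniform(0.1, 1.0))
        assert genes_in_domains(doms, ann, frac) == genes_in_domains_oracle(
            doms.domains, ann, frac
        )
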