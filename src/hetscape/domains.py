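"""Broad repressive-domain segmentation from binned H3K27me3 signal.

LOCKs (Large Organized Chromatin K-modification domains) are long runs of
signal bins enriched over the genome-wide background; BGRDs (Broad Genic
Repression Domains) are the subset of broad domains that blanket at least
one gene body. Segmentation:

1. a bin is enriched iff its value exceeds ``threshold x genome-wide median``
   (or, with a matched input track, iff the pseudocounted signal/input ratio
   exceeds the threshold);
2. maximal runs of enriched bins are stitched across gaps <= ``merge_gap``;
3. a stitched domain is kept iff its longest constituent enriched run is
   >= ``min_length`` (seed-run rule).

The seed-run rule, rather than a length filter on the stitched domain, keeps
the caller monotone: raising ``merge_gap`` can only merge called domains
(count never increases, coverage never decreases) and raising the threshold
can only shrink coverage, because clusters of short noise runs can never
assemble into a domain without a bona-fide seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genome_io import (
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    coverage_bp_per_interval,
)

__all__ = [
    "DomainParams",
    "LOCK_DEFAULTS",
    "BGRD_DEFAULTS",
    "DomainSet",
    "call_locks",
    "call_bgrds",
    "domain_stats",
    "ExpansionReport",
    "expansion",
    "genes_in_domains",
]


@dataclass(frozen=True)
class DomainParams:
    """Segmentation parameters.

    bin_size
        Signal bin width, bp.
    enrichment_threshold
        Fold over the genome-wide median bin value (or over the input ratio).
    merge_gap
        Maximum gap (bp) stitched between enriched runs.
    min_length
        Minimum length (bp) of the seed enriched run a domain must contain.
    pseudocount
        Guards the median (and the input denominator) against zero.
    """

    bin_size: int = 10_000
    enrichment_threshold: float = 1.5
    merge_gap: int = 25_000
    min_length: int = 100_000
    domain_kind: str = "LOCK"
    pseudocount: float = 0.1

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.enrichment_threshold <= 0:
            raise ValueError("enrichment_threshold must be > 0")
        if self.min_length < self.bin_size:
            raise ValueError("min_length must be >= bin_size")
        if self.domain_kind not in ("LOCK", "BGRD"):
            raise ValueError("domain_kind must be LOCK or BGRD")


LOCK_DEFAULTS = DomainParams()
BGRD_DEFAULTS = DomainParams(min_length=10_000, domain_kind="BGRD")


@dataclass
class DomainSet:
    """Non-overlapping sorted broad domains with per-domain mean enrichment."""

    domains: IntervalSet  # score = mean fold-enrichment over the track median
    params: DomainParams
    covered_genes: Optional[dict[int, list[str]]] = None  # BGRD annotation

    def __len__(self) -> int:
        return len(self.domains)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def coverage_bp(self) -> int:
        return self.domains.total_bp()

    def coverage_fraction(self, genome: GenomeModel) -> float:
        return self.coverage_bp / genome.total_size


def call_locks(
    track: SignalTrack,
    params: DomainParams = LOCK_DEFAULTS,
    input_track: Optional[SignalTrack] = None,
) -> DomainSet:
    """Segment broad enriched domains from a binned signal track.

    Deterministic; chromosome processing order does not affect the result.
    An all-zero track yields an empty DomainSet with a warning.
    """
    if input_track is not None and input_track.bin_size != track.bin_size:
        raise ValueError("input track must share the signal track's binning")
    if track.bin_size != params.bin_size:
        raise ValueError(
            f"track bin_size {track.bin_size} != params.bin_size {params.bin_size}"
        )
    allv = track.all_values()
    med = float(np.median(allv)) if len(allv) else 0.0
    if med <= 0 and input_track is None:
        if not np.any(allv > 0):
            warnings.warn("all-zero signal track: no domains called", stacklevel=2)
    denom_med = max(med, params.pseudocount)
    bs = params.bin_size
    gap_bins = params.merge_gap // bs
    ivals: list[GenomicInterval] = []
    for chrom in track.genome.chrom_names:
        v = track.values[chrom]
        if input_track is not None:
            ratio = (v + params.pseudocount) / (
                input_track.values[chrom] + params.pseudocount
            )
            enriched = ratio > params.enrichment_threshold
        else:
            enriched = v > params.enrichment_threshold * denom_med
        if not enriched.any():
            continue
        idx = np.flatnonzero(enriched)
        # maximal runs of consecutive enriched bins
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1  # exclusive bin
        run_len_bp = (run_ends - run_starts) * bs
        # stitch runs whose bin gap is <= gap_bins
        clen = track.genome.length(chrom)
        d_start, d_end, d_seed = run_starts[0], run_ends[0], run_len_bp[0]
        for rs, re_, rl in zip(run_starts[1:], run_ends[1:], run_len_bp[1:]):
            if (rs - d_end) * bs <= params.merge_gap:
                d_end = re_
                d_seed = max(d_seed, rl)
            else:
                if d_seed >= params.min_length:
                    ivals.append(_mk_domain(chrom, d_start, d_end, bs, clen, v, denom_med))
                d_start, d_end, d_seed = rs, re_, rl
        if d_seed >= params.min_length:
            ivals.append(_mk_domain(chrom, d_start, d_end, bs, clen, v, denom_med))
    return DomainSet(IntervalSet(ivals, track.genome), params)


def _mk_domain(chrom, b0, b1, bs, clen, v, denom) -> GenomicInterval:
    start = b0 * bs
    end = min(b1 * bs, clen)
    enr = float(np.mean(v[b0:b1]) / denom)
    return GenomicInterval(chrom, start, end, score=enr)


def call_bgrds(
    lock_like: DomainSet,
    ann: GeneAnnotation,
    gene_cover_fraction: float = 0.8,
) -> DomainSet:
    """Keep domains covering >= ``gene_cover_fraction`` of at least one gene
    body; annotate each kept domain with the gene_ids it covers."""
    if not (0 < gene_cover_fraction <= 1):
        raise ValueError("gene_cover_fraction must be in (0, 1]")
    bodies = ann.gene_bodies()
    cov = coverage_bp_per_interval(bodies, lock_like.domains)
    lengths = np.array([len(iv) for iv in bodies])
    covered = cov >= gene_cover_fraction * lengths
    covered_bodies = [iv for iv, c in zip(bodies, covered) if c]
    kept: list[GenomicInterval] = []
    covered_genes: dict[int, list[str]] = {}
    for dom in lock_like.domains:
        gids = [
            b.label
            for b in covered_bodies
            if b.chrom == dom.chrom and dom.overlap_bp(b) >= gene_cover_fraction * len(b)
        ]
        if gids:
            covered_genes[len(kept)] = sorted(gids)
            kept.append(dom)
    params = DomainParams(
        bin_size=lock_like.params.bin_size,
        enrichment_threshold=lock_like.params.enrichment_threshold,
        merge_gap=lock_like.params.merge_gap,
        min_length=lock_like.params.min_length,
        domain_kind="BGRD",
        pseudocount=lock_like.params.pseudocount,
    )
    return DomainSet(IntervalSet(kept, lock_like.domains.genome), params, covered_genes)


def domain_stats(domains: DomainSet, genome: GenomeModel) -> dict[str, float]:
    """n_domains, coverage in bp, and coverage as a genome fraction."""
    cov = domains.coverage_bp
    return {
        "n_domains": domains.n_domains,
        "coverage_bp": cov,
        "coverage_fraction": cov / genome.total_size,
    }


@dataclass
class ExpansionReport:
    """Day-to-day domain matching: every day-1 domain is matched (to the
    day-2 domain with maximal overlap, ties leftmost) or lost; unmatched
    day-2 domains are new. A day-2 domain absorbing several day-1 domains is
    a merger, counted as an expansion of each and flagged."""

    pairs: pd.DataFrame  # day1 idx/coords, day2 idx/coords, length_ratio, merger flag
    n_matched: int
    n_new: int
    n_lost: int
    n_expanded: int
    n_contracted: int
    coverage_day1_bp: int
    coverage_day2_bp: int

    @property
    def median_length_ratio(self) -> Optional[float]:
        if self.n_matched == 0:
            return None
        return float(self.pairs["length_ratio"].median())


def expansion(day1: DomainSet, day2: DomainSet) -> ExpansionReport:
    """Match each day-1 domain to its maximal-overlap day-2 domain and report
    length ratios, new/lost counts, and per-day coverage."""
    d2 = list(day2.domains)
    rows = []
    matched_d2: dict[int, int] = {}
    for i, d1 in enumerate(day1.domains):
        best_j, best_ov = None, 0
        for j, cand in enumerate(d2):
            ov = d1.overlap_bp(cand)
            if ov > best_ov:  # ties keep the leftmost (first) candidate
                best_j, best_ov = j, ov
        if best_j is None:
            rows.append(
                {
                    "day1_index": i,
                    "chrom": d1.chrom,
                    "day1_start": d1.start,
                    "day1_end": d1.end,
                    "day2_index": -1,
                    "day2_start": -1,
                    "day2_end": -1,
                    "length_ratio": np.nan,
                    "status": "lost",
                    "merger": False,
                }
            )
        else:
            matched_d2[best_j] = matched_d2.get(best_j, 0) + 1
            cand = d2[best_j]
            rows.append(
                {
                    "day1_index": i,
                    "chrom": d1.chrom,
                    "day1_start": d1.start,
                    "day1_end": d1.end,
                    "day2_index": best_j,
                    "day2_start": cand.start,
                    "day2_end": cand.end,
                    "length_ratio": len(cand) / len(d1),
                    "status": "matched",
                    "merger": False,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "day1_index", "chrom", "day1_start", "day1_end", "day2_index",
            "day2_start", "day2_end", "length_ratio", "status", "merger",
        ],
    )
    if len(df):
        multi = {j for j, c in matched_d2.items() if c > 1}
        df["merger"] = df["day2_index"].isin(multi)
    matched = df[df["status"] == "matched"] if len(df) else df
    return ExpansionReport(
        pairs=df,
        n_matched=len(matched),
        n_new=len(d2) - len(matched_d2),
        n_lost=int((df["status"] == "lost").sum()) if len(df) else 0,
        n_expanded=int((matched["length_ratio"] > 1).sum()) if len(matched) else 0,
        n_contracted=int((matched["length_ratio"] < 1).sum()) if len(matched) else 0,
        coverage_day1_bp=day1.coverage_bp,
        coverage_day2_bp=day2.coverage_bp,
    )


def genes_in_domains(
    domains: DomainSet,
    ann: GeneAnnotation,
    min_gene_overlap_fraction: float = 0.5,
) -> list[str]:
    """Genes whose body is covered by the domain set over >= the given
    fraction of its length; deduplicated, sorted."""
    if not (0 < min_gene_overlap_fraction <= 1):
        raise ValueError("min_gene_overlap_fraction must be in (0, 1]")
    bodies = ann.gene_bodies()
    if len(bodies) == 0 or len(domains.domains) == 0:
        return []
    cov = coverage_bp_per_interval(bodies, domains.domains)
    lengths = np.array([len(iv) for iv in bodies])
    hit = cov >= min_gene_overlap_fraction * lengths
    return sorted({iv.label for iv, h in zip(bodies, hit) if h})
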