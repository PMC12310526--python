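"""Genomic coordinate model, interval algebra, and readers/writers for the
standard text formats (BED, bedGraph, GTF, expression TSV).

All coordinates are 0-based half-open internally (BED convention). GTF input,
which is 1-based closed, is converted on read. Strand is used only to orient
promoter windows; all peak and domain logic is strand-agnostic because histone
modification data carry no strand.
"""

from __future__ import annotations

import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "GeneAnnotation",
    "ExpressionTable",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gtf_genes",
    "read_expression",
    "merge",
    "overlap_partition",
]


class GenomeIOError(ValueError):
    """Malformed input file or coordinates outside the genome model."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


class GenomeModel:
    """Ordered chromosome names with their lengths in bp."""

    def __init__(self, chroms: Sequence[tuple[str, int]]):
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise GenomeIOError("duplicate chromosome names")
        for name, length in chroms:
            if length <= 0:
                raise GenomeIOError(f"chromosome {name!r} has non-positive length")
        self._lengths = dict(chroms)
        self.chrom_names: tuple[str, ...] = tuple(names)
        self._order = {name: i for i, name in enumerate(names)}

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeIOError(f"unknown chromosome {chrom!r}") from None

    def order(self, chrom: str) -> int:
        try:
            return self._order[chrom]
        except KeyError:
            raise GenomeIOError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_size(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeModel)
            and self.chrom_names == other.chrom_names
            and self._lengths == other._lengths
        )

    def __repr__(self) -> str:
        return f"GenomeModel({len(self.chrom_names)} chroms, {self.total_size} bp)"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f"{name}\t{self._lengths[name]}\n")

    @classmethod
    def from_tsv(cls, path) -> "GenomeModel":
        chroms = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, length = line.rstrip("\n").split("\t")[:2]
                chroms.append((name, int(length)))
        return cls(chroms)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A sorted collection of genomic intervals bound to a genome model.

    Sorting key is (chromosome order in the genome, start, end). After
    :meth:`merge` the set is pairwise non-overlapping.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], genome: GenomeModel):
        ivals = list(intervals)
        for iv in ivals:
            if iv.chrom not in genome:
                raise GenomeIOError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length(iv.chrom):
                raise GenomeIOError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {genome.length(iv.chrom)}"
                )
        ivals.sort(key=lambda iv: (genome.order(iv.chrom), iv.start, iv.end))
        self.intervals: list[GenomicInterval] = ivals
        self.genome = genome

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
            }
        )

    def merge(self, gap: int = 0) -> "IntervalSet":
        return merge(self, gap)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge(a: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union intervals whose separation is <= ``gap`` bp.

    Idempotent; the result is sorted and pairwise non-overlapping.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    cur: Optional[GenomicInterval] = None
    for iv in a:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged, a.genome)


def _max_overlap_per_interval(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """For each interval of ``a``, the largest single-partner overlap (bp) with ``b``."""
    out = np.zeros(len(a), dtype=np.int64)
    b_chrom = b.by_chrom()
    index: dict[str, tuple[list[int], list[tuple[int, int]], list[int]]] = {}
    for chrom, ivs in b_chrom.items():
        starts = [iv.start for iv in ivs]
        spans = [(iv.start, iv.end) for iv in ivs]
        # running max of end coordinates enables early scan termination
        cummax: list[int] = []
        m = 0
        for _, e in spans:
            m = max(m, e)
            cummax.append(m)
        index[chrom] = (starts, spans, cummax)
    for i, iv in enumerate(a):
        if iv.chrom not in index:
            continue
        starts, spans, cummax = index[iv.chrom]
        hi = bisect_right(starts, iv.end - 1)
        best = 0
        for j in range(hi - 1, -1, -1):
            if cummax[j] <= iv.start:
                break
            s, e = spans[j]
            if e > iv.start:
                best = max(best, min(iv.end, e) - max(iv.start, s))
        out[i] = best
    return out


def overlap_partition(
    a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1
) -> tuple[IntervalSet, IntervalSet]:
    """Split ``a`` into (a_only, a_and_b) by overlap with *any* interval of ``b``.

    An interval of ``a`` lands in ``a_and_b`` iff at least one interval of
    ``b`` overlaps it by >= ``min_overlap_bp``. Counts are conserved:
    ``len(a_only) + len(a_and_b) == len(a)``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ov = _max_overlap_per_interval(a, b)
    hit = ov >= min_overlap_bp
    a_only = IntervalSet([iv for iv, h in zip(a, hit) if not h], a.genome)
    a_and_b = IntervalSet([iv for iv, h in zip(a, hit) if h], a.genome)
    return a_only, a_and_b


def overlaps_any(a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean per-interval-of-``a`` overlap indicator against ``b``."""
    return _max_overlap_per_interval(a, b) >= min_overlap_bp


def coverage_bp_per_interval(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Total bp of each interval of ``a`` covered by the union of ``b``.

    ``b`` is merged internally so double-covered bp count once.
    """
    bm = merge(b, 0)
    out = np.zeros(len(a), dtype=np.int64)
    by_chrom = bm.by_chrom()
    idx = {c: ([iv.start for iv in ivs], [(iv.start, iv.end) for iv in ivs]) for c, ivs in by_chrom.items()}
    for i, iv in enumerate(a):
        if iv.chrom not in idx:
            continue
        starts, spans = idx[iv.chrom]
        hi = bisect_right(starts, iv.end - 1)
        total = 0
        for j in range(hi - 1, -1, -1):
            s, e = spans[j]
            if e <= iv.start:
                # merged intervals are disjoint & sorted: nothing earlier overlaps
                break
            total += min(iv.end, e) - max(iv.start, s)
        out[i] = total
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, genome: GenomeModel) -> IntervalSet:
    """Read 3+ column BED (0-based half-open) into a sorted IntervalSet."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeIOError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GenomeIOError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if chrom not in genome:
                raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                intervals.append(GenomicInterval(chrom, start, end, score, label))
            except GenomeIOError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals, genome)


def write_bed(ivals: IntervalSet, path) -> None:
    """Write BED3/BED6 depending on whether labels/scores are present."""
    with open(path, "w") as fh:
        for iv in ivals:
            if iv.label is None and iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.label if iv.label is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# bedGraph / SignalTrack
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """Fixed-bin mean signal per chromosome.

    ``values[chrom]`` has length ceil(chrom_length / bin_size); the last bin
    may be shorter than ``bin_size`` and its mean is taken over the bp it
    actually spans. Bin values are >= 0; bp not covered by any record
    contribute 0 to the bin mean.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    genome: GenomeModel

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.length(chrom) // self.bin_size)

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.chrom_names])

    @classmethod
    def zeros(cls, genome: GenomeModel, bin_size: int) -> "SignalTrack":
        vals = {
            c: np.zeros(-(-genome.length(c) // bin_size)) for c in genome.chrom_names
        }
        return cls(bin_size, vals, genome)


def read_bedgraph(path, genome: GenomeModel, bin_size: int) -> SignalTrack:
    """Bin a 4-column bedGraph into a SignalTrack of per-bin means.

    Per-bp values are the mean of all records covering that bp (overlapping
    records are averaged, with a warning); uncovered bp count as 0. The bin
    value is the mean over the bp the bin spans.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    ) if _file_nonempty(path) else pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if len(df) and (df["value"] < 0).any():
        bad = df.index[df["value"] < 0][0]
        raise GenomeIOError(f"{path}: negative value at record {bad + 1}")
    track = SignalTrack.zeros(genome, bin_size)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise GenomeIOError(f"{path}: unknown chromosome {chrom!r}")
        clen = genome.length(chrom)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        v = sub["value"].to_numpy()
        if (s < 0).any() or (e > clen).any() or (s >= e).any():
            raise GenomeIOError(f"{path}: record outside chromosome {chrom!r}")
        order = np.argsort(s, kind="stable")
        has_overlap = bool((e[order][:-1] > s[order][1:]).any())
        if has_overlap:
            warnings.warn(
                f"{path}: overlapping bedGraph records on {chrom}; "
                "resolved by per-bp averaging",
                stacklevel=2,
            )
            # elementary segments between all record boundaries; per-bp value
            # is the mean of covering records
            bounds = np.unique(np.concatenate([s, e]))
            nseg = len(bounds) - 1
            li = np.searchsorted(bounds, s)
            ri = np.searchsorted(bounds, e)
            val_sum = np.zeros(nseg)
            cov = np.zeros(nseg)
            for arr, inc in ((val_sum, v), (cov, np.ones_like(v))):
                diff = np.zeros(nseg + 1)
                np.add.at(diff, li, inc)
                np.subtract.at(diff, ri, inc)
                arr[:] = np.cumsum(diff[:-1])
            segs = zip(
                bounds[:-1], bounds[1:],
                np.where(cov > 0, val_sum / np.maximum(cov, 1), 0.0),
            )
        else:
            segs = zip(s, e, v)
        binned = track.values[chrom]
        acc = np.zeros_like(binned)
        for ss, ee, sv in segs:
            if sv == 0.0:
                continue
            b0, b1 = ss // bin_size, (ee - 1) // bin_size
            if b0 == b1:
                acc[b0] += sv * (ee - ss)
            else:
                acc[b0] += sv * ((b0 + 1) * bin_size - ss)
                if b1 > b0 + 1:
                    acc[b0 + 1 : b1] += sv * bin_size
                acc[b1] += sv * (ee - b1 * bin_size)
        widths = np.full(len(binned), bin_size, dtype=float)
        widths[-1] = clen - (len(binned) - 1) * bin_size
        binned += acc / widths
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write one bedGraph record per bin (zero bins included, for exact round-trip)."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            clen = track.genome.length(chrom)
            vals = track.values[chrom]
            bs = track.bin_size
            for i, v in enumerate(vals):
                fh.write(f"{chrom}\t{i * bs}\t{min((i + 1) * bs, clen)}\t{v:.6g}\n")


def _file_nonempty(path) -> bool:
    import os

    return os.path.getsize(path) > 0


# ---------------------------------------------------------------------------
# GTF / gene annotation
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


@dataclass
class GeneAnnotation:
    """Gene models (outermost transcript extent) plus a promoter window.

    ``genes`` columns: gene_id (unique), chrom, strand (+/-), start, end
    (0-based half-open). The TSS is ``start`` for + genes and ``end`` for -
    genes; the promoter is [TSS - upstream, TSS + downstream) oriented by
    strand and clipped to the chromosome.
    """

    genes: pd.DataFrame
    promoter_window: tuple[int, int]
    genome: GenomeModel

    def __post_init__(self):
        if self.genes["gene_id"].duplicated().any():
            raise GenomeIOError("duplicate gene_id in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def tss(self) -> pd.Series:
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"]),
            index=g["gene_id"].to_numpy(),
            name="tss",
        )

    def promoters(self) -> IntervalSet:
        up, down = self.promoter_window
        g = self.genes
        plus = g["strand"].to_numpy() == "+"
        s = np.where(plus, g["start"] - up, g["end"] - down)
        e = np.where(plus, g["start"] + down, g["end"] + up)
        clens = np.array([self.genome.length(c) for c in g["chrom"]])
        s = np.maximum(0, s)
        e = np.minimum(clens, e)
        ivals = [
            GenomicInterval(c, int(ss), int(ee), label=gid)
            for c, ss, ee, gid in zip(g["chrom"], s, e, g["gene_id"])
            if ss < ee
        ]
        return IntervalSet(ivals, self.genome)

    def gene_bodies(self) -> IntervalSet:
        g = self.genes
        ivals = [
            GenomicInterval(c, int(s), int(e), label=gid)
            for c, s, e, gid in zip(g["chrom"], g["start"], g["end"], g["gene_id"])
        ]
        return IntervalSet(ivals, self.genome)


def read_gtf_genes(
    path, genome: GenomeModel, promoter_window: tuple[int, int] = (2000, 500)
) -> GeneAnnotation:
    """Read gene extents from GTF gene/transcript features.

    One record per gene_id spanning the outermost transcript extent.
    GTF 1-based closed coordinates become 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "transcript"):
                continue
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise GenomeIOError(f"{path}:{lineno}: missing gene_id attribute")
            if chrom not in genome:
                raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            rows.append((m.group(1), chrom, strand, int(start) - 1, int(end)))
    if rows:
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
        df = (
            df.groupby("gene_id", sort=False)
            .agg(
                chrom=("chrom", "first"),
                strand=("strand", "first"),
                start=("start", "min"),
                end=("end", "max"),
            )
            .reset_index()
        )
        if not df["strand"].isin(["+", "-"]).all():
            raise GenomeIOError(f"{path}: strand must be + or -")
        if (df["start"] >= df["end"]).any():
            raise GenomeIOError(f"{path}: gene with start >= end")
    else:
        df = pd.DataFrame(columns=["gene_id", "chrom", "strand", "start", "end"])
    return GeneAnnotation(df, promoter_window, genome)


def write_gtf_genes(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for _, row in ann.genes.iterrows():
            fh.write(
                f"{row['chrom']}\thetscape\tgene\t{row['start'] + 1}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\tgene_id \"{row['gene_id']}\";\n"
            )


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """gene_id -> non-negative expression value (e.g. TPM) per named condition."""

    data: pd.DataFrame  # index: gene_id; columns: condition names

    def __post_init__(self):
        if (self.data.to_numpy() < 0).any():
            raise GenomeIOError("negative expression values")
        if self.data.index.duplicated().any():
            raise GenomeIOError("duplicate gene_id in expression table")

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    def values_for(self, genes: Sequence[str], condition: str) -> np.ndarray:
        return self.data.loc[list(genes), condition].to_numpy()

    def expressed_genes(self) -> pd.Index:
        """Genes with nonzero expression in at least one condition."""
        return self.data.index[(self.data > 0).any(axis=1)]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionTable(df)
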