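"""Factor/mark co-occupancy analysis.

Partitions a reference peak set by its membership combination over other
factor peak sets, classifies peaks by genomic element (promoter > gene body >
intergenic), quantifies direct-vs-indirect relationships between a histone
mark and a DNA-binding factor, and measures the epigenetic switch: loci that
are factor-bound but mark-negative in the null state and gain the mark after
factor re-expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneAnnotation,
    IntervalSet,
    overlaps_any,
)

__all__ = [
    "ELEMENT_CLASSES",
    "classify_elements",
    "CoOccupancyPartition",
    "co_occupancy",
    "SwitchReport",
    "switch_analysis",
    "DirectIndirectReport",
    "direct_indirect",
]

ELEMENT_CLASSES = ("promoter", "gene_body", "intergenic")


def classify_elements(
    peaks: IntervalSet, ann: GeneAnnotation
) -> tuple[list[str], dict[str, float]]:
    """Assign each peak exactly one element class.

    Precedence promoter > gene_body > intergenic with any-bp overlap, so a
    peak touching both a promoter window and a gene body counts as promoter.
    Returns (per-peak labels in set order, class -> fraction summing to 1).
    """
    prom = overlaps_any(peaks, ann.promoters())
    body = overlaps_any(peaks, ann.gene_bodies())
    labels = [
        "promoter" if p else ("gene_body" if b else "intergenic")
        for p, b in zip(prom, body)
    ]
    n = len(labels)
    fractions = {
        cls: (labels.count(cls) / n if n else 0.0) for cls in ELEMENT_CLASSES
    }
    return labels, fractions


@dataclass
class CoOccupancyPartition:
    """Reference peaks partitioned by membership over the other factor sets.

    ``counts`` keys are tuples of the other-set names the reference peak
    overlaps (empty tuple = reference-only). Combinations are disjoint and
    exhaustive: counts sum to the reference set size.
    """

    reference_name: str
    other_names: tuple[str, ...]
    counts: dict[tuple[str, ...], int]
    sets: dict[tuple[str, ...], IntervalSet]
    element_fractions: Optional[dict[tuple[str, ...], dict[str, float]]] = None

    @property
    def n_reference(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[tuple[str, ...], float]:
        n = self.n_reference
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}

    @staticmethod
    def combo_label(combo: tuple[str, ...], reference_name: str) -> str:
        return "+".join((reference_name,) + combo) if combo else f"{reference_name}-only"

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        fr = self.fractions()
        for combo in sorted(self.counts, key=lambda c: (len(c), c)):
            rows.append(
                {
                    "combination": self.combo_label(combo, self.reference_name),
                    "count": self.counts[combo],
                    "fraction": fr[combo],
                }
            )
        return pd.DataFrame(rows)


def co_occupancy(
    named_sets: Sequence[tuple[str, IntervalSet]],
    min_overlap_bp: int = 1,
    ann: Optional[GeneAnnotation] = None,
) -> CoOccupancyPartition:
    """Label each peak of the first (reference) set by which other sets it overlaps.

    Each reference peak is counted once, under the full membership combination
    (power-set label) over the remaining sets. With ``ann`` given, the element
    class breakdown of each combination is included.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    names = [n for n, _ in named_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    ref_name, ref = named_sets[0]
    other = named_sets[1:]
    flags = np.column_stack(
        [overlaps_any(ref, s, min_overlap_bp) for _, s in other]
    ) if other else np.zeros((len(ref), 0), dtype=bool)
    other_names = tuple(n for n, _ in other)
    members: dict[tuple[str, ...], list] = {}
    for iv, row in zip(ref, flags):
        combo = tuple(n for n, f in zip(other_names, row) if f)
        members.setdefault(combo, []).append(iv)
    counts = {combo: len(ivs) for combo, ivs in members.items()}
    sets = {combo: IntervalSet(ivs, ref.genome) for combo, ivs in members.items()}
    elem = None
    if ann is not None:
        elem = {
            combo: classify_elements(ivset, ann)[1] for combo, ivset in sets.items()
        }
    return CoOccupancyPartition(ref_name, other_names, counts, sets, elem)


@dataclass
class SwitchReport:
    """Epigenetic-switch quantification.

    Candidates are day-0 factor-bound, mark-negative loci; a candidate
    switched if it carries the mark at day 1. ``switch_fraction`` is None
    when there are no candidates (undefined, not 0).
    """

    n_candidates: int
    n_switched: int
    switch_fraction: Optional[float]
    frac_switched_ikaros_hdac1: Optional[float]
    candidates: IntervalSet
    switched_mask: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = self.candidates.to_dataframe()
        df["switched"] = self.switched_mask
        return df


def switch_analysis(
    day0_ezh2: IntervalSet,
    day0_h3k27me3: IntervalSet,
    day1_ikaros: IntervalSet,
    day1_hdac1: IntervalSet,
    day1_h3k27me3: IntervalSet,
    min_overlap_bp: int = 1,
) -> SwitchReport:
    """Fraction of day-0 EZH2-only loci that gain H3K27me3 by day 1.

    Also reports how many of the switched loci are co-occupied by both
    IKAROS and HDAC1 at day 1.
    """
    pre_marked = overlaps_any(day0_ezh2, day0_h3k27me3, min_overlap_bp)
    candidates = IntervalSet(
        [iv for iv, m in zip(day0_ezh2, pre_marked) if not m], day0_ezh2.genome
    )
    n_cand = len(candidates)
    if n_cand == 0:
        return SwitchReport(0, 0, None, None, candidates, np.zeros(0, dtype=bool))
    switched = overlaps_any(candidates, day1_h3k27me3, min_overlap_bp)
    n_sw = int(switched.sum())
    frac_ikhd: Optional[float] = None
    if n_sw:
        sw_set = IntervalSet(
            [iv for iv, s in zip(candidates, switched) if s], candidates.genome
        )
        ik = overlaps_any(sw_set, day1_ikaros, min_overlap_bp)
        hd = overlaps_any(sw_set, day1_hdac1, min_overlap_bp)
        frac_ikhd = float((ik & hd).mean())
    return SwitchReport(n_cand, n_sw, n_sw / n_cand, frac_ikhd, candidates, switched)


@dataclass
class DirectIndirectReport:
    """Mark peaks split by factor co-occupancy (direct) or not (indirect)."""

    n_mark_peaks: int
    n_direct: int
    n_indirect: int
    fold_change_vs_reference: Optional[float]

    @property
    def frac_direct(self) -> Optional[float]:
        return self.n_direct / self.n_mark_peaks if self.n_mark_peaks else None


def direct_indirect(
    mark_peaks: IntervalSet,
    factor_peaks: IntervalSet,
    reference_mark_peaks: Optional[IntervalSet] = None,
    min_overlap_bp: int = 1,
) -> DirectIndirectReport:
    """Split mark peaks by factor overlap; optional count fold-change vs reference.

    ``fold_change_vs_reference`` is len(mark)/len(reference), the "N-fold
    increase in peaks" style statistic; None (flagged undefined) when the
    reference is absent or empty.
    """
    direct = overlaps_any(mark_peaks, factor_peaks, min_overlap_bp)
    n_direct = int(direct.sum())
    fold = None
    if reference_mark_peaks is not None and len(reference_mark_peaks) > 0:
        fold = len(mark_peaks) / len(reference_mark_peaks)
    return DirectIndirectReport(
        len(mark_peaks), n_direct, len(mark_peaks) - n_direct, fold
    )
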