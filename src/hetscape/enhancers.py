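"""Distal enhancer catalog, four-state chromatin classification, gene linkage,
and expression stratification.

Enhancers are merged distal H3K4me1 regions. Each gets exactly one state from
the mark combination:

========  ========  ========  ========
H3K4me1   H3K27ac   H3K27me3  state
========  ========  ========  ========
+         +         -         active
+         -         -         primed
+         +         +         intermediate
+         -         +         poised
========  ========  ========  ========

Genes are linked to the nearest TSS (center-to-TSS distance), and group
expression is compared with two-sided rank-sum tests against a reference
group (state grouping: active; occupancy grouping: IKAROS-/HDAC1-).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    ExpressionTable,
    GeneAnnotation,
    IntervalSet,
    merge,
    overlap_partition,
    overlaps_any,
)

__all__ = [
    "ENHANCER_STATES",
    "build_catalog",
    "classify_states",
    "link_targets",
    "EnhancerRecord",
    "make_records",
    "StateExpressionReport",
    "expression_by_group",
]

# ordered from least to most repressive; the order is the tie-break when one
# gene is linked by enhancers in several states
ENHANCER_STATES = ("active", "primed", "intermediate", "poised")
_REPRESSIVENESS = {s: i for i, s in enumerate(ENHANCER_STATES)}

# occupancy combos from least to most occupied; same tie-break role
OCCUPANCY_GROUPS = ("none", "IKAROS", "HDAC1", "IKAROS+HDAC1")


def build_catalog(
    h3k4me1: IntervalSet, ann: GeneAnnotation, merge_gap: int = 1000
) -> IntervalSet:
    """Candidate enhancers: H3K4me1 peaks merged at ``merge_gap``, promoter-
    overlapping regions removed (distal requirement)."""
    merged = merge(h3k4me1, merge_gap)
    distal, _ = overlap_partition(merged, ann.promoters())
    return distal


def classify_states(
    catalog: IntervalSet,
    h3k27ac: IntervalSet,
    h3k27me3: IntervalSet,
    min_overlap_bp: int = 1,
) -> list[str]:
    """One state per catalog enhancer from the H3K27ac/H3K27me3 truth table."""
    ac = overlaps_any(catalog, h3k27ac, min_overlap_bp)
    me3 = overlaps_any(catalog, h3k27me3, min_overlap_bp)
    states = []
    for a, m in zip(ac, me3):
        if a and not m:
            states.append("active")
        elif a and m:
            states.append("intermediate")
        elif m:
            states.append("poised")
        else:
            states.append("primed")
    return states


def link_targets(
    catalog: IntervalSet, ann: GeneAnnotation, max_distance_bp: int = 100_000
) -> list[tuple[Optional[str], Optional[int]]]:
    """Nearest-TSS linkage by enhancer center, ties to the lexicographically
    lower gene_id; (None, None) beyond ``max_distance_bp``."""
    if max_distance_bp <= 0:
        raise ValueError("max_distance_bp must be > 0")
    g = ann.genes
    tss = np.where(g["strand"].to_numpy() == "+", g["start"].to_numpy(), g["end"].to_numpy())
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in g["chrom"].unique():
        mask = (g["chrom"] == chrom).to_numpy()
        pos = tss[mask]
        ids = g["gene_id"].to_numpy()[mask]
        order = np.argsort(pos, kind="stable")
        per_chrom[chrom] = (pos[order], ids[order])
    out: list[tuple[Optional[str], Optional[int]]] = []
    for iv in catalog:
        if iv.chrom not in per_chrom:
            out.append((None, None))
            continue
        pos, ids = per_chrom[iv.chrom]
        center = (iv.start + iv.end) // 2
        j = int(np.searchsorted(pos, center))
        best_d = None
        for k in (j - 1, j):
            if 0 <= k < len(pos):
                d = abs(int(pos[k]) - center)
                if best_d is None or d < best_d:
                    best_d = d
        if best_d is None or best_d > max_distance_bp:
            out.append((None, None))
            continue
        # collect every gene at exactly the minimal distance (tie handling)
        cands = []
        lo = int(np.searchsorted(pos, center - best_d, side="left"))
        hi = int(np.searchsorted(pos, center + best_d, side="right"))
        for k in range(lo, hi):
            if abs(int(pos[k]) - center) == best_d:
                cands.append(ids[k])
        out.append((min(cands), best_d))
    return out


@dataclass
class EnhancerRecord:
    """A distal enhancer with its state, factor occupancy, and linked gene."""

    chrom: str
    start: int
    end: int
    state: str
    ikaros: bool
    hdac1: bool
    gene_id: Optional[str]
    distance: Optional[int]

    @property
    def occupancy_group(self) -> str:
        if self.ikaros and self.hdac1:
            return "IKAROS+HDAC1"
        if self.ikaros:
            return "IKAROS"
        if self.hdac1:
            return "HDAC1"
        return "none"


def make_records(
    h3k4me1: IntervalSet,
    h3k27ac: IntervalSet,
    h3k27me3: IntervalSet,
    ikaros: Optional[IntervalSet],
    hdac1: Optional[IntervalSet],
    ann: GeneAnnotation,
    merge_gap: int = 1000,
    max_distance_bp: int = 100_000,
    min_overlap_bp: int = 1,
) -> list[EnhancerRecord]:
    """Catalog -> states -> occupancy flags -> target genes, in one pass."""
    catalog = build_catalog(h3k4me1, ann, merge_gap)
    states = classify_states(catalog, h3k27ac, h3k27me3, min_overlap_bp)
    ik = (
        overlaps_any(catalog, ikaros, min_overlap_bp)
        if ikaros is not None
        else np.zeros(len(catalog), dtype=bool)
    )
    hd = (
        overlaps_any(catalog, hdac1, min_overlap_bp)
        if hdac1 is not None
        else np.zeros(len(catalog), dtype=bool)
    )
    links = link_targets(catalog, ann, max_distance_bp)
    return [
        EnhancerRecord(iv.chrom, iv.start, iv.end, st, bool(i), bool(h), gid, dist)
        for iv, st, i, h, (gid, dist) in zip(catalog, states, ik, hd, links)
    ]


@dataclass
class StateExpressionReport:
    """Per-group expression summaries and rank-sum comparisons vs a reference."""

    grouping: str
    reference: str
    condition: str
    groups: dict[str, list[str]]  # group -> gene ids
    table: pd.DataFrame  # group, n, median, iqr, median_ratio_vs_ref, u_stat, p
    excluded_groups: list[str]


def _assign_genes(
    records: Sequence[EnhancerRecord], grouping: str
) -> dict[str, str]:
    """gene_id -> group; a multiply-linked gene goes to its most repressive /
    most occupied group so it appears once per report."""
    assign: dict[str, str] = {}
    if grouping == "by_state":
        rank = _REPRESSIVENESS
        for r in records:
            if r.gene_id is None:
                continue
            g = r.state
            prev = assign.get(r.gene_id)
            if prev is None or rank[g] > rank[prev]:
                assign[r.gene_id] = g
    elif grouping == "by_occupancy":
        rank = {g: i for i, g in enumerate(OCCUPANCY_GROUPS)}
        for r in records:
            # the occupancy comparison concerns active enhancers only
            if r.gene_id is None or r.state != "active":
                continue
            g = r.occupancy_group
            prev = assign.get(r.gene_id)
            if prev is None or rank[g] > rank[prev]:
                assign[r.gene_id] = g
    else:
        raise ValueError("grouping must be 'by_state' or 'by_occupancy'")
    return assign


def expression_by_group(
    records: Sequence[EnhancerRecord],
    expr: ExpressionTable,
    grouping: str = "by_state",
    condition: Optional[str] = None,
) -> StateExpressionReport:
    """Stratify linked-gene expression by enhancer state or factor occupancy.

    Reports per-group median/IQR and two-sided Mann-Whitney rank-sum p-values
    against the reference group (active for by_state, none for by_occupancy).
    Raw p-values; with at most a handful of pairwise comparisons no multiple-
    testing correction is applied.
    """
    condition = condition or expr.conditions[0]
    reference = "active" if grouping == "by_state" else "none"
    order = ENHANCER_STATES if grouping == "by_state" else OCCUPANCY_GROUPS
    assign = _assign_genes(records, grouping)
    groups: dict[str, list[str]] = {g: [] for g in order}
    for gid, grp in assign.items():
        if gid in expr.gene_ids:
            groups[grp].append(gid)
    excluded = [g for g, members in groups.items() if not members]
    for g in excluded:
        warnings.warn(f"group {g!r} is empty; excluded from report", stacklevel=2)
    groups = {g: sorted(m) for g, m in groups.items() if m}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} is empty")
    ref_vals = expr.values_for(groups[reference], condition)
    ref_med = float(np.median(ref_vals))
    rows = []
    for g in order:
        if g not in groups:
            continue
        vals = expr.values_for(groups[g], condition)
        med = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        if g == reference:
            u, p = np.nan, np.nan
        else:
            u, p = stats.mannwhitneyu(vals, ref_vals, alternative="two-sided")
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "median": med,
                "iqr": float(q3 - q1),
                "median_ratio_vs_ref": med / ref_med if ref_med > 0 else np.nan,
                "u_stat": u,
                "p_value": p,
            }
        )
    return StateExpressionReport(
        grouping, reference, condition, groups, pd.DataFrame(rows), excluded
    )
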