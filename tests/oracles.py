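"""Independent brute-force oracles for the interval algebra.

Everything here works on per-bp boolean masks or exhaustive all-pairs scans,
deliberately avoiding the sweep/searchsorted code paths of the package, so
the two routes check each other. Only usable on small genomes.
"""

from __future__ import annotations

import numpy as np

from hetscape.genome_io import GenomeModel, IntervalSet


def bp_mask(ivset: IntervalSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chrom_names}
    for iv in ivset:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_to_intervals(masks: dict[str, np.ndarray], genome: GenomeModel) -> list[tuple[str, int, int]]:
    out = []
    for chrom in genome.chrom_names:
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out += [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return out


def merge_oracle(ivset: IntervalSet, gap: int) -> list[tuple[str, int, int]]:
    """Per-bp union, then join runs separated by <= gap bp."""
    runs = mask_to_intervals(bp_mask(ivset, ivset.genome), ivset.genome)
    out: list[list] = []
    for chrom, s, e in runs:
        if out and out[-1][0] == chrom and s - out[-1][2] <= gap:
            out[-1][2] = e
        else:
            out.append([chrom, s, e])
    return [tuple(r) for r in out]


def overlap_partition_oracle(
    a: IntervalSet, b: IntervalSet, min_overlap_bp: int
) -> list[bool]:
    """All-pairs scan: does any single b interval overlap by >= min_overlap_bp."""
    out = []
    for iv in a:
        hit = False
        for jv in b:
            if iv.overlap_bp(jv) >= min_overlap_bp:
                hit = True
                break
        out.append(hit)
    return out


def classify_oracle(peaks: IntervalSet, ann) -> list[str]:
    """Per-peak scan over every gene's promoter and body."""
    proms = list(ann.promoters())
    bodies = list(ann.gene_bodies())
    out = []
    for p in peaks:
        if any(p.overlap_bp(q) >= 1 for q in proms):
            out.append("promoter")
        elif any(p.overlap_bp(q) >= 1 for q in bodies):
            out.append("gene_body")
        else:
            out.append("intergenic")
    return out


def catalog_oracle(h3k4me1: IntervalSet, ann, merge_gap: int) -> list[tuple[str, int, int]]:
    """Merge-then-subtract computed on bp masks: merged H3K4me1 regions that
    touch no promoter bp."""
    merged = merge_oracle(h3k4me1, merge_gap)
    pmask = bp_mask(ann.promoters(), h3k4me1.genome)
    return [
        (c, s, e) for c, s, e in merged if not pmask[c][s:e].any()
    ]


def genes_in_domains_oracle(domains: IntervalSet, ann, frac: float) -> list[str]:
    dmask = bp_mask(domains, domains.genome)
    out = set()
    for body in ann.gene_bodies():
        covered = int(dmask[body.chrom][body.start : body.end].sum())
        if covered >= frac * len(body):
            out.add(body.label)
    return sorted(out)


def nearest_tss_oracle(catalog: IntervalSet, ann, max_distance: int):
    """Exhaustive nearest-TSS scan with the lexicographic tie rule."""
    genes = ann.genes
    out = []
    for iv in catalog:
        center = (iv.start + iv.end) // 2
        best = None
        for _, row in genes.iterrows():
            if row["chrom"] != iv.chrom:
                continue
            tss = row["start"] if row["strand"] == "+" else row["end"]
            d = abs(tss - center)
            if best is None or d < best[1] or (d == best[1] and row["gene_id"] < best[0]):
                best = (row["gene_id"], d)
        if best is None or best[1] > max_distance:
            out.append((None, None))
        else:
            out.append(best)
    return out
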