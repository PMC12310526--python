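"""Synthetic chromatin landscapes with planted ground truth.

The generator emits the exact text formats the readers consume (BED peaks per
factor and timepoint, binned H3K27me3 bedGraph, GTF gene models, expression
TSV) plus truth tables, so every pipeline stage can be tested against known
answers without external data.

Design: feature classes live on dedicated chromosome territories so the
planted truth is unambiguous —

* ``chr1`` broad-domain territory: planted H3K27me3 LOCKs (day1, expanded at
  day2), genes inside the domains (repressed by ``repression_effect``) and
  background genes outside them;
* ``chr2`` enhancer territory: one enhancer + target gene per fixed-size
  slot, states and IKAROS/HDAC1 occupancy planted per design, target-gene
  expression multiplied by the state/occupancy effects;
* ``chr3`` factor-site territory: transcription-factor/mark co-occupancy
  sites drawn per combination design and element-class design
  (promoter / gene body / intergenic), with per-factor peaks jittered around
  a shared locus so the designed overlap survives;
* ``chr4`` neutral filler genes, so the expression universe is dominated by
  unaffected genes as in a real transcriptome.

Timepoints follow the re-expression time course: ``day0`` is the
IKAROS-null state (no IKAROS binding, no planted domains, baseline
expression), ``day1``/``day2`` carry the planted landscape.

Identical seed => byte-identical output files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    ExpressionTable,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_gtf_genes,
)

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SwitchScenario",
    "simulate",
    "make_switch_scenario",
    "make_knockout_scenario",
]

FACTORS = ("IKAROS", "EZH2", "HDAC1", "H3K27me3", "H3K4me1", "H3K27ac")


def _default_co_occupancy_design():
    # combination -> fraction of the timepoint's sites; day0 is the
    # IKAROS-null state (EZH2 binds without H3K27me3), day1 couples
    # IKAROS/HDAC1 binding to de novo H3K27me3, day2 H3K27me3 is mostly
    # factor-independent and ~4.5x the day1 peak count
    return {
        "day0": {
            ("EZH2",): 0.80,
            ("HDAC1",): 0.10,
            ("EZH2", "HDAC1"): 0.10,
        },
        "day1": {
            ("IKAROS", "HDAC1", "EZH2", "H3K27me3"): 0.35,
            ("IKAROS", "HDAC1", "H3K27me3"): 0.30,
            ("IKAROS", "EZH2"): 0.10,
            ("HDAC1", "H3K27me3"): 0.10,
            ("IKAROS",): 0.15,
        },
        "day2": {
            ("H3K27me3",): 0.35,
            ("HDAC1", "H3K27me3"): 0.25,
            ("IKAROS", "HDAC1", "EZH2", "H3K27me3"): 0.12,
            ("IKAROS", "HDAC1", "H3K27me3"): 0.12,
            ("HDAC1",): 0.16,
        },
    }


def _default_element_fractions():
    return {
        "day0": {"promoter": 0.40, "gene_body": 0.30, "intergenic": 0.30},
        "day1": {"promoter": 0.50, "gene_body": 0.25, "intergenic": 0.25},
        "day2": {"promoter": 0.34, "gene_body": 0.33, "intergenic": 0.33},
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the standard scenario."""

    seed: int = 0
    timepoints: tuple[str, ...] = ("day0", "day1", "day2")
    promoter_window: tuple[int, int] = (2000, 500)
    noise_sd: float = 0.2  # CV of binned background signal

    # factor co-occupancy territory; day2 site count is set so the
    # genome-wide H3K27me3 peak total (sites + enhancer marks) rises ~4.4x
    # over day1, the global de novo expansion the landscape emulates
    site_chrom_length: int = 36_000_000
    n_sites: dict = field(default_factory=lambda: {"day0": 1000, "day1": 1000, "day2": 6000})
    co_occupancy_design: dict = field(default_factory=_default_co_occupancy_design)
    element_fractions: dict = field(default_factory=_default_element_fractions)
    site_genes: int = 2500
    site_gene_slot: int = 12_000
    site_gene_length: int = 6_000
    peak_width_median: int = 400
    peak_width_sigma: float = 0.35
    peak_width_min: int = 200
    peak_width_max: int = 2_000
    peak_jitter: int = 50

    # enhancer territory
    enhancer_chrom_length: int = 31_000_000
    enhancer_slot: int = 30_000
    enhancer_width_range: tuple[int, int] = (1_000, 2_000)
    enhancer_gene_offset: int = 12_000
    enhancer_gene_length: int = 3_000
    enhancer_state_design: dict = field(
        default_factory=lambda: {"active": 250, "primed": 250, "intermediate": 250, "poised": 250}
    )
    # (ikaros, hdac1) occupancy fractions among active / among repressed-state enhancers
    occupancy_design_active: dict = field(
        default_factory=lambda: {
            (False, False): 0.40, (True, False): 0.20, (False, True): 0.20, (True, True): 0.20,
        }
    )
    occupancy_design_nonactive: dict = field(
        default_factory=lambda: {
            (True, True): 0.50, (False, True): 0.30, (True, False): 0.10, (False, False): 0.10,
        }
    )
    state_expression_effect: dict = field(
        default_factory=lambda: {"active": 1.0, "primed": 0.6, "intermediate": 0.35, "poised": 0.25}
    )
    occupancy_expression_effect: dict = field(
        default_factory=lambda: {
            (False, False): 1.0, (True, False): 0.6, (False, True): 0.4, (True, True): 0.35,
        }
    )

    # broad-domain territory
    lock_chrom_length: int = 20_000_000
    n_planted_locks: int = 20
    lock_length_range: tuple[int, int] = (200_000, 400_000)
    lock_expansion_factor: float = 2.0
    bin_size: int = 10_000
    signal_baseline: float = 1.0
    plateau_height: float = 3.0
    lock_genes_per_domain: int = 15
    lock_gene_length_range: tuple[int, int] = (2_000, 5_000)
    background_genes: int = 300
    repression_effect: float = 0.25

    # neutral filler
    filler_chrom_length: int = 30_000_000
    filler_genes: int = 9_000
    filler_gene_length: int = 2_000

    # expression model
    tpm_median: float = 50.0
    tpm_sigma: float = 0.8
    expr_jitter_sigma: float = 0.1

    # switch scenario
    switch_n_candidates: int = 2000
    switch_fraction: float = 0.75
    switch_ikhd_fraction: float = 0.95
    switch_n_premarked: int = 500
    switch_n_denovo: int = 300
    switch_locus_spacing: int = 3_000

    def genome(self) -> GenomeModel:
        return GenomeModel(
            [
                ("chr1", self.lock_chrom_length),
                ("chr2", self.enhancer_chrom_length),
                ("chr3", self.site_chrom_length),
                ("chr4", self.filler_chrom_length),
            ]
        )

    def validate(self) -> None:
        """Raise before any file is written if the design cannot fit."""
        for tp, design in self.co_occupancy_design.items():
            total = sum(design.values())
            if any(f < 0 or f > 1 for f in design.values()) or total > 1 + 1e-9:
                raise ValueError(f"co-occupancy fractions for {tp} invalid (sum {total})")
        for tp in self.timepoints:
            n = self.n_sites.get(tp, 0)
            ef = self.element_fractions.get(tp, {})
            n_prom = round(ef.get("promoter", 0) * n)
            n_body = round(ef.get("gene_body", 0) * n)
            if n_prom > self.site_genes or n_body > self.site_genes:
                raise ValueError(
                    f"infeasible design: {tp} needs {max(n_prom, n_body)} distinct "
                    f"genes for promoter/gene-body sites but only {self.site_genes} exist"
                )
            n_inter = n - n_prom - n_body
            zone = self.site_chrom_length - self.site_genes * self.site_gene_slot - 51_000
            if n_inter > 0 and (zone <= 0 or zone // n_inter < 2_600):
                raise ValueError("infeasible design: intergenic zone too small for site count")
        if self.site_genes * self.site_gene_slot > self.site_chrom_length:
            raise ValueError("infeasible design: site-gene zone exceeds chromosome")
        n_enh = sum(self.enhancer_state_design.values())
        if n_enh * self.enhancer_slot > self.enhancer_chrom_length:
            raise ValueError("infeasible design: enhancer slots exceed chromosome")
        slot = self.lock_chrom_length // max(1, self.n_planted_locks)
        d2max = _snap(int(self.lock_length_range[1] * self.lock_expansion_factor), self.bin_size)
        if self.n_planted_locks and slot < d2max + 200_000:
            raise ValueError("infeasible design: planted domains do not fit their slots")
        if self.filler_genes and self.filler_chrom_length // self.filler_genes < self.filler_gene_length + 400:
            raise ValueError("infeasible design: filler genes do not fit")


def _snap(x: int, bs: int) -> int:
    return max(bs, int(round(x / bs)) * bs)


def _quantize(fracs: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n items over fractional targets."""
    raw = [f * n for f in fracs]
    base = [math.floor(x) for x in raw]
    total = int(round(sum(raw)))
    rem = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


@dataclass
class TruthTables:
    """Ground truth paired bit-for-bit with the emitted files."""

    config: SimulationConfig
    genome: GenomeModel
    annotation: GeneAnnotation
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, category, lock_id, enhancer_state
    sites: pd.DataFrame  # timepoint, chrom, start, end, combination, element_class
    enhancers: pd.DataFrame  # chrom, start, end, state, ikaros, hdac1, gene_id
    peaks: dict  # (factor, timepoint) -> IntervalSet
    locks: dict  # timepoint -> IntervalSet
    lock_gene_ids: dict  # timepoint -> sorted list of gene ids inside planted domains
    tracks: dict  # timepoint -> SignalTrack
    expression: ExpressionTable

    def site_fractions(self, timepoint: str) -> dict[tuple[str, ...], float]:
        sub = self.sites[self.sites["timepoint"] == timepoint]
        n = len(sub)
        out: dict[tuple[str, ...], float] = {}
        for combo, cnt in sub["combination"].value_counts().items():
            out[tuple(combo.split("|"))] = cnt / n
        return out


def _peak(rng, chrom, center, cfg: SimulationConfig, clen: int) -> GenomicInterval:
    w = int(
        np.clip(
            rng.lognormal(math.log(cfg.peak_width_median), cfg.peak_width_sigma),
            cfg.peak_width_min,
            cfg.peak_width_max,
        )
    )
    c = center + int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
    s = max(0, c - w // 2)
    e = min(clen, s + w)
    return GenomicInterval(chrom, s, e)


def simulate(config: SimulationConfig, out_dir: Optional[str] = None) -> TruthTables:
    """Generate the full planted landscape; write files when ``out_dir`` given."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = config.genome()
    bs = config.bin_size

    # ---- broad domains (chr1) ------------------------------------------------
    lock_slot = config.lock_chrom_length // max(1, config.n_planted_locks)
    d1_locks, d2_locks = [], []
    lock_genes_rows = []
    gid_counter = 0
    for i in range(config.n_planted_locks):
        center = i * lock_slot + lock_slot // 2
        d1_len = _snap(int(rng.integers(*config.lock_length_range)), bs)
        d2_len = _snap(int(d1_len * config.lock_expansion_factor), bs)
        d1_start = _snap(center - d1_len // 2, bs)
        d2_start = _snap(center - d2_len // 2, bs)
        d1_locks.append(GenomicInterval("chr1", d1_start, d1_start + d1_len))
        d2_locks.append(GenomicInterval("chr1", d2_start, d2_start + d2_len))
        sub = d1_len // config.lock_genes_per_domain
        for k in range(config.lock_genes_per_domain):
            glen = int(rng.integers(*config.lock_gene_length_range))
            lo = d1_start + k * sub + 200
            hi = d1_start + (k + 1) * sub - glen - 200
            gstart = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            lock_genes_rows.append(
                (f"LG{gid_counter:05d}", "chr1", gstart, gstart + glen, strand, "lock", i, "")
            )
            gid_counter += 1
    # background genes in the left margin of each slot, clear of the day2 extent
    bg_rows = []
    bgn = config.background_genes // max(1, config.n_planted_locks)
    for i in range(config.n_planted_locks):
        usable_lo = i * lock_slot + 5_000
        usable_hi = d2_locks[i].start - 5_000
        sub = max(1, (usable_hi - usable_lo) // max(1, bgn))
        for k in range(bgn):
            lo = usable_lo + k * sub
            glen = 2_000
            hi = lo + sub - glen - 100
            if hi <= lo:
                continue
            gstart = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            bg_rows.append(
                (f"BG{i:03d}_{k:03d}", "chr1", gstart, gstart + glen, strand, "background", -1, "")
            )

    # ---- enhancers (chr2) ----------------------------------------------------
    states = []
    for st, cnt in config.enhancer_state_design.items():
        states += [st] * cnt
    states = [states[i] for i in rng.permutation(len(states))]
    enh_rows, enh_gene_rows = [], []
    clen2 = config.enhancer_chrom_length
    for i, st in enumerate(states):
        slot = i * config.enhancer_slot
        estart = slot + 1_500 + int(rng.integers(-500, 501))
        ewidth = int(rng.integers(*config.enhancer_width_range))
        design = (
            config.occupancy_design_active if st == "active" else config.occupancy_design_nonactive
        )
        combos = list(design.keys())
        probs = np.array([design[c] for c in combos], dtype=float)
        ik, hd = combos[int(rng.choice(len(combos), p=probs / probs.sum()))]
        gid = f"EG{i:05d}"
        gstart = slot + config.enhancer_gene_offset + int(rng.integers(-500, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        enh_rows.append((("chr2"), estart, estart + ewidth, st, ik, hd, gid))
        enh_gene_rows.append(
            (gid, "chr2", gstart, gstart + config.enhancer_gene_length, strand, "enhancer_target", -1, st)
        )
    enh_df = pd.DataFrame(
        enh_rows, columns=["chrom", "start", "end", "state", "ikaros", "hdac1", "gene_id"]
    )

    # ---- factor co-occupancy sites (chr3) ------------------------------------
    site_gene_rows = []
    for i in range(config.site_genes):
        slot = i * config.site_gene_slot
        gstart = slot + 2_000
        strand = "+" if rng.random() < 0.5 else "-"
        site_gene_rows.append(
            (f"SG{i:05d}", "chr3", gstart, gstart + config.site_gene_length, strand, "site", -1, "")
        )
    site_tss = []
    for gid, chrom, s, e, strand, *_ in site_gene_rows:
        site_tss.append((s if strand == "+" else e, strand))
    inter_zone_lo = config.site_genes * config.site_gene_slot + 50_000
    inter_zone_hi = config.site_chrom_length - 1_000

    sites_rows = []
    site_peaks: dict[tuple[str, str], list[GenomicInterval]] = {}
    clen3 = config.site_chrom_length
    up, down = config.promoter_window
    for tp in config.timepoints:
        n_tp = config.n_sites.get(tp, 0)
        design = config.co_occupancy_design.get(tp, {})
        if n_tp == 0 or not design:
            continue
        combos = list(design.keys())
        counts = _quantize([design[c] for c in combos], n_tp)
        combo_list: list[tuple[str, ...]] = []
        for c, k in zip(combos, counts):
            combo_list += [c] * k
        n_eff = len(combo_list)
        ef = config.element_fractions.get(
            tp, {"promoter": 1 / 3, "gene_body": 1 / 3, "intergenic": 1 / 3}
        )
        ecounts = _quantize(
            [ef.get("promoter", 0.0), ef.get("gene_body", 0.0), ef.get("intergenic", 0.0)],
            n_eff,
        )
        # pad/trim so every site has a class
        while sum(ecounts) < n_eff:
            ecounts[2] += 1
        classes = (
            ["promoter"] * ecounts[0] + ["gene_body"] * ecounts[1] + ["intergenic"] * ecounts[2]
        )[:n_eff]
        combo_list = [combo_list[i] for i in rng.permutation(n_eff)]
        # positions per class
        prom_genes = rng.choice(config.site_genes, size=ecounts[0], replace=False)
        body_genes = rng.choice(config.site_genes, size=min(ecounts[1], config.site_genes), replace=False)
        centers = []
        pi = bi = ii = 0
        n_inter = ecounts[2]
        spacing = max(2_600, (inter_zone_hi - inter_zone_lo) // max(1, n_inter))
        for cls in classes:
            if cls == "promoter":
                tss, strand = site_tss[prom_genes[pi]]
                off = int(rng.integers(-(up - 400), down - 400 + 1))
                centers.append(tss + off if strand == "+" else tss - off)
                pi += 1
            elif cls == "gene_body":
                tss, strand = site_tss[body_genes[bi]]
                off = int(rng.integers(2_300, config.site_gene_length - 800))
                centers.append(tss + off if strand == "+" else tss - off)
                bi += 1
            else:
                centers.append(
                    inter_zone_lo + ii * spacing + spacing // 2 + int(rng.integers(-200, 201))
                )
                ii += 1
        for combo, cls, center in zip(combo_list, classes, centers):
            peaks_here = {}
            for factor in combo:
                iv = _peak(rng, "chr3", center, config, clen3)
                peaks_here[factor] = iv
                site_peaks.setdefault((factor, tp), []).append(iv)
            first = peaks_here[combo[0]]
            sites_rows.append((tp, "chr3", first.start, first.end, "|".join(combo), cls))
    sites_df = pd.DataFrame(
        sites_rows, columns=["timepoint", "chrom", "start", "end", "combination", "element_class"]
    )

    # ---- filler genes (chr4) -------------------------------------------------
    filler_rows = []
    if config.filler_genes:
        fslot = config.filler_chrom_length // config.filler_genes
        for i in range(config.filler_genes):
            lo = i * fslot + 200
            hi = (i + 1) * fslot - config.filler_gene_length - 200
            gstart = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            filler_rows.append(
                (f"FG{i:05d}", "chr4", gstart, gstart + config.filler_gene_length, strand, "filler", -1, "")
            )

    genes_df = pd.DataFrame(
        lock_genes_rows + bg_rows + enh_gene_rows + site_gene_rows + filler_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "category", "lock_id", "enhancer_state"],
    )
    ann = GeneAnnotation(
        genes_df[["gene_id", "chrom", "strand", "start", "end"]].copy(),
        config.promoter_window,
        genome,
    )

    # ---- assemble per-factor peak sets ---------------------------------------
    peaks: dict[tuple[str, str], IntervalSet] = {}
    for tp in config.timepoints:
        for factor in FACTORS:
            ivals = list(site_peaks.get((factor, tp), []))
            for chrom, es, ee, st, ik, hd, _gid in enh_rows:
                if factor == "H3K4me1":
                    ivals.append(GenomicInterval(chrom, es, ee))
                elif tp == "day0":
                    continue  # IKAROS-null state: no planted marks/occupancy at enhancers
                elif factor == "H3K27ac" and st in ("active", "intermediate"):
                    ivals.append(_mark_peak(rng, chrom, es, ee, clen2))
                elif factor == "H3K27me3" and st in ("intermediate", "poised"):
                    ivals.append(_mark_peak(rng, chrom, es, ee, clen2))
                elif factor == "IKAROS" and ik:
                    ivals.append(_mark_peak(rng, chrom, es, ee, clen2))
                elif factor == "HDAC1" and hd:
                    ivals.append(_mark_peak(rng, chrom, es, ee, clen2))
            peaks[(factor, tp)] = IntervalSet(ivals, genome)

    # ---- H3K27me3 signal tracks ----------------------------------------------
    locks = {
        tp: IntervalSet(
            [] if tp == "day0" else (d1_locks if tp == "day1" else d2_locks), genome
        )
        for tp in config.timepoints
    }
    tracks = {}
    for tp in config.timepoints:
        track = SignalTrack.zeros(genome, bs)
        for chrom in genome.chrom_names:
            n = track.n_bins(chrom)
            if config.noise_sd > 0:
                vals = np.maximum(
                    0.0, rng.normal(config.signal_baseline, config.noise_sd, size=n)
                )
            else:
                vals = np.full(n, config.signal_baseline)
            track.values[chrom] = vals
        for dom in locks[tp]:
            b0, b1 = dom.start // bs, dom.end // bs
            track.values[dom.chrom][b0:b1] += config.plateau_height
        tracks[tp] = track

    # ---- expression -----------------------------------------------------------
    base = rng.lognormal(math.log(config.tpm_median), config.tpm_sigma, size=len(genes_df))
    occ_eff = config.occupancy_expression_effect
    state_eff = config.state_expression_effect
    mult = np.ones(len(genes_df))
    cats = genes_df["category"].to_numpy()
    enh_lookup = {gid: (st, ik, hd) for _chrom, _es, _ee, st, ik, hd, gid in enh_rows}
    for idx, (gid, cat) in enumerate(zip(genes_df["gene_id"], cats)):
        if cat == "lock":
            mult[idx] = config.repression_effect
        elif cat == "enhancer_target":
            st, ik, hd = enh_lookup[gid]
            m = state_eff[st]
            if st == "active":
                m *= occ_eff[(bool(ik), bool(hd))]
            mult[idx] = m
    cols = {}
    for tp in config.timepoints:
        eff = np.ones(len(genes_df)) if tp == "day0" else mult
        if config.expr_jitter_sigma > 0 and config.noise_sd > 0:
            jitter = np.exp(rng.normal(0.0, config.expr_jitter_sigma, size=len(genes_df)))
        else:
            jitter = 1.0
        cols[tp] = base * eff * jitter
    expr = ExpressionTable(pd.DataFrame(cols, index=pd.Index(genes_df["gene_id"], name="gene_id")))

    lock_gene_ids = {
        tp: (sorted(genes_df.loc[genes_df["category"] == "lock", "gene_id"]) if tp != "day0" else [])
        for tp in config.timepoints
    }

    truth = TruthTables(
        config=config,
        genome=genome,
        annotation=ann,
        genes=genes_df,
        sites=sites_df,
        enhancers=enh_df,
        peaks=peaks,
        locks=locks,
        lock_gene_ids=lock_gene_ids,
        tracks=tracks,
        expression=expr,
    )
    if out_dir is not None:
        _write_outputs(truth, out_dir)
    return truth


def _mark_peak(rng, chrom, start, end, clen) -> GenomicInterval:
    """A mark/factor peak jittered around an enhancer but still covering it."""
    s = int(start) + int(rng.integers(-50, 51))
    e = int(end) + int(rng.integers(-50, 51))
    return GenomicInterval(chrom, max(0, s), min(clen, max(s + 200, e)))


def _write_outputs(truth: TruthTables, out_dir: str) -> None:
    cfg = truth.config
    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "peaks"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "signal"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "truth"), exist_ok=True)
    truth.genome.to_tsv(os.path.join(out_dir, "genome.tsv"))
    write_gtf_genes(truth.annotation, os.path.join(out_dir, "genes.gtf"))
    truth.expression.to_tsv(os.path.join(out_dir, "expression.tsv"))
    for (factor, tp), ivset in truth.peaks.items():
        write_bed(ivset, os.path.join(out_dir, "peaks", f"{factor}_{tp}.bed"))
    for tp, track in truth.tracks.items():
        write_bedgraph(track, os.path.join(out_dir, "signal", f"H3K27me3_{tp}.bedgraph"))
    truth.sites.to_csv(os.path.join(out_dir, "truth", "sites.tsv"), sep="\t", index=False)
    truth.enhancers.to_csv(os.path.join(out_dir, "truth", "enhancers.tsv"), sep="\t", index=False)
    truth.genes.to_csv(os.path.join(out_dir, "truth", "genes.tsv"), sep="\t", index=False)
    lock_rows = []
    for tp, ivset in truth.locks.items():
        for iv in ivset:
            lock_rows.append((tp, iv.chrom, iv.start, iv.end))
    pd.DataFrame(lock_rows, columns=["timepoint", "chrom", "start", "end"]).to_csv(
        os.path.join(out_dir, "truth", "locks.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "config.tsv"), "w") as fh:
        for key, val in sorted(vars(cfg).items()):
            fh.write(f"{key}\t{val!r}\n")


# ---------------------------------------------------------------------------
# switch scenario
# ---------------------------------------------------------------------------


@dataclass
class SwitchScenario:
    """Planted epigenetic-switch truth plus the emitted peak sets."""

    config: SimulationConfig
    genome: GenomeModel
    planted_fraction: float
    realized_fraction: float
    n_candidates: int
    n_switched: int
    peaks: dict  # (factor, timepoint) -> IntervalSet


def make_switch_scenario(
    config: SimulationConfig, out_dir: Optional[str] = None
) -> SwitchScenario:
    """Plant EZH2-only day-0 loci of which a configured fraction gain
    IKAROS+HDAC1+H3K27me3 at day 1.

    Noise-free mode (``noise_sd == 0``) switches exactly
    ``round(fraction * n)`` loci; otherwise each candidate switches
    independently with probability ``fraction`` (binomial realization).
    """
    rng = np.random.default_rng(config.seed)
    n_cand = config.switch_n_candidates
    n_pre = config.switch_n_premarked
    n_extra = config.switch_n_denovo
    spacing = config.switch_locus_spacing
    n_loci = n_cand + n_pre + n_extra
    clen = n_loci * spacing + 10_000
    genome = GenomeModel([("chrS", clen)])
    roles = ["candidate"] * n_cand + ["premarked"] * n_pre + ["denovo"] * n_extra
    roles = [roles[i] for i in rng.permutation(n_loci)]
    centers = [i * spacing + spacing // 2 for i in range(n_loci)]
    if config.noise_sd == 0:
        k = int(round(config.switch_fraction * n_cand))
        cand_idx = [i for i, r in enumerate(roles) if r == "candidate"]
        chosen = set(
            np.array(cand_idx)[rng.permutation(n_cand)[:k]].tolist() if k else []
        )
        switched = {i: (i in chosen) for i in cand_idx}
    else:
        switched = {
            i: bool(rng.random() < config.switch_fraction)
            for i, r in enumerate(roles)
            if r == "candidate"
        }
    peaks: dict[tuple[str, str], list[GenomicInterval]] = {
        ("EZH2", "day0"): [], ("H3K27me3", "day0"): [],
        ("IKAROS", "day1"): [], ("HDAC1", "day1"): [], ("H3K27me3", "day1"): [],
    }
    n_sw = sum(switched.values())
    # exact count of switched loci co-occupied by IKAROS+HDAC1 in noise-free mode
    sw_indices = [i for i, s in switched.items() if s]
    if config.noise_sd == 0:
        k_ikhd = int(round(config.switch_ikhd_fraction * n_sw))
        ikhd = set(np.array(sw_indices)[rng.permutation(n_sw)[:k_ikhd]].tolist() if n_sw else [])
    else:
        ikhd = {i for i in sw_indices if rng.random() < config.switch_ikhd_fraction}
    for i, (role, center) in enumerate(zip(roles, centers)):
        if role in ("candidate", "premarked"):
            peaks[("EZH2", "day0")].append(_peak(rng, "chrS", center, config, clen))
        if role == "premarked":
            peaks[("H3K27me3", "day0")].append(_peak(rng, "chrS", center, config, clen))
            peaks[("H3K27me3", "day1")].append(_peak(rng, "chrS", center, config, clen))
        if role == "denovo":
            peaks[("H3K27me3", "day1")].append(_peak(rng, "chrS", center, config, clen))
        if role == "candidate" and switched[i]:
            peaks[("H3K27me3", "day1")].append(_peak(rng, "chrS", center, config, clen))
            if i in ikhd:
                peaks[("IKAROS", "day1")].append(_peak(rng, "chrS", center, config, clen))
                peaks[("HDAC1", "day1")].append(_peak(rng, "chrS", center, config, clen))
    ivsets = {key: IntervalSet(ivs, genome) for key, ivs in peaks.items()}
    if out_dir is not None:
        os.makedirs(os.path.join(out_dir, "peaks"), exist_ok=True)
        genome.to_tsv(os.path.join(out_dir, "genome.tsv"))
        for (factor, tp), ivset in ivsets.items():
            write_bed(ivset, os.path.join(out_dir, "peaks", f"{factor}_{tp}.bed"))
    return SwitchScenario(
        config=config,
        genome=genome,
        planted_fraction=config.switch_fraction,
        realized_fraction=(n_sw / n_cand if n_cand else float("nan")),
        n_candidates=n_cand,
        n_switched=n_sw,
        peaks=ivsets,
    )


# ---------------------------------------------------------------------------
# wildtype-vs-knockout scenario
# ---------------------------------------------------------------------------


def make_knockout_scenario(
    config: SimulationConfig, out_dir: Optional[str] = None
) -> tuple[TruthTables, TruthTables]:
    """Two single-condition landscapes: wildtype (the default day-1 design)
    and an IKAROS-knockout with depleted H3K27me3/HDAC1 occupancy, a reduced
    promoter fraction, and fewer planted broad domains."""
    wt_cfg = replace(config, timepoints=("day1",))
    ko_design = {
        "day1": {
            ("EZH2",): 0.55,
            ("HDAC1",): 0.25,
            ("EZH2", "HDAC1"): 0.10,
            ("HDAC1", "H3K27me3"): 0.05,
            ("H3K27me3",): 0.05,
        }
    }
    ko_cfg = replace(
        config,
        seed=config.seed + 1,
        timepoints=("day1",),
        n_sites={"day1": max(1, int(config.n_sites.get("day1", 1000) * 0.6))},
        co_occupancy_design=ko_design,
        element_fractions={"day1": {"promoter": 0.15, "gene_body": 0.35, "intergenic": 0.50}},
        n_planted_locks=max(1, config.n_planted_locks // 4),
        occupancy_design_active={(False, False): 1.0},
        occupancy_design_nonactive={(False, False): 1.0},
    )
    wt = simulate(wt_cfg, os.path.join(out_dir, "wt") if out_dir else None)
    ko = simulate(ko_cfg, os.path.join(out_dir, "ko") if out_dir else None)
    return wt, ko
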