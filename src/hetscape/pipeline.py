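"""End-to-end orchestration: run every analysis stage over a generated (or
user-supplied) data directory and emit one consolidated summary table, plus
the two-condition (e.g. wildtype vs knockout) comparison mode.

A run directory follows the generator layout::

    genome.tsv              chrom <TAB> length
    genes.gtf
    expression.tsv          gene_id <TAB> <condition>...
    peaks/<FACTOR>_<tp>.bed
    signal/H3K27me3_<tp>.bedgraph

Every number in the summary is re-derivable by calling the corresponding
module operation directly; the pipeline adds no logic of its own.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import pandas as pd

from . import domains as dom
from . import enhancers as enh
from . import occupancy as occ
from . import repression as rep
from .genome_io import (
    GenomeModel,
    IntervalSet,
    read_bed,
    read_bedgraph,
    read_expression,
    read_gtf_genes,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "compare_conditions"]

log = logging.getLogger("hetscape")

_PEAK_RE = re.compile(r"^(?P<factor>[A-Za-z0-9]+)_(?P<tp>[A-Za-z0-9]+)\.bed$")
_SIGNAL_RE = re.compile(r"^H3K27me3_(?P<tp>[A-Za-z0-9]+)\.bedgraph$")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and per-stage parameters for one pipeline run."""

    run_dir: str
    out_dir: str
    seed: int = 0
    promoter_window: tuple[int, int] = (2000, 500)
    min_overlap_bp: int = 1
    enhancer_merge_gap: int = 1000
    enhancer_max_distance: int = 100_000
    lock_params: dom.DomainParams = field(default_factory=lambda: dom.LOCK_DEFAULTS)
    bgrd_gene_cover_fraction: float = 0.8
    lock_gene_fraction: float = 0.5
    n_resamples: int = 1000

    def validate_paths(self) -> None:
        for sub in ("genome.tsv", "genes.gtf", "expression.tsv", "peaks"):
            p = os.path.join(self.run_dir, sub)
            if not os.path.exists(p):
                raise PipelineError("config", f"missing required input: {p}")


def _discover(run_dir: str):
    peaks: dict[tuple[str, str], str] = {}
    for fname in sorted(os.listdir(os.path.join(run_dir, "peaks"))):
        m = _PEAK_RE.match(fname)
        if m:
            peaks[(m["factor"], m["tp"])] = os.path.join(run_dir, "peaks", fname)
    signals: dict[str, str] = {}
    sig_dir = os.path.join(run_dir, "signal")
    if os.path.isdir(sig_dir):
        for fname in sorted(os.listdir(sig_dir)):
            m = _SIGNAL_RE.match(fname)
            if m:
                signals[m["tp"]] = os.path.join(sig_dir, fname)
    tps = sorted({tp for _, tp in peaks} | set(signals))
    return peaks, signals, tps


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute occupancy -> enhancers -> domains -> repression over every
    timepoint found in the run directory; returns and writes the summary."""
    config.validate_paths()
    os.makedirs(config.out_dir, exist_ok=True)
    _setup_logging(config.out_dir)
    log.info("run_dir=%s seed=%d", config.run_dir, config.seed)

    genome = GenomeModel.from_tsv(os.path.join(config.run_dir, "genome.tsv"))
    ann = read_gtf_genes(
        os.path.join(config.run_dir, "genes.gtf"), genome, config.promoter_window
    )
    expr = read_expression(os.path.join(config.run_dir, "expression.tsv"))
    peak_paths, signal_paths, tps = _discover(config.run_dir)
    peaks: dict[tuple[str, str], IntervalSet] = {}
    for key, path in peak_paths.items():
        peaks[key] = read_bed(path, genome)

    rows: list[tuple[str, str, float]] = []
    lock_cache: dict[str, tuple] = {}

    def add(metric: str, tp: str, value) -> None:
        rows.append((metric, tp, float(value)))

    for tp in tps:
        stage = f"occupancy:{tp}"
        try:
            for factor in ("IKAROS", "EZH2", "HDAC1", "H3K27me3", "H3K4me1", "H3K27ac"):
                if (factor, tp) in peaks:
                    add(f"n_peaks_{factor}", tp, len(peaks[(factor, tp)]))
            me3 = peaks.get(("H3K27me3", tp))
            if me3 is not None and len(me3):
                _, fr = occ.classify_elements(me3, ann)
                for cls, f in fr.items():
                    add(f"h3k27me3_frac_{cls}", tp, f)
                for factor in ("IKAROS", "HDAC1", "EZH2"):
                    if (factor, tp) in peaks:
                        di = occ.direct_indirect(
                            me3, peaks[(factor, tp)], min_overlap_bp=config.min_overlap_bp
                        )
                        add(f"h3k27me3_frac_direct_{factor}", tp, di.frac_direct or 0.0)
            hd = peaks.get(("HDAC1", tp))
            if hd is not None and len(hd):
                _, fr = occ.classify_elements(hd, ann)
                for cls, f in fr.items():
                    add(f"hdac1_frac_{cls}", tp, f)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"enhancers:{tp}"
        try:
            if (("H3K4me1", tp) in peaks) and len(peaks[("H3K4me1", tp)]):
                records = enh.make_records(
                    peaks[("H3K4me1", tp)],
                    peaks.get(("H3K27ac", tp), IntervalSet([], genome)),
                    peaks.get(("H3K27me3", tp), IntervalSet([], genome)),
                    peaks.get(("IKAROS", tp)),
                    peaks.get(("HDAC1", tp)),
                    ann,
                    merge_gap=config.enhancer_merge_gap,
                    max_distance_bp=config.enhancer_max_distance,
                    min_overlap_bp=config.min_overlap_bp,
                )
                for state in enh.ENHANCER_STATES:
                    add(
                        f"enhancer_n_{state}", tp,
                        sum(1 for r in records if r.state == state),
                    )
                _write_enhancer_bed(records, os.path.join(config.out_dir, f"enhancers_{tp}.bed"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"domains:{tp}"
        try:
            if tp in signal_paths:
                track = read_bedgraph(
                    signal_paths[tp], genome, config.lock_params.bin_size
                )
                locks = dom.call_locks(track, config.lock_params)
                st = dom.domain_stats(locks, genome)
                add("lock_n", tp, st["n_domains"])
                add("lock_coverage_bp", tp, st["coverage_bp"])
                add("lock_coverage_fraction", tp, st["coverage_fraction"])
                lock_genes = dom.genes_in_domains(locks, ann, config.lock_gene_fraction)
                add("lock_n_genes", tp, len(lock_genes))
                lock_cache[tp] = (locks, lock_genes)

                stage = f"repression:{tp}"
                if lock_genes and tp in expr.conditions:
                    report = rep.repression_test(
                        lock_genes,
                        expr,
                        condition=tp,
                        n_resamples=config.n_resamples,
                        seed=config.seed,
                        set_name=f"lock_genes_{tp}",
                    )
                    add("lock_gene_log2_effect", tp, report.effect)
                    add("lock_gene_empirical_p", tp, report.empirical_p)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # cross-timepoint analyses
    try:
        if (
            ("EZH2", "day0") in peaks
            and ("H3K27me3", "day1") in peaks
        ):
            sw = occ.switch_analysis(
                peaks[("EZH2", "day0")],
                peaks.get(("H3K27me3", "day0"), IntervalSet([], genome)),
                peaks.get(("IKAROS", "day1"), IntervalSet([], genome)),
                peaks.get(("HDAC1", "day1"), IntervalSet([], genome)),
                peaks[("H3K27me3", "day1")],
                min_overlap_bp=config.min_overlap_bp,
            )
            add("switch_n_candidates", "day0-day1", sw.n_candidates)
            if sw.switch_fraction is not None:
                add("switch_fraction", "day0-day1", sw.switch_fraction)
            if sw.frac_switched_ikaros_hdac1 is not None:
                add("switch_frac_ikaros_hdac1", "day0-day1", sw.frac_switched_ikaros_hdac1)
        if ("H3K27me3", "day1") in peaks and ("H3K27me3", "day2") in peaks:
            di = occ.direct_indirect(
                peaks[("H3K27me3", "day2")],
                peaks.get(("IKAROS", "day2"), IntervalSet([], genome)),
                reference_mark_peaks=peaks[("H3K27me3", "day1")],
                min_overlap_bp=config.min_overlap_bp,
            )
            if di.fold_change_vs_reference is not None:
                add("h3k27me3_fold_day2_vs_day1", "day1-day2", di.fold_change_vs_reference)
        if "day1" in lock_cache and "day2" in lock_cache:
            exp_rep = dom.expansion(lock_cache["day1"][0], lock_cache["day2"][0])
            if exp_rep.median_length_ratio is not None:
                add("lock_expansion_median_ratio", "day1-day2", exp_rep.median_length_ratio)
            add("lock_expansion_n_new", "day1-day2", exp_rep.n_new)
            add("lock_expansion_n_lost", "day1-day2", exp_rep.n_lost)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cross-timepoint", str(exc)) from exc

    summary = pd.DataFrame(rows, columns=["metric", "timepoint", "value"])
    _write_summary(summary, os.path.join(config.out_dir, "summary.tsv"))
    log.info("wrote %d metrics", len(summary))
    return summary



def _write_summary(summary: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\ttimepoint\tvalue\n")
        for _, row in summary.iterrows():
            fh.write(f"{row['metric']}\t{row['timepoint']}\t{row['value']:.6g}\n")


def _write_enhancer_bed(records, path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\t"
                f"{int(r.ikaros)}\t{int(r.hdac1)}\t{r.gene_id or '.'}\t"
                f"{r.distance if r.distance is not None else '.'}\n"
            )


def _setup_logging(out_dir: str) -> None:
    # one run.log per output directory; drop handlers from previous runs
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(os.path.join(out_dir, "run.log"))
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)


def compare_conditions(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, names: tuple[str, str] = ("a", "b")
) -> pd.DataFrame:
    """Per-metric deltas between two completed runs (e.g. wildtype vs
    knockout). A metric present in only one run is flagged, not dropped."""
    a = summary_a.set_index(["metric", "timepoint"])["value"]
    b = summary_b.set_index(["metric", "timepoint"])["value"]
    keys = sorted(set(a.index) | set(b.index))
    rows = []
    for key in keys:
        va = a.get(key)
        vb = b.get(key)
        rows.append(
            {
                "metric": key[0],
                "timepoint": key[1],
                f"value_{names[0]}": va,
                f"value_{names[1]}": vb,
                "delta": (vb - va) if va is not None and vb is not None else None,
                "note": "" if va is not None and vb is not None else "missing in one run",
            }
        )
    return pd.DataFrame(rows)
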