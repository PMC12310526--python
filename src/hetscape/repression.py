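"""Resampling test for transcriptional repression of a gene set.

The observed summary is the median expression of the query set (LOCK genes,
BGRD genes, enhancer-linked genes, ...). The null is the distribution of
medians of equally sized gene sets drawn uniformly without replacement from
all expressed genes ("random genes"). The empirical p-value is one-sided in
the repression direction with the add-one rule, so it is never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import ExpressionTable

__all__ = ["RepressionReport", "repression_test"]


@dataclass
class RepressionReport:
    """Result of one resampling repression test.

    effect = log2(observed_median / mean(null medians)); negative means the
    query set is expressed below random gene sets of the same size.
    """

    set_name: str
    condition: str
    n_genes: int
    n_missing: int
    observed_median: float
    null_medians: np.ndarray
    effect: float
    empirical_p: float
    alternative: str
    seed: int

    @property
    def null_median_mean(self) -> float:
        return float(self.null_medians.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_name": self.set_name,
                    "condition": self.condition,
                    "n_genes": self.n_genes,
                    "n_missing": self.n_missing,
                    "observed_median": self.observed_median,
                    "null_median_mean": self.null_median_mean,
                    "log2_effect": self.effect,
                    "empirical_p": self.empirical_p,
                    "alternative": self.alternative,
                    "n_resamples": len(self.null_medians),
                    "seed": self.seed,
                }
            ]
        )


def repression_test(
    gene_set: Sequence[str],
    expr: ExpressionTable,
    condition: Optional[str] = None,
    n_resamples: int = 1000,
    seed: int = 0,
    set_name: str = "gene_set",
    alternative: str = "less",
) -> RepressionReport:
    """Compare median expression of ``gene_set`` to size-matched random gene sets.

    The universe is every gene with nonzero expression in at least one
    condition. Genes absent from the table are dropped with a warning and the
    dropped count is reported. ``alternative='less'`` (default) tests for
    repression; ``'two-sided'`` doubles the smaller tail.
    Deterministic for a fixed seed.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    if alternative not in ("less", "two-sided"):
        raise ValueError("alternative must be 'less' or 'two-sided'")
    condition = condition or expr.conditions[0]
    universe = expr.expressed_genes()
    present = [g for g in gene_set if g in expr.gene_ids]
    n_missing = len(gene_set) - len(present)
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) missing from the expression table; dropped",
            stacklevel=2,
        )
    n = len(present)
    if n == 0:
        raise ValueError("no query genes present in the expression table")
    if n > len(universe):
        raise ValueError(
            f"gene set ({n}) larger than the expressed-gene universe ({len(universe)})"
        )
    observed = float(np.median(expr.values_for(present, condition)))
    pool = expr.data.loc[universe, condition].to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        draw = rng.choice(len(pool), size=n, replace=False)
        null[i] = np.median(pool[draw])
    p_less = (1 + int(np.sum(null <= observed))) / (1 + n_resamples)
    if alternative == "less":
        p = p_less
    else:
        p_greater = (1 + int(np.sum(null >= observed))) / (1 + n_resamples)
        p = min(1.0, 2 * min(p_less, p_greater))
    effect = float(np.log2(observed / null.mean())) if null.mean() > 0 and observed > 0 else float("-inf")
    return RepressionReport(
        set_name=set_name,
        condition=condition,
        n_genes=n,
        n_missing=n_missing,
        observed_median=observed,
        null_medians=null,
        effect=effect,
        empirical_p=p,
        alternative=alternative,
        seed=seed,
    )
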