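"""Deletion-strain validation of predicted conditional regulation.

A predicted conditional regulon is tested by contrasting expression of the
selected genes between two defined samples (e.g. 1 vs 160 minutes after
paraquat addition for an activator; high vs low OD600 for a repressor) in the
deletion strain versus the parental control.  Per replicate, the statistic is
the median per-gene delta over the regulon; replicate medians are compared
between strains with an unpaired one-sided Wilcoxon rank-sum test (exact for
small samples, where the minimum attainable one-sided p for triplicates is
exactly 1/C(6,3) = 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import exact_rank_sum_p
from .genome_binding import target_overlap, OverlapResult

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
REPRESSION = "repression"


@dataclass(frozen=True)
class ContrastDesign:
    """One strain's two-sample contrast (sample_a minus sample_b)."""

    strain: str
    reference_strain: str
    sample_a: str  # array id of the minuend (e.g. 1 min, or the larger OD)
    sample_b: str
    direction: str  # activation | repression

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("sample_a and sample_b must differ")
        if self.direction not in (ACTIVATION, REPRESSION):
            raise ValueError(f"unknown direction {self.direction!r}")


def relative_change(expr: pd.DataFrame, gene_set, design: ContrastDesign
                    ) -> pd.Series:
    """Per-gene delta (log2 units): expr[sample_a] - expr[sample_b].

    Genes missing either sample are dropped and logged.
    """
    for col in (design.sample_a, design.sample_b):
        if col not in expr.columns:
            raise KeyError(f"array {col!r} absent from expression table")
    genes = [g for g in sorted(set(gene_set)) if g in expr.index]
    absent = sorted(set(gene_set) - set(genes))
    if absent:
        logger.warning("%d gene(s) absent from expression table, dropped",
                       len(absent))
    delta = expr.loc[genes, design.sample_a] - expr.loc[genes, design.sample_b]
    n_missing = int(delta.isna().sum())
    if n_missing:
        logger.warning("%d gene(s) with missing values dropped from contrast",
                       n_missing)
    return delta.dropna()


def strain_effect_test(deltas_mutant, deltas_control,
                       alternative: str = "less",
                       exact_max_total: int = 16) -> float:
    """Unpaired one-sided Wilcoxon rank-sum p-value (mutant vs control).

    Exact-conditional enumeration (midranks under ties) for small samples;
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(deltas_mutant, dtype=float)
    y = np.asarray(deltas_control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= exact_max_total:
        return exact_rank_sum_p(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def replicate_medians(expr: pd.DataFrame, gene_set,
                      design_table: pd.DataFrame) -> pd.DataFrame:
    """Median per-gene delta per (strain, replicate).

    ``design_table`` columns: strain, replicate, sample_label in {a, b},
    array_id.  Returns a frame with columns strain, replicate, median_delta.
    """
    rows = []
    for (strain, rep), grp in design_table.groupby(["strain", "replicate"]):
        labels = dict(zip(grp["sample_label"], grp["array_id"]))
        if set(labels) != {"a", "b"}:
            raise ValueError(f"strain {strain} replicate {rep}: need exactly "
                             "one 'a' and one 'b' sample")
        design = ContrastDesign(str(strain), "", labels["a"], labels["b"],
                                ACTIVATION)
        delta = relative_change(expr, gene_set, design)
        rows.append((strain, rep, float(delta.median())))
    return pd.DataFrame(rows, columns=["strain", "replicate", "median_delta"])


def validate_regulon(expr: pd.DataFrame, gene_set, design_table: pd.DataFrame,
                     mutant: str, control: str, role: str) -> float:
    """End-to-end contrast test for one predicted regulon.

    Activators: the deletion strain should show *less* activation than the
    control (one-sided 'less'); repressors: *less* repression, i.e. a higher
    late-minus-early delta in the mutant (one-sided 'greater').
    """
    meds = replicate_medians(expr, gene_set, design_table)
    xm = meds.loc[meds["strain"] == mutant, "median_delta"].values
    xc = meds.loc[meds["strain"] == control, "median_delta"].values
    alternative = "less" if role == "activator" else "greater"
    return strain_effect_test(xm, xc, alternative)


def regulon_overlap_test(selected_a, selected_b, universe) -> OverlapResult:
    """Hypergeometric overlap of two conditional regulons (delegates)."""
    return target_overlap(set(selected_a), set(selected_b), universe)
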