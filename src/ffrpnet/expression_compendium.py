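"""The expression compendium: a genes x arrays log2-ratio matrix grouped into
condition sets, plus TF-TF co-expression.

All expression values are log2 ratios versus a common reference; every array
belongs to exactly one named condition set (a group of arrays sharing a
growth/perturbation condition).  Correlations are Spearman, pairwise-complete
over missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._stats import spearman_pair

logger = logging.getLogger(__name__)


@dataclass
class ExpressionCompendium:
    """Log2-ratio matrix (genes x arrays) with an array -> condition-set manifest.

    Genes and arrays are kept in sorted order internally so downstream results
    are invariant to input row/column order.
    """

    matrix: pd.DataFrame
    manifest: pd.Series  # array_id -> condition_set_id
    _sets: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        missing = [a for a in self.matrix.columns if a not in self.manifest.index]
        if missing:
            raise ValueError(f"arrays missing from manifest: {missing}")
        self.matrix = self.matrix.sort_index(axis=0).sort_index(axis=1)
        self.manifest = self.manifest.loc[list(self.matrix.columns)]
        sets: dict[str, list[str]] = {}
        for arr, cs in self.manifest.items():
            sets.setdefault(str(cs), []).append(str(arr))
        small = [cs for cs, arrs in sets.items() if len(arrs) < 2]
        if small:
            raise ValueError(f"condition sets with fewer than 2 arrays: {sorted(small)}")
        self._sets = {cs: sorted(arrs) for cs, arrs in sets.items()}

    @property
    def condition_sets(self) -> dict[str, list[str]]:
        return dict(self._sets)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.matrix.columns)

    def set_arrays(self, condition_set: str) -> list[str]:
        return list(self._sets[condition_set])

    def missing_rate_per_gene(self) -> pd.Series:
        return self.matrix.isna().mean(axis=1)


def load_compendium(matrix_path, manifest_path) -> ExpressionCompendium:
    """Load matrix TSV (rows = genes, header = array ids) and manifest TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index.name = None
    manifest_df = pd.read_csv(manifest_path, sep="\t")
    manifest = pd.Series(
        manifest_df["condition_set_id"].astype(str).values,
        index=manifest_df["array_id"].astype(str),
    )
    comp = ExpressionCompendium(matrix, manifest)
    rate = comp.missing_rate_per_gene()
    logger.info("loaded compendium: %d genes x %d arrays, %.2f%% missing",
                len(comp.genes), len(comp.arrays), 100 * rate.mean())
    return comp


def write_compendium(comp: ExpressionCompendium, matrix_path, manifest_path) -> None:
    comp.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    pd.DataFrame({
        "array_id": comp.manifest.index,
        "condition_set_id": comp.manifest.values,
    }).to_csv(manifest_path, sep="\t", index=False)


def ffrp_coexpression(comp: ExpressionCompendium, tfs: list[str],
                      min_arrays: int = 10, rho_cutoff: float = 0.5,
                      p_cutoff: float = 0.05,
                      condition_set: str | None = None) -> pd.DataFrame:
    """Pairwise Spearman co-expression edges between TFs.

    Computed across all arrays pooled by default, or within one
    ``condition_set``.  An edge is significant when rho >= ``rho_cutoff``
    (signed) and p <= ``p_cutoff``.  Pairs with fewer than ``min_arrays``
    complete observations yield no edge and are logged.
    """
    for tf in tfs:
        if tf not in comp.matrix.index:
            raise KeyError(f"TF {tf!r} absent from expression matrix")
    cols = comp.set_arrays(condition_set) if condition_set is not None \
        else comp.arrays
    tfs = sorted(tfs)
    rows = []
    for i, a in enumerate(tfs):
        xa = comp.matrix.loc[a, cols].values
        for b in tfs[i + 1:]:
            xb = comp.matrix.loc[b, cols].values
            rho, p, n = spearman_pair(xa, xb)
            if n < min_arrays:
                logger.warning("coexpression %s-%s skipped: only %d complete pairs",
                               a, b, n)
                continue
            sig = bool(rho >= rho_cutoff and p <= p_cutoff)
            rows.append((a, b, rho, p, n, sig))
    return pd.DataFrame(
        rows, columns=["tf_a", "tf_b", "rho", "pvalue", "n", "significant"])
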