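"""Growth-curve parameter extraction and strain comparison.

From each OD600 time series (plate-reader sampling every 30 minutes over four
days) three parameters are extracted: the maximum specific growth rate mu_max
(the largest least-squares slope of ln OD over a sliding window, the standard
microbiological definition), the time at which it occurs (centre of the
earliest maximising window), and the area under the curve (trapezoidal
integral of OD over the full observed window).  Strains are compared per
parameter by an unpaired two-sided Student's t-test over biological
replicates, Bonferroni-corrected across strains, and the per-strain evidence
is combined across the three parameters by Stouffer's Z-score method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from ._stats import stouffer_combine

logger = logging.getLogger(__name__)

GROWTH_COLUMNS = ["strain", "bio_rep", "tech_rep", "time_h", "od600"]
PARAMETERS = ["mu_max", "t_mu_max", "auc"]


@dataclass(frozen=True)
class GrowthParams:
    mu_max: float    # 1/h
    t_mu_max: float  # h
    auc: float       # OD * h


def collapse_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Pointwise mean of technical replicates within (strain, bio_rep)."""
    out = []
    for (strain, bio), grp in records.groupby(["strain", "bio_rep"]):
        pivot = grp.pivot_table(index="time_h", columns="tech_rep",
                                values="od600", aggfunc="first")
        if pivot.isna().any().any():
            raise ValueError(
                f"strain {strain} bio_rep {bio}: technical replicates do not "
                "share the time grid; interpolation refused")
        mean = pivot.mean(axis=1)
        out.append(pd.DataFrame({
            "strain": strain, "bio_rep": bio,
            "time_h": mean.index.values, "od600": mean.values}))
    return pd.concat(out, ignore_index=True)


def growth_parameters(times, od, window: int = 5,
                      rate_on: str = "log") -> GrowthParams:
    """Extract (mu_max, t_mu_max, auc) from one curve.

    mu_max is the maximum over sliding windows of the least-squares slope of
    ln(OD) against time (or raw OD with ``rate_on='linear'``); t_mu_max is
    the centre time of the earliest maximising window; auc is the trapezoidal
    integral of OD over the observed time range.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size != y.size:
        raise ValueError("times and od must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("OD values must be positive")
    if window < 2 or window > t.size:
        raise ValueError("window must satisfy 2 <= window <= n points")

    signal = np.log(y) if rate_on == "log" else y
    tw = sliding_window_view(t, window)
    sw = sliding_window_view(signal, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    sc = sw - sw.mean(axis=1, keepdims=True)
    slopes = (tc * sc).sum(axis=1) / (tc**2).sum(axis=1)
    top = float(slopes.max())
    # earliest maximising window wins ties (up to floating-point noise)
    tol = 1e-9 * max(1.0, abs(top))
    best = int(np.nonzero(slopes >= top - tol)[0][0])
    mu_max = top
    t_mu_max = float(tw[best].mean())
    auc = float(np.trapezoid(y, t))
    return GrowthParams(mu_max, t_mu_max, auc)


def strain_growth_table(records: pd.DataFrame, window: int = 5,
                        rate_on: str = "log") -> pd.DataFrame:
    """Per-(strain, bio_rep) growth parameters after technical collapse."""
    collapsed = collapse_technical(records)
    rows = []
    for (strain, bio), grp in collapsed.groupby(["strain", "bio_rep"]):
        grp = grp.sort_values("time_h")
        p = growth_parameters(grp["time_h"].values, grp["od600"].values,
                              window, rate_on)
        rows.append((strain, bio, p.mu_max, p.t_mu_max, p.auc))
    return pd.DataFrame(rows, columns=["strain", "bio_rep"] + PARAMETERS)


def _ttest(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 biological replicates per strain")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def compare_strains(params_a: pd.DataFrame, params_b: pd.DataFrame,
                    n_comparisons: int = 8) -> dict:
    """Compare two strains' replicate growth parameters.

    Returns per-parameter two-sided t-test p-values, their Bonferroni
    correction (factor = number of strains compared, capped at 1), and the
    Stouffer combination of the corrected values across the three parameters.
    """
    raw: dict[str, float] = {}
    bonf: dict[str, float] = {}
    for param in PARAMETERS:
        a = params_a[param].values.astype(float)
        b = params_b[param].values.astype(float)
        if np.isnan(a).all() or np.isnan(b).all():
            logger.warning("parameter %s all-NaN; excluded", param)
            raw[param] = math.nan
            bonf[param] = math.nan
            continue
        p = _ttest(a, b)
        raw[param] = p
        bonf[param] = min(1.0, p * n_comparisons)
    combined = stouffer_combine([v for v in bonf.values() if not math.isnan(v)])
    return {"pvalues": raw, "bonferroni": bonf, "combined": combined}


def comparison_table(records: pd.DataFrame, control: str, window: int = 5,
                     n_comparisons: int | None = None) -> pd.DataFrame:
    """Per-strain comparison against the control strain.

    One row per non-control strain with the three Bonferroni-corrected
    per-parameter p-values and the Stouffer-combined p, mirroring the layout
    of a growth-phenotype summary table.
    """
    table = strain_growth_table(records, window)
    strains = sorted(s for s in table["strain"].unique() if s != control)
    if control not in set(table["strain"]):
        raise KeyError(f"control strain {control!r} not in records")
    if n_comparisons is None:
        n_comparisons = len(strains)
    ctrl = table[table["strain"] == control]
    rows = []
    for strain in strains:
        res = compare_strains(table[table["strain"] == strain], ctrl,
                              n_comparisons)
        rows.append((strain,
                     res["bonferroni"]["mu_max"],
                     res["bonferroni"]["t_mu_max"],
                     res["bonferroni"]["auc"],
                     res["combined"]))
    return pd.DataFrame(rows, columns=[
        "strain", "mu_max_p", "t_mu_max_p", "auc_p", "combined_p"])


def read_growth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth CSV missing columns: {missing}")
    if (df["od600"] <= 0).any():
        raise ValueError("OD600 values must be positive")
    return df
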