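"""Conditional-regulon discovery: where and how a TF's binding targets respond.

For each (TF, condition set) pair the procedure is:

1. keep only condition sets where the TF itself moves by at least a 1.75-fold
   change (max - min of its log2 ratios across the set's arrays);
2. correlate the TF's within-set expression profile with each of its binding
   targets (Spearman by default, pairwise-complete);
3. summarise with the median correlation; a positive median proposes an
   activator role, a negative one a repressor role;
4. compare the observed median against medians of randomly sampled gene sets
   of the same size (default 100,000 permutations, sampled without
   replacement from all genes excluding the TF), in both tails;
5. correct all (TF, set, tail) p-values jointly by Benjamini-Hochberg;
6. require in addition that the per-array dispersion (variance across the
   TF's targets) is coupled to the TF's profile (same permutation machinery,
   BH-corrected alongside);
7. for called pairs, select the conditionally regulated genes: targets whose
   correlation is strictly beyond the median (above it for activators, below
   it for repressors).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import (
    bh_adjust,
    pearson_rows_vs_vector,
    spearman_rows_vs_vector,
)
from .expression_compendium import ExpressionCompendium

logger = logging.getLogger(__name__)

ACTIVATOR = "activator"
REPRESSOR = "repressor"


@dataclass
class PermutationSpec:
    """Permutation-null settings for the median-correlation test."""

    n_perm: int = 100_000
    seed: int = 0
    dispersion_n_perm: int | None = None  # defaults to min(n_perm, 2000)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.dispersion_n_perm is None:
            self.dispersion_n_perm = self.n_perm


@dataclass
class ConditionSetResult:
    """All statistics computed for one (TF, condition set) pair."""

    tf: str
    condition_set: str
    fold_change: float  # max - min of the TF (log2) across the set's arrays
    per_gene_r: pd.Series  # target gene -> correlation with the TF
    median_r: float
    role: str | None  # proposed by the sign of median_r
    permuted_p: float  # in the proposed role's tail
    p_upper: float
    p_lower: float
    bh_q: float  # BH q of the proposed tail (across all tf x set x tail)
    dispersion_stat: float
    dispersion_p: float
    dispersion_q: float
    dispersion_pass: bool
    called: bool
    selected_genes: frozenset[str] = field(default_factory=frozenset)
    n_arrays: int = 0


def filter_condition_sets(comp: ExpressionCompendium, tf: str,
                          min_fold: float = 1.75) -> list[str]:
    """Condition sets where the TF's log2 range >= log2(min_fold)."""
    if tf not in comp.matrix.index:
        raise KeyError(f"TF {tf!r} absent from expression matrix")
    threshold = math.log2(min_fold)
    passing = []
    for cs in sorted(comp.condition_sets):
        vals = comp.matrix.loc[tf, comp.set_arrays(cs)].values.astype(float)
        finite = vals[~np.isnan(vals)]
        if finite.size == 0:
            logger.warning("set %s: TF %s all-missing, excluded", cs, tf)
            continue
        if finite.max() - finite.min() >= threshold:
            passing.append(cs)
    return passing


def _set_submatrix(comp: ExpressionCompendium, condition_set: str):
    arrays = comp.set_arrays(condition_set)
    return comp.matrix[arrays]


def _row_correlations(x: np.ndarray, tf_values: np.ndarray,
                      method: str) -> np.ndarray:
    if method == "spearman":
        return spearman_rows_vs_vector(x, tf_values)
    if method == "pearson":
        return pearson_rows_vs_vector(x, tf_values)
    raise ValueError(f"unknown correlation method {method!r}")


def per_gene_correlations(comp: ExpressionCompendium, tf: str, targets,
                          condition_set: str, method: str = "spearman",
                          min_arrays: int = 6) -> pd.Series:
    """Correlation of each target with the TF across the set's arrays."""
    sub = _set_submatrix(comp, condition_set)
    if tf not in sub.index:
        raise KeyError(f"TF {tf!r} absent from expression matrix")
    tf_values = sub.loc[tf].values.astype(float)
    if (~np.isnan(tf_values)).sum() < min_arrays:
        raise ValueError(
            f"set {condition_set}: fewer than {min_arrays} arrays with "
            f"non-missing values for TF {tf}")
    present = [g for g in sorted(set(targets)) if g in sub.index]
    skipped = sorted(set(targets) - set(present))
    if skipped:
        logger.warning("set %s, TF %s: %d target(s) absent from matrix, skipped",
                       condition_set, tf, len(skipped))
    r = _row_correlations(sub.loc[present].values.astype(float), tf_values, method)
    return pd.Series(r, index=present, name=f"{tf}:{condition_set}")


def median_statistic(per_gene_r) -> float:
    """Median of the per-target correlations; NaN entries are ignored."""
    r = np.asarray(per_gene_r, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no finite correlations to take the median of")
    return float(np.median(r))


def _universe_correlations(comp: ExpressionCompendium, tf: str,
                           condition_set: str, method: str) -> pd.Series:
    """Per-gene correlation with the TF for every gene except the TF itself."""
    sub = _set_submatrix(comp, condition_set)
    genes = [g for g in sub.index if g != tf]
    tf_values = sub.loc[tf].values.astype(float)
    r = _row_correlations(sub.loc[genes].values.astype(float), tf_values, method)
    return pd.Series(r, index=genes)


def _draw_subsets(rng: np.random.Generator, n_items: int, size: int,
                  n_perm: int, chunk: int = 4000):
    """Yield index matrices of random ``size``-subsets of range(n_items)."""
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, n_items), dtype=np.float32)
        yield np.argpartition(u, size - 1, axis=1)[:, :size]
        done += m


try:  # fast Floyd-sampling kernel; the numpy path below is the reference
    from numba import njit

    @njit(cache=False)
    def _floyd_subset_medians(values, size, n_perm, seed):  # pragma: no cover
        np.random.seed(seed)
        n = values.shape[0]
        out = np.empty(n_perm)
        flags = np.zeros(n, np.uint8)
        chosen = np.empty(size, np.int64)
        buf = np.empty(size)
        for p in range(n_perm):
            cnt = 0
            for j in range(n - size, n):
                r = np.random.randint(0, j + 1)
                if flags[r] == 1:
                    r = j
                flags[r] = 1
                chosen[cnt] = r
                cnt += 1
            for i in range(size):
                buf[i] = values[chosen[i]]
            out[p] = np.median(buf)
            for i in range(size):
                flags[chosen[i]] = 0
        return out

    @njit(cache=False)
    def _dispersion_null_kernel(pool, tf_vals, size, n_perm, seed,
                                use_variance):  # pragma: no cover
        """|Spearman| of the per-column variance (or median) of random row
        subsets against ``tf_vals``; NaN-aware; ties in the continuous
        statistic have measure zero so plain ordinal ranks are used."""
        np.random.seed(seed)
        n, m = pool.shape
        out = np.empty(n_perm)
        flags = np.zeros(n, np.uint8)
        chosen = np.empty(size, np.int64)
        series = np.empty(m)
        buf = np.empty(size)
        for p in range(n_perm):
            cnt = 0
            for j in range(n - size, n):
                r = np.random.randint(0, j + 1)
                if flags[r] == 1:
                    r = j
                flags[r] = 1
                chosen[cnt] = r
                cnt += 1
            for c in range(m):
                if use_variance:
                    s1 = 0.0
                    s2 = 0.0
                    k = 0
                    for i in range(size):
                        v = pool[chosen[i], c]
                        if not np.isnan(v):
                            s1 += v
                            s2 += v * v
                            k += 1
                    if k >= 2:
                        series[c] = (s2 - s1 * s1 / k) / (k - 1)
                    else:
                        series[c] = np.nan
                else:
                    k = 0
                    for i in range(size):
                        v = pool[chosen[i], c]
                        if not np.isnan(v):
                            buf[k] = v
                            k += 1
                    series[c] = np.median(buf[:k]) if k > 0 else np.nan
            # pairwise-complete Spearman of series vs tf_vals
            nv = 0
            for c in range(m):
                if not (np.isnan(series[c]) or np.isnan(tf_vals[c])):
                    nv += 1
            if nv < 3:
                out[p] = np.nan
                for i in range(size):
                    flags[chosen[i]] = 0
                continue
            xs = np.empty(nv)
            ys = np.empty(nv)
            k = 0
            for c in range(m):
                if not (np.isnan(series[c]) or np.isnan(tf_vals[c])):
                    xs[k] = series[c]
                    ys[k] = tf_vals[c]
                    k += 1
            rx = np.empty(nv)
            ry = np.empty(nv)
            ox = np.argsort(xs)
            oy = np.argsort(ys)
            for i in range(nv):
                rx[ox[i]] = i + 1.0
                ry[oy[i]] = i + 1.0
            mx = rx.mean()
            my = ry.mean()
            num = 0.0
            dx = 0.0
            dy = 0.0
            for i in range(nv):
                num += (rx[i] - mx) * (ry[i] - my)
                dx += (rx[i] - mx) ** 2
                dy += (ry[i] - my) ** 2
            if dx == 0.0 or dy == 0.0:
                out[p] = np.nan
            else:
                out[p] = abs(num / np.sqrt(dx * dy))
            for i in range(size):
                flags[chosen[i]] = 0
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _null_medians(gene_r: np.ndarray, size: int, n_perm: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Medians of random gene subsets (without replacement) of ``gene_r``."""
    finite = np.ascontiguousarray(gene_r[~np.isnan(gene_r)], dtype=float)
    if size > finite.size:
        raise ValueError("set_size exceeds the usable universe")
    if _HAVE_NUMBA:
        seed = int(rng.integers(0, 2**31 - 1))
        return _floyd_subset_medians(finite, size, n_perm, seed)
    out = np.empty(n_perm)
    pos = 0
    for idx in _draw_subsets(rng, finite.size, size, n_perm):
        out[pos:pos + idx.shape[0]] = np.median(finite[idx], axis=1)
        pos += idx.shape[0]
    return out


def permutation_pvalue(comp: ExpressionCompendium, tf: str, set_size: int,
                       condition_set: str, observed_median: float,
                       tail: str, spec: PermutationSpec,
                       method: str = "spearman") -> float:
    """Monte-Carlo p for the observed median against random gene sets.

    p = (1 + #{null as-or-more-extreme in ``tail``}) / (n_perm + 1); the
    per-gene correlation vector is computed once, so each draw reduces to a
    median of sampled entries.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    gene_r = _universe_correlations(comp, tf, condition_set, method).values
    rng = np.random.default_rng(spec.seed)
    null = _null_medians(gene_r, set_size, spec.n_perm, rng)
    return _tail_p(null, observed_median, tail, spec.n_perm)


def _tail_p(null: np.ndarray, observed: float, tail: str, n_perm: int) -> float:
    if tail == "upper":
        extreme = int((null >= observed).sum())
    elif tail == "lower":
        extreme = int((null <= observed).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + extreme) / (n_perm + 1)


def dispersion_coupling_filter(comp: ExpressionCompendium, tf: str, targets,
                               condition_set: str, spec: PermutationSpec,
                               method: str = "per_array_variance",
                               null: str = "correlation",
                               rng: np.random.Generator | None = None,
                               ) -> tuple[float, float]:
    """Test whether target dispersion (or the median profile) tracks the TF.

    ``per_array_variance``: the statistic is |Spearman correlation| between
    the per-array variance across target genes and the TF's profile.
    ``median_profile``: the statistic is |Spearman correlation| between the
    per-array median across target genes and the TF's profile.

    ``null='correlation'`` (default) takes the correlation test's own
    two-sided p-value ("significantly correlated" read literally);
    ``null='permutation'`` redraws random gene sets of the same size, which
    is conservative when the compendium carries genuine regulon signal
    (random sets then contain regulated genes and the rank-based statistic
    saturates).  Returns (statistic, p); statistic NaN means the filter
    fails closed.
    """
    sub = _set_submatrix(comp, condition_set)
    arrays_ok = ~np.isnan(sub.loc[tf].values.astype(float))
    if int(arrays_ok.sum()) < 3:
        raise ValueError("fewer than 3 arrays with TF values; filter skipped")
    tf_values = sub.loc[tf].values.astype(float)[arrays_ok]
    present = [g for g in sorted(set(targets)) if g in sub.index]
    X = sub.loc[present].values.astype(float)[:, arrays_ok]

    def statistic(mat: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            if method == "per_array_variance":
                series = np.nanvar(mat, axis=-2, ddof=1)
            elif method == "median_profile":
                series = np.nanmedian(mat, axis=-2)
            else:
                raise ValueError(f"unknown dispersion method {method!r}")
        if series.ndim == 1:
            series = series[None, :]
        r = spearman_rows_vs_vector(series, tf_values)
        return np.abs(r)

    obs = float(statistic(X)[0])
    if np.isnan(obs):
        logger.warning("set %s, TF %s: degenerate dispersion series; "
                       "filter fails closed", condition_set, tf)
        return np.nan, np.nan

    if null == "correlation":
        with np.errstate(invalid="ignore", divide="ignore"):
            if method == "per_array_variance":
                series = np.nanvar(X, axis=0, ddof=1)
            else:
                series = np.nanmedian(X, axis=0)
        from ._stats import spearman_pair
        _, p, _ = spearman_pair(series, tf_values)
        if np.isnan(p):
            return np.nan, np.nan
        return obs, max(float(p), 1e-300)
    if null != "permutation":
        raise ValueError(f"unknown dispersion null {null!r}")

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pool = sub.loc[[g for g in sub.index if g != tf]].values.astype(float)[:, arrays_ok]
    n_perm = spec.dispersion_n_perm
    if _HAVE_NUMBA:
        seed = int(rng.integers(0, 2**31 - 1))
        null = _dispersion_null_kernel(
            np.ascontiguousarray(pool), np.ascontiguousarray(tf_values),
            len(present), n_perm, seed, method == "per_array_variance")
        exceed = int(np.nansum(null >= obs))
    else:
        exceed = 0
        for idx in _draw_subsets(rng, pool.shape[0], len(present), n_perm,
                                 chunk=500):
            null = statistic(pool[idx])
            exceed += int(np.nansum(null >= obs))
    p = (1 + exceed) / (n_perm + 1)
    return obs, p


def select_conditional_genes(per_gene_r: pd.Series, role: str) -> frozenset[str]:
    """Targets strictly beyond the median correlation for the given role."""
    med = median_statistic(per_gene_r)
    if role == ACTIVATOR:
        sel = per_gene_r[per_gene_r > med]
    elif role == REPRESSOR:
        sel = per_gene_r[per_gene_r < med]
    else:
        raise ValueError(f"unknown role {role!r}")
    return frozenset(sel.index)


def call_regulons(comp: ExpressionCompendium, target_maps, spec: PermutationSpec,
                  min_fold: float = 1.75, min_abs_r: float = 0.4,
                  alpha: float = 0.05, method: str = "spearman",
                  min_arrays: int = 6,
                  dispersion_method: str = "per_array_variance",
                  dispersion_null: str = "correlation",
                  dispersion_alpha: float = 0.05,
                  bh_family: str = "global") -> list[ConditionSetResult]:
    """Run the full conditional-regulon procedure for every TF and condition set.

    ``target_maps`` maps TF id -> target gene collection (or TargetMap).
    Returns one ConditionSetResult per tested (TF, set) pair; ``called`` marks
    pairs passing bh_q <= alpha, |median_r| >= min_abs_r and the dispersion
    filter.  Results are deterministic given the spec's seed and invariant to
    the input row/column order of the matrix.
    """
    tfs = sorted(target_maps)
    pairs: list[tuple[str, str, pd.Series, float, int]] = []
    for tf in tfs:
        targets = target_maps[tf]
        targets = getattr(targets, "targets", targets)
        if len(targets) == 0:
            continue
        for cs in filter_condition_sets(comp, tf, min_fold):
            tf_vals = comp.matrix.loc[tf, comp.set_arrays(cs)].values.astype(float)
            n_ok = int((~np.isnan(tf_vals)).sum())
            if n_ok < min_arrays:
                logger.warning("TF %s set %s: only %d arrays, excluded", tf, cs, n_ok)
                continue
            finite = tf_vals[~np.isnan(tf_vals)]
            fold = float(finite.max() - finite.min())
            r = per_gene_correlations(comp, tf, targets, cs, method, min_arrays)
            if r.dropna().empty:
                logger.warning("TF %s set %s: no finite target correlations", tf, cs)
                continue
            pairs.append((tf, cs, r, fold, n_ok))

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(pairs))

    records = []
    for (tf, cs, r, fold, n_ok), child in zip(pairs, children):
        rng = np.random.default_rng(child)
        med = median_statistic(r)
        gene_r = _universe_correlations(comp, tf, cs, method).values
        size = int(r.dropna().size)
        null = _null_medians(gene_r, size, spec.n_perm, rng)
        p_up = _tail_p(null, med, "upper", spec.n_perm)
        p_lo = _tail_p(null, med, "lower", spec.n_perm)
        try:
            disp_stat, disp_p = dispersion_coupling_filter(
                comp, tf, r.index, cs, spec, dispersion_method,
                null=dispersion_null, rng=rng)
        except ValueError:
            disp_stat, disp_p = np.nan, 1.0  # too few arrays: skipped, flagged
            logger.warning("TF %s set %s: dispersion filter skipped", tf, cs)
        records.append({
            "tf": tf, "cs": cs, "r": r, "fold": fold, "n_ok": n_ok,
            "median": med, "p_upper": p_up, "p_lower": p_lo,
            "disp_stat": disp_stat, "disp_p": disp_p,
        })

    # BH across all tf x set x tail tests jointly (or per TF)
    def families(recs):
        if bh_family == "global":
            yield recs
        elif bh_family == "per_tf":
            for tf in sorted({r["tf"] for r in recs}):
                yield [r for r in recs if r["tf"] == tf]
        else:
            raise ValueError(f"unknown bh_family {bh_family!r}")

    for fam in families(records):
        ps = [r["p_upper"] for r in fam] + [r["p_lower"] for r in fam]
        qs = bh_adjust(ps)
        for i, rec in enumerate(fam):
            rec["q_upper"] = qs[i]
            rec["q_lower"] = qs[len(fam) + i]
        disp_idx = [i for i, r in enumerate(fam) if not np.isnan(r["disp_p"])]
        if disp_idx:
            dq = bh_adjust([fam[i]["disp_p"] for i in disp_idx])
            for i, q in zip(disp_idx, dq):
                fam[i]["disp_q"] = q
        for rec in fam:
            rec.setdefault("disp_q", np.nan)

    results = []
    for rec in records:
        med = rec["median"]
        role = ACTIVATOR if med > 0 else REPRESSOR if med < 0 else None
        if role == ACTIVATOR:
            p_role, q_role = rec["p_upper"], rec["q_upper"]
        elif role == REPRESSOR:
            p_role, q_role = rec["p_lower"], rec["q_lower"]
        else:
            p_role, q_role = 1.0, 1.0
        disp_pass = (not np.isnan(rec["disp_q"])) and rec["disp_q"] <= dispersion_alpha
        called = (role is not None and q_role <= alpha
                  and abs(med) >= min_abs_r and disp_pass)
        selected = select_conditional_genes(rec["r"].dropna(), role) \
            if called else frozenset()
        results.append(ConditionSetResult(
            tf=rec["tf"], condition_set=rec["cs"], fold_change=rec["fold"],
            per_gene_r=rec["r"], median_r=med, role=role,
            permuted_p=p_role, p_upper=rec["p_upper"], p_lower=rec["p_lower"],
            bh_q=q_role, dispersion_stat=rec["disp_stat"],
            dispersion_p=rec["disp_p"], dispersion_q=rec["disp_q"],
            dispersion_pass=disp_pass, called=called,
            selected_genes=selected, n_arrays=rec["n_ok"]))
    logger.info("call_regulons: %d pairs tested, %d called",
                len(results), sum(r.called for r in results))
    return results


def results_to_frame(results: list[ConditionSetResult]) -> pd.DataFrame:
    """Summary table mirroring the results TSV contract."""
    rows = [(r.tf, r.condition_set, r.role, r.fold_change, r.median_r,
             r.permuted_p, r.bh_q, r.dispersion_p, r.called,
             len(r.selected_genes)) for r in results]
    return pd.DataFrame(rows, columns=[
        "tf", "condition_set", "role", "fold_change", "median_r",
        "permuted_p", "bh_q", "dispersion_p", "called", "n_selected"])
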