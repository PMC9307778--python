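"""Copy-number expression-QTL scan with a column-permutation empirical FDR.

Each (window, gene) pair is tested by ordinary least squares of expression
on copy number across patients (two-sided t on the slope, n - 2 degrees of
freedom, pairwise deletion of missing entries).  The null is induced by
randomly permuting the patient-column assignment of the expression matrix
(the copy-number matrix is untouched) and rerunning the scan; the empirical
FDR is the median null significant count over the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LabelledMatrix, ValidationError

logger = logging.getLogger("semap.cnveqtl")

DEFAULT_P_THRESHOLD = 1e-3
P_FLOOR = 1e-300  # numeric floor for exact fits


@dataclass
class NullSummary:
    """Significant-count stream across expression-column permutations."""

    counts: np.ndarray
    n_perm: int
    seed: int

    @property
    def median_count(self) -> float:
        return float(np.median(self.counts))


def filter_expression(expr: LabelledMatrix, max_bad: int = 100) -> LabelledMatrix:
    """Drop genes with more than ``max_bad`` missing-or-zero entries.

    The boundary is strict: a gene with exactly ``max_bad`` bad entries is
    kept ("over 100" semantics).
    """
    vals = expr.values
    bad = np.isnan(vals) | (vals == 0)
    n_bad = bad.sum(axis=1)
    keep = n_bad <= max_bad
    if not keep.any():
        raise ValidationError("filter_expression removed every gene")
    out = LabelledMatrix(expr.df.loc[keep])
    logger.info("filter_expression: %d of %d gene(s) kept (max_bad=%d)",
                len(out.df), len(expr.df), max_bad)
    return out


def linear_association(cn_values: np.ndarray,
                       expr_values: np.ndarray) -> tuple[float, float, float]:
    """OLS of expression on copy number for one (window, gene) pair.

    Returns (slope, t, two-sided p).  Missing entries are dropped pairwise;
    needs >= 3 paired observations and non-constant copy number (constant
    copy number raises, mirroring the scan's skip-with-flag behaviour).
    Exact fits report p at a numeric floor rather than zero.
    """
    x = np.asarray(cn_values, dtype=float)
    y = np.asarray(expr_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValidationError("need >= 3 paired non-missing observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValidationError("zero variance in copy number")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    resid = y - (y.mean() + beta * (x - x.mean()))
    rss = np.sum(resid**2)
    if rss == 0:
        return float(beta), np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0), \
            (P_FLOOR if beta != 0 else 1.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(beta), float(t), max(float(p), P_FLOOR)


def _scan_stats(cn_vals: np.ndarray, expr_vals: np.ndarray):
    """Vectorized OLS slope/t/p for all windows x genes with pairwise deletion.

    cn_vals: (W, P); expr_vals: (G, P) with NaN missing.  Returns arrays of
    shape (W, G): beta, t, p, and a validity mask.
    """
    W, P = cn_vals.shape
    G = expr_vals.shape[0]
    e_ok = ~np.isnan(expr_vals)
    e0 = np.where(e_ok, expr_vals, 0.0)
    beta = np.full((W, G), np.nan)
    tstat = np.full((W, G), np.nan)
    pval = np.full((W, G), np.nan)
    valid = np.zeros((W, G), dtype=bool)
    for w in range(W):
        x = cn_vals[w]
        x_ok = ~np.isnan(x)
        m = e_ok & x_ok  # (G, P)
        x0 = np.where(x_ok, x, 0.0)
        n = m.sum(axis=1).astype(float)
        sx = m @ x0
        sxx = m @ (x0 * x0)
        sy = (e0 * m).sum(axis=1)
        syy = (e0 * e0 * m).sum(axis=1)
        sxy = (e0 * m) @ x0
        with np.errstate(invalid="ignore", divide="ignore"):
            den = n * sxx - sx * sx
            b = (n * sxy - sx * sy) / den
            ssr = syy - sy * sy / n - b * b * den / n
            ssr = np.maximum(ssr, 0.0)
            se2 = ssr / (n - 2) / (den / n)
            t = b / np.sqrt(se2)
        ok = (n >= 3) & (den > 0)
        p = np.full(G, np.nan)
        finite_t = ok & np.isfinite(t)
        p[finite_t] = 2.0 * stats.t.sf(np.abs(t[finite_t]), n[finite_t] - 2)
        exact = ok & ~np.isfinite(t)
        p[exact] = P_FLOOR
        p = np.maximum(p, P_FLOOR)
        beta[w], tstat[w], pval[w], valid[w] = b, t, p, ok
    return beta, tstat, pval, valid


def scan(cn: LabelledMatrix, expr: LabelledMatrix,
         p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Test every (window, gene) pair; return records with p < threshold.

    Patient columns of ``cn`` and ``expr`` must match exactly (order is
    aligned internally).  Output columns: window, gene, beta, t, p; sorted
    ascending by p.
    """
    if set(cn.col_ids) != set(expr.col_ids):
        raise ValidationError("patient columns differ between copy-number and "
                              "expression matrices")
    expr_df = expr.df[cn.col_ids]
    beta, tstat, pval, valid = _scan_stats(cn.values, expr_df.to_numpy())
    sig = valid & (pval < p_threshold)
    wi, gi = np.nonzero(sig)
    out = pd.DataFrame(
        {
            "window": np.asarray(cn.row_ids)[wi],
            "gene": np.asarray(expr.row_ids)[gi],
            "beta": beta[sig],
            "t": tstat[sig],
            "p": pval[sig],
        }
    ).sort_values("p", kind="mergesort").reset_index(drop=True)
    logger.info("scan: %d significant pair(s) of %d test(s) at p < %g",
                len(out), int(valid.sum()), p_threshold)
    return out


def _significant_count(cn_vals, expr_vals, p_threshold) -> int:
    _, _, pval, valid = _scan_stats(cn_vals, expr_vals)
    return int((valid & (pval < p_threshold)).sum())


def permutation_null(cn: LabelledMatrix, expr: LabelledMatrix,
                     p_threshold: float = DEFAULT_P_THRESHOLD,
                     n_perm: int = 1000, seed: int = 0,
                     identity_first: bool = False) -> NullSummary:
    """Column-permutation null for the CNVeQTL scan.

    Each permutation shuffles which patient column of the expression matrix
    is paired with each copy-number column, reruns the scan, and records the
    significant count.  ``identity_first`` forces the first permutation to
    be the identity (testing hook: its count equals the unpermuted count).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    expr_df = expr.df[cn.col_ids]
    cn_vals = cn.values
    evals = expr_df.to_numpy()
    rng = np.random.default_rng(seed)
    P = evals.shape[1]
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        if i == 0 and identity_first:
            perm = np.arange(P)
        else:
            perm = rng.permutation(P)
        counts[i] = _significant_count(cn_vals, evals[:, perm], p_threshold)
    summary = NullSummary(counts=counts, n_perm=n_perm, seed=seed)
    logger.info("permutation_null: median significant count %.1f over %d "
                "permutation(s)", summary.median_count, n_perm)
    return summary


def empirical_fdr(observed_count: float, null_median: float) -> float:
    """Median null count over observed count, capped at 1.

    Defined as 1.0 when there are no discoveries.
    """
    if observed_count < 0 or null_median < 0:
        raise ValueError("counts must be nonnegative")
    if observed_count == 0:
        return 1.0
    return min(null_median / observed_count, 1.0)
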