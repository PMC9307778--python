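"""Hi-C contact normalization and direct-target classification.

A symmetric binned contact matrix is balanced with the Knight-Ruiz
algorithm so all unmasked row sums equal 1, expected contact is estimated
per bin distance, and each super-enhancer/gene pair is summarized by its
observed/expected (O/E) contact.  Downregulated genes are classified as
direct targets when their O/E exceeds the 75th percentile of a pooled
control distribution built from 100 permutations of distance-matched
non-significant genes on the same chromosome (the analysis is
intra-chromosomal by construction).  A modified Activity-by-Contact score
(z-standardized log2 activity times z-standardized log2 contact) ranks
putative targets per super-enhancer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ContactMatrix, DETable, ValidationError

logger = logging.getLogger("semap.hic_targets")

DEFAULT_PERCENTILE = 75.0
DEFAULT_N_PERM = 100
DEFAULT_K_NEAR = 10
DEFAULT_PADJ = 0.0005
ABC_RESOLUTION = 50_000  # bp; contact resolution for the ABC score


@dataclass
class TargetCall:
    """One SE-gene link with its contact evidence."""

    se_id: str
    gene: str
    distance: int  # bp between SE midpoint and gene TSS
    oe: float
    classification: str  # "direct" | "indirect"


@dataclass
class AbcRecord:
    se_id: str
    gene: str
    activity: float
    contact: float
    score: float


class ConvergenceError(RuntimeError):
    """Balancing failed to reach tolerance; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------


def _kr_newton(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Knight-Ruiz inner-outer Newton iteration for diag(x) A diag(x) e = e.

    Returns the positive scaling vector, or None if the iteration stalls
    (caller falls back to a damped Sinkhorn fixed point).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    mvp = 0
    while rout > rt:
        k = 0
        y = e.copy()
        inner_tol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > inner_tol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                return None
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k + mvp > max_iter:
                return None
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += k + 1
        if mvp > max_iter:
            return None
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def _sinkhorn_polish(A: np.ndarray, x: np.ndarray, tol: float,
                     max_iter: int) -> tuple[np.ndarray, float]:
    """Damped symmetric Sinkhorn fixed point x <- sqrt(x / (A x))."""
    resid = np.inf
    for _ in range(max_iter):
        v = x * (A @ x)
        resid = float(np.abs(v - 1.0).max())
        if resid < tol:
            break
        with np.errstate(divide="ignore"):
            x = np.sqrt(x / (A @ x))
    return x, resid


def kr_balance(m: ContactMatrix, tol: float = 1e-6,
               max_iter: int = 3000) -> ContactMatrix:
    """Balance a symmetric contact matrix so unmasked row sums equal 1.

    All-zero bins are masked out first.  The primary solver is the
    Knight-Ruiz Newton iteration; when it stalls, a damped Sinkhorn fixed
    point finishes (logged).  The returned matrix carries the balancing
    vector; masked bins keep zero rows/columns.
    """
    A = m.matrix
    row_sums = A.sum(axis=1)
    mask = row_sums == 0
    if mask.all():
        raise ValidationError("fully zero contact matrix cannot be balanced")
    keep = ~mask
    sub = A[np.ix_(keep, keep)]
    x = _kr_newton(sub, tol, max_iter)
    if x is None:
        logger.warning("kr_balance: KR stalled; finishing with Sinkhorn fallback")
        x = np.ones(sub.shape[0])
    x, resid = _sinkhorn_polish(sub, x, tol, max_iter)
    if resid >= tol:
        raise ConvergenceError(
            f"balancing did not converge (residual {resid:.3g} >= tol {tol:g})",
            resid)
    balanced = np.zeros_like(A)
    balanced[np.ix_(keep, keep)] = sub * np.outer(x, x)
    bal_vec = np.full(A.shape[0], np.nan)
    bal_vec[keep] = x
    out = ContactMatrix(chrom=m.chrom, binsize=m.binsize, matrix=balanced,
                        bin_starts=m.bin_starts, mask=mask, balanced=True,
                        balancing=bal_vec)
    check = balanced[keep].sum(axis=1)
    assert np.abs(check - 1.0).max() < tol
    logger.info("kr_balance: %d bin(s) balanced, %d masked, residual %.3g",
                int(keep.sum()), int(mask.sum()), resid)
    return out


# ---------------------------------------------------------------------------
# Observed / expected
# ---------------------------------------------------------------------------


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean balanced contact per bin distance over unmasked pairs.

    Returns an array indexed by distance (0..n_bins-1); NaN where no
    unmasked pair exists at that distance.
    """
    if not m.balanced:
        raise ValidationError("expected_by_distance requires a balanced matrix")
    n = m.n_bins
    keep = ~m.mask
    expected = np.full(n, np.nan)
    idx = np.arange(n)
    for d in range(n):
        i = idx[: n - d]
        j = i + d
        ok = keep[i] & keep[j]
        if ok.any():
            expected[d] = m.matrix[i[ok], j[ok]].mean()
    return expected


def se_gene_oe(m: ContactMatrix, expected: np.ndarray, se_start: int,
               se_end: int, tss: int) -> float:
    """Observed/expected contact between the SE midpoint bin and the TSS bin.

    NaN (flagged) when either bin is masked; the d = 0 stratum is used when
    SE and TSS share a bin (logged as self-bin).
    """
    se_bin = m.bin_of((se_start + se_end) // 2)
    tss_bin = m.bin_of(tss)
    if m.mask[se_bin] or m.mask[tss_bin]:
        logger.warning("se_gene_oe: masked bin; O/E undefined")
        return float("nan")
    d = abs(se_bin - tss_bin)
    if d == 0:
        logger.debug("se_gene_oe: SE and TSS share a bin (self-bin stratum)")
    exp = expected[d]
    if not np.isfinite(exp) or exp == 0:
        return float("nan")
    return float(m.matrix[se_bin, tss_bin] / exp)


# ---------------------------------------------------------------------------
# Distance-matched permutation null and classification
# ---------------------------------------------------------------------------


def distance_matched_null(m: ContactMatrix, expected: np.ndarray,
                          se_start: int, se_end: int,
                          target_tss: dict[str, int],
                          pool_tss: dict[str, int],
                          n_perm: int = DEFAULT_N_PERM,
                          k_near: int = DEFAULT_K_NEAR,
                          seed: int = 0) -> np.ndarray:
    """Pooled control O/E distribution from distance-matched permutations.

    For each permutation and each target at SE-TSS distance d, one control
    gene is drawn uniformly from the ``k_near`` pool genes closest to d
    (without replacement within a permutation) and its O/E with the SE is
    recorded; all permutations are pooled into one distribution.
    """
    if len(pool_tss) < len(target_tss):
        raise ValidationError("control pool smaller than target set")
    se_mid = (se_start + se_end) // 2
    pool_ids = list(pool_tss)
    pool_dist = np.array([abs(pool_tss[g] - se_mid) for g in pool_ids])
    target_dist = [abs(t - se_mid) for t in target_tss.values()]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        used = np.zeros(len(pool_ids), dtype=bool)
        for d in target_dist:
            free = np.nonzero(~used)[0]
            order = free[np.argsort(np.abs(pool_dist[free] - d), kind="stable")]
            candidates = order[: min(k_near, len(order))]
            pick = int(rng.choice(candidates))
            used[pick] = True
            g = pool_ids[pick]
            out.append(se_gene_oe(m, expected, se_start, se_end, pool_tss[g]))
    return np.asarray(out, dtype=float)


def classify_targets(target_oe: dict[str, float], control: np.ndarray,
                     se_id: str, target_distance: dict[str, int],
                     percentile: float = DEFAULT_PERCENTILE) -> list[TargetCall]:
    """Direct iff O/E strictly exceeds the control percentile.

    The threshold uses linear interpolation between closest ranks; the
    boundary is strict ("greater than").
    """
    control = np.asarray(control, dtype=float)
    control = control[np.isfinite(control)]
    if len(control) == 0:
        raise ValidationError("control distribution is empty")
    threshold = float(np.percentile(control, percentile))
    calls = []
    for gene, oe in target_oe.items():
        cls = "direct" if np.isfinite(oe) and oe > threshold else "indirect"
        calls.append(TargetCall(se_id=se_id, gene=gene,
                                distance=int(target_distance.get(gene, -1)),
                                oe=float(oe), classification=cls))
    n_direct = sum(c.classification == "direct" for c in calls)
    logger.info("classify_targets: %d direct / %d total at threshold %.4g "
                "(%gth percentile)", n_direct, len(calls), threshold, percentile)
    return calls


def run_target_analysis(m: ContactMatrix, se_start: int, se_end: int,
                        se_id: str, de: DETable, tss: dict[str, int],
                        padj_max: float = DEFAULT_PADJ,
                        lfc_max: float | None = None,
                        n_perm: int = DEFAULT_N_PERM,
                        k_near: int = DEFAULT_K_NEAR,
                        percentile: float = DEFAULT_PERCENTILE,
                        seed: int = 0) -> list[TargetCall]:
    """Full direct/indirect pipeline for one SE on its chromosome.

    Target genes are cis genes (present in ``tss``, which must hold only
    same-chromosome genes) significant at ``padj_max`` (optionally further
    restricted to log2FC < ``lfc_max``); the control pool is the remaining
    cis expressed genes.  Pipeline: O/E per target -> distance-matched
    permutation null -> percentile classification.
    """
    df = de.df
    cis = df[df["gene"].isin(tss)]
    if cis.empty:
        logger.warning("run_target_analysis: no cis genes (intra-chromosomal "
                       "restriction); empty output")
        return []
    sig = cis["padj"] < padj_max
    if lfc_max is not None:
        sig = sig & (cis["log2fc"] < lfc_max)
    targets = cis[sig]
    pool = cis[~sig]
    if targets.empty:
        logger.info("run_target_analysis: no cis targets at padj < %g", padj_max)
        return []
    expected = expected_by_distance(m)
    se_mid = (se_start + se_end) // 2
    target_tss = {g: tss[g] for g in targets["gene"]}
    pool_tss = {g: tss[g] for g in pool["gene"]}
    target_oe = {g: se_gene_oe(m, expected, se_start, se_end, t)
                 for g, t in target_tss.items()}
    control = distance_matched_null(m, expected, se_start, se_end, target_tss,
                                    pool_tss, n_perm=n_perm, k_near=k_near,
                                    seed=seed)
    dist = {g: abs(t - se_mid) for g, t in target_tss.items()}
    return classify_targets(target_oe, control, se_id, dist, percentile=percentile)


# ---------------------------------------------------------------------------
# Activity-by-Contact
# ---------------------------------------------------------------------------


def _scale(v: np.ndarray, method: str) -> np.ndarray:
    if method == "zscore":
        sd = v.std()
        if sd == 0:
            raise ValidationError("cannot standardize a constant vector")
        return (v - v.mean()) / sd
    if method == "minmax":
        rng = np.ptp(v)
        if rng == 0:
            raise ValidationError("cannot min-max scale a constant vector")
        return (v - v.min()) / rng
    raise ValueError("scaling must be 'zscore' or 'minmax'")


def abc_scores(ses: list, gene_tss: dict[str, int], m: ContactMatrix,
               scaling: str = "zscore") -> list[AbcRecord]:
    """Modified Activity-by-Contact scores for SE-gene pairs.

    Activity is each SE's aggregate BRD4 signal; contact is the balanced
    count between the SE midpoint bin and the gene TSS bin (50-kb default
    resolution upstream).  Both vectors are log2(x + 1)-transformed and
    scaled (z-standardization by default) over all scored pairs, then
    multiplied; records are ranked descending per SE.  Callers restrict
    ``gene_tss`` to expressed genes (base mean > 100).
    """
    if not m.balanced:
        raise ValidationError("abc_scores requires a balanced matrix")
    pairs = []
    for se in ses:
        if se.chrom != m.chrom:
            continue
        se_bin = m.bin_of((se.start + se.end) // 2)
        for gene, t in gene_tss.items():
            tss_bin = m.bin_of(t)
            if m.mask[se_bin] or m.mask[tss_bin]:
                continue
            pairs.append((se.id, gene, float(se.signal),
                          float(m.matrix[se_bin, tss_bin])))
    if len(pairs) < 2:
        raise ValidationError("need >= 2 SE-gene pairs to standardize")
    activity = np.array([p[2] for p in pairs])
    contact = np.array([p[3] for p in pairs])
    a = _scale(np.log2(activity + 1.0), scaling)
    c = _scale(np.log2(contact + 1.0), scaling)
    score = a * c
    records = [AbcRecord(se_id=p[0], gene=p[1], activity=p[2], contact=p[3],
                         score=float(s)) for p, s in zip(pairs, score)]
    records.sort(key=lambda r: (r.se_id, -r.score))
    return records


def abc_table(records: list[AbcRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"se_id": r.se_id, "gene": r.gene,
                          "activity": r.activity, "contact": r.contact,
                          "score": r.score} for r in records])
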