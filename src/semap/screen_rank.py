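"""Replicate-free CRISPRi screen analysis via rank changes.

Wells (one perturbed super-enhancer per well, plus negative controls)
carry raw gene counts.  Counts are normalized by median-of-ratios size
factors and a log2 variance-stabilization stand-in, then every gene is
ranked within each well (rank 1 = highest expression) and against a global
rank (rank of the per-gene median across wells).  The rank change
RC = within-well rank - global rank is the differential-expression
statistic: RC > 0 means downranked (lower relative expression).  Per-well
target calls pick the smallest rank-change threshold whose empirical FDR
(median control exceedance count / well exceedance count) is at or below
the target (0.1 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .core_io import LabelledMatrix, ValidationError

logger = logging.getLogger("semap.screen_rank")

DEFAULT_TARGET_EFDR = 0.1


@dataclass
class ScreenTable:
    """Genes x wells raw counts plus well metadata.

    ``wells`` maps well id -> role, where role is ``"control"`` or the id
    of the targeted super-enhancer.  At least two control wells required.
    """

    counts: LabelledMatrix
    wells: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.wells) != set(self.counts.col_ids):
            raise ValidationError("well metadata does not match count columns")
        vals = self.counts.values
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be nonnegative integers")
        if len(self.control_wells) < 2:
            raise ValidationError("need >= 2 negative-control wells")

    @property
    def control_wells(self) -> list[str]:
        return [w for w, role in self.wells.items() if role == "control"]

    @property
    def se_wells(self) -> list[str]:
        return [w for w, role in self.wells.items() if role != "control"]


@dataclass
class RankChangeTable:
    """Rank changes (genes x wells), global ranks, and within-well ranks."""

    rc: LabelledMatrix
    within_rank: LabelledMatrix
    global_rank: pd.Series


@dataclass
class WellCall:
    """Target call for one SE well."""

    well: str
    threshold_down: float | None
    efdr_down: float | None
    down_genes: list[str]
    threshold_up: float | None
    efdr_up: float | None
    up_genes: list[str]


@dataclass
class TargetCallSet:
    calls: dict[str, WellCall] = field(default_factory=dict)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per well/column).

    The reference is the per-gene geometric mean across wells, computed over
    genes with all-positive counts.
    """
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValidationError(
            "no gene has positive counts in every well; size factors undefined "
            "(consider a pseudo-reference fallback)")
    logc = np.log(counts[pos])
    ref = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - ref, axis=0))


def preprocess_counts(screen: ScreenTable, n_surrogates: int = 0) -> LabelledMatrix:
    """Normalize raw screen counts.

    Steps: drop genes with zero counts in every well; divide by
    median-of-ratios size factors; log2(x + 1) as the variance-stabilization
    stand-in; optionally remove the ``n_surrogates`` leading singular
    components of the centered matrix (stand-in for surrogate-variable
    removal).
    """
    df = screen.counts.df
    keep = (df.to_numpy() > 0).any(axis=1)
    df = df.loc[keep]
    sf = size_factors(df.to_numpy())
    norm = np.log2(df.to_numpy() / sf + 1.0)
    if n_surrogates > 0:
        center = norm.mean(axis=1, keepdims=True)
        X = norm - center
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        k = min(n_surrogates, len(s))
        X = X - (u[:, :k] * s[:k]) @ vt[:k]
        norm = X + center
    logger.info("preprocess_counts: %d of %d gene(s) kept; %d surrogate "
                "component(s) removed", len(df), len(screen.counts.df), n_surrogates)
    return LabelledMatrix(pd.DataFrame(norm, index=df.index, columns=df.columns))


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Rank 1 = highest value; ties receive average ranks."""
    return stats.rankdata(-values, method="average", axis=0)


def rank_table(norm: LabelledMatrix, aggregate: str = "median") -> RankChangeTable:
    """Within-well ranks, global rank, and rank changes.

    The global rank is the rank of the per-gene ``aggregate`` (median by
    default, mean as an alternative) of normalized values across all wells.
    RC = within-well rank - global rank; positive RC means downranked.
    """
    if norm.df.shape[1] < 2:
        raise ValidationError("need >= 2 wells")
    vals = norm.values
    within = _rank_desc(vals)
    if aggregate == "median":
        agg = np.median(vals, axis=1)
    elif aggregate == "mean":
        agg = vals.mean(axis=1)
    else:
        raise ValueError("aggregate must be 'median' or 'mean'")
    glob = stats.rankdata(-agg, method="average")
    rc = within - glob[:, None]
    idx, cols = norm.df.index, norm.df.columns
    return RankChangeTable(
        rc=LabelledMatrix(pd.DataFrame(rc, index=idx, columns=cols)),
        within_rank=LabelledMatrix(pd.DataFrame(within, index=idx, columns=cols)),
        global_rank=pd.Series(glob, index=idx),
    )


def efdr_at_threshold(rc: RankChangeTable, well: str, controls: list[str],
                      threshold: float, direction: str = "down"
                      ) -> tuple[float, int]:
    """Empirical FDR for one well at one rank-change threshold.

    Counts genes beyond the threshold (RC >= threshold for "down",
    RC <= -threshold for "up") in the well; the eFDR is the median of the
    same count across control wells divided by the well count (1.0 when the
    well count is zero; capped at 1.0).
    """
    if not controls:
        raise ValidationError("controls must be nonempty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    def count(col: str) -> int:
        v = rc.rc.df[col].to_numpy()
        return int((v >= threshold).sum() if direction == "down"
                   else (v <= -threshold).sum())

    well_count = count(well)
    if well_count == 0:
        return 1.0, 0
    ctrl_median = float(np.median([count(c) for c in controls]))
    return min(ctrl_median / well_count, 1.0), well_count


def default_threshold_grid(n_genes: int) -> list[float]:
    """Integer multiples of 1% of the gene count, from 1% to 30%."""
    return [max(1.0, round(0.01 * i * n_genes)) for i in range(1, 31)]


def select_targets(rc: RankChangeTable, screen: ScreenTable,
                   threshold_grid: list[float] | None = None,
                   target_efdr: float = DEFAULT_TARGET_EFDR) -> TargetCallSet:
    """Per SE well and direction, call targets at the smallest qualifying
    grid threshold (eFDR <= ``target_efdr``); empty call set when none
    qualifies."""
    if threshold_grid is not None and len(threshold_grid) == 0:
        raise ValueError("threshold grid must be nonempty")
    n_genes = len(rc.rc.df)
    grid = sorted(threshold_grid) if threshold_grid else default_threshold_grid(n_genes)
    controls = screen.control_wells
    genes = rc.rc.df.index
    out = TargetCallSet()
    for well in screen.se_wells:
        v = rc.rc.df[well].to_numpy()
        res = {}
        for direction in ("down", "up"):
            chosen, efdr_chosen, gene_ids = None, None, []
            for thr in grid:
                efdr, cnt = efdr_at_threshold(rc, well, controls, thr, direction)
                if cnt > 0 and efdr <= target_efdr:
                    chosen, efdr_chosen = thr, efdr
                    sel = v >= thr if direction == "down" else v <= -thr
                    gene_ids = list(genes[sel])
                    break
            res[direction] = (chosen, efdr_chosen, gene_ids)
        out.calls[well] = WellCall(
            well=well,
            threshold_down=res["down"][0], efdr_down=res["down"][1],
            down_genes=res["down"][2],
            threshold_up=res["up"][0], efdr_up=res["up"][1],
            up_genes=res["up"][2],
        )
    n_down = sum(len(c.down_genes) for c in out.calls.values())
    logger.info("select_targets: %d downranked target call(s) across %d SE well(s)",
                n_down, len(out.calls))
    return out


def control_lfc(norm: LabelledMatrix, well: str,
                controls: list[str]) -> pd.Series:
    """Per-gene log2 fold change of a well against the control median.

    Normalized values are already log2-scale, so the LFC is a difference.
    """
    if not controls:
        raise ValidationError("controls must be nonempty")
    ctrl_median = norm.df[controls].median(axis=1)
    return norm.df[well] - ctrl_median


def rc_lfc_correlation(rc: RankChangeTable, norm: LabelledMatrix,
                       screen: ScreenTable,
                       significant_genes: list[str]) -> pd.DataFrame:
    """SE x SE Pearson correlation of rank change against control-relative LFC.

    Entry (i, j) correlates -RC in well i with LFC in well j over the pooled
    significant genes (negated so self-agreement is positive: downrank is
    positive RC but negative LFC).  Zero-variance vectors yield NaN entries
    with a logged flag.
    """
    genes = [g for g in significant_genes if g in rc.rc.df.index]
    if len(genes) < 3:
        raise ValidationError("pooled significant gene set must have >= 3 genes")
    wells = screen.se_wells
    controls = screen.control_wells
    neg_rc = -rc.rc.df.loc[genes, wells]
    lfc = pd.DataFrame({w: control_lfc(norm, w, controls).loc[genes] for w in wells})
    mat = np.full((len(wells), len(wells)), np.nan)
    for i, wi in enumerate(wells):
        a = neg_rc[wi].to_numpy()
        if np.ptp(a) == 0:
            logger.warning("rc_lfc_correlation: constant RC vector in %s", wi)
            continue
        for j, wj in enumerate(wells):
            b = lfc[wj].to_numpy()
            if np.ptp(b) == 0:
                logger.warning("rc_lfc_correlation: constant LFC vector in %s", wj)
                continue
            mat[i, j] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(mat, index=wells, columns=wells)


def cluster_summary(rc: RankChangeTable, significant_genes: list[str],
                    k_range: list[int] | None = None, chosen_k: int = 3,
                    seed: int = 0):
    """K-means gene clusters with an elbow table, plus an SE dendrogram.

    Genes are clustered on their rank-change profiles across wells for each
    k in ``k_range`` (within-cluster sum of squares reported per k; default
    chosen k = 3).  Wells are clustered by average linkage on Euclidean
    distance of their rank-change profiles.
    """
    genes = [g for g in significant_genes if g in rc.rc.df.index]
    k_range = k_range or [1, 2, 3, 4, 5, 6]
    if len(genes) < max(k_range):
        raise ValidationError("need at least max(k_range) significant genes")
    X = rc.rc.df.loc[genes].to_numpy()
    if np.ptp(X) == 0:
        raise ValidationError("degenerate (constant) rank-change profiles")
    elbow = []
    labels_by_k = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        elbow.append((k, float(km.inertia_)))
        labels_by_k[k] = pd.Series(km.labels_, index=genes)
    elbow_table = pd.DataFrame(elbow, columns=["k", "wcss"])
    gene_clusters = labels_by_k[chosen_k if chosen_k in labels_by_k
                                else k_range[-1]]
    se_linkage = linkage(X.T, method="average", metric="euclidean")
    return gene_clusters, elbow_table, se_linkage
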