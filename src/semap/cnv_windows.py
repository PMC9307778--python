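"""15-kb genome tiling, per-patient copy-number assignment, and the
super-enhancer amplification tests.

The autosomal genome is tiled into fixed-width windows (15 kb by default;
the embedded hg19 autosomes give ~192,000 windows).  Each window receives,
per patient, the overlap-length-weighted mean of all copy-number segments
that overlap it by at least one base pair.  Amplification of the
SE-overlapping windows is tested against (a) repeated equally sized random
draws from the whole-genome window pool (Welch one-sided t plus one-sided
Mann-Whitney U per draw) and (b) a single direct comparison against all
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomeTable, IntervalSet, LabelledMatrix, SegmentFile

logger = logging.getLogger("semap.cnv_windows")

DEFAULT_WINDOW_BP = 15_000
P_FLOOR = 2.2e-16  # reporting floor for vanishing p-values


@dataclass
class WindowGrid:
    """Consecutive fixed-width windows tiling each chromosome.

    Window ids are ``<chrom>:<index>`` with index counted per chromosome;
    the last window of a chromosome may be shorter than ``width``.
    """

    windows: IntervalSet
    width: int

    @property
    def window_ids(self) -> list[str]:
        return list(self.windows.df["id"])

    def windows_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Ids of grid windows with >= 1 bp overlap to [start, end) on chrom."""
        df = self.windows.df
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            return []
        first = int(start // self.width)
        last = int((end - 1) // self.width)
        n = len(sub)
        first = max(first, 0)
        last = min(last, n - 1)
        if first > last:
            return []
        return [f"{chrom}:{i}" for i in range(first, last + 1)]


@dataclass
class AmplificationTestResult:
    """Per-iteration p-value streams from the random-draw test."""

    welch_p: np.ndarray
    mwu_p: np.ndarray
    n_iter: int
    degenerate: bool = False

    def summary(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "median_welch_p": float(np.median(self.welch_p)),
            "median_mwu_p": float(np.median(self.mwu_p)),
            "frac_welch_p_lt_0.05": float(np.mean(self.welch_p < 0.05)),
            "frac_mwu_p_lt_0.05": float(np.mean(self.mwu_p < 0.05)),
            "degenerate": self.degenerate,
        }


def tile_genome(genome: GenomeTable, width: int = DEFAULT_WINDOW_BP) -> WindowGrid:
    """Tile every chromosome into ceil(length/width) adjacent windows."""
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom in genome.chromosomes:
        length = genome[chrom]
        n = -(-length // width)  # ceil
        for i in range(n):
            rows.append((chrom, i * width, min((i + 1) * width, length),
                         f"{chrom}:{i}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    logger.info("tile_genome: %d window(s) at %d bp", len(df), width)
    return WindowGrid(windows=IntervalSet(df, genome=genome), width=width)


def assign_copy_number(grid: WindowGrid, segments: SegmentFile) -> LabelledMatrix:
    """Window x patient copy-number matrix.

    A window's value for a patient is the overlap-length-weighted mean of
    all segments overlapping it by >= 1 bp; missing (NaN) when no segment
    overlaps.
    """
    wdf = grid.windows.df
    patients = segments.patients
    patient_index = {p: i for i, p in enumerate(patients)}
    values = np.zeros((len(wdf), len(patients)))
    weights = np.zeros_like(values)

    w_start = wdf["start"].to_numpy()
    w_end = wdf["end"].to_numpy()
    # per-chromosome slice into the global window arrays
    chrom_slices: dict[str, tuple[int, int]] = {}
    for chrom, grp in wdf.groupby("chrom", sort=False):
        chrom_slices[chrom] = (int(grp.index[0]), int(grp.index[-1]) + 1)

    width = grid.width
    for seg in segments.df.itertuples(index=False):
        if seg.chrom not in chrom_slices:
            continue
        lo, hi = chrom_slices[seg.chrom]
        chrom_len = w_end[hi - 1]
        s, e = max(seg.start, 0), min(seg.end, chrom_len)
        if s >= e:
            continue
        first = lo + s // width
        last = lo + (e - 1) // width
        p_idx = patient_index[seg.patient]
        idx = np.arange(first, last + 1)
        ov = np.minimum(e, w_end[idx]) - np.maximum(s, w_start[idx])
        values[idx, p_idx] += ov * seg.value
        weights[idx, p_idx] += ov
    nz = weights > 0
    values[nz] = values[nz] / weights[nz]
    values[~nz] = np.nan
    out = LabelledMatrix(pd.DataFrame(values, index=wdf["id"].to_list(),
                                      columns=patients))
    n_assigned = int(nz.any(axis=1).sum())
    logger.info("assign_copy_number: %d of %d window(s) received signal",
                n_assigned, len(wdf))
    return out


def se_window_overlap(grid: WindowGrid, ses: IntervalSet) -> set[str]:
    """Ids of grid windows with >= 1 bp intersection with any SE."""
    hit: set[str] = set()
    for row in ses.df.itertuples(index=False):
        hit.update(grid.windows_overlapping(row.chrom, row.start, row.end))
    logger.info("se_window_overlap: %d window(s) overlap %d SE(s)",
                len(hit), len(ses))
    return hit


def _window_means(cn: LabelledMatrix) -> np.ndarray:
    """Per-window summary: mean copy number across patients, missing excluded."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(cn.values, axis=1)


def _one_sided_tests(se_vals: np.ndarray, other: np.ndarray,
                     axis: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Welch one-sided t (SE greater; Welch-Satterthwaite dof) and one-sided
    Mann-Whitney U (normal approximation with tie correction)."""
    welch = stats.ttest_ind(se_vals, other, axis=axis, equal_var=False,
                            alternative="greater")
    mwu = stats.mannwhitneyu(se_vals, other, axis=axis,
                             alternative="greater", method="asymptotic")
    return np.asarray(welch.pvalue), np.asarray(mwu.pvalue)


def random_draw_test(cn: LabelledMatrix, se_windows: set[str],
                     n_iter: int = 10_000, seed: int = 0) -> AmplificationTestResult:
    """Compare SE-window copy number against repeated random window draws.

    Each iteration draws ``|se_windows|`` window ids uniformly without
    replacement from the whole-window pool (inclusive of the SE windows) and
    compares per-window mean copy number of the SE set against the draw with
    a Welch one-sided t-test (SE greater) and a one-sided Mann-Whitney U.
    """
    if len(se_windows) < 2:
        raise ValueError("need >= 2 SE windows")
    means = _window_means(cn)
    ids = np.asarray(cn.row_ids)
    valid = ~np.isnan(means)
    means, ids = means[valid], ids[valid]
    se_mask = np.isin(ids, list(se_windows))
    se_vals = means[se_mask]
    k = len(se_vals)
    if k < 2:
        raise ValueError("fewer than 2 SE windows have copy-number signal")
    rng = np.random.default_rng(seed)
    if np.ptp(means) == 0:
        logger.warning("random_draw_test: constant copy number; degenerate")
        return AmplificationTestResult(np.ones(n_iter), np.ones(n_iter),
                                       n_iter, degenerate=True)
    draws = np.empty((n_iter, k))
    for it in range(n_iter):
        draws[it] = means[rng.choice(len(means), size=k, replace=False)]
    se_tiled = np.broadcast_to(se_vals, (n_iter, k))
    welch_p, mwu_p = _one_sided_tests(se_tiled, draws, axis=1)
    welch_p = np.nan_to_num(welch_p, nan=1.0)
    res = AmplificationTestResult(welch_p, mwu_p, n_iter)
    logger.info("random_draw_test: %d iteration(s), median Welch p = %.3g",
                n_iter, float(np.median(welch_p)))
    return res


def direct_comparison(cn: LabelledMatrix,
                      se_windows: set[str]) -> tuple[float, float]:
    """SE-window means versus all-window means (one Welch t, one MWU).

    Vanishing p-values are reported at the 2.2e-16 floor.
    """
    means = _window_means(cn)
    ids = np.asarray(cn.row_ids)
    valid = ~np.isnan(means)
    means, ids = means[valid], ids[valid]
    se_vals = means[np.isin(ids, list(se_windows))]
    if len(se_vals) < 2:
        raise ValueError("need >= 2 SE windows with signal")
    if np.ptp(means) == 0:
        logger.warning("direct_comparison: constant copy number; degenerate")
        return 1.0, 1.0
    welch_p, mwu_p = _one_sided_tests(se_vals, means)
    return max(float(welch_p), P_FLOOR), max(float(mwu_p), P_FLOOR)
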