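"""Enhancer filter chain and ROSE-style super-enhancer calling.

Active enhancers are defined as BRD4 peaks co-occupied (>= 1 bp overlap) by
H3K27ac peaks, with any peak overlapping an annotated gene or promoter
removed.  Surviving peaks are stitched into regions when their gap is at
most 12.5 kb (the ROSE default), and super-enhancers are the stitched
regions above the geometric inflection of the signal-vs-rank curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .core_io import IntervalSet, ValidationError

logger = logging.getLogger("semap.enhancer_se")

ROSE_STITCH_GAP = 12500  # bp, ROSE default stitching distance


@dataclass
class SuperEnhancer:
    """One called super-enhancer: a stitched region above the rank cutoff."""

    id: str
    chrom: str
    start: int
    end: int
    constituent_ids: list[str]
    signal: float  # sum of constituent BRD4 signal
    rank: int  # 1 = highest aggregate signal


def _trees_by_chrom(ivs: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in ivs.df.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def co_occupied_peaks(brd4: IntervalSet, k27ac: IntervalSet) -> IntervalSet:
    """BRD4 peaks with >= 1 bp overlap to any H3K27ac peak.

    Output keeps the BRD4 coordinates; each BRD4 peak appears at most once
    however many H3K27ac peaks overlap it.
    """
    trees = _trees_by_chrom(k27ac)
    keep = [
        row.chrom in trees and bool(trees[row.chrom].overlap(row.start, row.end))
        for row in brd4.df.itertuples(index=False)
    ]
    out = brd4.subset(np.asarray(keep, dtype=bool))
    logger.info("co_occupied_peaks: %d of %d BRD4 peak(s) kept", len(out), len(brd4))
    return out


def exclude_genic(peaks: IntervalSet, genes: IntervalSet,
                  promoters: IntervalSet) -> IntervalSet:
    """Remove peaks with >= 1 bp overlap to any gene body or promoter."""
    gene_trees = _trees_by_chrom(genes)
    prom_trees = _trees_by_chrom(promoters)
    keep = []
    for row in peaks.df.itertuples(index=False):
        hit = (row.chrom in gene_trees
               and bool(gene_trees[row.chrom].overlap(row.start, row.end)))
        hit = hit or (row.chrom in prom_trees
                      and bool(prom_trees[row.chrom].overlap(row.start, row.end)))
        keep.append(not hit)
    out = peaks.subset(np.asarray(keep, dtype=bool))
    logger.info("exclude_genic: %d of %d peak(s) survive the genic/promoter filter",
                len(out), len(peaks))
    return out


def stitch(peaks: IntervalSet, gap: int = ROSE_STITCH_GAP) -> IntervalSet:
    """Transitively merge same-chromosome peaks separated by <= ``gap`` bp.

    Region span runs from the minimum start to the maximum end of its
    constituents, region signal is the sum of constituent signals, and the
    region id records the constituent peak ids (comma-joined).  Idempotent.
    """
    df = peaks.sorted().df
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = [row.chrom, row.start, row.end, [str(row.id)],
                       0.0 if np.isnan(row.signal) else float(row.signal)]
            elif row.start - cur[2] <= gap:
                cur[2] = max(cur[2], row.end)
                cur[3].append(str(row.id))
                cur[4] += 0.0 if np.isnan(row.signal) else float(row.signal)
            else:
                rows.append(cur)
                cur = [row.chrom, row.start, row.end, [str(row.id)],
                       0.0 if np.isnan(row.signal) else float(row.signal)]
        if cur is not None:
            rows.append(cur)
    import pandas as pd

    out = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "id": [",".join(r[3]) for r in rows],
            "signal": [r[4] for r in rows],
        }
    )
    logger.info("stitch: %d peak(s) -> %d stitched region(s) at gap <= %d bp",
                len(peaks), len(out), gap)
    return IntervalSet(out, genome=peaks.genome)


def rank_curve(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled rank/signal axes and the central-finite-difference derivative.

    Signals are sorted ascending; both axes are rescaled to [0, 1]; the
    derivative is estimated by central differences at interior points and
    one-sided differences at the ends.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    x = np.arange(n, dtype=float) / (n - 1)
    rng = s[-1] - s[0]
    if rng == 0:
        y = np.zeros(n)
    else:
        y = (s - s[0]) / rng
    deriv = np.gradient(y, x)
    return x, y, deriv


def rank_cutoff(regions: IntervalSet) -> tuple[list[SuperEnhancer], float]:
    """Call super-enhancers as regions above the rank-curve inflection.

    The cutoff is the signal at the lowest-rank point whose scaled
    derivative strictly exceeds 1; regions with signal strictly above that
    cutoff are super-enhancers, ranked descending by signal.  When no point
    exceeds derivative 1 (identical or perfectly linear signals) the SE set
    is empty and a warning is logged.
    """
    df = regions.df
    if len(df) < 3:
        raise ValidationError("rank_cutoff needs >= 3 stitched regions")
    signals = df["signal"].to_numpy(float)
    s_sorted = np.sort(signals)
    _, _, deriv = rank_curve(signals)
    above = np.nonzero(deriv > 1.0)[0]
    if len(above) == 0:
        logger.warning("rank_cutoff: derivative never exceeds 1; no SEs called")
        return [], float("nan")
    cutoff_signal = float(s_sorted[above[0]])
    se_df = df[df["signal"] > cutoff_signal].sort_values(
        "signal", ascending=False, kind="mergesort")
    ses = [
        SuperEnhancer(
            id=f"SE{rank}",
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            constituent_ids=str(row.id).split(","),
            signal=float(row.signal),
            rank=rank,
        )
        for rank, row in enumerate(se_df.itertuples(index=False), start=1)
    ]
    logger.info("rank_cutoff: %d SE(s) above cutoff signal %.6g", len(ses),
                cutoff_signal)
    return ses, cutoff_signal


def call_super_enhancers(
    brd4: IntervalSet,
    k27ac: IntervalSet,
    genes: IntervalSet,
    promoters: IntervalSet,
    gap: int = ROSE_STITCH_GAP,
) -> tuple[list[SuperEnhancer], IntervalSet, float]:
    """Full chain: co-occupancy filter -> genic exclusion -> stitch -> cutoff.

    Returns the SE list, the stitched regions, and the cutoff signal.
    """
    peaks = co_occupied_peaks(brd4, k27ac)
    peaks = exclude_genic(peaks, genes, promoters)
    stitched = stitch(peaks, gap=gap)
    ses, cutoff = rank_cutoff(stitched)
    return ses, stitched, cutoff


def ses_to_intervals(ses: list[SuperEnhancer],
                     genome=None) -> IntervalSet:
    """Represent a called SE list as an IntervalSet (signal = aggregate)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": [se.chrom for se in ses],
            "start": [se.start for se in ses],
            "end": [se.end for se in ses],
            "id": [se.id for se in ses],
            "signal": [se.signal for se in ses],
        }
    )
    return IntervalSet(df, genome=genome)
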