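"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure of the corresponding
real dataset at desk scale: clustered BRD4/H3K27ac peak tracks with a
heavy-tailed (log-normal) signal distribution and planted super-enhancer
clusters; piecewise-constant per-patient copy-number segments with
amplified windows linearly driving expression of linked genes;
negative-binomial screen counts with a minority of planted down-regulated
genes per perturbation well (a median of four targets per well, matching
the screen's observed scale); power-law distance-decay contact matrices
with planted enhancer-gene loops; and a differential-expression stand-in
table.  All generators are fully deterministic under a fixed seed, and the
:class:`PlantedTruth` they return is the only simulator state downstream
recovery tests may inspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    GenomeTable,
    IntervalSet,
    LabelledMatrix,
    SegmentFile,
    DETable,
)
from .screen_rank import ScreenTable

__all__ = [
    "PlantedTruth",
    "simulate_peaks",
    "simulate_cohort",
    "simulate_screen",
    "simulate_contacts",
    "simulate_de_table",
]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    Fields are filled by whichever generator produced the object; recovery
    tests read these and nothing else.
    """

    se_regions: IntervalSet | None = None
    amplified_windows: dict[str, float] = field(default_factory=dict)
    linked_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    well_targets: dict[str, list[str]] = field(default_factory=dict)
    loops: list[tuple[int, int, float]] = field(default_factory=list)
    target_lfc: float | None = None


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

MIN_PEAK_BP = 200
MAX_PEAK_BP = 1500


def simulate_peaks(
    genome: GenomeTable,
    n_background_peaks: int = 500,
    n_se_clusters: int = 5,
    peaks_per_cluster: int = 8,
    cluster_span: int = 30_000,
    signal_mu: float = 1.0,
    signal_sigma: float = 0.3,
    signal_inflation: float = 20.0,
    co_occupancy_prob: float = 1.0,
    n_genes: int = 50,
    seed: int = 0,
) -> tuple[IntervalSet, IntervalSet, IntervalSet, IntervalSet, PlantedTruth]:
    """BRD4/H3K27ac peak tracks with planted super-enhancer clusters.

    Background peaks scatter with log-normal signal, spaced more than the
    stitching gap apart so each yields its own stitched region; each
    planted cluster holds ``peaks_per_cluster`` peaks within
    ``cluster_span`` bp whose signal is ``signal_inflation`` times the
    background median (with log-normal scatter; the inflation must be at
    least 5).  Each BRD4 peak is overlapped by an H3K27ac peak with
    probability ``co_occupancy_prob``.  Genes and promoters are placed away
    from the planted clusters so the genic filter does not erode them.
    """
    if cluster_span < peaks_per_cluster * MIN_PEAK_BP:
        raise ValueError("cluster_span too small to pack the requested peaks")
    if signal_inflation < 5.0:
        raise ValueError("cluster signal inflation must be >= 5x background median")
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    # reserve cluster sites first so background/genes can avoid them
    cluster_sites: list[tuple[str, int, int]] = []
    guard = 100_000  # bp kept clear around each cluster
    for k in range(n_se_clusters):
        for _ in range(1000):
            c = chroms[rng.choice(len(chroms), p=probs)]
            start = int(rng.integers(0, genome[c] - cluster_span))
            if all(cc != c or not (start - guard < e and s - guard < start + cluster_span)
                   for cc, s, e in cluster_sites):
                cluster_sites.append((c, start, start + cluster_span))
                break
        else:
            raise ValueError("could not place super-enhancer clusters (infeasible)")

    def in_cluster(c, s, e, pad=guard):
        return any(cc == c and max(s, cs - pad) < min(e, ce + pad)
                   for cc, cs, ce in cluster_sites)

    brd4_rows = []
    bg_signals = rng.lognormal(signal_mu, signal_sigma, size=n_background_peaks)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    sep = 13_000  # keep isolated background peaks from stitching together
    attempts = 0
    while len(brd4_rows) < n_background_peaks:
        attempts += 1
        if attempts > 100 * n_background_peaks:
            raise ValueError("could not place background peaks (infeasible packing)")
        c = chroms[rng.choice(len(chroms), p=probs)]
        width = int(rng.integers(MIN_PEAK_BP, MAX_PEAK_BP))
        s = int(rng.integers(0, genome[c] - width))
        if in_cluster(c, s, s + width):
            continue
        if any(s - sep < e and o_s - sep < s + width for o_s, e in occupied[c]):
            continue
        occupied[c].append((s, s + width))
        brd4_rows.append((c, s, s + width, f"bg_{len(brd4_rows)}",
                          float(bg_signals[len(brd4_rows)])))

    bg_median = float(np.median(bg_signals))
    truth_rows = []
    for k, (c, cs, ce) in enumerate(cluster_sites):
        slot = cluster_span // peaks_per_cluster
        for j in range(peaks_per_cluster):
            width = int(rng.integers(MIN_PEAK_BP, min(MAX_PEAK_BP, slot)))
            s = cs + j * slot + int(rng.integers(0, max(1, slot - width)))
            sig = signal_inflation * bg_median * float(rng.lognormal(0.0, 0.25))
            brd4_rows.append((c, s, s + width, f"se{k}_p{j}", sig))
        truth_rows.append((c, cs, ce, f"planted_se_{k}", np.nan))

    brd4_df = pd.DataFrame(brd4_rows,
                           columns=["chrom", "start", "end", "id", "signal"])
    brd4 = IntervalSet(brd4_df, genome=genome)

    # H3K27ac: one overlapping peak per co-occupied BRD4 peak, plus scatter
    k27_rows = []
    for row in brd4_df.itertuples(index=False):
        if rng.random() < co_occupancy_prob:
            shift = int(rng.integers(-100, 101))
            s = max(0, row.start + shift)
            e = min(genome[row.chrom], row.end + shift)
            if s < e:
                k27_rows.append((row.chrom, s, e, f"k27_{row.id}", np.nan))
    for j in range(n_background_peaks // 2):  # K27ac-only background
        c = chroms[rng.choice(len(chroms), p=probs)]
        width = int(rng.integers(MIN_PEAK_BP, MAX_PEAK_BP))
        s = int(rng.integers(0, genome[c] - width))
        k27_rows.append((c, s, s + width, f"k27only_{j}", np.nan))
    k27ac = IntervalSet(
        pd.DataFrame(k27_rows, columns=["chrom", "start", "end", "id", "signal"]),
        genome=genome)

    gene_rows, prom_rows = [], []
    j = 0
    while len(gene_rows) < n_genes:
        c = chroms[rng.choice(len(chroms), p=probs)]
        width = int(rng.integers(5_000, 50_000))
        s = int(rng.integers(2_000, genome[c] - width))
        if in_cluster(c, s - 2_000, s + width):
            continue
        gene_rows.append((c, s, s + width, f"gene_{j}", np.nan))
        prom_rows.append((c, s - 2_000, s, f"prom_{j}", np.nan))
        j += 1
    genes = IntervalSet(
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "id", "signal"]),
        genome=genome)
    promoters = IntervalSet(
        pd.DataFrame(prom_rows, columns=["chrom", "start", "end", "id", "signal"]),
        genome=genome)

    truth = PlantedTruth(se_regions=IntervalSet(
        pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "id", "signal"]),
        genome=genome))
    return brd4, k27ac, genes, promoters, truth


# ---------------------------------------------------------------------------
# Patient cohort (copy number + expression)
# ---------------------------------------------------------------------------


def simulate_cohort(
    grid,
    n_patients: int = 300,
    amp_windows: list[str] | None = None,
    amp_effect: float = 1.0,
    amp_carrier_prob: float = 0.5,
    n_genes: int = 200,
    linked_pairs: int = 20,
    slope: float = 1.0,
    noise_sd: float = 0.3,
    missing_rate: float = 0.02,
    mean_segment_windows: float = 8.0,
    seed: int = 0,
) -> tuple[SegmentFile, LabelledMatrix, PlantedTruth]:
    """Piecewise-constant copy number with amplified windows driving linked
    gene expression.

    Per patient, each chromosome is cut into segments of geometric length
    (mean ``mean_segment_windows`` windows, so windows can straddle segment
    boundaries) with baseline seg-mean values Normal(0, 0.1).  Each planted
    amplified window is shifted by ``amp_effect`` in carrier patients
    (carriage probability ``amp_carrier_prob``, independent per patient) —
    carriage varies across patients the way real focal amplifications do,
    which is what gives the eQTL scan its signal.  Linked genes follow
    ``expr = mu_g + slope * CN_window + Normal(0, noise_sd)``; unlinked
    genes are noise around their baseline; entries are masked missing at
    ``missing_rate``.
    """
    if n_patients < 3:
        raise ValueError("association undefined for fewer than 3 patients")
    if linked_pairs > n_genes:
        raise ValueError("linked_pairs cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    wdf = grid.windows.df
    width = grid.width
    amp_windows = list(amp_windows or [])
    amp_set = set(amp_windows)

    patients = [f"P{i:04d}" for i in range(n_patients)]
    seg_rows = []
    # per-patient window-level CN (for the expression linkage)
    window_ids = list(wdf["id"])
    widx = {w: i for i, w in enumerate(window_ids)}
    cn_true = np.zeros((len(window_ids), n_patients))

    amp_bounds: dict[str, tuple[str, int, int]] = {}
    for w in amp_windows:
        row = wdf[wdf["id"] == w].iloc[0]
        amp_bounds[w] = (row["chrom"], int(row["start"]), int(row["end"]))

    carrier = rng.random((len(amp_windows), n_patients)) < amp_carrier_prob

    for p_idx, patient in enumerate(patients):
        for chrom, grp in wdf.groupby("chrom", sort=False):
            chrom_len = int(grp["end"].max())
            pos = 0
            while pos < chrom_len:
                seg_len = int(rng.geometric(1.0 / (mean_segment_windows * width))
                              ) or width
                end = min(pos + seg_len, chrom_len)
                value = float(rng.normal(0.0, 0.1))
                # split at amplified-window boundaries within this segment
                cuts = [pos, end]
                for a_i, w in enumerate(amp_windows):
                    c, ws, we = amp_bounds[w]
                    if c == chrom and carrier[a_i, p_idx] and ws < end and pos < we:
                        cuts.extend([max(ws, pos), min(we, end)])
                cuts = sorted(set(cuts))
                for s, e in zip(cuts[:-1], cuts[1:]):
                    v = value
                    for a_i, w in enumerate(amp_windows):
                        c, ws, we = amp_bounds[w]
                        if (c == chrom and carrier[a_i, p_idx]
                                and s >= ws and e <= we):
                            v = value + amp_effect
                    seg_rows.append((patient, chrom, s, e, v))
                pos = end
    segments = SegmentFile(pd.DataFrame(
        seg_rows, columns=["patient", "chrom", "start", "end", "value"]))

    # true window CN via length-weighted averaging of the emitted segments
    sdf = segments.df
    pidx = {p: i for i, p in enumerate(patients)}
    for row in sdf.itertuples(index=False):
        first = row.start // width
        last = (row.end - 1) // width
        for k in range(first, last + 1):
            wid = f"{row.chrom}:{k}"
            if wid not in widx:
                continue
            w_lo, w_hi = k * width, (k + 1) * width
            ov = min(row.end, w_hi) - max(row.start, w_lo)
            cn_true[widx[wid], pidx[row.patient]] += ov * row.value
    # window widths (last window may be short)
    w_len = (wdf["end"] - wdf["start"]).to_numpy()
    cn_true = cn_true / w_len[:, None]

    mu = rng.normal(8.0, 1.0, size=n_genes)
    expr = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_patients))
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    links: list[tuple[str, str, float]] = []
    link_windows = (amp_windows * (linked_pairs // max(len(amp_windows), 1) + 1)
                    if amp_windows else [])
    for gi in range(linked_pairs):
        w = link_windows[gi] if link_windows else window_ids[gi % len(window_ids)]
        expr[gi] += slope * cn_true[widx[w]]
        links.append((w, gene_ids[gi], slope))
    if missing_rate > 0:
        mask = rng.random(expr.shape) < missing_rate
        expr[mask] = np.nan
    expression = LabelledMatrix(pd.DataFrame(expr, index=gene_ids,
                                             columns=patients))
    truth = PlantedTruth(
        amplified_windows={w: amp_effect for w in amp_set},
        linked_pairs=links,
    )
    return segments, expression, truth


# ---------------------------------------------------------------------------
# CRISPRi screen counts
# ---------------------------------------------------------------------------


def simulate_screen(
    n_genes: int = 2000,
    n_se_wells: int = 86,
    n_control_wells: int = 10,
    mean_targets_per_well: float = 4.0,
    target_lfc: float = -2.0,
    dispersion: float = 0.01,
    baseline_log_mean: float = 7.0,
    baseline_log_sigma: float = 1.0,
    target_expression_quantile: float = 0.3,
    seed: int = 0,
) -> tuple[ScreenTable, PlantedTruth]:
    """Negative-binomial screen counts with planted down-regulated genes.

    Gene baselines are log-normal; counts are negative binomial with
    variance ``mean + dispersion * mean**2`` (the small default dispersion
    reflects wells drawn from one clonal cell population).  Each SE well
    receives Poisson(``mean_targets_per_well``) planted target genes whose
    mean is multiplied by ``2**target_lfc``; control wells are unperturbed.
    The default of four targets per well matches the observed median number
    of genes downregulated per super-enhancer.  Planted targets are drawn
    from genes above the ``target_expression_quantile`` of baseline
    expression: enhancer target genes are actively transcribed, and a rank
    statistic is blind to knockdown of genes already at the rank floor.
    """
    if n_control_wells < 2:
        raise ValueError("need >= 2 control wells")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(mean=baseline_log_mean, sigma=baseline_log_sigma,
                         size=n_genes)

    wells: dict[str, str] = {}
    well_ids = []
    for i in range(n_se_wells):
        wid = f"SE{i:02d}_well"
        wells[wid] = f"SE{i:02d}"
        well_ids.append(wid)
    for i in range(n_control_wells):
        wid = f"ctrl{i:02d}"
        wells[wid] = "control"
        well_ids.append(wid)

    truth_targets: dict[str, list[str]] = {}
    means = np.tile(base[:, None], (1, len(well_ids))).astype(float)
    expressed = np.nonzero(base >= np.quantile(base, target_expression_quantile))[0]
    for w_i, wid in enumerate(well_ids):
        if wells[wid] == "control":
            continue
        n_t = int(rng.poisson(mean_targets_per_well))
        n_t = min(n_t, len(expressed))
        targets = rng.choice(expressed, size=n_t, replace=False)
        means[targets, w_i] *= 2.0**target_lfc
        truth_targets[wid] = [gene_ids[t] for t in targets]

    r = 1.0 / dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    table = ScreenTable(
        counts=LabelledMatrix(pd.DataFrame(counts.astype(float),
                                           index=gene_ids, columns=well_ids)),
        wells=wells,
    )
    truth = PlantedTruth(well_targets=truth_targets, target_lfc=target_lfc)
    return table, truth


# ---------------------------------------------------------------------------
# Hi-C contacts
# ---------------------------------------------------------------------------


def simulate_contacts(
    n_bins: int = 300,
    binsize: int = 50_000,
    decay_exponent: float = 1.0,
    scale: float = 300.0,
    loops: list[tuple[int, int, float]] | None = None,
    self_contact_scale: float = 2.0,
    chrom: str = "chrS",
    seed: int = 0,
):
    """Power-law distance-decay contact matrix with planted loops.

    ``count_ij ~ Poisson(scale * |i-j|**-decay_exponent * enrichment_ij)``
    symmetrized by construction; the diagonal uses a fixed self-contact
    scale.  Loops are (bin_i, bin_j, enrichment >= 1) with |i-j| >= 1.
    """
    from .core_io import ContactMatrix

    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    loops = loops or []
    for i, j, enr in loops:
        if enr < 1:
            raise ValueError("loop enrichment must be >= 1")
        if abs(i - j) < 1:
            raise ValueError("loops must join distinct bins")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = scale * dist**-decay_exponent
    mean = np.nan_to_num(mean, nan=0.0, posinf=0.0)
    np.fill_diagonal(mean, scale * self_contact_scale)
    for i, j, enr in loops:
        mean[i, j] *= enr
        mean[j, i] *= enr
    upper = np.triu(rng.poisson(mean)).astype(float)
    mat = upper + np.triu(upper, 1).T
    cm = ContactMatrix(chrom=chrom, binsize=binsize, matrix=mat,
                       bin_starts=idx * binsize)
    truth = PlantedTruth(loops=list(loops))
    return cm, truth


# ---------------------------------------------------------------------------
# Differential-expression stand-in
# ---------------------------------------------------------------------------


def simulate_de_table(
    genes: list[str],
    planted_targets: dict[str, float],
    lfc_noise_sd: float = 0.1,
    frac_low_base_mean: float = 0.2,
    seed: int = 0,
) -> DETable:
    """DESeq-style results table with planted significant targets.

    Planted targets get their planted log2FC plus noise and adjusted
    p < 0.0005; non-targets get log2FC near 0 and adjusted p uniform on
    (0.1, 1).  Base means are log-normal with ``frac_low_base_mean`` of
    genes pushed below the 100-count expression floor.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if g in planted_targets:
            lfc = planted_targets[g] + rng.normal(0.0, lfc_noise_sd)
            padj = float(rng.uniform(0.0, 0.0005 * 0.9))
        else:
            lfc = rng.normal(0.0, 0.05)
            padj = float(rng.uniform(0.1, 1.0))
        if rng.random() < frac_low_base_mean:
            base = float(rng.uniform(1.0, 99.0))
        else:
            base = float(100.0 + rng.lognormal(5.0, 1.0))
        rows.append((g, float(lfc), padj, base))
    return DETable(pd.DataFrame(rows,
                                columns=["gene", "log2fc", "padj", "base_mean"]))
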