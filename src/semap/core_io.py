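"""Readers, writers, coordinate conventions, and shared containers.

Every module in the package works on the small set of containers defined
here: a :class:`GenomeTable` of chromosome lengths, an :class:`IntervalSet`
of named genomic intervals with optional signal, a :class:`SegmentFile` of
per-patient copy-number segments, a :class:`LabelledMatrix` of real values
with explicit missingness, a :class:`DETable` of differential-expression
results, and a :class:`ContactMatrix` of binned chromatin contacts.

Coordinates are 0-based half-open (BED native) everywhere internally.
Two intervals overlap iff ``max(starts) < min(ends)``; that predicate,
:func:`intervals_overlap`, is the single shared overlap routine used by
every module in the package.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("semap")


def configure_logging(verbose: bool = False) -> None:
    """Send structured log messages to standard error.

    Parameters
    ----------
    verbose
        When True, log at DEBUG level; otherwise INFO.
    """
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("semap")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


class ValidationError(ValueError):
    """Input violates a container invariant."""


def intervals_overlap(start1: int, end1: int, start2: int, end2: int) -> bool:
    """True iff the two half-open intervals share at least one base pair."""
    return max(start1, start2) < min(end1, end2)


# ---------------------------------------------------------------------------
# Genome table
# ---------------------------------------------------------------------------

#: hg19 autosome (chr1-chr22) lengths in bp.  These sum to 2,881,033,286.
HG19_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
}


@dataclass(frozen=True)
class GenomeTable:
    """Ordered mapping of chromosome name to length in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def total_length(self) -> int:
        return sum(self.lengths.values())


def hg19_autosomes() -> GenomeTable:
    """The embedded hg19 autosomal (chr1-22) genome."""
    return GenomeTable(dict(HG19_AUTOSOME_LENGTHS))


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------

_INTERVAL_COLS = ["chrom", "start", "end", "id", "signal"]


@dataclass
class IntervalSet:
    """Named genomic intervals with optional per-interval signal.

    Backed by a pandas DataFrame with columns ``chrom, start, end, id,
    signal``; ``signal`` is NaN when absent.  Intervals are validated
    against an optional :class:`GenomeTable` on construction.
    """

    df: pd.DataFrame
    genome: GenomeTable | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _INTERVAL_COLS:
            if col not in df.columns:
                if col == "id":
                    df["id"] = [f"iv_{i}" for i in range(len(df))]
                elif col == "signal":
                    df["signal"] = np.nan
                else:
                    raise ValidationError(f"missing required column {col!r}")
        df = df[_INTERVAL_COLS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValidationError(
                f"interval {df.loc[bad, 'id']!r}: start >= end "
                f"({df.loc[bad, 'start']} >= {df.loc[bad, 'end']})"
            )
        sig = df["signal"].to_numpy(float)
        if np.any(sig[~np.isnan(sig)] < 0):
            raise ValidationError("negative signal values")
        if self.genome is not None:
            for _, row in df.iterrows():
                if row["chrom"] not in self.genome:
                    raise ValidationError(f"chromosome {row['chrom']!r} not in genome")
                if row["end"] > self.genome[row["chrom"]]:
                    raise ValidationError(
                        f"interval {row['id']!r} extends past end of {row['chrom']}"
                    )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_signal(self) -> bool:
        return bool(self.df["signal"].notna().any())

    def sorted(self) -> "IntervalSet":
        out = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalSet(out.reset_index(drop=True), genome=self.genome)

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[mask].reset_index(drop=True), genome=self.genome)


def read_intervals(path, genome: GenomeTable | None = None,
                   one_based: bool = False) -> IntervalSet:
    """Read a BED3/BED4/bedGraph-dialect file into an :class:`IntervalSet`.

    Column 4, when present, is taken as the signal if numeric and as the
    interval id otherwise (BED name column); a numeric column 5 after a
    name column is taken as signal.  Records on chromosomes absent from
    ``genome`` are dropped with a logged count.  Set ``one_based`` for
    1-based inclusive input dialects; starts are shifted down by one at
    this boundary.
    """
    rows = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name, signal = None, np.nan
            if len(parts) >= 4:
                try:
                    signal = float(parts[3])
                except ValueError:
                    name = parts[3]
                    if len(parts) >= 5:
                        try:
                            signal = float(parts[4])
                        except ValueError:
                            signal = np.nan
            if genome is not None and chrom not in genome:
                n_dropped += 1
                continue
            rows.append((chrom, start, end, name, signal))
    if n_dropped:
        logger.warning("read_intervals: dropped %d record(s) on chromosomes "
                       "absent from the genome table", n_dropped)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "signal"])
    if df["id"].isna().all():
        df = df.drop(columns="id")
    else:
        df["id"] = [n if n is not None else f"iv_{i}" for i, n in enumerate(df["id"])]
    ivs = IntervalSet(df, genome=genome)
    logger.info("read_intervals: %d interval(s) from %s", len(ivs), path)
    return ivs


def write_intervals(ivs: IntervalSet, path) -> None:
    """Write an :class:`IntervalSet` as BED (4th col id, 5th col signal).

    Signal is written to 6 significant digits; round-trips through
    :func:`read_intervals`.
    """
    with open(path, "w") as fh:
        for _, row in ivs.df.iterrows():
            fields = [row["chrom"], str(row["start"]), str(row["end"]), str(row["id"])]
            if not np.isnan(row["signal"]):
                fields.append(f"{row['signal']:.6g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# SegmentFile
# ---------------------------------------------------------------------------


@dataclass
class SegmentFile:
    """Per-patient copy-number segments (SEG-like: continuous seg-mean values).

    DataFrame columns: ``patient, chrom, start, end, value``.  A patient's
    segments on one chromosome must be non-overlapping; validated on
    construction.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df[["patient", "chrom", "start", "end", "value"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValidationError("segment with start >= end")
        for (patient, chrom), grp in df.groupby(["patient", "chrom"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"overlapping segments for patient {patient!r} on {chrom}"
                )
        self.df = df.reset_index(drop=True)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.df["patient"]))


def read_segments(path) -> SegmentFile:
    """Read delimited text with header ``patient chrom start end value``."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"patient", "chrom", "start", "end", "value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must contain {sorted(required)}")
    seg = SegmentFile(df)
    logger.info("read_segments: %d segment(s), %d patient(s) from %s",
                len(seg.df), len(seg.patients), path)
    return seg


def write_segments(seg: SegmentFile, path) -> None:
    seg.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LabelledMatrix
# ---------------------------------------------------------------------------


@dataclass
class LabelledMatrix:
    """Row-labelled, column-labelled real matrix with explicit missingness.

    ``values`` is float with NaN marking missing entries; the mask is
    recoverable as ``isna()``.  Row and column ids must be unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate row ids")
        if self.df.columns.has_duplicates:
            raise ValidationError("duplicate column ids")
        self.df = self.df.astype(float)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)

    def missing_mask(self) -> np.ndarray:
        return self.df.isna().to_numpy()


def read_matrix(path) -> LabelledMatrix:
    """Read a gene-by-sample (or window-by-patient) TSV with header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LabelledMatrix(df)


def write_matrix(m: LabelledMatrix, path) -> None:
    m.df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# DETable
# ---------------------------------------------------------------------------


@dataclass
class DETable:
    """Differential-expression results: gene, log2FC, adjusted p, base mean."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df[["gene", "log2fc", "padj", "base_mean"]].copy()
        p = df["padj"].to_numpy(float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("adjusted p outside [0, 1]")
        if (df["base_mean"].to_numpy(float) < 0).any():
            raise ValidationError("negative base mean")
        self.df = df.reset_index(drop=True)


def read_de_table(path) -> DETable:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return DETable(df)


def write_de_table(de: DETable, path) -> None:
    de.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ContactMatrix
# ---------------------------------------------------------------------------


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    ``matrix`` is dense symmetric; ``bin_starts`` gives the genomic start of
    each bin at uniform ``binsize``.  ``mask`` flags bins excluded from all
    statistics (all-zero rows after construction or balancing drop-out).
    ``balancing`` holds the scaling vector once :func:`hic_targets.kr_balance`
    has run.
    """

    chrom: str
    binsize: int
    matrix: np.ndarray
    bin_starts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    balanced: bool = False
    balancing: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValidationError("contact matrix must be symmetric")
        if np.any(m < 0):
            raise ValidationError("negative contact counts")
        self.matrix = m
        self.bin_starts = np.asarray(self.bin_starts, dtype=np.int64)
        if self.mask is None:
            self.mask = np.zeros(m.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, position: int) -> int:
        """Index of the bin containing a genomic position."""
        idx = int((position - self.bin_starts[0]) // self.binsize)
        if idx < 0 or idx >= self.n_bins:
            raise ValidationError(f"position {position} outside binned range")
        return idx


def read_contacts(bins_path, triplets_path) -> dict[str, ContactMatrix]:
    """Read a bin table plus (bin_i, bin_j, count) triplets.

    The bin table is delimited text with header ``chrom start end bin_id``;
    bins must tile each chromosome at a uniform width.  Each triplet count is
    stored once and mirrored, so the returned per-chromosome matrices are
    exactly symmetric.  Inter-chromosomal triplets are retained in the
    returned ``trans`` log only as a count: downstream analysis is
    intra-chromosomal.
    """
    bins = pd.read_csv(bins_path, sep=None, engine="python")
    bins.columns = [c.strip().lower() for c in bins.columns]
    if not {"chrom", "start", "end", "bin_id"}.issubset(bins.columns):
        raise ParseError(f"{bins_path}: header must contain chrom start end bin_id")
    widths = bins["end"] - bins["start"]
    by_chrom = {}
    bin_chrom = dict(zip(bins["bin_id"], bins["chrom"]))
    bin_local: dict = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        g = grp.sort_values("start").reset_index(drop=True)
        w = (g["end"] - g["start"]).to_numpy()
        # last bin may be truncated at the chromosome end
        if len(w) > 1 and not (w[:-1] == w[0]).all():
            raise ParseError(f"non-uniform bin width on {chrom}")
        binsize = int(w[0])
        starts = g["start"].to_numpy()
        if len(starts) > 1 and not (np.diff(starts) == binsize).all():
            raise ParseError(f"bins do not tile {chrom} uniformly")
        for local, bid in enumerate(g["bin_id"]):
            bin_local[bid] = local
        by_chrom[chrom] = (binsize, starts, len(g))

    mats = {c: np.zeros((n, n)) for c, (_, _, n) in by_chrom.items()}
    n_trans = 0
    trip = pd.read_csv(triplets_path, sep=None, engine="python")
    trip.columns = [c.strip().lower() for c in trip.columns]
    for lineno, row in enumerate(trip.itertuples(index=False), 2):
        bi, bj, count = row[0], row[1], float(row[2])
        if bi not in bin_chrom or bj not in bin_chrom:
            raise ParseError(f"{triplets_path}:{lineno}: unknown bin id")
        ci, cj = bin_chrom[bi], bin_chrom[bj]
        if ci != cj:
            n_trans += 1
            continue
        i, j = bin_local[bi], bin_local[bj]
        mats[ci][i, j] = count
        mats[ci][j, i] = count
    if n_trans:
        logger.warning("read_contacts: %d inter-chromosomal triplet(s) flagged and "
                       "excluded (analysis is intra-chromosomal)", n_trans)
    out = {}
    for chrom, (binsize, starts, _) in by_chrom.items():
        out[chrom] = ContactMatrix(chrom=chrom, binsize=binsize,
                                   matrix=mats[chrom], bin_starts=starts)
    return out


def write_contacts(mats: dict[str, ContactMatrix], bins_path, triplets_path) -> None:
    """Write per-chromosome contact matrices as a bin table + upper triplets."""
    bin_rows, trip_rows = [], []
    offset = 0
    for chrom, cm in mats.items():
        for i, s in enumerate(cm.bin_starts):
            bin_rows.append((chrom, int(s), int(s) + cm.binsize, offset + i))
        iu, ju = np.triu_indices(cm.n_bins)
        vals = cm.matrix[iu, ju]
        nz = vals > 0
        for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
            trip_rows.append((offset + int(i), offset + int(j), v))
        offset += cm.n_bins
    pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "bin_id"]).to_csv(
        bins_path, sep="\t", index=False)
    pd.DataFrame(trip_rows, columns=["bin_i", "bin_j", "count"]).to_csv(
        triplets_path, sep="\t", index=False)
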