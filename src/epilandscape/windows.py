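"""Non-overlapping genome tiling and per-window statistics.

The genome is cut into fixed-width windows (100 bp by default; the last
window of a chromosome may be shorter).  Per window we track, for each
cytosine context, the summed methylated and total read counts and the
weighted methylation level sum_meth / sum_total; windows with no covered
cytosines in a context carry a *missing* level (NaN), never 0, and are
excluded from every downstream average in that context.  ChIP enrichment
is the raw sum of reads intersecting the window by >= 1 bp.

Both strands' cytosines are pooled per window (configurable upstream by
filtering the record stream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import ChipRead, CytosineRecord, FeatureRecord, GenomicInterval

CONTEXTS = ("CG", "CHG", "CHH")
LEVEL_COLUMNS = {"CG": "mCG", "CHG": "mCHG", "CHH": "mCHH"}


class WindowTable:
    """The genome tiling plus all per-window tracks, backed by a DataFrame.

    Window rows are globally indexed in chromosome order; because windows
    tile the genome, interval queries reduce to index arithmetic.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], window_size: int = 100):
        if window_size <= 0:
            raise ValueError(f"window_size must be positive, got {window_size}")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.window_size = window_size
        self._offsets: dict[str, int] = {}
        chroms, starts = [], []
        offset = 0
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // window_size)  # ceil
            self._offsets[chrom] = offset
            chroms.extend([chrom] * n)
            starts.extend(range(0, size, window_size))
            offset += n
        start_arr = np.asarray(starts, dtype=np.int64)
        end_arr = start_arr + window_size
        sizes = np.asarray([self.chrom_sizes[c] for c in chroms], dtype=np.int64)
        np.minimum(end_arr, sizes, out=end_arr)
        self.df = pd.DataFrame({"chrom": chroms, "start": start_arr, "end": end_arr})
        for ctx in CONTEXTS:
            self.df[f"sum_meth_{ctx}"] = 0
            self.df[f"sum_total_{ctx}"] = 0
            self.df[f"n_sites_{ctx}"] = 0
            self.df[LEVEL_COLUMNS[ctx]] = np.nan
        self.df["chip_count"] = 0
        self.df["location"] = "other"

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindowTable":
        """Rebuild a WindowTable from a written window-table DataFrame."""
        widths = (df["end"] - df["start"]).to_numpy()
        window_size = int(widths.max())
        chrom_sizes = {
            str(chrom): int(sub["end"].max())
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        table = cls(chrom_sizes, window_size)
        if len(table.df) != len(df):
            raise ValueError("window table does not tile its chromosomes")
        for col in df.columns:
            if col not in ("chrom", "start", "end"):
                table.df[col] = df[col].to_numpy()
        return table

    # -- index arithmetic ---------------------------------------------------

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing base ``pos``."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise IndexError(f"position {chrom}:{pos} outside tiled genome")
        return self._offsets[chrom] + pos // self.window_size

    def window_indices(self, chrom: str, start: int, end: int) -> range:
        """Global indices of all windows overlapping [start, end) by >= 1 bp."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        start = max(start, 0)
        end = min(end, size)
        if start >= end:
            return range(0)
        off = self._offsets[chrom]
        return range(off + start // self.window_size,
                     off + (end - 1) // self.window_size + 1)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])
        ]

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0

    def track(self, name: str) -> np.ndarray:
        """A named per-window track: mCG / mCHG / mCHH / chip_count."""
        if name not in self.df.columns:
            raise KeyError(f"unknown track {name!r}")
        return self.df[name].to_numpy(dtype=float)


def tile_genome(chrom_sizes: Mapping[str, int], window_size: int = 100) -> WindowTable:
    """Partition every chromosome into non-overlapping windows."""
    return WindowTable(chrom_sizes, window_size)


def weighted_methylation(
    cytosines: Iterable[CytosineRecord],
    windows: WindowTable,
    min_sites: int = 1,
) -> WindowTable:
    """Accumulate weighted methylation levels per window and context.

    level = sum(n_meth) / sum(n_total) over the window's cytosines of that
    context.  Windows whose summed total is zero, or with fewer than
    ``min_sites`` read-covered cytosines, get a missing level.
    """
    per_ctx: dict[str, list[list[int]]] = {ctx: [[], [], []] for ctx in CONTEXTS}
    for rec in cytosines:
        try:
            idx = windows.window_index(rec.chrom, rec.pos)
        except KeyError:
            raise ValueError(
                f"cytosine on unknown chromosome {rec.chrom!r}"
            ) from None
        bucket = per_ctx[rec.context]
        bucket[0].append(idx)
        bucket[1].append(rec.n_meth)
        bucket[2].append(rec.n_total)
    n = len(windows)
    for ctx in CONTEXTS:
        idxs, meths, totals = per_ctx[ctx]
        idx_arr = np.asarray(idxs, dtype=np.int64)
        meth_arr = np.asarray(meths, dtype=np.int64)
        total_arr = np.asarray(totals, dtype=np.int64)
        sum_meth = np.zeros(n, dtype=np.int64)
        sum_total = np.zeros(n, dtype=np.int64)
        n_sites = np.zeros(n, dtype=np.int64)
        if len(idx_arr):
            np.add.at(sum_meth, idx_arr, meth_arr)
            np.add.at(sum_total, idx_arr, total_arr)
            np.add.at(n_sites, idx_arr[total_arr > 0], 1)
        windows.df[f"sum_meth_{ctx}"] = sum_meth
        windows.df[f"sum_total_{ctx}"] = sum_total
        windows.df[f"n_sites_{ctx}"] = n_sites
        defined = (sum_total > 0) & (n_sites >= min_sites)
        level = np.full(n, np.nan)
        level[defined] = sum_meth[defined] / sum_total[defined]
        windows.df[LEVEL_COLUMNS[ctx]] = level
    return windows


def chip_window_counts(
    reads: Sequence[ChipRead], windows: WindowTable, cpm: bool = False
) -> np.ndarray:
    """Sum of reads intersecting each window (a read overlapping k windows
    increments all k, bedtools-intersect semantics).

    Raw read sums by default; ``cpm=True`` rescales to counts per million
    input reads for cross-library comparison.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    for read in reads:
        iv = read.interval
        for idx in windows.window_indices(iv.chrom, iv.start, iv.end):
            counts[idx] += 1
    out = counts * 1e6 / len(reads) if (cpm and reads) else counts
    windows.df["chip_count"] = out
    return out


@dataclass(frozen=True)
class SignificanceThreshold:
    """mean + k * sd cutoff over genome-wide window values (population sd)."""

    mean: float
    sd: float
    k: float

    @property
    def cutoff(self) -> float:
        return self.mean + self.k * self.sd

    def flag(self, values) -> np.ndarray:
        """Strictly-greater-than flag per value."""
        return np.asarray(values, dtype=float) > self.cutoff


def significance_threshold(values, k: float) -> SignificanceThreshold:
    """Genome-wide mean + k*sd threshold (ddof=0; strict > when flagging)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    return SignificanceThreshold(mean=float(arr.mean()), sd=float(arr.std(ddof=0)), k=k)


def level_distribution(
    windows: WindowTable, context: str, bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Histogram of tile counts per methylation-level bin.

    Only windows with a defined level contribute; proportions sum to 1
    over those windows.  The final bin includes its upper edge.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    levels = windows.track(LEVEL_COLUMNS[context])
    levels = levels[~np.isnan(levels)]
    counts, _ = np.histogram(levels, bins=edges)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "proportion": counts / total if total else np.zeros_like(counts, dtype=float),
        }
    )


def classify_window_location(
    windows: WindowTable, features: Sequence[FeatureRecord]
) -> pd.Series:
    """Label each window genic / TE / both / other by >= 1 bp overlap."""
    genic = np.zeros(len(windows), dtype=bool)
    te = np.zeros(len(windows), dtype=bool)
    for feat in features:
        if feat.kind == "gene":
            target = genic
        elif feat.kind == "TE":
            target = te
        else:
            continue
        iv = feat.interval
        if iv.chrom not in windows.chrom_sizes:
            continue
        rng = windows.window_indices(iv.chrom, iv.start, iv.end)
        target[rng.start: rng.stop] = True
    location = np.where(
        genic & te, "both", np.where(genic, "genic", np.where(te, "TE", "other"))
    )
    windows.df["location"] = location
    return windows.df["location"]


__all__ = [
    "CONTEXTS",
    "LEVEL_COLUMNS",
    "WindowTable",
    "tile_genome",
    "weighted_methylation",
    "chip_window_counts",
    "SignificanceThreshold",
    "significance_threshold",
    "level_distribution",
    "classify_window_location",
]
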