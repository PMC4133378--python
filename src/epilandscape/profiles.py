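"""Element-anchored metaprofiles.

Two plot geometries:

* relative: each element is rescaled to a 1-1000 axis with fixed-width
  flanks on either side; the concatenated axis (upstream flank, scaled
  body, downstream flank) is cut into 60 bins, 20 per segment.
* absolute: physical bp distance from the TSS (5' plot: upstream flank +
  into-gene extent) or the TTS (3' plot: into-gene extent + downstream
  flank), 100 equal bins per plot; into-gene distances are capped at the
  gene's actual span, so deep-body bins draw on progressively fewer genes.

Each retained window-element pair is one observation; per-bin means pool
pairs by default (gene-first averaging available via ``per_gene_average``).
Windows are assigned to their closest element only (ties go to the
leftmost element in genome order), and a window straddling an element
edge is classified internal vs flank by its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import FeatureRecord, GenomicInterval
from .windows import WindowTable

DEFAULT_TRACKS = ("mCG", "mCHG", "mCHH", "chip_count")


@dataclass
class ProfileResult:
    """Per-bin track means with contributing-observation counts."""

    mode: str  # relative | absolute_5prime | absolute_3prime
    df: pd.DataFrame  # bin_index, bin_center[, segment], mean_<t>, n_<t>

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def mean(self, track: str) -> np.ndarray:
        return self.df[f"mean_{track}"].to_numpy()

    def n(self, track: str) -> np.ndarray:
        return self.df[f"n_{track}"].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "mode", self.mode)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


class _BinAccumulator:
    """Accumulates (bin, value) observations per track, NaN-aware."""

    def __init__(self, n_bins: int, tracks: Sequence[str]):
        self.n_bins = n_bins
        self.tracks = list(tracks)
        self.sums = {t: np.zeros(n_bins) for t in tracks}
        self.counts = {t: np.zeros(n_bins, dtype=np.int64) for t in tracks}

    def add(self, bins: np.ndarray, windows: WindowTable, window_idx: np.ndarray) -> None:
        for t in self.tracks:
            vals = windows.track(t)[window_idx]
            ok = ~np.isnan(vals)
            np.add.at(self.sums[t], bins[ok], vals[ok])
            np.add.at(self.counts[t], bins[ok], 1)

    def result(self, mode: str, centers: np.ndarray, extra: dict | None = None) -> ProfileResult:
        data: dict = {"bin_index": np.arange(1, self.n_bins + 1), "bin_center": centers}
        if extra:
            data.update(extra)
        for t in self.tracks:
            with np.errstate(invalid="ignore"):
                mean = np.where(
                    self.counts[t] > 0, self.sums[t] / np.maximum(self.counts[t], 1), np.nan
                )
            data[f"mean_{t}"] = mean
            data[f"n_{t}"] = self.counts[t]
        return ProfileResult(mode=mode, df=pd.DataFrame(data))


def _element_intervals(elements: Iterable) -> list[GenomicInterval]:
    out = []
    for e in elements:
        out.append(e.interval if isinstance(e, FeatureRecord) else e)
    return out


def relative_profile(
    windows: WindowTable,
    elements: Sequence,
    flank: int = 1000,
    track_names: Sequence[str] = DEFAULT_TRACKS,
    bins_per_segment: int = 20,
) -> ProfileResult:
    """Scaled-element profile over ``elements`` and ``flank`` bp on each side.

    Internal positions are rescaled to 1..1000 via
    ``scaled = 1 + floor(999 * (mid - start) / (len - 1))`` and flank
    positions keep physical bp distances (negative upstream, positive
    downstream).  Bin conventions are mirror-symmetric: upstream bins are
    left-open, downstream bins right-open, so a planted symmetric signal
    yields symmetric flank bins.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    ivs = _element_intervals(elements)
    if not ivs:
        raise ValueError("no elements supplied")
    n_bins = 3 * bins_per_segment
    acc = _BinAccumulator(n_bins, track_names)
    step = flank / bins_per_segment
    scale_step = 1000 / bins_per_segment

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    total_kept = 0
    for chrom, chrom_ivs in by_chrom.items():
        if chrom not in windows.chrom_sizes:
            continue
        chrom_ivs.sort(key=lambda iv: (iv.start, iv.end))
        starts = np.array([iv.start for iv in chrom_ivs], dtype=float)
        ends = np.array([iv.end for iv in chrom_ivs], dtype=float)

        mask = windows.df["chrom"].to_numpy() == chrom
        widx = np.flatnonzero(mask)
        m = windows.midpoints()[widx]

        # nearest element: candidate left (largest start <= m) vs right
        j = np.searchsorted(starts, m, side="right") - 1
        jl = np.clip(j, 0, len(starts) - 1)
        jr = np.clip(j + 1, 0, len(starts) - 1)
        inside_l = (m >= starts[jl]) & (m < ends[jl]) & (j >= 0)
        dist_l = np.where(inside_l, 0.0, m - (ends[jl] - 1))
        dist_l = np.where(j >= 0, dist_l, np.inf)
        dist_r = np.where(j + 1 < len(starts), starts[jr] - m, np.inf)
        use_left = dist_l <= dist_r  # tie -> leftmost element
        choice = np.where(use_left, jl, jr)
        d = np.where(use_left, dist_l, -(dist_r))
        inside = inside_l & use_left

        keep = inside | (np.abs(d) <= flank)
        if not keep.any():
            continue
        widx_k = widx[keep]
        d_k = d[keep]
        inside_k = inside[keep]
        el = choice[keep]

        bins = np.empty(keep.sum(), dtype=np.int64)
        # upstream flank: left-open bins over (-flank, 0]
        up = ~inside_k & (d_k < 0)
        bins[up] = np.clip(
            np.ceil((d_k[up] + flank) / step).astype(np.int64) - 1, 0, bins_per_segment - 1
        )
        # internal: midpoint clipped into the element, scaled to 1..1000
        if inside_k.any():
            s = starts[el[inside_k]]
            length = ends[el[inside_k]] - s
            mid = np.clip(windows.midpoints()[widx_k[inside_k]], s, s + length - 1)
            scaled = np.where(
                length > 1, 1 + np.floor(999 * (mid - s) / (length - 1)), 500.0
            )
            bins[inside_k] = bins_per_segment + np.clip(
                ((scaled - 1) // scale_step).astype(np.int64), 0, bins_per_segment - 1
            )
        # downstream flank: right-open bins over [0, flank) with closed end
        down = ~inside_k & (d_k > 0)
        bins[down] = 2 * bins_per_segment + np.clip(
            np.floor(d_k[down] / step).astype(np.int64), 0, bins_per_segment - 1
        )
        acc.add(bins, windows, widx_k)
        total_kept += int(keep.sum())

    if total_kept == 0:
        import warnings

        warnings.warn("no window within range of any element; empty profile")
    b = np.arange(n_bins)
    centers = np.concatenate(
        [
            -flank + step * (b[:bins_per_segment] + 0.5),
            scale_step * (b[:bins_per_segment] + 0.5),
            step * (b[:bins_per_segment] + 0.5),
        ]
    )
    segment = (
        ["upstream"] * bins_per_segment
        + ["internal"] * bins_per_segment
        + ["downstream"] * bins_per_segment
    )
    return acc.result("relative", centers, extra={"segment": segment})


def _anchor_points(gene: FeatureRecord, flip_minus: bool) -> tuple[int, int, int]:
    """(tss, tts, sign): 0-based anchor bases and the 5'->3' axis sign."""
    iv = gene.interval
    if iv.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.feature_id} has no strand")
    if iv.strand == "-" and flip_minus:
        return iv.end - 1, iv.start, -1
    return iv.start, iv.end - 1, 1


def _absolute(
    windows: WindowTable,
    genes: Sequence[FeatureRecord],
    anchor: str,
    upstream: int,
    into_gene: int,
    track_names: Sequence[str],
    n_bins: int,
    flip_minus: bool,
    exclude_genic: np.ndarray | None,
    restrict_genic: dict[str, list[tuple[int, int]]] | None,
    per_gene_average: bool,
) -> ProfileResult:
    """Shared engine for the 5' (TSS) and 3' (TTS) plots.

    Axis runs 5'->3': for the TSS plot from -upstream to +into_gene, for
    the TTS plot from -into_gene to +upstream (negative = genic side).
    ``exclude_genic`` is a per-window bool mask dropped from genic bins
    only; ``restrict_genic`` limits genic windows to midpoints inside the
    given per-gene intervals (e.g. exons or introns).
    """
    span = upstream + into_gene
    width = span / n_bins
    acc = _BinAccumulator(n_bins, track_names)
    mids = windows.midpoints()
    gene_accs: list[_BinAccumulator] = []

    for gene in genes:
        tss, tts, sign = _anchor_points(gene, flip_minus)
        iv = gene.interval
        gene_len = len(iv)
        cap = min(into_gene, gene_len)
        anchor_pos = tss if anchor == "tss" else tts
        if anchor == "tss":
            lo_d, hi_d = -upstream, cap  # keep lo_d <= d < hi_d
        else:
            lo_d, hi_d = -cap, upstream
        # physical extent touched by this gene's plot
        if sign > 0:
            phys_lo, phys_hi = anchor_pos + lo_d, anchor_pos + hi_d
        else:
            phys_lo, phys_hi = anchor_pos - hi_d + 1, anchor_pos - lo_d + 1
        if iv.chrom not in windows.chrom_sizes:
            continue
        rng = windows.window_indices(iv.chrom, int(phys_lo) - 1, int(phys_hi) + 1)
        if len(rng) == 0:
            continue
        widx = np.arange(rng.start, rng.stop)
        d = sign * (mids[widx] - anchor_pos)
        keep = (d >= lo_d) & (d < hi_d)
        genic = d >= 0 if anchor == "tss" else d <= 0
        if exclude_genic is not None:
            keep &= ~(genic & exclude_genic[widx])
        if restrict_genic is not None:
            allowed = np.zeros(len(widx), dtype=bool)
            for s, e in restrict_genic.get(gene.feature_id, []):
                allowed |= (mids[widx] >= s) & (mids[widx] < e)
            keep &= ~genic | allowed
        if not keep.any():
            continue
        offset = upstream if anchor == "tss" else into_gene
        bins = np.clip(((d[keep] + offset) // width).astype(np.int64), 0, n_bins - 1)
        target = _BinAccumulator(n_bins, track_names) if per_gene_average else acc
        target.add(bins, windows, widx[keep])
        if per_gene_average:
            gene_accs.append(target)

    offset = upstream if anchor == "tss" else into_gene
    centers = -offset + width * (np.arange(n_bins) + 0.5)
    mode = "absolute_5prime" if anchor == "tss" else "absolute_3prime"
    if not per_gene_average:
        return acc.result(mode, centers)
    # gene-first averaging: mean over genes of each gene's per-bin mean
    data: dict = {"bin_index": np.arange(1, n_bins + 1), "bin_center": centers}
    for t in track_names:
        means = np.full((len(gene_accs), n_bins), np.nan)
        for i, ga in enumerate(gene_accs):
            ok = ga.counts[t] > 0
            means[i, ok] = ga.sums[t][ok] / ga.counts[t][ok]
        n_genes = np.sum(~np.isnan(means), axis=0)
        with np.errstate(invalid="ignore"):
            data[f"mean_{t}"] = np.nanmean(means, axis=0) if len(gene_accs) else np.full(n_bins, np.nan)
        data[f"n_{t}"] = n_genes
    return ProfileResult(mode=mode, df=pd.DataFrame(data))


def absolute_gene_profile(
    windows: WindowTable,
    genes: Sequence[FeatureRecord],
    upstream: int = 2000,
    into_gene: int = 3000,
    track_names: Sequence[str] = DEFAULT_TRACKS,
    n_bins: int = 100,
    flip_minus: bool = True,
    per_gene_average: bool = False,
) -> tuple[ProfileResult, ProfileResult]:
    """TSS- and TTS-anchored physical-distance profiles (a pair of plots)."""
    args = (windows, genes)
    kw = dict(
        upstream=upstream,
        into_gene=into_gene,
        track_names=track_names,
        n_bins=n_bins,
        flip_minus=flip_minus,
        exclude_genic=None,
        restrict_genic=None,
        per_gene_average=per_gene_average,
    )
    return (
        _absolute(*args, anchor="tss", **kw),
        _absolute(*args, anchor="tts", **kw),
    )


def masked_profile(
    windows: WindowTable,
    genes: Sequence[FeatureRecord],
    mask_features: Sequence[FeatureRecord] = (),
    track_names: Sequence[str] = DEFAULT_TRACKS,
    upstream: int = 2000,
    into_gene: int = 3000,
    n_bins: int = 100,
    flip_minus: bool = True,
    restrict_to: dict[str, list[tuple[int, int]]] | None = None,
    per_gene_average: bool = False,
) -> tuple[ProfileResult, ProfileResult]:
    """Absolute profiles with windows overlapping ``mask_features`` dropped
    from genic bins (flank bins unaffected); ``restrict_to`` optionally
    limits genic windows to per-gene interval lists (exons or introns)."""
    exclude = np.zeros(len(windows), dtype=bool)
    for feat in mask_features:
        iv = feat.interval if isinstance(feat, FeatureRecord) else feat
        if iv.chrom not in windows.chrom_sizes:
            continue
        rng = windows.window_indices(iv.chrom, iv.start, iv.end)
        exclude[rng.start: rng.stop] = True
    args = (windows, genes)
    kw = dict(
        upstream=upstream,
        into_gene=into_gene,
        track_names=track_names,
        n_bins=n_bins,
        flip_minus=flip_minus,
        exclude_genic=exclude,
        restrict_genic=restrict_to,
        per_gene_average=per_gene_average,
    )
    return (
        _absolute(*args, anchor="tss", **kw),
        _absolute(*args, anchor="tts", **kw),
    )


def grouped_profiles(
    windows: WindowTable,
    genes: Sequence[FeatureRecord],
    group_by: str,
    **kwargs,
) -> dict[str, tuple[ProfileResult, ProfileResult]]:
    """Absolute profiles computed independently per gene-metadata label."""
    if genes and not hasattr(genes[0], group_by):
        raise ValueError(f"unknown gene metadata field {group_by!r}")
    groups: dict[str, list[FeatureRecord]] = {}
    for g in genes:
        label = getattr(g, group_by)
        groups.setdefault(str(label), []).append(g)
    return {
        label: absolute_gene_profile(windows, members, **kwargs)
        for label, members in sorted(groups.items())
    }


__all__ = [
    "DEFAULT_TRACKS",
    "ProfileResult",
    "relative_profile",
    "absolute_gene_profile",
    "masked_profile",
    "grouped_profiles",
]
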