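"""TE-centric chromatin summaries.

Sub-family means pool windows (window-weighted): all windows overlapping
any member element of a sub-family by >= 1 bp contribute once to that
sub-family, and a window overlapping elements of two sub-families
contributes to both (intersect semantics; no nesting resolution).
Flank statistics use fixed distance bands (900-1000 bp by default) on
each side of every element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import FeatureRecord, GenomicInterval, derive_introns
from .profiles import DEFAULT_TRACKS, ProfileResult, relative_profile
from .windows import WindowTable

logger = logging.getLogger(__name__)

TE_CLASSES = ("TIR", "LINE", "LTR")


@dataclass
class GenicTE:
    """A TE fully contained in one intron of a host gene."""

    te: FeatureRecord
    host_gene_id: str
    containing_intron: GenomicInterval
    te_length: int


def _window_set(windows: WindowTable, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    """Sorted unique global indices of windows overlapping any interval."""
    hit = np.zeros(len(windows), dtype=bool)
    for iv in intervals:
        if iv.chrom not in windows.chrom_sizes:
            continue
        rng = windows.window_indices(iv.chrom, iv.start, iv.end)
        hit[rng.start: rng.stop] = True
    return np.flatnonzero(hit)


def _track_means(
    windows: WindowTable, idx: np.ndarray, tracks: Sequence[str]
) -> dict[str, float | int]:
    out: dict[str, float | int] = {}
    for t in tracks:
        vals = windows.track(t)[idx]
        vals = vals[~np.isnan(vals)]
        out[f"mean_{t}"] = float(vals.mean()) if vals.size else np.nan
        out[f"n_{t}"] = int(vals.size)
    return out


def _group_tes(
    tes: Sequence[FeatureRecord], group_field: str, split_spreading: bool
) -> dict[str, list[FeatureRecord]]:
    if tes and not hasattr(tes[0], group_field):
        raise ValueError(f"unknown group_field {group_field!r}")
    groups: dict[str, list[FeatureRecord]] = {}
    for te in tes:
        label = str(getattr(te, group_field))
        if split_spreading:
            label = f"{label}/{te.spreading}"
        groups.setdefault(label, []).append(te)
    return groups


def subfamily_summary(
    windows: WindowTable,
    tes: Sequence[FeatureRecord],
    group_field: str = "te_subfamily",
    track_names: Sequence[str] = DEFAULT_TRACKS,
    split_spreading: bool = False,
    near: int = 900,
    far: int = 1000,
) -> pd.DataFrame:
    """Internal and flank-band track means per TE sub-family.

    One row per sub-family (or sub-family/spreading split), columns
    ``mean_<t>`` / ``n_<t>`` for internal windows plus ``flank_up_<t>``,
    ``flank_down_<t>`` and flank window counts.
    """
    groups = _group_tes(tes, group_field, split_spreading)
    flanks = flank_summary(
        windows, tes, near=near, far=far, group_field=group_field,
        track_names=track_names, split_spreading=split_spreading,
    ).set_index("group")
    rows = []
    for label, members in sorted(groups.items()):
        idx = _window_set(windows, [m.interval for m in members])
        row: dict = {"group": label, "n_elements": len(members),
                     "n_windows_internal": len(idx)}
        row.update(_track_means(windows, idx, track_names))
        frow = flanks.loc[label]
        for t in track_names:
            row[f"flank_up_{t}"] = frow[f"up_mean_{t}"]
            row[f"flank_down_{t}"] = frow[f"down_mean_{t}"]
        row["n_windows_flank"] = int(frow["n_windows_up"] + frow["n_windows_down"])
        rows.append(row)
    return pd.DataFrame(rows)


def flank_bands(
    te: FeatureRecord, near: int = 900, far: int = 1000
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Upstream band [start-far, start-near) and downstream [end+near, end+far)."""
    if near >= far:
        raise ValueError(f"need near < far, got {near} >= {far}")
    iv = te.interval
    up = None
    if iv.start - near > 0:
        up = GenomicInterval(iv.chrom, max(iv.start - far, 0), iv.start - near)
    down = GenomicInterval(iv.chrom, iv.end + near, iv.end + far)
    return up, down


def flank_summary(
    windows: WindowTable,
    tes: Sequence[FeatureRecord],
    near: int = 900,
    far: int = 1000,
    group_field: str = "te_subfamily",
    track_names: Sequence[str] = DEFAULT_TRACKS,
    split_spreading: bool = False,
    exclude_te_overlap: bool = False,
) -> pd.DataFrame:
    """Mean track levels in the near-far bp bands flanking each sub-family.

    A window qualifies by >= 1 bp overlap with a band.  Upstream and
    downstream means are reported separately and pooled.  With
    ``exclude_te_overlap`` a band colliding with any other TE is dropped
    (useful for clean spreading contrasts).
    """
    groups = _group_tes(tes, group_field, split_spreading)
    te_cov = None
    if exclude_te_overlap:
        te_cov = np.zeros(len(windows), dtype=bool)
        for te in tes:
            iv = te.interval
            if iv.chrom not in windows.chrom_sizes:
                continue
            rng = windows.window_indices(iv.chrom, iv.start, iv.end)
            te_cov[rng.start: rng.stop] = True
    rows = []
    for label, members in sorted(groups.items()):
        ups, downs = [], []
        for te in members:
            up, down = flank_bands(te, near, far)
            for band, dest in ((up, ups), (down, downs)):
                if band is None or band.chrom not in windows.chrom_sizes:
                    continue
                if band.start >= windows.chrom_sizes[band.chrom]:
                    continue
                idx = np.array(
                    list(windows.window_indices(band.chrom, band.start, band.end)),
                    dtype=np.int64,
                )
                if te_cov is not None and te_cov[idx].any():
                    continue
                dest.append(idx)
        up_idx = np.unique(np.concatenate(ups)) if ups else np.array([], dtype=np.int64)
        down_idx = np.unique(np.concatenate(downs)) if downs else np.array([], dtype=np.int64)
        both_idx = np.unique(np.concatenate([up_idx, down_idx]))
        row: dict = {
            "group": label,
            "n_windows_up": len(up_idx),
            "n_windows_down": len(down_idx),
        }
        for prefix, idx in (("up", up_idx), ("down", down_idx), ("pooled", both_idx)):
            means = _track_means(windows, idx, track_names)
            for t in track_names:
                row[f"{prefix}_mean_{t}"] = means[f"mean_{t}"]
        rows.append(row)
    return pd.DataFrame(rows)


def nearest_gene_distance(
    tes: Sequence[FeatureRecord],
    genes: Sequence[FeatureRecord],
    group_field: str = "te_subfamily",
) -> tuple[pd.DataFrame, pd.Series]:
    """bp gap from each TE to its nearest gene (0 when overlapping).

    Returns (per-TE table, per-sub-family mean distance).  TEs on
    chromosomes without genes get NaN.
    """
    if not tes or not genes:
        raise ValueError("both TE and gene sets must be non-empty")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append((g.interval.start, g.interval.end))
    sorted_arr = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        sorted_arr[chrom] = (
            np.array([s for s, _ in spans]), np.array([e for _, e in spans])
        )
    rows = []
    for te in tes:
        iv = te.interval
        if iv.chrom not in sorted_arr:
            dist = np.nan
        else:
            starts, ends = sorted_arr[iv.chrom]
            # gap to each gene; overlap -> 0
            gaps = np.maximum(starts - iv.end, iv.start - ends)
            dist = float(max(gaps.min(), 0))
        rows.append(
            {"te_id": te.feature_id, "group": str(getattr(te, group_field)), "distance": dist}
        )
    df = pd.DataFrame(rows)
    return df, df.groupby("group")["distance"].mean()


def genic_te_catalog(
    tes: Sequence[FeatureRecord],
    genes: Sequence[FeatureRecord],
    exons: Sequence[FeatureRecord],
    min_len: int = 1000,
) -> tuple[list[GenicTE], set[str]]:
    """TEs strictly longer than ``min_len`` fully contained in an intron.

    Returns the (gene, intron, TE) catalog and the flagged host-gene id
    set.  TEs that overlap a gene but straddle an exon-intron boundary
    (or poke out of the gene) are excluded and counted in the log.
    """
    catalog: list[GenicTE] = []
    flagged: set[str] = set()
    n_boundary = 0
    gene_introns = {g.feature_id: (g, derive_introns(g, exons)) for g in genes}
    for te in tes:
        te_len = len(te.interval)
        for gene_id, (gene, introns) in gene_introns.items():
            if not te.interval.overlaps(gene.interval):
                continue
            contained = next(
                (intron for intron in introns if intron.contains(te.interval)), None
            )
            if contained is None:
                n_boundary += 1
                continue
            if te_len > min_len:
                catalog.append(
                    GenicTE(
                        te=te,
                        host_gene_id=gene_id,
                        containing_intron=contained,
                        te_length=te_len,
                    )
                )
                flagged.add(gene_id)
    if n_boundary:
        logger.info(
            "%d gene-overlapping TEs excluded (not fully contained in one intron)",
            n_boundary,
        )
    return catalog, flagged


def genic_te_chromatin(
    windows: WindowTable,
    catalog: Sequence[GenicTE],
    all_tes: Sequence[FeatureRecord],
    exons: Sequence[FeatureRecord],
    track_names: Sequence[str] = DEFAULT_TRACKS,
) -> pd.DataFrame:
    """Track means over three region classes: all TEs, genic TEs, exons."""
    region_sets = {
        "all_TEs": [te.interval for te in all_tes],
        "genic_TEs": [g.te.interval for g in catalog],
        "exons": [e.interval for e in exons],
    }
    rows = []
    for name, ivs in region_sets.items():
        idx = _window_set(windows, ivs)
        row: dict = {"region": name, "n_windows": len(idx)}
        row.update(_track_means(windows, idx, track_names))
        rows.append(row)
    return pd.DataFrame(rows)


def genic_te_profile(
    windows: WindowTable,
    catalog: Sequence[GenicTE],
    flank: int = 1000,
    track_names: Sequence[str] = DEFAULT_TRACKS,
) -> ProfileResult:
    """Relative profile restricted to cataloged genic TEs."""
    return relative_profile(
        windows, [g.te for g in catalog], flank=flank, track_names=track_names
    )


def class_enrichment_in_genes(
    catalog: Sequence[GenicTE], all_tes: Sequence[FeatureRecord]
) -> pd.DataFrame:
    """TE-class composition of genic TEs vs the genome-wide TE set.

    Proportion vectors over {TIR, LINE, LTR} each sum to 1; the ratio
    column is genic / genome-wide (NaN when the genome proportion is 0).
    """
    def _props(classes: list[str]) -> np.ndarray:
        counts = np.array([classes.count(c) for c in TE_CLASSES], dtype=float)
        total = counts.sum()
        return counts / total if total else np.full(len(TE_CLASSES), np.nan)

    genic = _props([g.te.te_class for g in catalog if g.te.te_class in TE_CLASSES])
    genome = _props([t.te_class for t in all_tes if t.te_class in TE_CLASSES])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(genome > 0, genic / genome, np.nan)
    return pd.DataFrame(
        {
            "te_class": TE_CLASSES,
            "genic_proportion": genic,
            "genome_proportion": genome,
            "ratio": ratio,
        }
    )


__all__ = [
    "TE_CLASSES",
    "GenicTE",
    "subfamily_summary",
    "flank_bands",
    "flank_summary",
    "nearest_gene_distance",
    "genic_te_catalog",
    "genic_te_chromatin",
    "genic_te_profile",
    "class_enrichment_in_genes",
]
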