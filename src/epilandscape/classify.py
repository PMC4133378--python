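"""Chromatin-state classification and expression grouping.

* CHG x CHH heatmap: windows with data on all three marks (CHG level,
  CHH level, ChIP count) are cross-tabulated into 10 CHG bins x 9 CHH
  bins and the mean ChIP count per cell reported.
* TSS classification: a gene's promoter state is read from the single
  100 bp tile overlapping its TSS; "high CHG" means above the empirical
  top-decile boundary of all genome-wide window CHG levels (the cutoff
  is data-derived, never hard-coded) and "high H3K9me2" means more than
  ``k`` SDs above the genome-wide mean window read sum.
* Expression: RPKM per replicate averaged, then five categories (not
  expressed + four expressed quartiles of equal size +/- 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import ExpressionRecord, FeatureRecord
from .windows import SignificanceThreshold, WindowTable, significance_threshold

EXPR_CATEGORIES = ("not_expressed", "Q1", "Q2", "Q3", "Q4")

# CHH percent bin edges: 1%-steps to 5%, 5%-steps to 20%, then >20%.
CHH_EDGES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 15.0, 20.0, 100.0)
N_CHG_BINS = 10
N_CHH_BINS = 9


def chg_bin(level: float) -> int:
    """1..10 decile bin of a CHG level in [0, 1]; top edge closed."""
    return min(N_CHG_BINS - 1, int(level * 100 // 10)) + 1


def chh_bin(level: float) -> int:
    """1..9 bin of a CHH level in [0, 1] on the uneven percent edges;
    bin 8 is [15%, 20%] (closed so the edges partition) and bin 9 is
    (20%, 100%]."""
    pct = level * 100
    if pct > 20:
        return 9
    inner = CHH_EDGES[1:-1]
    return min(int(np.searchsorted(inner, pct, side="right")), 7) + 1


def chg_chh_heatmap(windows: WindowTable) -> pd.DataFrame:
    """10 x 9 grid of mean ChIP counts over CHG x CHH level bins.

    Only windows with a defined level in both non-CG contexts contribute;
    all 90 cells are emitted, with NaN means where n_windows == 0.
    """
    chg = windows.track("mCHG")
    chh = windows.track("mCHH")
    chip = windows.track("chip_count")
    ok = ~np.isnan(chg) & ~np.isnan(chh) & ~np.isnan(chip)
    cbins = np.minimum((chg[ok] * 10).astype(np.int64), N_CHG_BINS - 1)
    pct = chh[ok] * 100
    hbins = np.searchsorted(CHH_EDGES[1:-1], pct, side="right")  # 0..8
    hbins[pct == 20.0] = 7  # top edge of bin 8 closed, bin 9 is strictly >20%
    cell = cbins * N_CHH_BINS + hbins
    sums = np.zeros(N_CHG_BINS * N_CHH_BINS)
    counts = np.zeros(N_CHG_BINS * N_CHH_BINS, dtype=np.int64)
    np.add.at(sums, cell, chip[ok])
    np.add.at(counts, cell, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    grid = pd.DataFrame(
        {
            "chg_bin": np.repeat(np.arange(1, N_CHG_BINS + 1), N_CHH_BINS),
            "chh_bin": np.tile(np.arange(1, N_CHH_BINS + 1), N_CHG_BINS),
            "mean_chip": means,
            "n_windows": counts,
        }
    )
    return grid


def tss_position(gene: FeatureRecord) -> int:
    """0-based TSS coordinate: start for + strand, end-1 for - strand."""
    iv = gene.interval
    if iv.strand == "+":
        return iv.start
    if iv.strand == "-":
        return iv.end - 1
    raise ValueError(f"gene {gene.feature_id} has no strand")


def tss_window_index(gene: FeatureRecord, windows: WindowTable) -> int:
    """Global index of the unique tile containing the gene's TSS."""
    pos = tss_position(gene)
    try:
        return windows.window_index(gene.interval.chrom, pos)
    except (KeyError, IndexError) as exc:
        raise ValueError(
            f"TSS of gene {gene.feature_id} ({gene.interval.chrom}:{pos}) "
            "outside tiled genome"
        ) from exc


def tss_window(gene: FeatureRecord, windows: WindowTable) -> pd.Series:
    """The window row overlapping the gene's TSS."""
    return windows.df.iloc[tss_window_index(gene, windows)]


@dataclass
class TssClassification:
    """High-CHG / high-H3K9me2 TSS gene sets with realized cutoffs."""

    high_chg: set[str]
    high_k9: set[str]
    chg_cutoff: float
    k9_threshold: SignificanceThreshold
    set_stats: pd.DataFrame = field(repr=False)

    @property
    def overlap(self) -> set[str]:
        return self.high_chg & self.high_k9


def high_tss_genes(
    genes: list[FeatureRecord],
    windows: WindowTable,
    chg_quantile: float = 0.90,
    k9_sd_mult: float = 2.0,
) -> TssClassification:
    """Flag genes whose TSS tile exceeds genome-wide CHG / ChIP cutoffs.

    The CHG cutoff is the empirical ``chg_quantile`` quantile of every
    defined window CHG level genome-wide; the ChIP cutoff is the mean +
    ``k9_sd_mult`` * sd of all window read sums.  Both flags use strict >.
    """
    if not genes:
        raise ValueError("no genes supplied")
    chg_all = windows.track("mCHG")
    chg_all = chg_all[~np.isnan(chg_all)]
    if chg_all.size == 0:
        raise ValueError("no window has a defined CHG level")
    chg_cutoff = float(np.quantile(chg_all, chg_quantile))
    k9_thr = significance_threshold(windows.track("chip_count"), k9_sd_mult)

    chg_track = windows.track("mCHG")
    chip_track = windows.track("chip_count")
    high_chg: set[str] = set()
    high_k9: set[str] = set()
    tss_chg: dict[str, float] = {}
    tss_chip: dict[str, float] = {}
    for gene in genes:
        idx = tss_window_index(gene, windows)
        chg = chg_track[idx]
        chip = chip_track[idx]
        tss_chg[gene.feature_id] = chg
        tss_chip[gene.feature_id] = chip
        if not np.isnan(chg) and chg > chg_cutoff:
            high_chg.add(gene.feature_id)
        if chip > k9_thr.cutoff:
            high_k9.add(gene.feature_id)

    def _stats(ids: set[str]) -> dict:
        chg_vals = np.array([tss_chg[g] for g in ids])
        chip_vals = np.array([tss_chip[g] for g in ids])
        return {
            "n": len(ids),
            "mean_chg": float(np.nanmean(chg_vals)) if len(ids) else np.nan,
            "mean_chip": float(np.nanmean(chip_vals)) if len(ids) else np.nan,
        }

    stats = pd.DataFrame(
        [
            {"set": "high_chg", **_stats(high_chg)},
            {"set": "high_k9", **_stats(high_k9)},
            {"set": "overlap", **_stats(high_chg & high_k9)},
            {"set": "all_genes", **_stats(set(tss_chg))},
        ]
    )
    return TssClassification(
        high_chg=high_chg,
        high_k9=high_k9,
        chg_cutoff=chg_cutoff,
        k9_threshold=k9_thr,
        set_stats=stats,
    )


def compute_rpkm(
    records: list[ExpressionRecord], replicate_policy: str = "mean"
) -> pd.Series:
    """Reads per kilobase per million mapped, averaged over replicates.

    Per-replicate library size is the column sum over all genes; a
    replicate with zero mapped reads is an error.  Records carrying a
    precomputed rpkm pass through unchanged.
    """
    if replicate_policy not in ("mean", "median"):
        raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
    precomputed = {r.gene_id: r.rpkm for r in records if r.rpkm is not None}
    counted = [r for r in records if r.counts_per_replicate is not None]
    out: dict[str, float] = dict(precomputed)
    if counted:
        mat = np.array([r.counts_per_replicate for r in counted], dtype=float)
        lib_sizes = mat.sum(axis=0)
        if np.any(lib_sizes == 0):
            bad = int(np.flatnonzero(lib_sizes == 0)[0]) + 1
            raise ValueError(f"replicate {bad} has zero total mapped reads")
        lengths_kb = np.array([r.gene_length_bp for r in counted], dtype=float) / 1000
        per_rep = mat / lengths_kb[:, None] / (lib_sizes[None, :] / 1e6)
        agg = per_rep.mean(axis=1) if replicate_policy == "mean" else np.median(per_rep, axis=1)
        for r, v in zip(counted, agg):
            out[r.gene_id] = float(v)
    return pd.Series(out, name="rpkm")


def expression_groups(rpkm: pd.Series, floor: float = 0.0) -> pd.Series:
    """Five categories: not_expressed (rpkm <= floor) + 4 equal quartiles.

    Expressed genes are ranked by (rpkm, gene_id) — gene-id order breaks
    ties deterministically — and cut into quartiles whose sizes differ by
    at most 1 (Q1 = lowest expression).
    """
    groups = pd.Series("not_expressed", index=rpkm.index, name="expr_group")
    expressed = rpkm[rpkm > floor]
    order = sorted(expressed.index, key=lambda g: (expressed[g], str(g)))
    for qi, chunk in enumerate(np.array_split(np.array(order, dtype=object), 4)):
        groups.loc[list(chunk)] = f"Q{qi + 1}"
    return groups


def classify_genes(
    genes: list[FeatureRecord],
    windows: WindowTable,
    rpkm: pd.Series,
    expr_group: pd.Series,
    tss: TssClassification,
    genic_te_genes: set[str],
) -> pd.DataFrame:
    """Assemble the per-gene classification table (one row per gene)."""
    rows = []
    for gene in genes:
        idx = tss_window_index(gene, windows)
        win = windows.df.iloc[idx]
        gid = gene.feature_id
        rows.append(
            {
                "gene_id": gid,
                "rpkm": float(rpkm.get(gid, np.nan)),
                "expr_group": expr_group.get(gid, "not_expressed"),
                "high_chg_tss": gid in tss.high_chg,
                "high_k9_tss": gid in tss.high_k9,
                "has_genic_te": gid in genic_te_genes,
                "tss_window_chrom": win["chrom"],
                "tss_window_start": int(win["start"]),
                "tss_window_end": int(win["end"]),
            }
        )
    return pd.DataFrame(rows)


def class_expression_crosstab(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-flag proportions over the five expression categories.

    One row per flag (plus an ``all_genes`` background row); proportions
    sum to 1 when the flagged set is non-empty, NaN otherwise.
    """
    flags = ["has_genic_te", "high_chg_tss", "high_k9_tss"]
    rows = []
    for name, subset in [("all_genes", classification)] + [
        (f, classification[classification[f]]) for f in flags
    ]:
        n = len(subset)
        row: dict = {"flag": name, "n": n}
        for cat in EXPR_CATEGORIES:
            row[cat] = (subset["expr_group"] == cat).sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "EXPR_CATEGORIES",
    "CHH_EDGES",
    "chg_bin",
    "chh_bin",
    "chg_chh_heatmap",
    "tss_position",
    "tss_window_index",
    "tss_window",
    "TssClassification",
    "high_tss_genes",
    "compute_rpkm",
    "expression_groups",
    "classify_genes",
    "class_expression_crosstab",
]
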