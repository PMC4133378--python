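"""Synthetic genome, methylome, ChIP and expression generator.

Every emitted record traces back to a planted parameter: TE families
carry per-context methylation probabilities and a ChIP intensity, gene
bodies and background have their own regimes, and selected genes get a
planted high-CHG or high-ChIP TSS tile.  The returned manifest records
all planted truth so downstream analyses can be validated against it.

Noise model: per-cytosine read depth ~ Poisson(coverage); methylated
reads ~ Binomial(depth, p at that position).  ChIP reads are fixed-length
single-end; start positions form an inhomogeneous Poisson process whose
intensity is scaled so that the expected number of reads *overlapping*
any window inside a feature equals the feature's ``chip_rate``.

Cytosine sites are placed at uniform random positions at configured
per-context densities; context is a site label (the analysis consumes
contexts, not sequence, so no FASTA is involved).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (
    ChipRead,
    CytosineRecord,
    ExpressionRecord,
    FeatureRecord,
    GenomicInterval,
    te_class_from_code,
    write_chip_bed,
    write_cytosine_report,
    write_expression_table,
)

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class TEFamilyConfig:
    """Planted parameters for one TE family."""

    code: str
    n_elements: int
    length_range: tuple[int, int]
    p_cg: float
    p_chg: float
    p_chh: float
    chip_rate: float  # expected reads over a 100 bp window inside the element
    spreading: str = "none"  # none | linear_decay
    spread_distance: int = 0

    def p(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}[context]


@dataclass
class RegimeConfig:
    """Methylation probabilities + ChIP rate for background or gene bodies."""

    p_cg: float
    p_chg: float
    p_chh: float
    chip_rate: float

    def p(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}[context]


@dataclass
class ExpressionConfig:
    log_mean: float = 1.0
    log_sigma: float = 1.2
    fraction_silent: float = 0.2
    n_replicates: int = 3
    depth_per_replicate: float = 2e6
    suppression_factor: float = 1.0  # multiplier for planted high-TSS-mark genes


@dataclass
class SimConfig:
    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    n_genes: int = 60
    exons_per_gene: int = 4
    gene_length_range: tuple[int, int] = (2500, 4000)
    te_families: list[TEFamilyConfig] = field(default_factory=list)
    genic_te_fraction: float = 0.1
    genic_te_length_range: tuple[int, int] = (1200, 2500)
    genic_te_family_weights: dict[str, float] | None = None
    background: RegimeConfig = field(
        default_factory=lambda: RegimeConfig(0.40, 0.30, 0.02, 2.0)
    )
    gene_body: RegimeConfig = field(
        default_factory=lambda: RegimeConfig(0.55, 0.05, 0.01, 1.0)
    )
    coverage: float = 20.0
    cytosine_density: dict[str, float] = field(
        default_factory=lambda: {"CG": 6.0, "CHG": 5.0, "CHH": 10.0}
    )
    read_length: int = 50
    window_size: int = 100
    gap_range: tuple[int, int] = (2200, 3200)
    n_high_chg_tss_genes: int = 0
    n_high_k9_tss_genes: int = 0
    n_high_both_tss_genes: int = 0
    tss_chg_p: float = 0.95
    tss_k9_rate: float = 40.0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        for fam in self.te_families:
            for p in (fam.p_cg, fam.p_chg, fam.p_chh):
                if not 0 <= p <= 1:
                    raise ValueError(f"family {fam.code}: probability {p} outside [0,1]")
            if fam.length_range[0] <= 0 or fam.length_range[0] > fam.length_range[1]:
                raise ValueError(f"family {fam.code}: bad length_range")
        if not 0 <= self.genic_te_fraction <= 1:
            raise ValueError("genic_te_fraction outside [0,1]")
        if self.coverage < 0 or self.window_size <= 0 or self.read_length <= 0:
            raise ValueError("coverage/window_size/read_length must be non-negative")


def default_config(seed: int = 0) -> SimConfig:
    """A paper-like regime: two LTR families (high CHG + ChIP, one with
    flank spreading), a high-CHH/low-ChIP TIR family, a low-CHH TIR
    family and a LINE family."""
    return SimConfig(
        seed=seed,
        te_families=[
            TEFamilyConfig("RLG", 25, (3000, 5000), 0.90, 0.85, 0.04, 30.0,
                           spreading="linear_decay", spread_distance=1000),
            TEFamilyConfig("RLC", 25, (3000, 5000), 0.90, 0.80, 0.04, 25.0),
            TEFamilyConfig("DTA", 30, (600, 1400), 0.80, 0.60, 0.15, 3.0),
            TEFamilyConfig("DTM", 20, (600, 1400), 0.70, 0.50, 0.03, 5.0),
            TEFamilyConfig("RIL", 10, (1000, 2000), 0.85, 0.70, 0.04, 20.0),
        ],
        n_high_chg_tss_genes=4,
        n_high_k9_tss_genes=4,
        n_high_both_tss_genes=2,
        expression=ExpressionConfig(suppression_factor=0.05),
    )


def graded_chg_config(seed: int = 0) -> SimConfig:
    """A gene-free regime with a 10 x 5 grid of TE families spanning CHG
    levels 0.05..0.95 and CHH levels 0.5%..4.5%, so every low-CHH heatmap
    cell is well populated.  Pair with ``simulate_chip(rate_from_chg=...)``
    to plant a chip ~ CHG relation."""
    families = []
    for i, p_chg in enumerate(0.05 + 0.1 * np.arange(10)):
        for j, p_chh in enumerate(0.005 + 0.01 * np.arange(5)):
            families.append(
                TEFamilyConfig(
                    code=f"DTA{i}{j}",
                    n_elements=10,
                    length_range=(1600, 2000),
                    p_cg=0.6,
                    p_chg=round(float(p_chg), 3),
                    p_chh=round(float(p_chh), 4),
                    chip_rate=0.0,  # unused: chip is coupled to CHG
                )
            )
    return SimConfig(
        seed=seed,
        chrom_sizes={"chr1": 1_400_000},
        n_genes=0,
        te_families=families,
        genic_te_fraction=0.0,
        background=RegimeConfig(0.40, 0.45, 0.025, 0.0),
        gap_range=(600, 1000),
        n_high_chg_tss_genes=0,
        n_high_k9_tss_genes=0,
        n_high_both_tss_genes=0,
    )


def tss_benchmark_config(seed: int = 0, n_genes: int = 1000,
                         n_high_chg: int = 50) -> SimConfig:
    """1,000 short genes with a planted high-CHG TSS subset (p ~ 0.95
    against ~0.05 gene/background CHG) plus enough high-CHG TE windows
    that the genome-wide top decile lands inside the TE level cluster."""
    return SimConfig(
        seed=seed,
        chrom_sizes={"chr1": 950_000, "chr2": 950_000},
        n_genes=n_genes,
        exons_per_gene=2,
        gene_length_range=(800, 1200),
        te_families=[
            TEFamilyConfig("RLG", 150, (1800, 2200), 0.90, 0.90, 0.03, 20.0),
        ],
        genic_te_fraction=0.0,
        background=RegimeConfig(0.40, 0.05, 0.02, 2.0),
        gene_body=RegimeConfig(0.55, 0.05, 0.01, 1.0),
        cytosine_density={"CG": 6.0, "CHG": 8.0, "CHH": 10.0},
        gap_range=(300, 600),
        n_high_chg_tss_genes=n_high_chg,
        n_high_k9_tss_genes=0,
        n_high_both_tss_genes=0,
        tss_chg_p=0.95,
        expression=ExpressionConfig(fraction_silent=0.2, suppression_factor=0.0),
    )


@dataclass
class SimManifest:
    """All planted truth for one simulated dataset."""

    config: SimConfig
    genes: list[FeatureRecord]
    exons: list[FeatureRecord]
    tes: list[FeatureRecord]
    te_family_of: dict[str, str]  # te_id -> family code
    genic_te_of: dict[str, str]  # host gene_id -> te_id
    high_chg_genes: set[str]
    high_k9_genes: set[str]
    planted_rpkm: dict[str, float] = field(default_factory=dict)
    silent_genes: set[str] = field(default_factory=set)
    paths: dict[str, str] = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.config.chrom_sizes

    def family(self, code: str) -> TEFamilyConfig:
        for fam in self.config.te_families:
            if fam.code == code:
                return fam
        raise KeyError(code)

    def tss_tile(self, gene: FeatureRecord) -> tuple[int, int]:
        """The window-aligned tile containing the gene's TSS."""
        w = self.config.window_size
        tss = gene.interval.start if gene.interval.strand == "+" else gene.interval.end - 1
        lo = (tss // w) * w
        return lo, min(lo + w, self.chrom_sizes[gene.interval.chrom])

    def to_json(self, path: str | Path) -> None:
        def _feat(f: FeatureRecord) -> dict:
            return {
                "chrom": f.interval.chrom,
                "start": f.interval.start,
                "end": f.interval.end,
                "strand": f.interval.strand,
                "kind": f.kind,
                "id": f.feature_id,
                "parent": f.parent_id,
                "te_subfamily": f.te_subfamily,
                "spreading": f.spreading,
            }

        payload = {
            "config": asdict(self.config),
            "genes": [_feat(g) for g in self.genes],
            "exons": [_feat(e) for e in self.exons],
            "tes": [_feat(t) for t in self.tes],
            "te_family_of": self.te_family_of,
            "genic_te_of": self.genic_te_of,
            "high_chg_genes": sorted(self.high_chg_genes),
            "high_k9_genes": sorted(self.high_k9_genes),
            "planted_rpkm": self.planted_rpkm,
            "silent_genes": sorted(self.silent_genes),
            "paths": self.paths,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

@dataclass
class _GeneSpec:
    exon_lengths: list[int]
    intron_lengths: list[int]
    te_intron: int | None = None  # index into intron_lengths
    te_length: int = 0
    te_family: str = ""

    @property
    def length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


def _draw_gene_spec(rng: np.random.Generator, config: SimConfig,
                    te_len: int | None, te_family: str) -> _GeneSpec:
    n_exons = config.exons_per_gene
    target = int(rng.integers(*config.gene_length_range))
    exon_each = max(100, int(0.35 * target / n_exons))
    exon_lengths = [
        int(rng.integers(int(0.7 * exon_each), int(1.3 * exon_each) + 1))
        for _ in range(n_exons)
    ]
    remaining = max(target - sum(exon_lengths), 200 * max(n_exons - 1, 1))
    intron_each = remaining // max(n_exons - 1, 1)
    intron_lengths = [
        int(rng.integers(int(0.7 * intron_each), int(1.3 * intron_each) + 1))
        for _ in range(n_exons - 1)
    ]
    spec = _GeneSpec(exon_lengths, intron_lengths)
    if te_len is not None:
        idx = int(rng.integers(0, len(intron_lengths)))
        spec.intron_lengths[idx] = te_len + 200  # 100 bp margin each side
        spec.te_intron = idx
        spec.te_length = te_len
        spec.te_family = te_family
    return spec


def simulate_genome(config: SimConfig) -> SimManifest:
    """Place non-overlapping genes and TEs on the configured chromosomes.

    A deterministic round(genic_te_fraction * n_genes) of the genes get
    one intronic TE each.  Raises when the requested features cannot be
    packed with the minimum gap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fam_by_code = {f.code: f for f in config.te_families}

    n_genic = round(config.genic_te_fraction * config.n_genes)
    codes = list(fam_by_code)
    if config.genic_te_family_weights and codes:
        w = np.array([config.genic_te_family_weights.get(c, 0.0) for c in codes])
        w = w / w.sum()
    else:
        w = np.full(len(codes), 1 / len(codes)) if codes else None

    gene_specs: list[_GeneSpec] = []
    for i in range(config.n_genes):
        if i < n_genic and codes:
            te_len = int(rng.integers(*config.genic_te_length_range))
            fam = codes[int(rng.choice(len(codes), p=w))]
            gene_specs.append(_draw_gene_spec(rng, config, te_len, fam))
        else:
            gene_specs.append(_draw_gene_spec(rng, config, None, ""))

    blocks: list[tuple[str, object]] = [("gene", s) for s in gene_specs]
    for fam in config.te_families:
        for _ in range(fam.n_elements):
            length = int(rng.integers(fam.length_range[0], fam.length_range[1] + 1))
            blocks.append(("te", (fam.code, length)))

    def _block_len(b) -> int:
        return b[1].length if b[0] == "gene" else b[1][1]

    need = sum(_block_len(b) for b in blocks) + config.gap_range[0] * (len(blocks) + 1)
    capacity = sum(config.chrom_sizes.values())
    if need > capacity:
        raise ValueError(
            f"infeasible packing: need >= {need} bp but genome has {capacity} bp"
        )

    order = rng.permutation(len(blocks))
    chroms = list(config.chrom_sizes)
    chrom_i = 0
    cursor = int(rng.integers(*config.gap_range))
    genes: list[FeatureRecord] = []
    exons: list[FeatureRecord] = []
    tes: list[FeatureRecord] = []
    te_family_of: dict[str, str] = {}
    genic_te_of: dict[str, str] = {}
    fam_counter = {c: 0 for c in fam_by_code}
    gene_counter = 0

    def _place(length: int) -> tuple[str, int] | None:
        nonlocal chrom_i, cursor
        while chrom_i < len(chroms):
            chrom = chroms[chrom_i]
            if cursor + length + config.gap_range[0] <= config.chrom_sizes[chrom]:
                start = cursor
                cursor += length + int(rng.integers(*config.gap_range))
                return chrom, start
            chrom_i += 1
            cursor = int(rng.integers(*config.gap_range))
        return None

    def _new_te(code: str, chrom: str, start: int, end: int) -> FeatureRecord:
        fam_counter[code] += 1
        te_id = f"{code}{fam_counter[code]:05d}"
        fam = fam_by_code[code]
        te_family_of[te_id] = code
        return FeatureRecord(
            interval=GenomicInterval(chrom, start, end, "+"),
            kind="TE",
            feature_id=te_id,
            te_class=te_class_from_code(code) or "unknown",
            te_subfamily=code,
            spreading="spreading" if fam.spreading != "none" else "non_spreading",
        )

    for bi in order:
        kind, payload = blocks[bi]
        length = _block_len(blocks[bi])
        placed = _place(length)
        if placed is None:
            raise ValueError("infeasible packing: ran out of genome during placement")
        chrom, start = placed
        if kind == "te":
            code, _ = payload  # type: ignore[misc]
            tes.append(_new_te(code, chrom, start, start + length))
            continue
        spec: _GeneSpec = payload  # type: ignore[assignment]
        gene_counter += 1
        gene_id = f"gene{gene_counter:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene = FeatureRecord(
            interval=GenomicInterval(chrom, start, start + spec.length, strand),
            kind="gene",
            feature_id=gene_id,
            gene_set="FGS",
            synteny="syntenic" if rng.random() < 0.5 else "inserted",
            subgenome="sg1" if rng.random() < 0.5 else "sg2",
        )
        genes.append(gene)
        pos = start
        for ei, exon_len in enumerate(spec.exon_lengths):
            exons.append(
                FeatureRecord(
                    interval=GenomicInterval(chrom, pos, pos + exon_len, strand),
                    kind="exon",
                    feature_id=f"{gene_id}.exon{ei + 1}",
                    parent_id=gene_id,
                )
            )
            pos += exon_len
            if ei < len(spec.intron_lengths):
                if spec.te_intron == ei:
                    te_start = pos + 100
                    te = _new_te(spec.te_family, chrom, te_start, te_start + spec.te_length)
                    tes.append(te)
                    genic_te_of[gene_id] = te.feature_id
                pos += spec.intron_lengths[ei]

    # planted high-TSS-mark gene sets: disjoint "both", "chg only", "k9 only"
    n_marked = (config.n_high_both_tss_genes + config.n_high_chg_tss_genes
                + config.n_high_k9_tss_genes)
    if n_marked > len(genes):
        raise ValueError("more planted high-TSS genes requested than genes exist")
    picked = rng.choice(len(genes), size=n_marked, replace=False) if n_marked else []
    picked_ids = [genes[i].feature_id for i in picked]
    nb = config.n_high_both_tss_genes
    nc = config.n_high_chg_tss_genes
    high_chg = set(picked_ids[:nb + nc])
    high_k9 = set(picked_ids[:nb]) | set(picked_ids[nb + nc:])

    return SimManifest(
        config=config,
        genes=genes,
        exons=exons,
        tes=tes,
        te_family_of=te_family_of,
        genic_te_of=genic_te_of,
        high_chg_genes=high_chg,
        high_k9_genes=high_k9,
    )


# ---------------------------------------------------------------------------
# planted per-bp parameter fields
# ---------------------------------------------------------------------------

def _p_arrays(manifest: SimManifest) -> dict[str, dict[str, np.ndarray]]:
    """Per-chrom, per-context methylation probability at every bp.

    Painting priority (later overwrites earlier): background < gene body
    < TE flank decay (intergenic spreading TEs only) < TE interior <
    planted TSS tiles.  Genic TEs get no flank decay, so their
    boundaries stay sharp.
    """
    config = manifest.config
    genic_te_ids = set(manifest.genic_te_of.values())
    arrays: dict[str, dict[str, np.ndarray]] = {}
    for chrom, size in manifest.chrom_sizes.items():
        arrays[chrom] = {
            ctx: np.full(size, config.background.p(ctx), dtype=np.float32)
            for ctx in CONTEXTS
        }
    for gene in manifest.genes:
        iv = gene.interval
        for ctx in CONTEXTS:
            arrays[iv.chrom][ctx][iv.start: iv.end] = config.gene_body.p(ctx)
    for te in manifest.tes:
        fam = manifest.family(manifest.te_family_of[te.feature_id])
        iv = te.interval
        size = manifest.chrom_sizes[iv.chrom]
        if fam.spreading == "linear_decay" and fam.spread_distance > 0 \
                and te.feature_id not in genic_te_ids:
            d = np.arange(1, fam.spread_distance + 1, dtype=np.float32)
            frac = d / fam.spread_distance
            for ctx in CONTEXTS:
                p_fam, p_bg = fam.p(ctx), config.background.p(ctx)
                decay = p_fam + (p_bg - p_fam) * frac
                lo = max(iv.start - fam.spread_distance, 0)
                arrays[iv.chrom][ctx][lo: iv.start] = decay[::-1][-(iv.start - lo):] \
                    if iv.start > lo else arrays[iv.chrom][ctx][lo: iv.start]
                hi = min(iv.end + fam.spread_distance, size)
                arrays[iv.chrom][ctx][iv.end: hi] = decay[: hi - iv.end]
        for ctx in CONTEXTS:
            arrays[iv.chrom][ctx][iv.start: iv.end] = fam.p(ctx)
    for gene in manifest.genes:
        if gene.feature_id in manifest.high_chg_genes:
            lo, hi = manifest.tss_tile(gene)
            arrays[gene.interval.chrom]["CHG"][lo:hi] = config.tss_chg_p
    return arrays


def _chip_rate_array(manifest: SimManifest) -> dict[str, np.ndarray]:
    """Expected reads per window at every bp (same painting priority)."""
    config = manifest.config
    rates: dict[str, np.ndarray] = {}
    for chrom, size in manifest.chrom_sizes.items():
        rates[chrom] = np.full(size, config.background.chip_rate, dtype=np.float32)
    for gene in manifest.genes:
        iv = gene.interval
        rates[iv.chrom][iv.start: iv.end] = config.gene_body.chip_rate
    for te in manifest.tes:
        fam = manifest.family(manifest.te_family_of[te.feature_id])
        iv = te.interval
        rates[iv.chrom][iv.start: iv.end] = fam.chip_rate
    for gene in manifest.genes:
        if gene.feature_id in manifest.high_k9_genes:
            lo, hi = manifest.tss_tile(gene)
            # a read overlapping the tile can start up to read_length-1 bp
            # left of it; widen the painted band so the expected number of
            # reads overlapping the tile equals the planted rate
            lo = max(lo - (config.read_length - 1), 0)
            rates[gene.interval.chrom][lo:hi] = config.tss_k9_rate
    return rates


# ---------------------------------------------------------------------------
# data generators
# ---------------------------------------------------------------------------

def simulate_methylome(manifest: SimManifest) -> list[CytosineRecord]:
    """Per-cytosine calls: sites uniform at configured densities, depth ~
    Poisson(coverage), methylated reads ~ Binomial(depth, planted p)."""
    config = manifest.config
    rng = np.random.default_rng((config.seed, 1))
    p_arrays = _p_arrays(manifest)
    records: list[CytosineRecord] = []
    for chrom, size in manifest.chrom_sizes.items():
        per_ctx = []
        for ctx in CONTEXTS:
            n_sites = int(round(config.cytosine_density[ctx] * size / 100))
            n_sites = min(n_sites, size)
            pos = rng.choice(size, size=n_sites, replace=False)
            pos.sort()
            strand = rng.random(n_sites) < 0.5
            depth = rng.poisson(config.coverage, size=n_sites)
            p = p_arrays[chrom][ctx][pos].astype(float)
            meth = rng.binomial(depth, p)
            per_ctx.append((pos, strand, depth, meth, ctx))
        merged = sorted(
            (
                (int(pos[i]), bool(strand[i]), int(depth[i]), int(meth[i]), ctx)
                for pos, strand, depth, meth, ctx in per_ctx
                for i in range(len(pos))
            ),
        )
        for pos, plus, depth, meth, ctx in merged:
            records.append(
                CytosineRecord(
                    chrom=chrom,
                    pos=pos,
                    strand="+" if plus else "-",
                    context=ctx,
                    n_meth=meth,
                    n_total=depth,
                    covered=depth > 0,
                )
            )
    return records


def simulate_chip(
    manifest: SimManifest,
    rate_from_chg: tuple[float, float] | None = None,
) -> list[ChipRead]:
    """Fixed-length single-end reads from an inhomogeneous Poisson process.

    With ``rate_from_chg=(base, slope)`` the per-window rate is coupled to
    the planted CHG probability field (rate = base + slope * p_CHG)
    instead of the per-feature rates.
    """
    config = manifest.config
    rng = np.random.default_rng((config.seed, 2))
    rl = config.read_length
    if rate_from_chg is not None:
        base, slope = rate_from_chg
        p_arrays = _p_arrays(manifest)
        rate_arrays = {
            chrom: base + slope * p_arrays[chrom]["CHG"]
            for chrom in manifest.chrom_sizes
        }
    else:
        rate_arrays = _chip_rate_array(manifest)
    reads: list[ChipRead] = []
    # a read overlaps a given window iff its start lies in a
    # (window_size + rl - 1)-bp band, so scale intensity accordingly
    denom = config.window_size + rl - 1
    for chrom, size in manifest.chrom_sizes.items():
        lam = rate_arrays[chrom].astype(np.float64) / denom
        total = lam.sum()
        if total <= 0:
            continue
        n_reads = rng.poisson(total)
        if n_reads == 0:
            continue
        starts = rng.choice(size, size=n_reads, p=lam / total)
        starts.sort()
        for s in starts:
            s = int(s)
            reads.append(ChipRead(GenomicInterval(chrom, s, min(s + rl, size))))
    return reads


def simulate_expression(manifest: SimManifest) -> list[ExpressionRecord]:
    """Replicate counts whose realized RPKM matches a planted log-normal
    draw in expectation; a configured fraction is exactly silent and
    planted high-TSS-mark genes are optionally suppressed."""
    config = manifest.config
    expr = config.expression
    rng = np.random.default_rng((config.seed, 3))
    genes = manifest.genes
    n = len(genes)
    planted = rng.lognormal(expr.log_mean, expr.log_sigma, size=n)
    marked = manifest.high_chg_genes | manifest.high_k9_genes
    unmarked_idx = [i for i, g in enumerate(genes) if g.feature_id not in marked]
    n_silent = round(expr.fraction_silent * n)
    silent_idx = set(
        int(i) for i in rng.choice(
            unmarked_idx, size=min(n_silent, len(unmarked_idx)), replace=False
        )
    )
    records: list[ExpressionRecord] = []
    for i, gene in enumerate(genes):
        value = planted[i]
        if i in silent_idx:
            value = 0.0
        if gene.feature_id in marked:
            value *= expr.suppression_factor
        manifest.planted_rpkm[gene.feature_id] = float(value)
        if value == 0.0:
            manifest.silent_genes.add(gene.feature_id)
        length = len(gene.interval)
        lam = value * (length / 1000) * (expr.depth_per_replicate / 1e6)
        counts = rng.poisson(lam, size=expr.n_replicates)
        records.append(
            ExpressionRecord(
                gene_id=gene.feature_id,
                counts_per_replicate=[int(c) for c in counts],
                gene_length_bp=length,
            )
        )
    return records


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_gff3(manifest: SimManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in manifest.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for gene in manifest.genes:
            iv = gene.interval
            attrs = (
                f"ID={gene.feature_id};gene_set={gene.gene_set};"
                f"synteny={gene.synteny};subgenome={gene.subgenome}"
            )
            fh.write(
                f"{iv.chrom}\tsynth\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for exon in manifest.exons:
                if exon.parent_id != gene.feature_id:
                    continue
                eiv = exon.interval
                fh.write(
                    f"{eiv.chrom}\tsynth\texon\t{eiv.start + 1}\t{eiv.end}\t.\t"
                    f"{eiv.strand}\t.\tID={exon.feature_id};Parent={gene.feature_id}\n"
                )


def write_te_bed(manifest: SimManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in manifest.tes:
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.feature_id}\t.\t"
                f"{iv.strand}\t{te.te_subfamily}\t{te.spreading}\n"
            )


def simulate_all(config: SimConfig, outdir: str | Path) -> SimManifest:
    """Run all four generators and emit every input file + manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = simulate_genome(config)
    cytosines = simulate_methylome(manifest)
    reads = simulate_chip(manifest)
    expression = simulate_expression(manifest)

    paths = {
        "gff3": outdir / "genes.gff3",
        "te_bed": outdir / "tes.bed",
        "cytosine_report": outdir / "cytosines.tsv",
        "chip_bed": outdir / "chip.bed",
        "expression": outdir / "expression.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_gff3(manifest, paths["gff3"])
    write_te_bed(manifest, paths["te_bed"])
    write_cytosine_report(cytosines, paths["cytosine_report"])
    write_chip_bed(reads, paths["chip_bed"])
    write_expression_table(expression, paths["expression"])
    # basenames, so manifests from identical seeds are byte-identical
    # regardless of where the dataset was written
    manifest.paths = {k: v.name for k, v in paths.items()}
    manifest.to_json(paths["manifest"])
    return manifest


def config_from_dict(data: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML/JSON) mapping."""
    data = dict(data)
    if "te_families" in data:
        data["te_families"] = [
            f if isinstance(f, TEFamilyConfig) else TEFamilyConfig(**{
                **f, "length_range": tuple(f["length_range"])
            })
            for f in data["te_families"]
        ]
    for key in ("background", "gene_body"):
        if key in data and not isinstance(data[key], RegimeConfig):
            data[key] = RegimeConfig(**data[key])
    if "expression" in data and not isinstance(data["expression"], ExpressionConfig):
        data["expression"] = ExpressionConfig(**data["expression"])
    for key in ("gene_length_range", "genic_te_length_range", "gap_range"):
        if key in data:
            data[key] = tuple(data[key])
    return SimConfig(**data)


__all__ = [
    "TEFamilyConfig",
    "RegimeConfig",
    "ExpressionConfig",
    "SimConfig",
    "SimManifest",
    "default_config",
    "graded_chg_config",
    "tss_benchmark_config",
    "simulate_genome",
    "simulate_methylome",
    "simulate_chip",
    "simulate_expression",
    "simulate_all",
    "write_gff3",
    "write_te_bed",
    "config_from_dict",
]
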