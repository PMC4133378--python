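"""Domain types and plain-text I/O.

Single source of coordinate conventions: everything in memory is 0-based,
half-open (BED style).  Readers convert at the boundary (the cytosine
report and GFF3 are 1-based inclusive on disk) and writers convert back.
All readers transparently handle gzip-compressed input by file extension.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

VALID_CONTEXTS = ("CG", "CHG", "CHH")

# sub-family code prefix -> TE class.  Codes follow the three-letter
# wicker-style convention (RL* = LTR retros, RI*/RS* = LINE/SINE-like,
# DT* = TIR DNA transposons); a "-nc" suffix marks non-coding variants.
_CLASS_PREFIXES = (
    ("RL", "LTR"),
    ("RI", "LINE"),
    ("RS", "LINE"),
    ("DT", "TIR"),
    ("DH", "TIR"),
)


def te_class_from_code(code: str | None) -> str | None:
    """Infer the coarse TE class (LTR / LINE / TIR) from a sub-family code."""
    if code is None:
        return None
    base = code.upper().removesuffix("-NC")
    if base.startswith("LINE"):
        return "LINE"
    for prefix, klass in _CLASS_PREFIXES:
        if base.startswith(prefix):
            return klass
    return None


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine site with its context and read support.

    ``covered`` is False when the site's total read count fell below the
    reader's ``min_coverage``; such records are retained but flagged so
    downstream code can exclude them.
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    n_meth: int
    n_total: int
    covered: bool = True

    def __post_init__(self) -> None:
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError(
                f"need 0 <= n_meth <= n_total, got {self.n_meth}/{self.n_total}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class FeatureRecord:
    """A gene, exon or TE with its classification metadata."""

    interval: GenomicInterval
    kind: str  # gene | exon | TE
    feature_id: str
    parent_id: str | None = None
    te_class: str | None = None
    te_subfamily: str | None = None
    spreading: str = "unknown"  # spreading | non_spreading | unknown
    gene_set: str | None = None  # FGS | WGS
    synteny: str = "unknown"  # syntenic | inserted | unknown
    subgenome: str = "unknown"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "exon", "TE"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "exon" and self.parent_id is None:
            raise ValueError(f"exon {self.feature_id} has no parent gene id")
        if self.kind == "TE" and self.te_class is None:
            raise ValueError(f"TE {self.feature_id} has no te_class")


@dataclass(frozen=True)
class ChipRead:
    interval: GenomicInterval


@dataclass
class ExpressionRecord:
    gene_id: str
    counts_per_replicate: Sequence[int] | None = None
    rpkm: float | None = None
    gene_length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.counts_per_replicate is None and self.rpkm is None:
            raise ValueError(f"gene {self.gene_id}: need counts or rpkm")
        if self.counts_per_replicate is not None and (
            self.gene_length_bp is None or self.gene_length_bp <= 0
        ):
            raise ValueError(f"gene {self.gene_id}: counts require gene_length_bp > 0")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path: str | Path, min_coverage: int = 1
) -> Iterator[CytosineRecord]:
    """Stream cytosine records from a 7-column report.

    On-disk columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide.  Positions are shifted to
    0-based; records with fewer than ``min_coverage`` reads are yielded
    with ``covered=False`` rather than dropped.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: unparseable line {lineno}: {line!r}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            if context not in VALID_CONTEXTS:
                raise ValueError(
                    f"{path}: unknown context {context!r} on line {lineno}"
                )
            try:
                pos = int(pos_s) - 1
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparseable line {lineno}: {line!r}"
                ) from exc
            n_total = n_meth + n_unmeth
            yield CytosineRecord(
                chrom=chrom,
                pos=pos,
                strand=strand,
                context=context,
                n_meth=n_meth,
                n_total=n_total,
                covered=n_total >= min_coverage,
            )


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Inverse of :func:`read_cytosine_report` (positions back to 1-based)."""
    tri = {"CG": "CGA", "CHG": "CAG", "CHH": "CTA"}
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.n_meth}\t"
                f"{r.n_total - r.n_meth}\t{r.context}\t{tri[r.context]}\n"
            )


# ---------------------------------------------------------------------------
# annotation (GFF3 genes/exons + TE BED)
# ---------------------------------------------------------------------------

def _parse_gff_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Read gene and exon features from a GFF3 file.

    Exons must carry a ``Parent`` attribute naming a gene in the same
    file; other feature types (mRNA etc.) are ignored.  Gene attributes
    ``gene_set``, ``synteny`` and ``subgenome`` are picked up when present.
    """
    genes: dict[str, FeatureRecord] = {}
    exons: list[FeatureRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: bad GFF3 line {lineno}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols[:9]
            if ftype not in ("gene", "exon"):
                continue
            attrs = _parse_gff_attributes(attrs_s)
            interval = GenomicInterval(chrom, int(start_s) - 1, int(end_s), strand)
            if ftype == "gene":
                fid = attrs.get("ID")
                if fid is None:
                    raise ValueError(f"{path}: gene without ID on line {lineno}")
                if fid in genes:
                    raise ValueError(f"{path}: duplicate gene id {fid!r}")
                genes[fid] = FeatureRecord(
                    interval=interval,
                    kind="gene",
                    feature_id=fid,
                    gene_set=attrs.get("gene_set"),
                    synteny=attrs.get("synteny", "unknown"),
                    subgenome=attrs.get("subgenome", "unknown"),
                )
            else:
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(
                        f"{path}: exon without Parent gene on line {lineno}"
                    )
                exons.append(
                    FeatureRecord(
                        interval=interval,
                        kind="exon",
                        feature_id=attrs.get("ID", f"exon:{lineno}"),
                        parent_id=parent,
                    )
                )
    for exon in exons:
        if exon.parent_id not in genes:
            raise ValueError(
                f"{path}: exon {exon.feature_id} references unknown gene "
                f"{exon.parent_id!r}"
            )
    return list(genes.values()) + exons


def read_sequence_regions(gff3_path: str | Path) -> dict[str, int]:
    """Chromosome sizes from ``##sequence-region`` GFF3 headers (may be empty)."""
    sizes: dict[str, int] = {}
    with _open_text(gff3_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    return sizes


def read_te_bed(path: str | Path) -> list[FeatureRecord]:
    """Read TE records from BED6+2 (name, score, strand, sub-family, spreading).

    The sub-family code (column 7) is carried verbatim; the coarse class
    is inferred from the code prefix.  Columns 7 and 8 are optional: with
    only 4+ columns the name is used as the sub-family code.
    """
    tes: list[FeatureRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: bad BED line {lineno}")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"TE:{lineno}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            subfam = cols[6] if len(cols) > 6 else name
            spreading = cols[7] if len(cols) > 7 else "unknown"
            if spreading not in ("spreading", "non_spreading", "unknown"):
                raise ValueError(
                    f"{path}: bad spreading class {spreading!r} on line {lineno}"
                )
            if name in seen:
                raise ValueError(f"{path}: duplicate TE id {name!r}")
            seen.add(name)
            tes.append(
                FeatureRecord(
                    interval=GenomicInterval(chrom, start, end, strand),
                    kind="TE",
                    feature_id=name,
                    te_class=te_class_from_code(subfam) or "unknown",
                    te_subfamily=subfam,
                    spreading=spreading,
                )
            )
    return tes


def read_features(
    gff3_path: str | Path, te_bed_path: str | Path
) -> list[FeatureRecord]:
    """Load genes + exons from GFF3 and TEs from BED into one feature list."""
    return read_gff3(gff3_path) + read_te_bed(te_bed_path)


def derive_introns(
    gene: FeatureRecord, exons: Sequence[FeatureRecord]
) -> list[GenomicInterval]:
    """Complement of a gene's exons within the gene span (0-based half-open)."""
    spans = sorted(
        (e.interval.start, e.interval.end)
        for e in exons
        if e.parent_id == gene.feature_id
    )
    introns: list[GenomicInterval] = []
    cursor = gene.interval.start
    for start, end in spans:
        if start > cursor:
            introns.append(
                GenomicInterval(gene.interval.chrom, cursor, start, gene.interval.strand)
            )
        cursor = max(cursor, end)
    if cursor < gene.interval.end:
        introns.append(
            GenomicInterval(
                gene.interval.chrom, cursor, gene.interval.end, gene.interval.strand
            )
        )
    return introns


# ---------------------------------------------------------------------------
# ChIP reads (BED3+)
# ---------------------------------------------------------------------------

def read_chip_bed(path: str | Path) -> list[ChipRead]:
    """Read aligned ChIP reads from BED3+; output sorted by (chrom, start).

    Duplicate removal is assumed done upstream; a warning is logged when
    more than 10% of reads are exact-interval duplicates.
    """
    reads: list[ChipRead] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: bad BED line {lineno}")
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(
                    f"{path}: start >= end on line {lineno} ({start} >= {end})"
                )
            reads.append(ChipRead(GenomicInterval(cols[0], start, end)))
    reads.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    if reads:
        uniq = len({(r.interval.chrom, r.interval.start, r.interval.end) for r in reads})
        dup_frac = 1 - uniq / len(reads)
        if dup_frac > 0.10:
            logger.warning(
                "%.1f%% of ChIP reads are exact-interval duplicates; "
                "deduplication is expected upstream",
                100 * dup_frac,
            )
    return reads


def write_chip_bed(reads: Iterable[ChipRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\n")


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV of gene_id, replicate counts, length (header required).

    A header containing an ``rpkm`` column is read as precomputed RPKM
    instead; otherwise every column between ``gene_id`` and ``length``
    is a replicate count column.
    """
    records: list[ExpressionRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lower = [h.lower() for h in header]
        if "rpkm" in lower:
            rpkm_idx = lower.index("rpkm")
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if not cols[0]:
                    continue
                records.append(
                    ExpressionRecord(gene_id=cols[0], rpkm=float(cols[rpkm_idx]))
                )
            return records
        if "length" not in lower:
            raise ValueError(f"{path}: expression header needs 'length' or 'rpkm'")
        len_idx = lower.index("length")
        count_idx = [
            i for i in range(1, len(header)) if i != len_idx
        ]
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if not cols[0]:
                continue
            records.append(
                ExpressionRecord(
                    gene_id=cols[0],
                    counts_per_replicate=[int(cols[i]) for i in count_idx],
                    gene_length_bp=int(cols[len_idx]),
                )
            )
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    records = list(records)
    if not records:
        raise ValueError("no expression records to write")
    n_reps = len(records[0].counts_per_replicate or [])
    with _open_text(path, "wt") as fh:
        reps = "\t".join(f"rep{i + 1}" for i in range(n_reps))
        fh.write(f"gene_id\t{reps}\tlength\n")
        for r in records:
            counts = "\t".join(str(c) for c in (r.counts_per_replicate or []))
            fh.write(f"{r.gene_id}\t{counts}\t{r.gene_length_bp}\n")


# ---------------------------------------------------------------------------
# window table
# ---------------------------------------------------------------------------

WINDOW_TABLE_COLUMNS = [
    "chrom", "start", "end",
    "mCG", "mCHG", "mCHH",
    "sum_meth_CG", "sum_total_CG", "n_sites_CG",
    "sum_meth_CHG", "sum_total_CHG", "n_sites_CHG",
    "sum_meth_CHH", "sum_total_CHH", "n_sites_CHH",
    "chip_count", "location",
]


def write_window_table(windows, path: str | Path) -> None:
    """Write a window table to TSV; missing levels serialized as ``NA``.

    ``windows`` is a :class:`~epilandscape.windows.WindowTable` or a
    pandas DataFrame with its columns.
    """
    df = getattr(windows, "df", windows)
    cols = [c for c in WINDOW_TABLE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, na_rep="NA")


def read_window_table(path: str | Path):
    """Round-trip companion of :func:`write_window_table`."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"])


__all__ = [
    "GenomicInterval",
    "CytosineRecord",
    "FeatureRecord",
    "ChipRead",
    "ExpressionRecord",
    "te_class_from_code",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_gff3",
    "read_te_bed",
    "read_features",
    "derive_introns",
    "read_chip_bed",
    "write_chip_bed",
    "read_expression_table",
    "write_expression_table",
    "read_window_table",
    "write_window_table",
    "WINDOW_TABLE_COLUMNS",
]
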