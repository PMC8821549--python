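"""Readers and writers for the standard formats the pipeline touches.

All coordinates are held internally in the BED convention: 0-based,
half-open ``[start, end)``.  GFF3, which is 1-based inclusive, is converted
at the boundary (``start - 1``, ``end``).  Chromosome names are matched by
exact string equality; no ``chr`` aliasing is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ExpressionRecord",
    "TermAnnotation",
    "FormatError",
    "read_peaks",
    "write_peaks",
    "read_gff3_genes",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "write_tsv",
]


class FormatError(ValueError):
    """A file did not conform to the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding interval from one replicate of one sample.

    ``height`` carries the pileup signal (narrowPeak signalValue);
    ``summit_offset`` is the summit position relative to ``interval.start``
    (narrowPeak column 10; the ``-1`` sentinel maps to ``None``).
    """

    interval: GenomicInterval
    height: float = 0.0
    summit_offset: Optional[int] = None
    sample_id: Optional[str] = None
    replicate_id: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"negative peak height {self.height}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of width "
                f"{self.interval.width}"
            )

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class GeneModel:
    """A gene-body span (introns included) with strand and identifiers."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene T3 response in wild type and TRα knockout.

    Each genotype carries a log2 fold change (+T3 over −T3) and an FDR;
    either pair may be absent (``None``) when the gene was not measured.
    """

    gene_id: str
    log2fc_wt: Optional[float] = None
    fdr_wt: Optional[float] = None
    log2fc_ko: Optional[float] = None
    fdr_ko: Optional[float] = None

    def __post_init__(self) -> None:
        for label, fdr in (("wt", self.fdr_wt), ("ko", self.fdr_ko)):
            if fdr is not None and not (0.0 <= fdr <= 1.0):
                raise ValueError(
                    f"{self.gene_id}: fdr_{label}={fdr} outside [0, 1]"
                )


@dataclass(frozen=True)
class TermAnnotation:
    """A named gene set (GO term, pathway, ...) from a GMT file."""

    term_id: str
    term_name: str
    gene_ids: frozenset

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"term {self.term_id} has no genes")


# ---------------------------------------------------------------------------
# Peak files (narrowPeak / BED)
# ---------------------------------------------------------------------------


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what}: {text!r}") from None


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise FormatError(f"line {lineno}: non-numeric {what}: {text!r}") from None
    if math.isnan(value):
        raise FormatError(f"line {lineno}: NaN {what}")
    return value


def read_peaks(
    path,
    format: str = "narrowPeak",
    sample_id: Optional[str] = None,
    replicate_id: Optional[str] = None,
) -> list[Peak]:
    """Read a narrowPeak (BED6+4) or plain BED file into :class:`Peak` records.

    narrowPeak column 7 (signalValue) becomes ``height`` and column 10 the
    summit offset (``-1`` → absent).  Plain BED peaks get height 0.  Records
    are returned sorted by (chrom, start, end).
    """
    if format not in ("narrowPeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if format == "narrowPeak":
                if len(cols) != 10:
                    raise FormatError(
                        f"line {lineno}: narrowPeak requires 10 columns, "
                        f"found {len(cols)}"
                    )
            elif len(cols) < 3:
                raise FormatError(
                    f"line {lineno}: BED requires at least 3 columns, "
                    f"found {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if start >= end:
                raise FormatError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            if format == "narrowPeak":
                height = _parse_float(cols[6], "signalValue", lineno)
                summit = _parse_int(cols[9], "summit", lineno)
                summit_offset = None if summit == -1 else summit
            else:
                height = 0.0
                summit_offset = None
            try:
                peaks.append(
                    Peak(
                        interval=interval,
                        height=height,
                        summit_offset=summit_offset,
                        sample_id=sample_id,
                        replicate_id=replicate_id,
                        name=name,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_peaks(path, peaks: Sequence[Peak]) -> None:
    """Write peaks as narrowPeak, sorted by (chrom, start, end)."""
    ordered = sorted(
        peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    with open(path, "w") as fh:
        for i, p in enumerate(ordered):
            summit = -1 if p.summit_offset is None else p.summit_offset
            name = p.name if p.name is not None else f"peak_{i + 1}"
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        name,
                        "0",
                        ".",
                        repr(p.height),
                        "-1",
                        "-1",
                        str(summit),
                    ]
                )
                + "\n"
            )


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write BED3, sorted by (chrom, start, end)."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for part in text.rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_genes(path, feature: str = "gene") -> list[GeneModel]:
    """Read gene models of one feature type from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open
    (``start - 1``, ``end``).  ``gene_id`` comes from the ``ID`` attribute,
    the display symbol from ``Name`` when present.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"line {lineno}: GFF3 requires 9 columns, found {len(cols)}"
                )
            if cols[2] != feature:
                continue
            chrom = cols[0]
            start = _parse_int(cols[3], "start", lineno)
            end = _parse_int(cols[4], "end", lineno)
            strand = cols[6]
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: unsupported strand {strand!r}")
            attrs = _parse_gff3_attributes(cols[8])
            if "ID" not in attrs:
                raise FormatError(f"line {lineno}: missing ID attribute: {line!r}")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            try:
                interval = GenomicInterval(chrom, start - 1, end)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    interval=interval,
                    strand=strand,
                    name=attrs.get("Name"),
                )
            )
    return genes


def write_gff3(path, genes: Sequence[GeneModel], source: str = "trchip") -> None:
    """Write gene models as GFF3 gene features (1-based inclusive)."""
    ordered = sorted(
        genes, key=lambda g: (g.interval.chrom, g.interval.start, g.interval.end)
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ordered:
            attrs = f"ID={g.gene_id}"
            if g.name is not None:
                attrs += f";Name={g.name}"
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        source,
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    sequences: dict = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(path, sequences: Mapping[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

_DEFAULT_EXPR_COLUMNS = {
    "gene_id": "gene_id",
    "log2fc_wt": "log2fc_wt",
    "fdr_wt": "fdr_wt",
    "log2fc_ko": "log2fc_ko",
    "fdr_ko": "fdr_ko",
}


def read_expression_table(
    path, columns: Optional[Mapping[str, str]] = None
) -> list[ExpressionRecord]:
    """Read a TSV of per-gene log2 fold changes and FDR values.

    ``columns`` maps the canonical field names (``gene_id``, ``log2fc_wt``,
    ``fdr_wt``, ``log2fc_ko``, ``fdr_ko``) onto the header names used in the
    file.  Blank cells become absent values.
    """
    colmap = dict(_DEFAULT_EXPR_COLUMNS)
    if columns:
        colmap.update(columns)
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        index = {name: i for i, name in enumerate(header)}
        if colmap["gene_id"] not in index:
            raise FormatError(
                f"missing gene id column {colmap['gene_id']!r} in header {header}"
            )

        def cell(cols, key, lineno):
            col = colmap[key]
            if col not in index or index[col] >= len(cols):
                return None
            text = cols[index[col]].strip()
            if text in ("", "NA", "nan"):
                return None
            return _parse_float(text, key, lineno)

        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            gene_id = cols[index[colmap["gene_id"]]]
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                records.append(
                    ExpressionRecord(
                        gene_id=gene_id,
                        log2fc_wt=cell(cols, "log2fc_wt", lineno),
                        fdr_wt=cell(cols, "fdr_wt", lineno),
                        log2fc_ko=cell(cols, "log2fc_ko", lineno),
                        fdr_ko=cell(cols, "fdr_ko", lineno),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    return records


def write_expression_table(path, records: Sequence[ExpressionRecord]) -> None:
    def fmt(value) -> str:
        return "" if value is None else repr(value)

    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc_wt\tfdr_wt\tlog2fc_ko\tfdr_ko\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            fh.write(
                f"{r.gene_id}\t{fmt(r.log2fc_wt)}\t{fmt(r.fdr_wt)}"
                f"\t{fmt(r.log2fc_ko)}\t{fmt(r.fdr_ko)}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[TermAnnotation]:
    """Read a GMT file: ``term_id <TAB> description <TAB> gene1 <TAB> ...``."""
    terms: list[TermAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"line {lineno}: GMT requires term, description and "
                    f"at least one gene, found {len(cols)} fields"
                )
            genes = frozenset(g for g in cols[2:] if g)
            if not genes:
                raise FormatError(f"line {lineno}: term {cols[0]!r} has no genes")
            terms.append(TermAnnotation(cols[0], cols[1], genes))
    return terms


def write_gmt(path, terms: Sequence[TermAnnotation]) -> None:
    with open(path, "w") as fh:
        for t in sorted(terms, key=lambda t: t.term_id):
            fh.write(
                "\t".join([t.term_id, t.term_name, *sorted(t.gene_ids)]) + "\n"
            )


def write_tsv(path, rows: Sequence[Sequence], header: Sequence[str]) -> None:
    """Write a plain TSV with header; values are str()-formatted."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
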