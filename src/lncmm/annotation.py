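"""Gene-annotation handling: GTF parsing, lncRNA biotype selection, overlap
flagging and anchor ("MM-gene") list resolution.

The annotation layer works at gene level: one :class:`GeneRecord` per
``gene`` feature of a GENCODE-dialect GTF.  Coordinates are kept 1-based
inclusive exactly as read; Ensembl version suffixes are stripped from gene
ids so that RNA-seq and array annotations join on stable identifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GeneRecord",
    "AnchorGeneList",
    "GtfParseError",
    "LNCRNA_BIOTYPES",
    "parse_gtf",
    "write_gtf",
    "write_gene_table",
    "write_bed",
    "select_lncrnas",
    "flag_ambiguous",
    "load_anchor_genes",
]

#: GENCODE biotypes treated as long non-coding RNA.
LNCRNA_BIOTYPES = frozenset(
    {
        "lincRNA",
        "antisense",
        "bidirectional_promoter_lncRNA",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncRNA",
    }
)


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted; carries the line number."""


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene.

    Coordinates are 1-based inclusive (GTF convention); ``gene_id`` has any
    ``.N`` version suffix stripped.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = ""
    is_lncRNA: bool = False
    is_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})"
            )

    @property
    def chrom_key(self) -> str:
        """Chromosome name with any leading 'chr' stripped, for comparisons."""
        return _norm_chrom(self.chrom)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnchorGeneList:
    """An ordered, de-duplicated list of anchor gene symbols with the subset
    that resolved to records of a parsed annotation."""

    symbols: list[str]
    resolved: dict[str, GeneRecord] = field(default_factory=dict)

    @property
    def unresolved(self) -> list[str]:
        return [s for s in self.symbols if s not in self.resolved]

    def __len__(self) -> int:
        return len(self.symbols)


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_VERSION_RE = re.compile(r"\.\d+$")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    # GENCODE GTF attributes: key "value"; pairs separated by "; ".
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str | Path, feature: str = "gene") -> list[GeneRecord]:
    """Parse gene-level records from a GENCODE-dialect GTF file.

    Rows whose feature type differs from *feature* are skipped.  Records are
    returned sorted by (chromosome, start).  Malformed lines or rows missing
    a ``gene_id`` attribute raise :class:`GtfParseError` naming the line.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != feature:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from exc
            attributes = _parse_attributes(attrs)
            if "gene_id" not in attributes:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = _VERSION_RE.sub("", attributes["gene_id"])
            if gene_id in seen:
                raise GtfParseError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                )
            seen.add(gene_id)
            # GENCODE uses gene_type; Ensembl GTFs use gene_biotype.
            biotype = attributes.get("gene_type", attributes.get("gene_biotype", ""))
            symbol = attributes.get("gene_name", gene_id)
            if strand not in {"+", "-", "."}:
                strand = "."
            try:
                rec = GeneRecord(
                    gene_id=gene_id,
                    symbol=symbol,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=biotype,
                    is_lncRNA=biotype in LNCRNA_BIOTYPES,
                )
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom_key, r.start, r.gene_id))
    return records


def write_gtf(records: Iterable[GeneRecord], path: str | Path, source: str = "lncmm") -> None:
    """Write gene records back out as gene-level GTF lines."""
    with Path(path).open("w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.gene_id}"; gene_type "{r.biotype}"; '
                f'gene_name "{r.symbol}";'
            )
            fh.write(
                f"{r.chrom}\t{source}\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Full TSV with every GeneRecord field."""
    cols = [
        "gene_id", "symbol", "chrom", "start", "end",
        "strand", "biotype", "is_lncRNA", "is_ambiguous",
    ]
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene_id, r.symbol, r.chrom, str(r.start), str(r.end),
                        r.strand, r.biotype, str(int(r.is_lncRNA)),
                        str(int(r.is_ambiguous)),
                    ]
                )
                + "\n"
            )


def write_bed(records: Iterable[GeneRecord], path: str | Path) -> None:
    """BED-like TSV: chrom, 0-based half-open start, end, gene_id, biotype, strand."""
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t{r.biotype}\t{r.strand}\n"
            )


def select_lncrnas(
    records: Sequence[GeneRecord],
    biotypes: Iterable[str] = LNCRNA_BIOTYPES,
) -> list[GeneRecord]:
    """Return the records whose biotype is in *biotypes*, marked as lncRNA.

    Order is preserved.  The default biotype set is the six GENCODE long
    non-coding classes used throughout this package.
    """
    bioset = set(biotypes)
    if not bioset:
        raise ValueError("biotype set must be nonempty")
    return [
        replace(r, is_lncRNA=True) for r in records if r.biotype in bioset
    ]


def flag_ambiguous(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Mark genes whose span overlaps any other gene on the same chromosome.

    Overlap is strand-agnostic and symmetric: both members of an overlapping
    pair are flagged.  All records are returned (same order) with
    ``is_ambiguous`` set; downstream stages may restrict to the unambiguous
    subset.
    """
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(records):
        # +1: IntervalTree is half-open, spans are inclusive.
        trees.setdefault(r.chrom_key, IntervalTree()).addi(r.start, r.end + 1, i)
    out: list[GeneRecord] = []
    for i, r in enumerate(records):
        hits = trees[r.chrom_key].overlap(r.start, r.end + 1)
        ambiguous = any(h.data != i for h in hits)
        out.append(replace(r, is_ambiguous=ambiguous))
    return out


def load_anchor_genes(
    path: str | Path, annotation: Sequence[GeneRecord]
) -> AnchorGeneList:
    """Load a one-symbol-per-line (or first-column TSV) anchor gene list and
    resolve each symbol against *annotation* by exact symbol match.

    Duplicates are collapsed keeping first occurrence; unresolved symbols are
    retained in ``symbols`` but absent from ``resolved``.
    """
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    with path.open() as fh:
        for line in fh:
            sym = line.split("\t")[0].strip()
            if not sym or sym in seen:
                continue
            seen.add(sym)
            symbols.append(sym)
    if not symbols:
        raise ValueError(f"{path}: anchor gene list is empty")
    by_symbol: dict[str, GeneRecord] = {}
    for r in annotation:
        by_symbol.setdefault(r.symbol, r)
    resolved = {s: by_symbol[s] for s in symbols if s in by_symbol}
    return AnchorGeneList(symbols=symbols, resolved=resolved)
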