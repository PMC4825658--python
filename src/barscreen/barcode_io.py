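"""Barcode catalogs, concatenated references, and FASTQ I/O.

A barcode catalog maps each gene (systematic name) to one or two ~20 nt
molecular barcodes ("up" and "dn" tags).  Catalogs from two provenances
(a primary design list and a resequenced correction list) can be merged,
with resequenced entries taking precedence; superseded sequences are
retained as alternative match candidates so reads carrying the older
barcode are still assignable.

The concatenated reference (all barcodes joined by runs of ``N``) is kept
for cross-validation with external aligners; the in-package counting path
(:mod:`barscreen.demux_count`) matches barcodes directly.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

Tag = Literal["up", "dn"]


class CatalogFormatError(ValueError):
    """Malformed catalog file (missing columns, bad header)."""


class CatalogValidationError(ValueError):
    """Catalog row content violates an invariant (non-DNA, duplicate gene)."""


class FastqParseError(ValueError):
    """Truncated or inconsistent FASTQ record."""


def _is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _DNA


@dataclass(frozen=True)
class CatalogEntry:
    """One gene's barcode assignment.

    ``alt_uptags``/``alt_dntags`` hold superseded sequences from catalog
    merges; they remain valid match candidates for this gene.
    """

    gene: str
    uptag: str | None = None
    dntag: str | None = None
    source: str = "primary_list"
    alt_uptags: tuple[str, ...] = ()
    alt_dntags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.uptag is None and self.dntag is None:
            raise CatalogValidationError(
                f"gene {self.gene!r}: at least one of uptag/dntag required"
            )
        for name, seq in (("uptag", self.uptag), ("dntag", self.dntag)):
            if seq is not None and not _is_dna(seq):
                raise CatalogValidationError(
                    f"gene {self.gene!r}: {name} {seq!r} is not a plain DNA sequence"
                )
        for seq in self.alt_uptags + self.alt_dntags:
            if not _is_dna(seq):
                raise CatalogValidationError(
                    f"gene {self.gene!r}: alternative barcode {seq!r} is not DNA"
                )

    def barcodes(self, tag: Tag) -> tuple[str, ...]:
        """All match candidates for this gene under ``tag`` (current first)."""
        if tag == "up":
            cur = (self.uptag,) if self.uptag else ()
            return cur + self.alt_uptags
        cur = (self.dntag,) if self.dntag else ()
        return cur + self.alt_dntags


@dataclass(frozen=True)
class AmpliconLayout:
    """Structure of a barcode amplicon read.

    Reads are laid out as ``multiplex_tag + upstream_primer + barcode +
    downstream_primer`` (then adaptor/padding).  The default priming sites
    are configurable stand-ins for the universal barcode-flanking primers;
    any equal-length DNA strings work.
    """

    multiplex_tag_length: int = 6
    upstream_primer: str = "GATGTCCACGAGGTCTCT"
    barcode_length: int = 20
    downstream_primer: str = "CGTACGCTGCAGGTCGAC"

    def __post_init__(self) -> None:
        if self.multiplex_tag_length <= 0 or self.barcode_length <= 0:
            raise ValueError("layout lengths must be > 0")
        if not _is_dna(self.upstream_primer) or not _is_dna(self.downstream_primer):
            raise ValueError("primers must be non-empty DNA strings")

    @property
    def barcode_offset(self) -> int:
        """Offset of the barcode in an error-free read."""
        return self.multiplex_tag_length + len(self.upstream_primer)

    @property
    def min_read_length(self) -> int:
        return self.barcode_offset + self.barcode_length


@dataclass
class BarcodeCatalog:
    """Ordered collection of :class:`CatalogEntry` with gene lookup.

    Entries sharing an identical barcode (within one tag) are recorded in
    ``ambiguous_barcodes``; reads matching them are never assigned to a
    single gene.
    """

    entries: list[CatalogEntry]
    layout: AmpliconLayout = field(default_factory=AmpliconLayout)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.gene in seen:
                raise CatalogValidationError(f"duplicate gene {e.gene!r} in catalog")
            seen.add(e.gene)
        self._by_gene = {e.gene: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def lookup(self, gene: str) -> CatalogEntry:
        try:
            return self._by_gene[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in catalog") from None

    def barcode_map(self, tag: Tag) -> dict[str, set[str]]:
        """barcode sequence -> set of genes carrying it (includes alternates)."""
        out: dict[str, set[str]] = {}
        for e in self.entries:
            for bc in e.barcodes(tag):
                out.setdefault(bc, set()).add(e.gene)
        return out

    def ambiguous_barcodes(self, tag: Tag) -> dict[str, set[str]]:
        """Barcodes shared verbatim by two or more genes."""
        return {bc: gs for bc, gs in self.barcode_map(tag).items() if len(gs) > 1}


@dataclass(frozen=True)
class ReadRecord:
    """A FASTQ read (sequence + per-base quality)."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )


@dataclass(frozen=True)
class ConcatenatedReference:
    """Barcodes joined with N spacers, plus the per-gene interval index.

    Intervals are 0-based, half-open, disjoint and sorted in catalog order,
    separated by exactly ``spacer_length`` N bases.
    """

    sequence: str
    intervals: dict[str, tuple[int, int]]
    spacer_length: int
    tag: Tag

    def barcode_of(self, gene: str) -> str:
        start, end = self.intervals[gene]
        return self.sequence[start:end]


# ---------------------------------------------------------------------------
# catalog I/O


def read_catalog(path: str | Path, source_tag: str = "primary_list") -> BarcodeCatalog:
    """Read a TSV barcode catalog.

    Dialect: tab-separated with a header line containing at least ``gene``
    and ``uptag`` and/or ``dntag`` columns; lines starting with ``#`` are
    comments; an empty ``dntag``/``uptag`` field means the tag is absent.
    """
    path = Path(path)
    header: list[str] | None = None
    entries: list[CatalogEntry] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if "gene" not in header or not ({"uptag", "dntag"} & set(header)):
                    raise CatalogFormatError(
                        f"{path}: header must contain 'gene' and 'uptag' and/or "
                        f"'dntag' columns, got {header}"
                    )
                continue
            if len(fields) < len(header):
                fields = fields + [""] * (len(header) - len(fields))
            row = dict(zip(header, (f.strip().upper() for f in fields)))
            gene = row["gene"]
            if not gene:
                raise CatalogValidationError(f"{path}:{lineno}: empty gene name")
            try:
                entries.append(
                    CatalogEntry(
                        gene=gene,
                        uptag=row.get("uptag") or None,
                        dntag=row.get("dntag") or None,
                        source=source_tag,
                    )
                )
            except CatalogValidationError as exc:
                raise CatalogValidationError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise CatalogFormatError(f"{path}: no header line found")
    return BarcodeCatalog(entries=entries)


def write_catalog(catalog: BarcodeCatalog, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tuptag\tdntag\tsource\n")
        for e in catalog.entries:
            fh.write(f"{e.gene}\t{e.uptag or ''}\t{e.dntag or ''}\t{e.source}\n")


def merge_catalogs(
    primary: BarcodeCatalog, resequenced: BarcodeCatalog
) -> tuple[BarcodeCatalog, int]:
    """Union of two catalogs; resequenced sequences win conflicts.

    Where a gene appears in both lists with a differing sequence, the
    resequenced sequence becomes current and the primary sequence is kept
    as an alternative match candidate.  Returns ``(merged, n_conflicts)``.
    Idempotent: re-merging the resequenced list changes nothing.
    """
    reseq_by_gene = {e.gene: e for e in resequenced.entries}
    merged: list[CatalogEntry] = []
    conflicts = 0
    for old in primary.entries:
        new = reseq_by_gene.pop(old.gene, None)
        if new is None:
            merged.append(old)
            continue
        alt_up = tuple(dict.fromkeys(new.alt_uptags + old.alt_uptags))
        alt_dn = tuple(dict.fromkeys(new.alt_dntags + old.alt_dntags))
        conflict = False
        if old.uptag and new.uptag and old.uptag != new.uptag and old.uptag not in alt_up:
            alt_up = alt_up + (old.uptag,)
            conflict = True
        if old.dntag and new.dntag and old.dntag != new.dntag and old.dntag not in alt_dn:
            alt_dn = alt_dn + (old.dntag,)
            conflict = True
        if conflict:
            conflicts += 1
            logger.info("catalog merge conflict for gene %s: resequenced wins", old.gene)
        merged.append(
            replace(
                new,
                uptag=new.uptag or old.uptag,
                dntag=new.dntag or old.dntag,
                alt_uptags=alt_up,
                alt_dntags=alt_dn,
            )
        )
    merged.extend(reseq_by_gene.values())  # genes unique to the resequenced list
    return BarcodeCatalog(entries=merged, layout=primary.layout), conflicts


# ---------------------------------------------------------------------------
# concatenated reference


def build_concatenated_reference(
    catalog: BarcodeCatalog, tag: Tag = "up", spacer_length: int = 20
) -> ConcatenatedReference:
    """Join all barcodes for ``tag`` with N spacers; index intervals per gene.

    Entries missing the requested tag are skipped with a warning.  Every
    interval is verified to read back the catalog barcode.
    """
    if spacer_length < 0:
        raise ValueError("spacer_length must be >= 0")
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    parts: list[str] = []
    intervals: dict[str, tuple[int, int]] = {}
    pos = 0
    for e in catalog.entries:
        bc = e.uptag if tag == "up" else e.dntag
        if bc is None:
            logger.warning("gene %s has no %stag; excluded from reference", e.gene, tag)
            continue
        if parts:
            parts.append("N" * spacer_length)
            pos += spacer_length
        parts.append(bc)
        intervals[e.gene] = (pos, pos + len(bc))
        pos += len(bc)
    if not intervals:
        raise ValueError(f"no entry in catalog carries a {tag}tag")
    ref = ConcatenatedReference(
        sequence="".join(parts), intervals=intervals, spacer_length=spacer_length, tag=tag
    )
    for gene, (start, end) in ref.intervals.items():
        assert ref.sequence[start:end] == catalog.lookup(gene).barcodes(tag)[0]
    return ref


def write_reference_fasta(
    ref: ConcatenatedReference, path: str | Path, record_id: str = "barcode_reference"
) -> None:
    """Single-record FASTA with literal N spacers, 70-column wrapped."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f">{record_id} tag={ref.tag} spacer={ref.spacer_length}\n")
        seq = ref.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path: str | Path, mode: str) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode + "t", encoding="ascii")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file."""
    with _open_text(path, "r") as fh:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"{path}: record {index} ({title!r}): quality length mismatch"
                    )
                yield ReadRecord(id=title, sequence=seq, quality=qual)
                index += 1
        except ValueError as exc:  # Biopython signals truncation via ValueError
            raise FastqParseError(f"{path}: record {index}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ (gzipped if path ends in .gz). Returns record count."""
    n = 0
    with _open_text(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n
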