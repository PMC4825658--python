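"""Demultiplexing, barcode matching, and count-table construction.

Reads are assigned to samples by Hamming distance on the leading multiplex
tag, the barcode is extracted by locating the upstream priming site within
a small search window, and extracted barcodes are matched against the
catalog by minimal Hamming distance (unique / ambiguous / none).  Matching
uses a pigeonhole-partition index: a barcode within ``max_mismatch`` of a
query must share at least one of ``max_mismatch + 1`` disjoint chunks
exactly, so only indexed candidates need full distance evaluation.  This
replaces alignment against the N-spacered concatenated reference with an
equivalent, oracle-testable direct computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .barcode_io import AmpliconLayout, BarcodeCatalog, ReadRecord

Tag = Literal["up", "dn"]

LEDGER_FIELDS = ("assigned", "ambiguous", "unmatched", "no_tag")


class SampleSheetError(ValueError):
    """Multiplex tags violate the separation needed for safe demultiplexing."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one barcode sequence against the catalog."""

    outcome: Literal["unique", "ambiguous", "none"]
    gene: str | None = None
    distance: int | None = None

    @classmethod
    def unique(cls, gene: str, distance: int) -> "MatchResult":
        return cls("unique", gene, distance)


MATCH_AMBIGUOUS = MatchResult("ambiguous")
MATCH_NONE = MatchResult("none")


@dataclass
class CountTable:
    """Genes x samples integer count matrix plus per-sample read ledgers.

    Ledger invariant (checked): assigned equals the column sum over genes,
    and assigned + ambiguous + unmatched + no_tag equals the total reads
    seen for the sample.
    """

    counts: pd.DataFrame
    ledger: pd.DataFrame  # samples x LEDGER_FIELDS
    tag: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        for sample in self.counts.columns:
            if sample not in self.ledger.index:
                raise ValueError(f"sample {sample!r} missing from ledger")
            if int(self.ledger.loc[sample, "assigned"]) != int(colsums[sample]):
                raise ValueError(f"ledger/assigned mismatch for sample {sample!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def total_reads(self, sample: str) -> int:
        return int(self.ledger.loc[sample, list(LEDGER_FIELDS)].sum())

    def to_tsv(self, counts_path, ledger_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if ledger_path is not None:
            self.ledger.to_csv(ledger_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, ledger_path=None, tag: str = "up") -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        if ledger_path is not None:
            ledger = pd.read_csv(ledger_path, sep="\t", index_col=0, comment="#")
        else:
            ledger = pd.DataFrame(
                {f: (counts.sum(axis=0) if f == "assigned" else 0) for f in LEDGER_FIELDS}
            )
        return cls(counts=counts.astype(int), ledger=ledger.astype(int), tag=tag)


# ---------------------------------------------------------------------------
# demultiplexing


def validate_sample_sheet(sample_sheet: dict[str, str], max_tag_mismatch: int) -> int:
    """Check equal tag lengths and pairwise separation > 2*max_tag_mismatch."""
    tags = list(sample_sheet)
    if not tags:
        raise SampleSheetError("empty sample sheet")
    length = len(tags[0])
    if any(len(t) != length for t in tags):
        raise SampleSheetError("multiplex tags must all have equal length")
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            if hamming(a, b) <= 2 * max_tag_mismatch:
                raise SampleSheetError(
                    f"tags {a!r} and {b!r} are within 2*max_tag_mismatch "
                    f"({2 * max_tag_mismatch}); demultiplexing would be unsafe"
                )
    return length


def demultiplex(
    reads: Iterable[ReadRecord],
    sample_sheet: dict[str, str],
    tag_length: int | None = None,
    max_tag_mismatch: int = 1,
) -> tuple[dict[str, list[ReadRecord]], int]:
    """Assign reads to samples by minimal Hamming distance on the leading tag.

    ``sample_sheet`` maps multiplex tag sequence -> sample name.  A read is
    assigned iff its best tag distance is <= ``max_tag_mismatch`` (the
    separation precondition makes the minimum unique whenever acceptable).
    Returns ``(per-sample reads, no_tag count)``.
    """
    length = validate_sample_sheet(sample_sheet, max_tag_mismatch)
    if tag_length is not None and tag_length != length:
        raise SampleSheetError(
            f"tag_length {tag_length} != sheet tag length {length}"
        )
    out: dict[str, list[ReadRecord]] = {s: [] for s in sample_sheet.values()}
    no_tag = 0
    items = list(sample_sheet.items())
    for read in reads:
        prefix = read.sequence[:length]
        if len(prefix) < length:
            no_tag += 1
            continue
        best_d, best_s = length + 1, None
        for tag, sample in items:
            d = hamming(prefix, tag)
            if d < best_d:
                best_d, best_s = d, sample
        if best_d <= max_tag_mismatch:
            out[best_s].append(read)
        else:
            no_tag += 1
    return out, no_tag


# ---------------------------------------------------------------------------
# barcode extraction


def extract_barcode(
    read: ReadRecord | str,
    layout: AmpliconLayout,
    primer_max_mismatch: int = 2,
    window_slack: int = 2,
) -> str | None:
    """Locate the upstream primer and return the following barcode, or None.

    The primer is searched at offsets ``layout.multiplex_tag_length ±
    window_slack`` (clipped at 0); the best-matching offset wins, accepted
    iff its mismatch count is <= ``primer_max_mismatch`` and a full-length
    barcode follows.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    primer = layout.upstream_primer
    lp, lb = len(primer), layout.barcode_length
    center = layout.multiplex_tag_length
    # scan the expected offset first: the common case is an exact hit there
    offsets = sorted(
        range(max(0, center - window_slack), center + window_slack + 1),
        key=lambda off: abs(off - center),
    )
    best_off, best_d = None, primer_max_mismatch + 1
    for off in offsets:
        if off + lp + lb > len(seq):
            continue
        d = hamming(seq[off : off + lp], primer)
        if d < best_d:
            best_d, best_off = d, off
            if d == 0:
                break
    if best_off is None:
        return None
    return seq[best_off + lp : best_off + lp + lb]


# ---------------------------------------------------------------------------
# barcode matching


def _encode_seq(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class BarcodeMatcher:
    """Minimal-Hamming-distance barcode lookup with a pigeonhole index.

    Every catalog barcode (current and alternative) is split into
    ``max_mismatch + 1`` near-equal chunks; a query within ``max_mismatch``
    must agree exactly with one chunk, so candidate barcodes are collected
    from chunk dictionaries and verified by full Hamming distance.
    Barcodes carried verbatim by several genes make any read at minimal
    distance ambiguous.
    """

    def __init__(self, catalog: BarcodeCatalog, tag: Tag, max_mismatch: int = 2):
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.tag = tag
        self.max_mismatch = max_mismatch
        self.length = catalog.layout.barcode_length
        bc_map = catalog.barcode_map(tag)
        self._barcodes: list[str] = []
        self._genes: list[frozenset[str]] = []
        for bc, genes in bc_map.items():
            if len(bc) != self.length:
                raise ValueError(
                    f"barcode {bc!r} length {len(bc)} != layout barcode_length {self.length}"
                )
            self._barcodes.append(bc)
            self._genes.append(frozenset(genes))
        self._mat = (
            np.vstack([_encode_seq(b) for b in self._barcodes])
            if self._barcodes else np.empty((0, self.length), dtype=np.uint8)
        )
        self._exact = {bc: i for i, bc in enumerate(self._barcodes)}
        k = max_mismatch + 1
        bounds = np.linspace(0, self.length, k + 1).astype(int)
        self._chunks = list(zip(bounds[:-1], bounds[1:]))
        self._index: list[dict[str, list[int]]] = []
        for start, end in self._chunks:
            d: dict[str, list[int]] = {}
            for i, bc in enumerate(self._barcodes):
                d.setdefault(bc[start:end], []).append(i)
            self._index.append(d)

    def match(self, seq: str) -> MatchResult:
        if len(seq) != self.length:
            raise ValueError(f"query length {len(seq)} != barcode length {self.length}")
        exact = self._exact.get(seq)
        if exact is not None:  # distance 0 is always the unique minimum
            genes = self._genes[exact]
            if len(genes) == 1:
                return MatchResult.unique(next(iter(genes)), 0)
            return MATCH_AMBIGUOUS
        cand: set[int] = set()
        for (start, end), idx in zip(self._chunks, self._index):
            cand.update(idx.get(seq[start:end], ()))
        if not cand:
            return MATCH_NONE
        ids = np.fromiter(cand, dtype=int)
        q = _encode_seq(seq)
        dists = (self._mat[ids] != q).sum(axis=1)
        dmin = int(dists.min())
        if dmin > self.max_mismatch:
            return MATCH_NONE
        hit_genes: set[str] = set()
        for i in ids[dists == dmin]:
            hit_genes.update(self._genes[int(i)])
        if len(hit_genes) == 1:
            return MatchResult.unique(next(iter(hit_genes)), dmin)
        return MATCH_AMBIGUOUS


def match_barcode(
    seq: str, catalog: BarcodeCatalog, tag: Tag, max_mismatch: int = 2
) -> MatchResult:
    """One-shot form of :meth:`BarcodeMatcher.match` (builds the index)."""
    return BarcodeMatcher(catalog, tag, max_mismatch).match(seq)


# ---------------------------------------------------------------------------
# counting


@dataclass(frozen=True)
class CountParams:
    max_barcode_mismatch: int = 2
    max_tag_mismatch: int = 1
    primer_max_mismatch: int = 2
    window_slack: int = 2


def count_barcodes(
    samples: dict[str, Iterable[ReadRecord]],
    catalog: BarcodeCatalog,
    layout: AmpliconLayout | None = None,
    tag: Tag = "up",
    params: CountParams = CountParams(),
    no_tag_counts: dict[str, int] | None = None,
) -> CountTable:
    """Count uniquely matched barcodes per gene per (already demultiplexed) sample.

    ``no_tag_counts`` lets demultiplexing losses be carried into the ledger
    (the per-sample ``no_tag`` entry; demultiplex-level unassigned reads
    belong to no sample and are reported separately by the caller).
    """
    layout = layout or catalog.layout
    matcher = BarcodeMatcher(catalog, tag, params.max_barcode_mismatch)
    gene_index = pd.Index(catalog.genes, name="gene")
    col_counts: dict[str, dict[str, int]] = {}
    ledger_rows: dict[str, dict[str, int]] = {}
    for sample, reads in samples.items():
        per_gene: dict[str, int] = {}
        led = dict.fromkeys(LEDGER_FIELDS, 0)
        for read in reads:
            bc = extract_barcode(read, layout, params.primer_max_mismatch,
                                 params.window_slack)
            if bc is None:
                led["unmatched"] += 1
                continue
            m = matcher.match(bc)
            if m.outcome == "unique":
                per_gene[m.gene] = per_gene.get(m.gene, 0) + 1
                led["assigned"] += 1
            elif m.outcome == "ambiguous":
                led["ambiguous"] += 1
            else:
                led["unmatched"] += 1
        col_counts[sample] = per_gene
        ledger_rows[sample] = led
    counts = pd.DataFrame(col_counts, dtype=float).reindex(gene_index).fillna(0).astype(int)
    counts.columns = list(samples)
    ledger = pd.DataFrame.from_dict(ledger_rows, orient="index").reindex(
        columns=list(LEDGER_FIELDS)
    )
    ledger.index.name = "sample"
    if no_tag_counts:
        for sample, n in no_tag_counts.items():
            ledger.loc[sample, "no_tag"] = n
    return CountTable(counts=counts, ledger=ledger.astype(int), tag=tag)


def apply_min_read_filter(
    up: CountTable,
    dn: CountTable,
    control_sample: str,
    threshold: int = 50,
    control_sample_dn: str | None = None,
) -> set[str]:
    """Genes with >= threshold reads in the presorted control on either tag.

    Implements the disjunctive "UPTAG and/or DNTAG" minimum-read rule: a
    gene passes if its UPTAG count OR its DNTAG count in the control
    (presorted library) sample reaches the threshold.  When the two tables
    name the control column differently, pass the DNTAG column as
    ``control_sample_dn``.
    """
    control_sample_dn = control_sample_dn or control_sample
    for name, table, col in (("up", up, control_sample),
                             ("dn", dn, control_sample_dn)):
        if col not in table.samples:
            raise KeyError(f"control sample {col!r} missing from {name} table")
    u = up.counts[control_sample]
    d = dn.counts.reindex(up.genes)[control_sample_dn]
    keep = (u >= threshold) | (d.fillna(0) >= threshold)
    return set(up.genes[keep])


def merge_tags(up: CountTable, dn: CountTable) -> CountTable:
    """Combine UPTAG and DNTAG tables as separate technical columns.

    Columns are suffixed ``__up`` / ``__dn``; counts are never summed
    across tags, so tag-specific PCR failure stays visible to the
    enrichment design.
    """
    if not up.genes.equals(dn.genes):
        raise ValueError("gene universes differ between up and dn tables")
    u = up.counts.add_suffix("__up")
    d = dn.counts.add_suffix("__dn")
    counts = pd.concat([u, d], axis=1)
    ledger = pd.concat([
        up.ledger.set_index(up.ledger.index + "__up"),
        dn.ledger.set_index(dn.ledger.index + "__dn"),
    ])
    return CountTable(counts=counts, ledger=ledger, tag="both")
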