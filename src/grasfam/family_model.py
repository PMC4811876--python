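"""Domain types and file formats for gene-family characterization.

The central object is the :class:`Locus` — one curated gene model described by
its genomic exon segments — collected into a :class:`GeneFamilyTable`.
Coordinates are 1-based, fully closed intervals throughout (the convention of
both GFF3 and curated locus tables); no half-open conversion happens at any
boundary.

The module also ships a verbatim transcription of the curated table of the 52
grapevine GRAS loci as a bundled fixture (:func:`grapevine_gras_table`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"

#: locus accessions of the form Vitvi08g00007 (or a synthetic equivalent with a
#: different alphabetic prefix); the two digits before ``g`` are the chromosome.
LOCUS_ID_RE = re.compile(r"^[A-Za-z]+?(\d{2})g\d{5}$")

_DASHES = "‐‒–—−"  # hyphen/figure/en/em dash, minus


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


def _normalize_strand(s: str) -> str:
    s = s.strip()
    if s in {"+", "-"}:
        return s
    if s in set(_DASHES):
        return "-"
    raise ParseError(f"invalid strand {s!r}")


def chromosome_from_locus_id(locus_id: str) -> int | None:
    """Chromosome number encoded in a Vitvi-style accession, else None."""
    m = LOCUS_ID_RE.match(locus_id)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class Locus:
    """One curated gene model.

    segments are (start, end) pairs in 1-based inclusive genomic coordinates,
    sorted by start and non-overlapping; minus-strand genes keep ascending
    genomic order.
    """

    locus_id: str
    short_name: str
    chromosome: int
    strand: str
    segments: tuple[tuple[int, int], ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.locus_id}: locus needs at least one segment")
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))
        for start, end in self.segments:
            if start > end:
                raise ValueError(
                    f"{self.locus_id}: segment ({start}, {end}) has end < start"
                )
        starts = [s for s, _ in self.segments]
        if starts != sorted(starts):
            raise ValueError(f"{self.locus_id}: segments not sorted by start")
        for (_, e1), (s2, _) in zip(self.segments, self.segments[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.locus_id}: overlapping segments")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-'")
        if self.chromosome < 1:
            raise ValueError(f"{self.locus_id}: chromosome must be >= 1")
        encoded = chromosome_from_locus_id(self.locus_id)
        if encoded is not None and encoded != self.chromosome:
            raise ValueError(
                f"{self.locus_id}: chromosome {self.chromosome} contradicts "
                f"accession-encoded chromosome {encoded}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional subfamily and genome labels.

    GRAS proteins are typically 400-700 aa; lengths outside that range are
    legal (truncated members exist) and only draw a warning from readers.
    """

    id: str
    sequence: str
    subfamily: str | None = None
    genome: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"{self.id}: illegal residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFamilyTable:
    loci: list[Locus]
    name: str = "family"

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids: {dup}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def get(self, locus_id: str) -> Locus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)


Interval = tuple[int, int, int]  # (chromosome, start, end)


@dataclass
class ParalogousSegmentMap:
    """Pairs of chromosome intervals descended from ancestral polyploidization.

    Pairs are unordered: (a, b) and (b, a) are the same link.
    """

    pairs: list[tuple[Interval, Interval]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            for chrom, start, end in (a, b):
                if start > end:
                    raise ValueError(f"invalid interval chr{chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# locus table (tab-separated)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("locus_id", "short_name", "strand", "position")


def _parse_position(cell: str, row: str) -> tuple[tuple[int, int], ...]:
    for d in _DASHES:
        cell = cell.replace(d, "-")
    segments = []
    for span in cell.split(","):
        span = span.strip()
        parts = span.split("-")
        if len(parts) != 2:
            raise ParseError(f"row {row!r}: malformed span {span!r}")
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ParseError(f"row {row!r}: non-numeric span {span!r}") from exc
        if end < start:
            raise ParseError(f"row {row!r}: span {span!r} has end < start")
        segments.append((start, end))
    return tuple(segments)


def parse_locus_table(path: str | Path, name: str = "family") -> GeneFamilyTable:
    """Read a tab-separated locus table.

    Columns: locus ID, short name, strand, position (comma-separated
    ``start-end`` spans, en-dash accepted); an optional fifth free-text notes
    column is preserved.  The chromosome is parsed from the accession.
    """
    loci: list[Locus] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for line in lines[1:]:  # header skipped
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 4:
            raise ParseError(f"row {line!r}: expected >= 4 tab-separated columns")
        locus_id, short_name, strand, position = cells[:4]
        notes = cells[4] if len(cells) > 4 else ""
        if locus_id in seen:
            raise ParseError(f"duplicate locus_id {locus_id!r}")
        seen.add(locus_id)
        chromosome = chromosome_from_locus_id(locus_id)
        if chromosome is None:
            raise ParseError(
                f"row {line!r}: cannot parse chromosome from accession {locus_id!r}"
            )
        loci.append(
            Locus(
                locus_id=locus_id,
                short_name=short_name,
                chromosome=chromosome,
                strand=_normalize_strand(strand),
                segments=_parse_position(position, line),
                notes=notes,
            )
        )
    return GeneFamilyTable(loci=loci, name=name)


def write_locus_table(table: GeneFamilyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for locus in table:
            position = ", ".join(f"{s}-{e}" for s, e in locus.segments)
            row = [locus.locus_id, locus.short_name, locus.strand, position]
            if locus.notes:
                row.append(locus.notes)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, genome: str = "") -> list[ProteinRecord]:
    """Read protein FASTA; IDs are the first whitespace-delimited token.

    Residues are uppercased; anything outside the 20-letter alphabet + X is
    replaced by X with a warning.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in AMINO_ACIDS else "X" for c in seq)
        if cleaned != seq:
            warnings.warn(f"{rec.id}: non-standard residues replaced by X")
        records.append(ProteinRecord(id=rec.id, sequence=cleaned, genome=genome))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attributes(cell: str) -> dict[str, str]:
    out = {}
    for item in cell.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path, name: str = "family") -> GeneFamilyTable:
    """Read gene models from GFF3 (gene + exon features, 1-based inclusive)."""
    genes: dict[str, dict] = {}
    exons: list[tuple[str, int, int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"GFF3 line {line!r}: expected 9 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            attributes = _gff_attributes(attrs)
            if ftype == "gene":
                gid = attributes.get("ID")
                if gid is None:
                    raise ParseError(f"gene without ID: {line!r}")
                genes[gid] = {
                    "seqid": seqid,
                    "strand": _normalize_strand(strand),
                    "name": attributes.get("Name", gid),
                    "segments": [],
                }
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent is None:
                    raise ParseError(f"exon without Parent: {line!r}")
                exons.append((parent, int(start), int(end), seqid))
    for parent, start, end, _ in exons:
        if parent not in genes:
            raise ParseError(f"exon Parent {parent!r} has no gene feature")
        genes[parent]["segments"].append((start, end))
    loci = []
    for gid, info in genes.items():
        chromosome = chromosome_from_locus_id(gid)
        if chromosome is None:
            m = re.search(r"(\d+)$", info["seqid"])
            if not m:
                raise ParseError(f"cannot infer chromosome for gene {gid!r}")
            chromosome = int(m.group(1))
        loci.append(
            Locus(
                locus_id=gid,
                short_name=info["name"],
                chromosome=chromosome,
                strand=info["strand"],
                segments=tuple(sorted(info["segments"])),
            )
        )
    return GeneFamilyTable(loci=loci, name=name)


def write_gff3(table: GeneFamilyTable, path: str | Path, source: str = "grasfam") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for locus in table:
            start, end = locus.span
            chrom = f"chr{locus.chromosome:02d}"
            fh.write(
                f"{chrom}\t{source}\tgene\t{start}\t{end}\t.\t{locus.strand}\t.\t"
                f"ID={locus.locus_id};Name={locus.short_name}\n"
            )
            for i, (s, e) in enumerate(locus.segments, 1):
                fh.write(
                    f"{chrom}\t{source}\texon\t{s}\t{e}\t.\t{locus.strand}\t.\t"
                    f"ID={locus.locus_id}.exon{i};Parent={locus.locus_id}\n"
                )


# ---------------------------------------------------------------------------
# paralogous segment map (6-column BED-pair TSV, 1-based inclusive)
# ---------------------------------------------------------------------------

def read_segment_map(path: str | Path) -> ParalogousSegmentMap:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ParseError(f"segment-map line {line!r}: expected 6 columns")
            ca, sa, ea, cb, sb, eb = cols
            pairs.append(
                ((int(ca), int(sa), int(ea)), (int(cb), int(sb), int(eb)))
            )
    return ParalogousSegmentMap(pairs=pairs)


def write_segment_map(seg_map: ParalogousSegmentMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for (ca, sa, ea), (cb, sb, eb) in seg_map.pairs:
            fh.write(f"{ca}\t{sa}\t{ea}\t{cb}\t{sb}\t{eb}\n")


# ---------------------------------------------------------------------------
# bundled fixture and subfamily nomenclature
# ---------------------------------------------------------------------------

#: gene-symbol prefixes -> subfamily, longest match first; RGA genes are the
#: DELLA subfamily (gibberellin-signaling repressors).
_SUBFAMILY_PREFIXES = (
    ("GRASV1", "GRASV1"),
    ("GRASV2", "GRASV2"),
    ("GRASV3", "GRASV3"),
    ("GRAS8", "GRAS8"),
    ("LISCL", "LISCL"),
    ("SCL26", "SCL26"),
    ("SCL3", "SCL3"),
    ("PAT", "PAT"),
    ("SHR", "SHR"),
    ("SCR", "SCR"),
    ("RGA", "DELLA"),
    ("LAS", "LAS"),
    ("HAM", "HAM"),
)

SUBFAMILIES = tuple(dict.fromkeys(label for _, label in _SUBFAMILY_PREFIXES))


def subfamily_from_short_name(short_name: str) -> str | None:
    """Subfamily implied by the family nomenclature of a gene symbol."""
    for prefix, label in _SUBFAMILY_PREFIXES:
        if short_name.upper().startswith(prefix.upper()):
            return label
    return None


def fixture_path(filename: str) -> Path:
    return Path(str(resources.files("grasfam.data").joinpath(filename)))


def grapevine_gras_table() -> GeneFamilyTable:
    """The bundled table of the 52 curated grapevine GRAS loci."""
    return parse_locus_table(
        fixture_path("table1_grapevine_gras.tsv"), name="VviGRAS"
    )
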