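"""Motif catalog scanning and de-novo conserved-window discovery.

Catalog patterns are consensus strings over residues with single-position
wildcards (``X`` or ``+``) and per-position alternative sets (``[LIVF]``).
A window's match score is the fraction of non-wildcard positions matched;
scanning keeps all windows at or above a score floor, greedily best-first and
non-overlapping per pattern.

De-novo discovery finds maximal runs of alignment columns whose per-column
identity (modal-residue fraction, gaps counting against) stays at or above a
floor for a minimum number of columns — the deterministic replacement for
manual inspection of subfamily alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import MultipleAlignment
from .family_model import ProteinRecord, fixture_path

#: canonical order of the five core GRAS-domain motifs
CORE_MOTIFS = ("LHRI", "VHIID", "LHRII", "PFYRE", "SAW")

_WILDCARDS = {"X", "+"}


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str
    region: str = "GRAS_domain"  # or N_terminal

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        self.positions  # validates

    @property
    def positions(self) -> tuple[frozenset[str] | None, ...]:
        """Per-position allowed residue sets; None marks a wildcard."""
        out: list[frozenset[str] | None] = []
        i, pat = 0, self.pattern
        while i < len(pat):
            c = pat[i]
            if c == "[":
                j = pat.index("]", i)
                alts = pat[i + 1 : j]
                if not alts:
                    raise ValueError(f"{self.name}: empty alternative set")
                out.append(frozenset(alts))
                i = j + 1
            elif c in _WILDCARDS:
                out.append(None)
                i += 1
            else:
                out.append(frozenset(c))
                i += 1
        return tuple(out)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: str
    start: int  # 1-based inclusive residue coordinates
    end: int
    match_score: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid hit coordinates")
        if not 0.0 <= self.match_score <= 1.0:
            raise ValueError("match_score must be in [0, 1]")

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ConservedWindowRule:
    min_identity: float = 0.50
    min_length: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class MotifAnnotation:
    protein_id: str
    hits: list[MotifHit]
    missing_expected: list[str]
    order_warnings: list[str] = field(default_factory=list)


def scan_pattern(
    protein: ProteinRecord, pattern: MotifPattern, min_score: float = 0.7
) -> list[MotifHit]:
    """All non-overlapping windows matching the pattern at or above the
    score floor, chosen greedily best-first (ties to the leftmost window)."""
    positions = pattern.positions
    k = len(positions)
    seq = protein.sequence
    if k > len(seq):
        return []
    informative = [(i, s) for i, s in enumerate(positions) if s is not None]
    candidates = []
    for start in range(len(seq) - k + 1):
        if informative:
            matched = sum(1 for i, s in informative if seq[start + i] in s)
            score = matched / len(informative)
        else:
            score = 1.0
        if score >= min_score:
            candidates.append((start, score))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    hits: list[MotifHit] = []
    for start, score in candidates:
        hit = MotifHit(protein.id, pattern.name, start + 1, start + k, score)
        if not any(hit.overlaps(h) for h in hits):
            hits.append(hit)
    hits.sort(key=lambda h: h.start)
    return hits


def column_identity(msa: MultipleAlignment, j: int) -> float:
    """Modal-residue fraction of column j; gaps count in the denominator."""
    col = msa.column(j)
    counts: dict[str, int] = {}
    for c in col:
        if c != "-":
            counts[c] = counts.get(c, 0) + 1
    return max(counts.values(), default=0) / len(col)


def discover_conserved_windows(
    msa: MultipleAlignment, rule: ConservedWindowRule | None = None
) -> list[tuple[tuple[int, int], list[float]]]:
    """Maximal runs of conserved columns.

    Returns ``((start_col, end_col), per_column_identity)`` with 1-based
    inclusive column coordinates; both rule bounds are inclusive ("at
    least").  Windows are maximal: extending either edge drops the run below
    the identity floor (or off the alignment).
    """
    rule = rule or ConservedWindowRule()
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    idents = [column_identity(msa, j) for j in range(msa.length)]
    windows = []
    j = 0
    while j < msa.length:
        if idents[j] >= rule.min_identity:
            start = j
            while j < msa.length and idents[j] >= rule.min_identity:
                j += 1
            if j - start >= rule.min_length:
                windows.append(((start + 1, j), idents[start:j]))
        else:
            j += 1
    return windows


def annotate(
    protein: ProteinRecord,
    catalog: list[MotifPattern],
    min_score: float = 0.7,
) -> MotifAnnotation:
    """Locate every catalog motif; flag expected-but-missing motifs and
    out-of-order core motifs.

    The five core GRAS-domain motifs must occur in LHRI -> VHIID -> LHRII ->
    PFYRE -> SAW order; a core hit overlapping or preceding an earlier core
    hit is dropped with a warning so core hits stay ordered and disjoint.
    """
    if not protein.sequence:
        raise ValueError("empty sequence")
    hits: list[MotifHit] = []
    missing: list[str] = []
    order_warnings: list[str] = []
    best_core: dict[str, MotifHit] = {}
    for pattern in catalog:
        found = scan_pattern(protein, pattern, min_score)
        if not found:
            missing.append(pattern.name)
            continue
        if pattern.name in CORE_MOTIFS:
            best_core[pattern.name] = max(found, key=lambda h: (h.match_score, -h.start))
        else:
            hits.extend(found)
    prev: MotifHit | None = None
    for name in CORE_MOTIFS:
        hit = best_core.get(name)
        if hit is None:
            continue
        if prev is not None and (hit.start <= prev.end):
            order_warnings.append(
                f"{name} at {hit.start}-{hit.end} out of order with "
                f"{prev.motif} at {prev.start}-{prev.end}"
            )
            continue
        hits.append(hit)
        prev = hit
    hits.sort(key=lambda h: (h.start, h.motif))
    return MotifAnnotation(
        protein_id=protein.id,
        hits=hits,
        missing_expected=missing,
        order_warnings=order_warnings,
    )


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path) -> list[MotifPattern]:
    """Catalog file: one motif per line, ``name<TAB>region<TAB>pattern``."""
    catalog = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"catalog line {line!r}: expected 3 columns")
            name, region, pattern = parts
            catalog.append(MotifPattern(name=name, pattern=pattern, region=region))
    return catalog


def default_catalog() -> list[MotifPattern]:
    """The bundled GRAS motif catalog."""
    return read_catalog(fixture_path("gras_motifs.tsv"))


def write_annotations_tsv(annotations: list[MotifAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein\tmotif\tstart\tend\tmatch_score\tmissing_expected\n")
        for ann in annotations:
            missing = ",".join(ann.missing_expected)
            for h in ann.hits:
                fh.write(
                    f"{ann.protein_id}\t{h.motif}\t{h.start}\t{h.end}\t"
                    f"{h.match_score:.3f}\t{missing}\n"
                )
            if not ann.hits:
                fh.write(f"{ann.protein_id}\t.\t0\t0\t0.000\t{missing}\n")


def write_annotations_gff3(annotations: list[MotifAnnotation], path) -> None:
    """Motif hits as GFF3 features on protein coordinates."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            for h in ann.hits:
                fh.write(
                    f"{ann.protein_id}\tgrasfam\tprotein_match\t{h.start}\t"
                    f"{h.end}\t{h.match_score:.3f}\t.\t.\tName={h.motif}\n"
                )
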