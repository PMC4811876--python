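"""Tandem-array and segmental-duplication classification.

Tandem arrays are maximal chains of same-subfamily loci on one chromosome
whose consecutive members lie within a gap threshold (default 250 kb — wide
enough to capture clustered arrays, narrow enough to exclude same-chromosome
loci megabases apart).  Segmental calls require two same-subfamily loci whose
genomic spans fall fully inside the two intervals of one pair of a supplied
paralogous-segment map (the ancestral-polyploidization blocks are an input,
not inferred here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .family_model import GeneFamilyTable, Locus, ParalogousSegmentMap

DEFAULT_MAX_GAP_BP = 250_000


@dataclass(frozen=True)
class DuplicationCall:
    kind: str  # tandem | segmental
    members: tuple[str, ...]
    evidence: str

    def __post_init__(self) -> None:
        if self.kind not in {"tandem", "segmental"}:
            raise ValueError(f"unknown duplication kind {self.kind!r}")
        if len(self.members) < 2:
            raise ValueError("a duplication call needs >= 2 members")


def _label_of(subfamilies, locus: Locus) -> str | None:
    if hasattr(subfamilies, "label"):
        lab = subfamilies.label(locus.locus_id)
        return None if lab == "unassigned" else lab
    return subfamilies.get(locus.locus_id)


def tandem_arrays(
    table: GeneFamilyTable,
    subfamilies: Mapping[str, str],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[DuplicationCall]:
    """Maximal same-subfamily chains along each chromosome.

    Consecutive members chain when the gap between one locus's end and the
    next locus's start is at most ``max_gap_bp``.  Arrays are disjoint by
    construction; loci without a subfamily label are skipped.
    """
    groups: dict[tuple[str, int], list[Locus]] = {}
    for locus in table:
        label = _label_of(subfamilies, locus)
        if label is None:
            continue
        groups.setdefault((label, locus.chromosome), []).append(locus)
    calls = []
    for (label, chrom), loci in sorted(groups.items()):
        loci.sort(key=lambda l: l.span)
        chain: list[Locus] = []
        for locus in loci + [None]:
            if locus is not None and (
                not chain or locus.span[0] - chain[-1].span[1] <= max_gap_bp
            ):
                chain.append(locus)
                continue
            if len(chain) >= 2:
                start, end = chain[0].span[0], chain[-1].span[1]
                calls.append(
                    DuplicationCall(
                        kind="tandem",
                        members=tuple(l.locus_id for l in chain),
                        evidence=f"chr{chrom}:{start}-{end} ({label})",
                    )
                )
            chain = [locus] if locus is not None else []
    return sorted(calls, key=lambda c: c.members)


def _contained(locus: Locus, interval: tuple[int, int, int]) -> bool:
    chrom, start, end = interval
    s, e = locus.span
    return locus.chromosome == chrom and start <= s and e <= end


def segmental_pairs(
    table: GeneFamilyTable,
    subfamilies: Mapping[str, str],
    seg_map: ParalogousSegmentMap,
    tolerance_bp: int = 0,
) -> list[DuplicationCall]:
    """Same-subfamily locus pairs residing inside linked paralogous segments.

    Containment is strict (the locus span fully inside the interval);
    ``tolerance_bp`` widens every interval symmetrically for near-segment
    loci.  Members must lie on different chromosomes.
    """
    calls = []
    seen: set[tuple[str, str]] = set()
    for pair in seg_map.pairs:
        widened = tuple(
            (c, s - tolerance_bp, e + tolerance_bp) for c, s, e in pair
        )
        in_a = [l for l in table if _contained(l, widened[0])]
        in_b = [l for l in table if _contained(l, widened[1])]
        for a in in_a:
            for b in in_b:
                if a.locus_id == b.locus_id or a.chromosome == b.chromosome:
                    continue
                la, lb = _label_of(subfamilies, a), _label_of(subfamilies, b)
                if la is None or la != lb:
                    continue
                key = tuple(sorted((a.locus_id, b.locus_id)))
                if key in seen:
                    continue
                seen.add(key)
                calls.append(
                    DuplicationCall(
                        kind="segmental",
                        members=key,
                        evidence=(
                            f"chr{a.chromosome}:{a.span[0]}-{a.span[1]} ~ "
                            f"chr{b.chromosome}:{b.span[0]}-{b.span[1]} ({la})"
                        ),
                    )
                )
    return sorted(calls, key=lambda c: c.members)


def write_calls_tsv(calls: list[DuplicationCall], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("kind\tmembers\tevidence\n")
        for c in calls:
            fh.write(f"{c.kind}\t{','.join(c.members)}\t{c.evidence}\n")
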