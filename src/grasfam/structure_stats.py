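"""Gene-structure statistics for a curated gene-family table.

Most GRAS genes are intronless; these helpers quantify exon/intron structure
and chromosomal distribution of a :class:`~grasfam.family_model.GeneFamilyTable`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .family_model import GeneFamilyTable, Locus


@dataclass
class StructureSummary:
    n_loci: int
    n_intronless: int
    pct_intronless: float
    exon_count_histogram: dict[int, int]
    per_chromosome_counts: dict[int, int]
    singleton_chromosomes: list[int]
    length_table: dict[str, tuple[int, int]]  # locus_id -> (span, spliced)

    def to_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "n_intronless": self.n_intronless,
            "pct_intronless": self.pct_intronless,
            "exon_count_histogram": dict(self.exon_count_histogram),
            "per_chromosome_counts": dict(self.per_chromosome_counts),
            "singleton_chromosomes": list(self.singleton_chromosomes),
            "length_table": {
                k: {"genomic_span": v[0], "spliced_length": v[1]}
                for k, v in self.length_table.items()
            },
        }


def exon_count(locus: Locus) -> int:
    """Number of exon segments (1 for an intronless gene)."""
    return len(locus.segments)


def spliced_length(locus: Locus) -> int:
    """Summed exon length in bp (coordinates are 1-based inclusive)."""
    return sum(end - start + 1 for start, end in locus.segments)


def genomic_span(locus: Locus) -> int:
    """End-to-end genomic extent in bp, introns included."""
    start, end = locus.span
    return end - start + 1


def _round2(x: float) -> float:
    """Round-half-even to 2 decimals (Python's float rounding)."""
    return round(x, 2)


def summarize(table: GeneFamilyTable) -> StructureSummary:
    """Full structure summary: intronless fraction, exon-count histogram,
    per-chromosome counts and per-locus lengths."""
    n = len(table)
    if n == 0:
        return StructureSummary(0, 0, 0.0, {}, {}, [], {})
    counts = Counter(exon_count(l) for l in table)
    n_intronless = counts.get(1, 0)
    per_chrom = Counter(l.chromosome for l in table)
    singletons = sorted(c for c, k in per_chrom.items() if k == 1)
    lengths = {l.locus_id: (genomic_span(l), spliced_length(l)) for l in table}
    return StructureSummary(
        n_loci=n,
        n_intronless=n_intronless,
        pct_intronless=_round2(100.0 * n_intronless / n),
        exon_count_histogram=dict(sorted(counts.items())),
        per_chromosome_counts=dict(sorted(per_chrom.items())),
        singleton_chromosomes=singletons,
        length_table=lengths,
    )
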