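"""Reciprocal-best-hit (RBH) orthology between two genomes.

A hit is retained when its E-value is strictly below ``max_evalue`` and its
identity strictly above ``min_identity`` (both gates read literally as strict
inequalities).  Gene A in the query genome and B in the target genome are
one-to-one orthologs when each is the other's best retained match; a query
with retained hits but no reciprocal best match has homologs without a clear
ortholog; a query with no retained hit is absent from the target genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .alignment import AlignmentParams, PairwiseHit, align_local, evalue, local_score
from .family_model import ProteinRecord

Category = Literal["one_to_one", "homolog_no_ortholog", "absent"]


@dataclass
class OrthologyThresholds:
    max_evalue: float = 1e-20
    min_identity: float = 0.40

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


@dataclass(frozen=True)
class OrthologyCall:
    query_id: str
    target_genome: str
    category: Category
    best_target_id: str | None
    reciprocal: bool

    def __post_init__(self) -> None:
        if self.category == "one_to_one" and not (
            self.reciprocal and self.best_target_id
        ):
            raise ValueError("one_to_one requires a reciprocal best target")
        if self.category == "absent" and self.best_target_id:
            raise ValueError("absent calls carry no best target")


def retained_hits(
    queries: list[ProteinRecord],
    targets: list[ProteinRecord],
    thresholds: OrthologyThresholds | None = None,
    params: AlignmentParams | None = None,
) -> list[PairwiseHit]:
    """All-vs-all local alignments passing both gates (strict inequalities)."""
    thresholds = thresholds or OrthologyThresholds()
    params = params or AlignmentParams()
    if not queries or not targets:
        raise ValueError("both genomes must be non-empty")
    hits = []
    for q in queries:
        for t in targets:
            # score-only pre-screen: the E-value gate depends only on the
            # score, so traceback is computed just for pairs passing it
            score = local_score(q, t, params)
            if evalue(score, len(q), len(t), params) >= thresholds.max_evalue:
                continue
            hit = align_local(q, t, params)
            if hit.evalue < thresholds.max_evalue and hit.identity > thresholds.min_identity:
                hits.append(hit)
    return hits


def best_match(
    gene_id: str, retained: list[PairwiseHit]
) -> PairwiseHit | None:
    """Highest-scoring retained hit for a query gene.

    Ties break by lower E-value, then lexicographic target id, so the choice
    is deterministic.
    """
    candidates = [h for h in retained if h.query_id == gene_id]
    if not candidates:
        return None
    return min(candidates, key=lambda h: (-h.raw_score, h.evalue, h.target_id))


def classify(
    queries: list[ProteinRecord],
    targets: list[ProteinRecord],
    thresholds: OrthologyThresholds | None = None,
    params: AlignmentParams | None = None,
    target_genome: str = "target",
) -> list[OrthologyCall]:
    """Per-query three-way classification against a target genome."""
    for genome in (queries, targets):
        ids = [r.id for r in genome]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate protein ids within a genome")
    thresholds = thresholds or OrthologyThresholds()
    params = params or AlignmentParams()
    forward = retained_hits(queries, targets, thresholds, params)
    # Smith-Waterman score, identity and the E-value are all symmetric in
    # the two sequences, so the reverse search is the mirrored forward one
    backward = [
        PairwiseHit(
            query_id=h.target_id,
            target_id=h.query_id,
            raw_score=h.raw_score,
            evalue=h.evalue,
            identity=h.identity,
            aligned_span=(h.aligned_span[1], h.aligned_span[0]),
        )
        for h in forward
    ]
    calls = []
    for q in queries:
        fwd = best_match(q.id, forward)
        if fwd is None:
            calls.append(OrthologyCall(q.id, target_genome, "absent", None, False))
            continue
        back = best_match(fwd.target_id, backward)
        reciprocal = back is not None and back.target_id == q.id
        category: Category = "one_to_one" if reciprocal else "homolog_no_ortholog"
        calls.append(
            OrthologyCall(q.id, target_genome, category, fwd.target_id, reciprocal)
        )
    return calls


_CATEGORY_CODE = {"one_to_one": "green", "homolog_no_ortholog": "gray", "absent": "white"}


def write_orthology_matrix(
    calls_by_genome: dict[str, list[OrthologyCall]], path
) -> None:
    """Presence matrix: rows query genes, columns genomes, cells the
    green/gray/white category codes."""
    genomes = sorted(calls_by_genome)
    gene_ids: list[str] = []
    for calls in calls_by_genome.values():
        for c in calls:
            if c.query_id not in gene_ids:
                gene_ids.append(c.query_id)
    lookup = {
        (g, c.query_id): _CATEGORY_CODE[c.category]
        for g, calls in calls_by_genome.items()
        for c in calls
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(genomes) + "\n")
        for gid in gene_ids:
            cells = [lookup.get((g, gid), "white") for g in genomes]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")
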