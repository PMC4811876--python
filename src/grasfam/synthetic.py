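"""Seeded synthetic gene families with ground truth.

Generates everything the pipeline consumes — two protein genomes, a curated
locus table, a paralogous-segment map and an expression matrix — with known
subfamily structure, planted motifs, tandem arrays, segmental pairs,
cross-genome orthologs and co-expression modules, so every analysis stage can
be validated against the construction.

Sequence evolution is residue-frequency-weighted random replacement along
star-like trees (subfamily ancestors radiate from a family root; members
radiate from their ancestor).  That is deliberately simpler than a full
empirical-matrix simulation: the downstream stages consume identities and
distances, not substitution-model fits.  Motifs are overwritten after
mutation at fixed offsets, so they are exactly conserved within their
subfamilies.  A fixed seed makes all outputs byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .family_model import (
    AMINO_ACIDS,
    GeneFamilyTable,
    Locus,
    ParalogousSegmentMap,
    ProteinRecord,
    SUBFAMILIES,
    write_fasta,
    write_gff3,
    write_locus_table,
    write_segment_map,
)
from .motifs import MotifPattern, default_catalog

#: background amino-acid frequencies (approximate natural abundances)
_AA20 = AMINO_ACIDS[:20]
_AA_FREQ = np.array(
    [
        0.083, 0.014, 0.054, 0.067, 0.039, 0.071, 0.022, 0.059, 0.058, 0.097,
        0.024, 0.041, 0.047, 0.040, 0.055, 0.066, 0.053, 0.069, 0.011, 0.030,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: planted-motif layout: motif -> (anchor, offset); anchor N counts from the
#: N-terminus (0-based), anchor C from the C-terminus
_MOTIF_LAYOUT = {
    "DELLA": ("N", 5),
    "TVHYNP": ("N", 30),
    "XIV": ("N", 60),
    "XV": ("N", 100),
    "XVI": ("N", 130),
    "LHRI": ("C", 250),
    "NLS": ("C", 230),
    "VHIID": ("C", 200),
    "LRITG": ("C", 185),
    "LHRII": ("C", 160),
    "LXXLL": ("C", 140),
    "PFYRE": ("C", 120),
    "RVER": ("C", 60),
    "SAW": ("C", 30),
}


def default_planted_motifs(subfamilies: tuple[str, ...]) -> list[tuple[str, tuple[str, ...]]]:
    """Family-architecture defaults: the five core motifs everywhere, the
    DELLA/TVHYNP pair and NLS in the DELLA subfamily, RVER absent from HAM,
    XIV/XV confined to HAM and XVI to PAT."""
    everyone = tuple(subfamilies)
    non_ham = tuple(s for s in subfamilies if s != "HAM")
    plan = [
        ("LHRI", everyone),
        ("VHIID", everyone),
        ("LRITG", everyone),
        ("LHRII", everyone),
        ("PFYRE", everyone),
        ("RVER", non_ham),
        ("SAW", everyone),
    ]
    if "DELLA" in subfamilies:
        plan += [
            ("DELLA", ("DELLA",)),
            ("TVHYNP", ("DELLA",)),
            ("NLS", ("DELLA",)),
        ]
    if "HAM" in subfamilies:
        plan += [("XIV", ("HAM",)), ("XV", ("HAM",))]
    if "PAT" in subfamilies:
        plan += [("XVI", ("PAT",))]
    return plan


@dataclass
class SimulationConfig:
    seed: int = 0
    n_subfamilies: int = 13
    members_per_subfamily: tuple[int, int] = (4, 4)
    protein_length: tuple[int, int] = (400, 700)
    within_subfamily_divergence: float = 0.20
    between_subfamily_divergence: float = 0.60
    planted_motifs: list[tuple[str, tuple[str, ...]]] | None = None
    n_tandem_arrays: int = 2
    n_segmental_pairs: int = 3
    tandem_gap_bp: int = 10_000
    ortholog_divergence: float = 0.10
    lost_subfamilies: int = 2
    n_lineage_duplicates: int = 2
    duplicate_divergence: float = 0.02
    expr_n_conditions: int = 50
    expr_module_size: int = 10
    module_pcc: float = 0.90
    n_tissue_specific: int = 5

    def __post_init__(self) -> None:
        if self.within_subfamily_divergence < 0 or self.between_subfamily_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.within_subfamily_divergence >= self.between_subfamily_divergence:
            raise ValueError("within-subfamily divergence must be < between")
        if self.ortholog_divergence < 0:
            raise ValueError("ortholog_divergence must be >= 0")
        lo, hi = self.members_per_subfamily
        if lo < 1 or hi < lo:
            raise ValueError("invalid members_per_subfamily range")
        if self.n_subfamilies < 1:
            raise ValueError("need at least one subfamily")
        if self.n_tandem_arrays + self.n_segmental_pairs > self.n_subfamilies:
            raise ValueError(
                "more tandem arrays + segmental pairs than subfamilies"
            )
        if self.n_segmental_pairs > 6:
            raise ValueError("at most 6 segmental pairs (19 chromosomes)")
        if self.n_segmental_pairs and lo < 2:
            raise ValueError("segmental pairs need >= 2 members per subfamily")
        if self.lost_subfamilies >= self.n_subfamilies:
            raise ValueError("cannot lose every subfamily from genome 2")
        if not 0.0 < self.module_pcc < 1.0:
            raise ValueError("module_pcc must be in (0, 1)")

    def subfamily_labels(self) -> tuple[str, ...]:
        if self.n_subfamilies <= len(SUBFAMILIES):
            return SUBFAMILIES[: self.n_subfamilies]
        extra = tuple(
            f"SF{i:02d}" for i in range(len(SUBFAMILIES), self.n_subfamilies)
        )
        return SUBFAMILIES + extra


@dataclass
class GroundTruth:
    subfamily: dict[str, str] = field(default_factory=dict)
    ortholog_pairs: dict[str, str] = field(default_factory=dict)
    lost_subfamilies: list[str] = field(default_factory=list)
    lineage_duplicates: dict[str, str] = field(default_factory=dict)
    motif_coordinates: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    tandem_arrays: list[list[str]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)
    module_genes: list[str] = field(default_factory=list)
    tissue_specific: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedFamily:
    genome1: list[ProteinRecord]
    genome2: list[ProteinRecord]
    table: GeneFamilyTable
    segment_map: ParalogousSegmentMap
    truth: GroundTruth
    config: SimulationConfig


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(20, size=length, p=_AA_FREQ)


def _mutate(rng: np.random.Generator, seq: np.ndarray, q: float) -> np.ndarray:
    """Substitute each site with probability q; replacements are drawn from
    the background frequencies excluding the original residue."""
    out = seq.copy()
    hit = np.where(rng.random(len(seq)) < q)[0]
    for i in hit:
        p = _AA_FREQ.copy()
        p[out[i]] = 0.0
        out[i] = rng.choice(20, p=p / p.sum())
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_AA20[i] for i in seq)


def _instantiate(rng: np.random.Generator, pattern: MotifPattern) -> np.ndarray:
    out = []
    for pos in pattern.positions:
        if pos is None:
            out.append(rng.choice(20, p=_AA_FREQ))
        else:
            choices = sorted(pos)
            out.append(_AA20.index(choices[int(rng.integers(len(choices)))]))
    return np.array(out, dtype=int)


def simulate_family(config: SimulationConfig | None = None) -> SimulatedFamily:
    """Generate two genomes, a locus table, a segment map and ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    labels = config.subfamily_labels()
    catalog = {m.name: m for m in default_catalog()}
    plan = (
        config.planted_motifs
        if config.planted_motifs is not None
        else default_planted_motifs(labels)
    )
    truth = GroundTruth()

    lo, hi = config.protein_length
    root = _random_sequence(rng, hi)
    members_lo, members_hi = config.members_per_subfamily
    genome1: list[ProteinRecord] = []
    by_subfamily: dict[str, list[int]] = {}
    seqs: list[np.ndarray] = []
    subfamily_of: list[str] = []
    for s, label in enumerate(labels):
        length = int(rng.integers(lo, hi + 1))
        ancestor = _mutate(rng, root, config.between_subfamily_divergence / 2.0)
        ancestor = ancestor[hi - length :]  # N-terminal variable region trimmed
        n_members = int(rng.integers(members_lo, members_hi + 1))
        # one concrete motif instance per (motif, subfamily): exactly
        # conserved within the subfamily after planting
        instances = {}
        for motif_name, targets in plan:
            if label in targets:
                instances[motif_name] = _instantiate(rng, catalog[motif_name])
        for _ in range(n_members):
            member = _mutate(rng, ancestor, config.within_subfamily_divergence / 2.0)
            coords: dict[str, tuple[int, int]] = {}
            for motif_name, inst in instances.items():
                anchor, offset = _MOTIF_LAYOUT[motif_name]
                start = offset if anchor == "N" else length - offset
                member[start : start + len(inst)] = inst
                coords[motif_name] = (start + 1, start + len(inst))
            idx = len(seqs)
            seqs.append(member)
            subfamily_of.append(label)
            by_subfamily.setdefault(label, []).append(idx)
            truth.motif_coordinates[idx] = coords  # re-keyed after naming

    # --- chromosomal layout -------------------------------------------------
    tandem_labels = list(labels[: config.n_tandem_arrays])
    segmental_labels = list(labels[len(labels) - config.n_segmental_pairs :])
    chrom_of = {}
    pos_of = {}
    for s, label in enumerate(labels):
        home = (s % 13) + 1
        pos = 1_000_000
        for k, idx in enumerate(by_subfamily[label]):
            gene_len = 3 * len(seqs[idx]) + 3
            chrom_of[idx] = home
            pos_of[idx] = pos
            if label in tandem_labels:
                pos += gene_len + config.tandem_gap_bp
            else:
                pos += gene_len + 2_000_000
    seg_pairs_intervals = []
    for k, label in enumerate(segmental_labels):
        a, b = by_subfamily[label][0], by_subfamily[label][1]
        partner = 14 + k
        chrom_of[b] = partner
        pos_of[b] = 1_000_000
        ga = (chrom_of[a], pos_of[a], pos_of[a] + 3 * len(seqs[a]) + 2)
        gb = (partner, pos_of[b], pos_of[b] + 3 * len(seqs[b]) + 2)
        seg_pairs_intervals.append(
            (
                (ga[0], ga[1] - 1_000, ga[2] + 1_000),
                (gb[0], gb[1] - 1_000, gb[2] + 1_000),
                a,
                b,
            )
        )

    # --- naming, loci, records ---------------------------------------------
    ids: list[str] = []
    loci: list[Locus] = []
    for idx, seq in enumerate(seqs):
        gid = f"Gv{chrom_of[idx]:02d}g{idx + 1:05d}"
        ids.append(gid)
        start = pos_of[idx]
        end = start + 3 * len(seq) + 2
        loci.append(
            Locus(
                locus_id=gid,
                short_name=f"{subfamily_of[idx]}{idx + 1}",
                chromosome=chrom_of[idx],
                strand="+" if idx % 2 == 0 else "-",
                segments=((start, end),),
            )
        )
        genome1.append(
            ProteinRecord(
                id=gid,
                sequence=_to_str(seq),
                subfamily=subfamily_of[idx],
                genome="GV",
            )
        )
        truth.subfamily[gid] = subfamily_of[idx]
    truth.motif_coordinates = {
        ids[idx]: coords for idx, coords in truth.motif_coordinates.items()
    }
    truth.tandem_arrays = [
        [ids[i] for i in by_subfamily[label]] for label in tandem_labels
    ]
    truth.segmental_pairs = [
        (ids[a], ids[b]) for *_ignored, a, b in seg_pairs_intervals
    ]
    segment_map = ParalogousSegmentMap(
        pairs=[(ia, ib) for ia, ib, _, _ in seg_pairs_intervals]
    )
    table = GeneFamilyTable(loci=loci, name="synthetic")

    # --- second genome: orthologs, losses, lineage-specific duplicates ------
    lost = list(
        labels[config.n_tandem_arrays : config.n_tandem_arrays + config.lost_subfamilies]
    )
    truth.lost_subfamilies = lost
    genome2: list[ProteinRecord] = []
    ortholog_seq: dict[str, np.ndarray] = {}
    for idx, seq in enumerate(seqs):
        if subfamily_of[idx] in lost:
            continue
        oseq = _mutate(rng, seq, config.ortholog_divergence)
        oid = "Gx" + ids[idx][2:]
        ortholog_seq[oid] = oseq
        genome2.append(
            ProteinRecord(
                id=oid,
                sequence=_to_str(oseq),
                subfamily=subfamily_of[idx],
                genome="GX",
            )
        )
        truth.ortholog_pairs[ids[idx]] = oid
    dup_sources = [r.id for r in genome2[: config.n_lineage_duplicates]]
    for oid in dup_sources:
        dseq = _mutate(rng, ortholog_seq[oid], config.duplicate_divergence)
        did = "Gd" + oid[2:]
        genome2.append(
            ProteinRecord(id=did, sequence=_to_str(dseq), genome="GX")
        )
        truth.lineage_duplicates[did] = oid

    return SimulatedFamily(
        genome1=genome1,
        genome2=genome2,
        table=table,
        segment_map=segment_map,
        truth=truth,
        config=config,
    )


_TISSUES = (
    ("leaf", "PO:0025034"),
    ("root", "PO:0009005"),
    ("berry", "PO:0009001"),
    ("flower", "PO:0009046"),
    ("seed", "PO:0009010"),
    ("stem", "PO:0009047"),
    ("tendril", "PO:0025361"),
    ("pollen", "PO:0025281"),
    ("bud", "PO:0000055"),
    ("rachis", "PO:0020122"),
)


def simulate_expression(
    config: SimulationConfig, gene_ids: list[str]
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Replicated expression matrix with a planted co-expression module and
    planted tissue-specific genes.

    Condition means sit around a log2 baseline of ~6; module genes share a
    per-condition latent factor scaled so pairwise Pearson correlation hits
    the configured target; tissue-specific genes are boosted to >= 8 in
    their tissue.  Each condition carries 3 or 4 replicates with small
    independent noise.
    """
    if config.expr_n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    if config.expr_module_size > len(gene_ids):
        raise ValueError("module larger than gene set")
    rng = np.random.default_rng(config.seed + 1)
    n_cond = config.expr_n_conditions
    genes = list(gene_ids)
    truth = GroundTruth()
    module = sorted(
        rng.choice(len(genes), size=config.expr_module_size, replace=False).tolist()
    )
    truth.module_genes = [genes[i] for i in module]
    non_module = [i for i in range(len(genes)) if i not in set(module)]
    specific = rng.choice(
        len(non_module), size=min(config.n_tissue_specific, len(non_module)),
        replace=False,
    )
    tissue_names = [_TISSUES[c % len(_TISSUES)][0] for c in range(n_cond)]
    for k, i in enumerate(sorted(specific.tolist())):
        tissue = _TISSUES[k % len(_TISSUES)][0]
        truth.tissue_specific[genes[non_module[i]]] = tissue

    baseline = 6.0 + 0.5 * rng.standard_normal(len(genes))
    scale = 1.5
    rho = config.module_pcc
    z = rng.standard_normal(n_cond)  # shared module factor per condition
    noise = rng.standard_normal((len(genes), n_cond))
    means = baseline[:, None] + scale * noise
    for i in module:
        means[i] = baseline[i] + scale * (
            np.sqrt(rho) * z + np.sqrt(1.0 - rho) * noise[i]
        )
    for gene, tissue in truth.tissue_specific.items():
        gi = genes.index(gene)
        cols = [c for c in range(n_cond) if tissue_names[c] == tissue]
        means[gi, cols] = np.maximum(means[gi, cols], 8.0) + 1.0

    samples, cols, meta_rows = [], [], []
    for c in range(n_cond):
        tissue, po = _TISSUES[c % len(_TISSUES)]
        n_rep = 3 if c % 2 == 0 else 4
        for r in range(n_rep):
            sid = f"c{c + 1:03d}_r{r + 1}"
            samples.append(sid)
            cols.append(means[:, c] + 0.15 * rng.standard_normal(len(genes)))
            meta_rows.append(
                {
                    "sample": sid,
                    "condition": f"c{c + 1:03d}",
                    "tissue": tissue,
                    "po_id": po,
                    "platform": "synthetic-array",
                }
            )
    values = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=samples
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values=values, sample_metadata=metadata), truth


def write_family(sim: SimulatedFamily, out_dir: str | Path) -> dict[str, Path]:
    """Write all simulated artifacts; returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome1": out / "genome1.faa",
        "genome2": out / "genome2.faa",
        "loci": out / "loci.tsv",
        "gff3": out / "loci.gff3",
        "segment_map": out / "segment_map.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_fasta(sim.genome1, paths["genome1"])
    write_fasta(sim.genome2, paths["genome2"])
    write_locus_table(sim.table, paths["loci"])
    write_gff3(sim.table, paths["gff3"])
    write_segment_map(sim.segment_map, paths["segment_map"])
    sim.truth.to_json(paths["ground_truth"])
    return paths
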