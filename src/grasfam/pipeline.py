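"""End-to-end orchestration of the family-characterization stages.

Stage order follows the analysis logic: structure statistics, phylogeny and
subfamily assignment, motif annotation, cross-genome orthology, duplication
classification, expression analysis.  Every run writes per-stage text outputs
plus a ``report.json`` recording package version, seed and a config hash, so
identical config + inputs + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import AlignmentParams, progressive_msa
from .duplication import segmental_pairs, tandem_arrays, write_calls_tsv
from .expression import (
    ExpressionParams,
    average_replicates,
    coexpression_clusters,
    po_attribution,
    write_clusters_tsv,
    write_expression_matrix,
)
from .motifs import (
    ConservedWindowRule,
    annotate,
    default_catalog,
    discover_conserved_windows,
    write_annotations_tsv,
)
from .orthology import OrthologyThresholds, classify, write_orthology_matrix
from .phylogeny import (
    PhyloParams,
    assign_subfamilies,
    bootstrap_consensus,
    mask_columns,
)
from .structure_stats import summarize
from .synthetic import SimulationConfig, simulate_expression, simulate_family, write_family

ALL_STAGES = (
    "structure",
    "phylo",
    "motifs",
    "orthology",
    "duplication",
    "expression",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


_SECTIONS = {
    "alignment": AlignmentParams,
    "orthology": OrthologyThresholds,
    "phylo": PhyloParams,
    "window_rule": ConservedWindowRule,
    "expression": ExpressionParams,
    "simulation": SimulationConfig,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "grasfam_out"
    stages: tuple[str, ...] = ALL_STAGES
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    orthology: OrthologyThresholds = field(default_factory=OrthologyThresholds)
    phylo: PhyloParams = field(default_factory=PhyloParams)
    window_rule: ConservedWindowRule = field(default_factory=ConservedWindowRule)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in _SECTIONS:
                section_cls = _SECTIONS[key]
                names = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - names
                if bad:
                    raise ValueError(
                        f"unknown keys in section {key!r}: {sorted(bad)}"
                    )
                value = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = section_cls(**value)
            elif key == "stages":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where outputs land, not what they are
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run the configured stages on a simulated family; returns the report.

    The simulation seed is tied to the global pipeline seed so one flag
    controls every source of randomness.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = dataclasses.replace(config.simulation, seed=config.seed)
    sim = simulate_family(sim_config)
    write_family(sim, out / "inputs")
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    assignment = None

    if "structure" in config.stages:
        try:
            summary = summarize(sim.table)
            (out / "structure_summary.json").write_text(
                json.dumps(summary.to_dict(), indent=1, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            report["stages"]["structure"] = {
                "n_loci": summary.n_loci,
                "n_intronless": summary.n_intronless,
                "pct_intronless": summary.pct_intronless,
            }
        except Exception as exc:
            raise PipelineError("structure", str(exc)) from exc

    if "phylo" in config.stages:
        try:
            msa = progressive_msa(sim.genome1, config.alignment)
            masked = mask_columns(msa, config.phylo.min_site_coverage)
            phylo = dataclasses.replace(config.phylo, seed=config.seed)
            tree = bootstrap_consensus(masked, phylo)
            anchors: dict[str, str] = {}
            for record in sim.genome1:  # first member of each subfamily
                if record.subfamily not in anchors.values():
                    anchors[record.id] = record.subfamily
            assignment = assign_subfamilies(tree, anchors)
            (out / "consensus_tree.nwk").write_text(
                tree.newick(lengths=False) + "\n", encoding="utf-8"
            )
            with open(out / "subfamilies.tsv", "w", encoding="utf-8") as fh:
                fh.write("gene\tsubfamily\n")
                for record in sim.genome1:
                    fh.write(f"{record.id}\t{assignment.label(record.id)}\n")
            n_correct = sum(
                1
                for record in sim.genome1
                if assignment.label(record.id) == sim.truth.subfamily[record.id]
            )
            report["stages"]["phylo"] = {
                "n_leaves": len(sim.genome1),
                "n_unassigned": len(assignment.unassigned),
                "label_accuracy": n_correct / len(sim.genome1),
            }
        except Exception as exc:
            raise PipelineError("phylo", str(exc)) from exc

    if "motifs" in config.stages:
        try:
            catalog = default_catalog()
            annotations = [annotate(r, catalog) for r in sim.genome1]
            write_annotations_tsv(annotations, out / "motif_annotations.tsv")
            by_subfamily: dict[str, list] = {}
            for record in sim.genome1:
                by_subfamily.setdefault(record.subfamily, []).append(record)
            n_windows = 0
            with open(out / "conserved_windows.tsv", "w", encoding="utf-8") as fh:
                fh.write("subfamily\tstart_col\tend_col\tmean_identity\n")
                for label, records in sorted(by_subfamily.items()):
                    if len(records) < 2:
                        continue
                    sub_msa = progressive_msa(records, config.alignment)
                    for (s, e), idents in discover_conserved_windows(
                        sub_msa, config.window_rule
                    ):
                        n_windows += 1
                        fh.write(
                            f"{label}\t{s}\t{e}\t"
                            f"{sum(idents) / len(idents):.3f}\n"
                        )
            report["stages"]["motifs"] = {
                "n_annotated": len(annotations),
                "n_conserved_windows": n_windows,
            }
        except Exception as exc:
            raise PipelineError("motifs", str(exc)) from exc

    if "orthology" in config.stages:
        try:
            calls = classify(
                sim.genome1,
                sim.genome2,
                config.orthology,
                config.alignment,
                target_genome="GX",
            )
            write_orthology_matrix({"GX": calls}, out / "orthology_matrix.tsv")
            counts = {"one_to_one": 0, "homolog_no_ortholog": 0, "absent": 0}
            for c in calls:
                counts[c.category] += 1
            report["stages"]["orthology"] = counts
        except Exception as exc:
            raise PipelineError("orthology", str(exc)) from exc

    if "duplication" in config.stages:
        try:
            labels = (
                assignment
                if assignment is not None
                else {r.id: r.subfamily for r in sim.genome1}
            )
            tandem = tandem_arrays(sim.table, labels)
            segmental = segmental_pairs(sim.table, labels, sim.segment_map)
            write_calls_tsv(tandem + segmental, out / "duplications.tsv")
            report["stages"]["duplication"] = {
                "n_tandem_arrays": len(tandem),
                "n_segmental_pairs": len(segmental),
            }
        except Exception as exc:
            raise PipelineError("duplication", str(exc)) from exc

    if "expression" in config.stages:
        try:
            gene_ids = [r.id for r in sim.genome1]
            matrix, expr_truth = simulate_expression(sim_config, gene_ids)
            write_expression_matrix(
                matrix, out / "expression.tsv", out / "expression_samples.tsv"
            )
            averaged = average_replicates(matrix)
            attribution = po_attribution(averaged, config.expression)
            (out / "po_attribution.json").write_text(
                json.dumps(
                    {g: sorted(v) for g, v in attribution.items()},
                    indent=1,
                    sort_keys=True,
                )
                + "\n",
                encoding="utf-8",
            )
            result = coexpression_clusters(averaged, config.expression)
            write_clusters_tsv(result, out / "coexpression_clusters.tsv")
            report["stages"]["expression"] = {
                "n_conditions": len(averaged.samples),
                "n_clusters": len(result.clusters),
                "n_attributed": sum(1 for v in attribution.values() if v),
            }
        except Exception as exc:
            raise PipelineError("expression", str(exc)) from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
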