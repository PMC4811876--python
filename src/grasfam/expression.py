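"""Expression-atlas thresholding and co-expression clustering.

Works on RMA-normalized log2 intensities (genes x samples).  Replicates of a
condition are averaged in log2 space; a Plant Ontology (PO) tissue term is
attributed to a gene when its averaged intensity reaches log2 = 8 (raw 256)
in any condition of that tissue — inclusive, so a raw value of exactly 256
counts.  Co-expression uses distance = 1 - Pearson correlation across
condition averages with average-linkage hierarchical clustering; reported
clusters are then verified against a strict complete-pair criterion: every
within-cluster pair must sit at distance strictly below the cutoff
(default 0.2), and violating clusters are re-split by complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ExpressionParams:
    po_log2_threshold: float = 8.0
    coexpr_distance_cutoff: float = 0.2
    #: inclusive (>=) PO gate by default so that raw 256 = 2**8 is attributed
    strict_po_threshold: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.po_log2_threshold):
            raise ValueError("po_log2_threshold must be finite")
        if not 0.0 <= self.coexpr_distance_cutoff <= 2.0:
            raise ValueError("coexpr_distance_cutoff must be in [0, 2]")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities plus per-sample metadata.

    ``sample_metadata`` is indexed by sample id with columns ``condition``,
    ``tissue`` and optionally ``po_id`` and ``platform``.
    """

    values: pd.DataFrame
    sample_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        missing = set(self.values.columns) - set(self.sample_metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression_matrix(
    values_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values=values, sample_metadata=metadata)


def write_expression_matrix(
    matrix: ExpressionMatrix, values_path: str | Path, metadata_path: str | Path
) -> None:
    matrix.values.to_csv(values_path, sep="\t", lineterminator="\n")
    matrix.sample_metadata.to_csv(metadata_path, sep="\t", lineterminator="\n")


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean over replicates of each condition, in log2 space.

    The returned matrix has one column per condition; tissue/PO/platform
    metadata is propagated from the condition's samples.
    """
    meta = matrix.sample_metadata
    if "condition" not in meta.columns:
        raise ValueError("sample metadata needs a 'condition' column")
    if meta.loc[list(matrix.samples), "condition"].isna().any():
        raise ValueError("every sample must be assigned a condition")
    conditions = meta.loc[list(matrix.samples)].groupby("condition", sort=True)
    cols, rows = {}, []
    for condition, samples in conditions.groups.items():
        if len(samples) == 0:
            raise ValueError(f"condition {condition!r} has no samples")
        cols[condition] = matrix.values[list(samples)].mean(axis=1)
        info = meta.loc[list(samples)[0]].to_dict()
        info["condition"] = condition
        info["n_replicates"] = len(samples)
        rows.append(info)
    averaged = pd.DataFrame(cols)
    cond_meta = pd.DataFrame(rows).set_index("condition", drop=False)
    cond_meta.index.name = "sample"
    return ExpressionMatrix(values=averaged, sample_metadata=cond_meta)


def po_attribution(
    matrix: ExpressionMatrix, params: ExpressionParams | None = None
) -> dict[str, set[str]]:
    """PO terms whose tissue shows intensity at/above the threshold.

    Conditions lacking a PO id contribute nothing.  The gate is inclusive by
    default (>= 8.0, i.e. raw 256 attributed); ``strict_po_threshold``
    switches to a strict inequality.
    """
    params = params or ExpressionParams()
    meta = matrix.sample_metadata
    if "po_id" not in meta.columns:
        return {gene: set() for gene in matrix.genes}
    out: dict[str, set[str]] = {gene: set() for gene in matrix.genes}
    thr = params.po_log2_threshold
    for condition in matrix.samples:
        po = meta.loc[condition].get("po_id")
        if po is None or (isinstance(po, float) and np.isnan(po)) or po == "":
            continue
        col = matrix.values[condition]
        passed = col > thr if params.strict_po_threshold else col >= thr
        for gene in col.index[passed]:
            out[gene].add(po)
    return out


@dataclass
class CoexpressionResult:
    clusters: list[list[str]]  # each of size >= 2
    distances: pd.DataFrame  # 1 - PCC, over non-constant genes
    excluded: list[str]  # constant-profile genes (undefined correlation)
    genes: list[str]  # every input gene

    def cluster_of(self, gene: str) -> list[str] | None:
        for cluster in self.clusters:
            if gene in cluster:
                return cluster
        return None


def coexpression_clusters(
    matrix: ExpressionMatrix, params: ExpressionParams | None = None
) -> CoexpressionResult:
    """Average-linkage clustering on 1 - Pearson correlation with a strict
    complete-pair cutoff.

    The average-linkage tree is cut at the distance cutoff; any resulting
    cluster containing a pair at distance >= cutoff is re-split by complete
    linkage just below the cutoff, so the reported clusters satisfy the
    pairwise bound exactly.  Singletons are unclustered; constant-profile
    genes are excluded up front with a warning.
    """
    params = params or ExpressionParams()
    if matrix.values.shape[1] < 2:
        raise ValueError("co-expression needs at least 2 conditions")
    values = matrix.values
    constant = values.std(axis=1, ddof=0) == 0.0
    excluded = list(values.index[constant])
    if excluded:
        warnings.warn(
            f"constant-profile genes excluded from clustering: {excluded}"
        )
    values = values.loc[~constant]
    genes = list(values.index)
    cutoff = params.coexpr_distance_cutoff
    if len(genes) < 2:
        dist_df = pd.DataFrame(index=genes, columns=genes, dtype=float)
        return CoexpressionResult([], dist_df, excluded, list(matrix.genes))
    corr = np.corrcoef(values.to_numpy())
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    # round so a pair at nominal distance 0.2 compares equal to the cutoff
    # (1 - 0.8 lands one ulp short of 0.2 in binary floating point) and the
    # strict < excludes it
    D = np.round(D, 12)
    dist_df = pd.DataFrame(D, index=genes, columns=genes)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    flat = fcluster(Z, t=cutoff, criterion="distance")
    clusters: list[list[str]] = []
    strict_t = np.nextafter(cutoff, 0.0)
    for cid in np.unique(flat):
        members = [genes[i] for i in np.where(flat == cid)[0]]
        if len(members) < 2:
            continue
        sub = dist_df.loc[members, members].to_numpy()
        if (sub[np.triu_indices(len(members), 1)] < cutoff).all():
            clusters.append(sorted(members))
            continue
        # complete-linkage heights bound the max within-cluster pair, so a
        # cut strictly below the cutoff enforces the pairwise criterion
        subZ = linkage(squareform(sub, checks=False), method="complete")
        subflat = fcluster(subZ, t=strict_t, criterion="distance")
        for scid in np.unique(subflat):
            sub_members = [members[i] for i in np.where(subflat == scid)[0]]
            if len(sub_members) >= 2:
                clusters.append(sorted(sub_members))
    clusters.sort()
    for cluster in clusters:  # assertable post-condition
        sub = dist_df.loc[cluster, cluster].to_numpy()
        assert (sub[np.triu_indices(len(cluster), 1)] < cutoff).all()
    return CoexpressionResult(clusters, dist_df, excluded, list(matrix.genes))


def partners(gene: str, result: CoexpressionResult) -> list[str]:
    """Other members of the gene's cluster (empty if unclustered)."""
    if gene not in result.genes:
        raise KeyError(gene)
    cluster = result.cluster_of(gene)
    if cluster is None:
        return []
    return [g for g in cluster if g != gene]


def write_clusters_tsv(result: CoexpressionResult, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cluster\tgene\tmean_within_distance\n")
        for cid, cluster in enumerate(result.clusters, 1):
            for gene in cluster:
                others = [g for g in cluster if g != gene]
                mean_d = float(result.distances.loc[gene, others].mean())
                fh.write(f"{cid}\t{gene}\t{mean_d:.4f}\n")
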