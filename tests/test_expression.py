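"""Replicate averaging, PO attribution and co-expression clustering."""

import numpy as np
import pandas as pd
import pytest

from grasfam.expression import (
    ExpressionMatrix,
    ExpressionParams,
    average_replicates,
    coexpression_clusters,
    partners,
    po_attribution,
)
from grasfam.synthetic import simulate_expression


def _matrix(values, genes, samples, conditions, tissues=None, po=None):
    tissues = tissues or ["leaf"] * len(samples)
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "tissue": tissues,
            "po_id": po if po is not None else ["PO:0025034"] * len(samples),
        },
        index=samples,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_metadata=meta,
    )


class TestAverageReplicates:
    def test_constant_replicates_average_to_value(self):
        m = _matrix(
            [[8.0, 8.0, 8.0, 8.0]], ["g1"],
            ["s1", "s2", "s3", "s4"], ["c1"] * 4,
        )
        avg = average_replicates(m)
        assert avg.values.loc["g1", "c1"] == 8.0
        assert avg.samples == ["c1"]

    def test_mean_in_log2_space(self):
        m = _matrix([[7.0, 9.0]], ["g1"], ["s1", "s2"], ["c1", "c1"])
        assert average_replicates(m).values.loc["g1", "c1"] == 8.0

    def test_mixed_replicate_design(self, small_config):
        matrix, _ = simulate_expression(
            small_config, [f"g{i}" for i in range(15)]
        )
        avg = average_replicates(matrix)
        n_conditions = matrix.sample_metadata["condition"].nunique()
        assert len(avg.samples) == n_conditions == small_config.expr_n_conditions
        reps = matrix.sample_metadata.groupby("condition").size()
        assert set(reps) == {3, 4}

    def test_metadata_propagated(self):
        m = _matrix(
            [[1.0, 2.0]], ["g1"], ["s1", "s2"], ["c1", "c1"],
            tissues=["root", "root"], po=["PO:0009005"] * 2,
        )
        avg = average_replicates(m)
        assert avg.sample_metadata.loc["c1", "tissue"] == "root"
        assert avg.sample_metadata.loc["c1", "po_id"] == "PO:0009005"


class TestPoAttribution:
    def _avg(self, value):
        m = _matrix([[value]], ["g1"], ["s1"], ["c1"])
        return average_replicates(m)

    def test_above_threshold_attributed(self):
        assert po_attribution(self._avg(8.3))["g1"] == {"PO:0025034"}

    def test_below_threshold_everywhere_empty(self):
        assert po_attribution(self._avg(7.9))["g1"] == set()

    def test_exact_threshold_is_inclusive(self):
        assert po_attribution(self._avg(8.0))["g1"] == {"PO:0025034"}
        strict = ExpressionParams(strict_po_threshold=True)
        assert po_attribution(self._avg(8.0), strict)["g1"] == set()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        values = 6 + 3 * rng.random((10, 6))
        m = _matrix(
            values, [f"g{i}" for i in range(10)],
            [f"s{j}" for j in range(6)], [f"c{j}" for j in range(6)],
            tissues=["leaf", "root"] * 3,
            po=["PO:1", "PO:2"] * 3,
        )
        avg = average_replicates(m)
        low = po_attribution(avg, ExpressionParams(po_log2_threshold=7.0))
        high = po_attribution(avg, ExpressionParams(po_log2_threshold=8.5))
        for gene in low:
            assert high[gene] <= low[gene]


class TestCoexpressionClusters:
    def test_identical_profiles_cluster_at_distance_zero(self):
        profile = [1.0, 5.0, 3.0, 8.0]
        m = _matrix(
            [profile, profile, [2.0, 1.0, 7.0, 3.0]],
            ["g1", "g2", "g3"],
            [f"s{j}" for j in range(4)], [f"c{j}" for j in range(4)],
        )
        res = coexpression_clusters(average_replicates(m))
        assert res.distances.loc["g1", "g2"] == 0.0
        assert ["g1", "g2"] in res.clusters

    def test_pcc_three_quarters_never_coclusters(self):
        # PCC 0.75 -> distance 0.25 > 0.2
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = 0.75 * x + np.sqrt(1 - 0.75**2) * np.array(
            [1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0]
        )
        m = _matrix(
            [x, y], ["g1", "g2"],
            [f"s{j}" for j in range(8)], [f"c{j}" for j in range(8)],
        )
        res = coexpression_clusters(average_replicates(m))
        assert res.distances.loc["g1", "g2"] == pytest.approx(0.25)
        assert res.clusters == []

    def test_distance_exactly_at_cutoff_excluded(self):
        # these profiles have Pearson correlation exactly 0.8, i.e. distance
        # exactly the 0.2 cutoff; "lower than" is strict
        m = _matrix(
            [[1.0, -1.0, 1.0, -1.0], [7.0, -1.0, 1.0, -7.0]],
            ["g1", "g2"],
            [f"s{j}" for j in range(4)], [f"c{j}" for j in range(4)],
        )
        res = coexpression_clusters(average_replicates(m))
        assert float(res.distances.loc["g1", "g2"]) == 0.2
        assert res.clusters == []

    def test_constant_gene_excluded_with_warning(self):
        m = _matrix(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
            ["g1", "gflat"],
            [f"s{j}" for j in range(3)], [f"c{j}" for j in range(3)],
        )
        with pytest.warns(UserWarning, match="constant"):
            res = coexpression_clusters(average_replicates(m))
        assert res.excluded == ["gflat"]

    def test_planted_module_recovered_intact(self, small_config):
        genes = [f"g{i:02d}" for i in range(30)]
        matrix, truth = simulate_expression(small_config, genes)
        res = coexpression_clusters(average_replicates(matrix))
        assert set(truth.module_genes) in [set(c) for c in res.clusters]

    def test_within_cluster_pairs_below_cutoff(self, small_config):
        genes = [f"g{i:02d}" for i in range(30)]
        matrix, _ = simulate_expression(small_config, genes)
        res = coexpression_clusters(average_replicates(matrix))
        for cluster in res.clusters:
            for i, a in enumerate(cluster):
                for b in cluster[i + 1 :]:
                    assert res.distances.loc[a, b] < 0.2

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.random((3, 6))
        m1 = _matrix(
            base, ["g1", "g2", "g3"],
            [f"s{j}" for j in range(6)], [f"c{j}" for j in range(6)],
        )
        scaled = base * np.array([[2.0], [5.0], [0.5]]) + np.array(
            [[1.0], [-3.0], [4.0]]
        )
        m2 = _matrix(
            scaled, ["g1", "g2", "g3"],
            [f"s{j}" for j in range(6)], [f"c{j}" for j in range(6)],
        )
        d1 = coexpression_clusters(average_replicates(m1)).distances
        d2 = coexpression_clusters(average_replicates(m2)).distances
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_fewer_than_two_conditions_rejected(self):
        m = _matrix([[1.0]], ["g1"], ["s1"], ["c1"])
        with pytest.raises(ValueError, match="2 conditions"):
            coexpression_clusters(average_replicates(m))


@pytest.fixture(scope="module")
def result(small_config):
    genes = [f"g{i:02d}" for i in range(30)]
    matrix, _ = simulate_expression(small_config, genes)
    return coexpression_clusters(average_replicates(matrix))


class TestPartners:
    def test_unclustered_gene_has_no_partners(self, result):
        clustered = {g for c in result.clusters for g in c}
        lonely = [g for g in result.genes if g not in clustered]
        assert lonely and partners(lonely[0], result) == []

    def test_module_member_partners(self, small_config):
        genes = [f"g{i:02d}" for i in range(30)]
        matrix, truth = simulate_expression(small_config, genes)
        result = coexpression_clusters(average_replicates(matrix))
        member = truth.module_genes[0]
        assert set(partners(member, result)) == set(truth.module_genes) - {member}

    def test_symmetry(self, result):
        for cluster in result.clusters:
            for a in cluster:
                for b in partners(a, result):
                    assert a in partners(b, result)

    def test_unknown_gene_rejected(self, result):
        with pytest.raises(KeyError):
            partners("nope", result)
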