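"""Linkage trees, cluster extraction, chaining paths and state dendrograms."""

import io

import numpy as np
import pandas as pd
import pytest

from chescatools import (
    CCSMatrix,
    CorrelationMatrix,
    agglomerate,
    build_matrix,
    chain_path,
    classify_cluster,
    correlation_matrix,
    cut_clusters,
    state_dendrogram,
)
from chescatools.exceptions import DegenerateInputError
from chescatools.shift_io import ActivityClass, StateMeta

from conftest import FIVE_STATES, dataset_from_profiles, random_correlation_matrix


def corr(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or list(range(1, len(values) + 1))
    return CorrelationMatrix(pd.DataFrame(values, index=ids, columns=ids))


@pytest.fixture
def three_residue_r():
    # r(A,B)=0.995, r(B,C)=0.99, r(A,C)=0.80, with A,B,C = 1,2,3
    return corr([[1.0, 0.995, 0.80], [0.995, 1.0, 0.99], [0.80, 0.99, 1.0]])


class TestAgglomerate:
    def test_hand_evaluated_three_leaf_recursion(self, three_residue_r):
        """Single links at min inter-cluster d, complete at max."""
        single = agglomerate(three_residue_r, "single")
        assert single.heights == pytest.approx([0.005, 0.01])
        complete = agglomerate(three_residue_r, "complete")
        assert complete.heights == pytest.approx([0.005, 0.20])

    def test_perfect_correlations_merge_at_zero(self):
        r = corr(np.ones((4, 4)))
        for method in ("single", "complete"):
            assert agglomerate(r, method).heights == pytest.approx([0, 0, 0])

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = random_correlation_matrix(rng, int(rng.integers(3, 12)))
            for method in ("single", "complete"):
                h = agglomerate(r, method).heights
                assert (np.diff(h) >= -1e-12).all()

    def test_too_few_residues(self):
        with pytest.raises(DegenerateInputError):
            agglomerate(corr([[1.0]]), "single")

    def test_absolute_value_distance_clusters_anticorrelations(self):
        r = corr([[1.0, -0.999, 0.1], [-0.999, 1.0, 0.05], [0.1, 0.05, 1.0]])
        d = agglomerate(r, "single")
        assert d.heights[0] == pytest.approx(0.001)
        # signed distances put the anti-correlated pair at d = 1 - r ~ 2, so
        # the first merge is the weakly positive pair (1,3) instead
        d_signed = agglomerate(r, "single", signed=True)
        assert d_signed.heights == pytest.approx([0.9, 0.95])


def naive_agglomeration(d, method):
    """O(n^3) reference agglomeration; returns merge heights in order."""
    n = len(d)
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pair_d = [d[a][b] for a in clusters[i] for b in clusters[j]]
                dist = min(pair_d) if method == "single" else max(pair_d)
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return heights


class TestOracleEquivalence:
    @pytest.mark.parametrize("method", ["single", "complete"])
    def test_matches_naive_agglomeration(self, method):
        rng = np.random.default_rng(123)
        for _ in range(15):
            n = int(rng.integers(3, 13))
            r = random_correlation_matrix(rng, n)
            d = 1.0 - np.abs(r.values.to_numpy())
            np.fill_diagonal(d, 0.0)
            expected = sorted(naive_agglomeration(d, method))
            got = sorted(agglomerate(r, method).heights)
            assert np.allclose(got, expected, atol=1e-12)


class TestCutClusters:
    def test_cut_three_residue_fixture(self, three_residue_r):
        single = cut_clusters(agglomerate(three_residue_r, "single"), 0.98, 1)
        assert set(single.clusters) == {frozenset({1, 2, 3})}
        complete = cut_clusters(agglomerate(three_residue_r, "complete"), 0.98, 1)
        assert set(complete.clusters) == {frozenset({1, 2}), frozenset({3})}

    def test_min_size_filter(self, three_residue_r):
        cs = cut_clusters(agglomerate(three_residue_r, "single"), 0.98, 4)
        assert len(cs) == 0
        assert cs.residues == frozenset()

    def test_cutoff_one_on_perfect_matrix(self):
        r = corr(np.ones((5, 5)))
        cs = cut_clusters(agglomerate(r, "single"), 1.0, 1)
        assert set(cs.clusters) == {frozenset({1, 2, 3, 4, 5})}

    def test_complete_linkage_guarantee(self):
        """Every reported complete-linkage cluster has min pairwise |r| >= cutoff."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            r = random_correlation_matrix(rng, 10)
            cs = cut_clusters(agglomerate(r, "complete"), 0.6, 2)
            vals = r.values
            for members in cs.clusters:
                ms = sorted(members)
                for i, u in enumerate(ms):
                    for v in ms[i + 1 :]:
                        assert abs(vals.at[u, v]) >= 0.6 - 1e-9

    def test_complete_refines_single(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            r = random_correlation_matrix(rng, 10)
            sl = cut_clusters(agglomerate(r, "single"), 0.6, 1)
            cl = cut_clusters(agglomerate(r, "complete"), 0.6, 1)
            for sub in cl.clusters:
                assert any(sub <= sup for sup in sl.clusters)

    @pytest.mark.parametrize("cutoff", [0.0, 1.5, -0.1])
    def test_cutoff_domain(self, three_residue_r, cutoff):
        d = agglomerate(three_residue_r, "single")
        with pytest.raises(ValueError):
            cut_clusters(d, cutoff)


class TestChainPath:
    def test_indirect_path_through_intermediate(self, three_residue_r):
        assert chain_path(three_residue_r, {1, 2, 3}, 1, 3, 0.98) == [1, 2, 3]

    def test_direct_edge(self, three_residue_r):
        assert chain_path(three_residue_r, {1, 2, 3}, 1, 2, 0.98) == [1, 2]

    def test_no_path_above_cutoff(self, three_residue_r):
        assert chain_path(three_residue_r, {1, 2, 3}, 1, 3, 0.999) is None

    def test_tie_break_prefers_max_bottleneck(self):
        # two 2-hop routes 1-2-4 and 1-3-4; route via 3 has the higher
        # minimum edge correlation and must win
        r = corr(
            [
                [1.0, 0.985, 0.995, 0.5],
                [0.985, 1.0, 0.5, 0.99],
                [0.995, 0.5, 1.0, 0.99],
                [0.5, 0.99, 0.99, 1.0],
            ]
        )
        assert chain_path(r, {1, 2, 3, 4}, 1, 4, 0.98) == [1, 3, 4]


class TestStateDendrogram:
    def test_inhibited_states_merge_first(self):
        """Apo and the reverse agonist pair up before joining the actives."""
        p = np.array([0.2, 0.1, 0.9, 0.95, 1.0])
        ds = dataset_from_profiles({i: a * p for i, a in enumerate((0.3, -0.2, 0.25), 1)})
        m = build_matrix(ds)
        dendro = state_dendrogram(m, {1, 2, 3})
        assert classify_cluster(dendro, ds.states) == "allosteric"
        # first merge joins two states with close activation fractions
        first_pair = {dendro.leaves[int(dendro.merges[0, k])] for k in (0, 1)}
        assert first_pair in ({"apo", "Rp"}, {"cAMP", "Sp"}, {"OMe", "cAMP"})

    def test_identical_columns_merge_at_zero(self):
        values = pd.DataFrame(
            {
                "apo": [1.0, 2.0, 4.0],
                "Rp": [1.0, 2.0, 4.0],
                "OMe": [2.0, 1.0, 3.0],
                "cAMP": [2.1, 1.1, 3.0],
                "Sp": [2.0, 1.2, 3.1],
            },
            index=[1, 2, 3],
        )
        m = CCSMatrix(values, "combined", 0.2)
        dendro = state_dendrogram(m, {1, 2, 3})
        assert dendro.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_residues(self, small_dataset):
        m = build_matrix(small_dataset)
        with pytest.raises(DegenerateInputError):
            state_dendrogram(m, {1, 2})


class TestClassifyCluster:
    def make_dendro(self, pattern):
        ds = dataset_from_profiles(
            {i: a * np.asarray(pattern) for i, a in enumerate((0.3, 0.22, 0.27), 1)}
        )
        return state_dendrogram(build_matrix(ds), {1, 2, 3}), ds.states

    def test_allosteric_split(self):
        dendro, states = self.make_dendro([0.2, 0.1, 0.8, 0.95, 1.0])
        assert classify_cluster(dendro, states) == "allosteric"

    def test_binding_split(self):
        dendro, states = self.make_dendro([0.0, 1.0, 1.05, 0.95, 1.0])
        assert classify_cluster(dendro, states) == "binding"

    def test_mixed_split(self):
        # apo groups with an agonist: matches neither template
        dendro, states = self.make_dendro([0.0, 1.0, 1.0, 1.0, 0.05])
        assert classify_cluster(dendro, states) == "mixed"

    def test_metadata_required(self):
        dendro, _ = self.make_dendro([0.2, 0.1, 0.8, 0.95, 1.0])
        from chescatools.exceptions import MetadataError

        with pytest.raises(MetadataError):
            classify_cluster(dendro, [StateMeta("apo", ActivityClass.APO, False)])


class TestNewick:
    def test_export_is_parseable_with_branch_lengths(self, three_residue_r):
        from Bio import Phylo

        dendro = agglomerate(three_residue_r, "complete")
        tree = Phylo.read(io.StringIO(dendro.to_newick()), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == {"1", "2", "3"}
        # total depth to any leaf equals the root merge height
        depths = tree.depths()
        leaf_depths = [d for c, d in depths.items() if c.name in leaves]
        assert max(leaf_depths) == pytest.approx(0.20, abs=1e-9)
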