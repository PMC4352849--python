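"""Distance-based trees, Newick serialization, bootstrap support, PCA."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
import skbio.tree

import strpop as sp


def _random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns the
    skbio tree and its (additive) tip-tip distance matrix."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    tree = nodes[0]
    ids = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances(endpoints=ids)
    return tree, DistanceMatrix(dm.data, dm.ids)


class TestUpgma:
    def test_two_taxa_split_distance(self):
        dm = DistanceMatrix([[0.0, 0.8], [0.8, 0.0]], ["A", "B"])
        t = sp.upgma(dm)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == {"A": 0.4, "B": 0.4}

    def test_three_taxa_ultrametric_heights(self):
        dm = DistanceMatrix(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]], ["A", "B", "C"]
        )
        t = sp.upgma(dm)
        tt = t.tip_tip_distances()
        assert tt["A", "B"] == pytest.approx(2.0)
        assert tt["A", "C"] == pytest.approx(6.0)
        # root-to-leaf heights all equal (ultrametric)
        depths = {tip.name: tip.accumulate_to_ancestor(t) for tip in t.tips()}
        assert all(abs(d - 3.0) < 1e-9 for d in depths.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_cophenetic_identity_on_ultrametric_inputs(self, seed):
        """scipy average-linkage cophenetic matrices are ultrametric; our
        UPGMA must return them exactly."""
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(8, 4))
        z = linkage(points, method="average")
        ultra = squareform(cophenet(z))
        ids = [f"P{i}" for i in range(8)]
        t = sp.upgma(DistanceMatrix(ultra, ids))
        tt = t.tip_tip_distances(endpoints=ids)
        original = DistanceMatrix(ultra, ids)
        assert np.allclose(tt.data, original.filter(tt.ids).data, atol=1e-9)

    def test_output_is_always_ultrametric(self):
        rng = np.random.default_rng(12)
        raw = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        t = sp.upgma(DistanceMatrix(d, list("ABCDEF")))
        depths = [tip.accumulate_to_ancestor(t) for tip in t.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_leaf_set_preserved(self, small_study):
        pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in small_study.populations]
        t = sp.upgma(sp.da_matrix(pops))
        assert {tip.name for tip in t.tips()} == {p.population_id for p in pops}


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", list(range(8)))
    def test_recovers_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        true_tree, dm = _random_additive_tree(n, rng)
        est = sp.neighbor_joining(dm)
        assert sp.bipartitions(est) == sp.bipartitions(true_tree)
        tt = est.tip_tip_distances(endpoints=list(dm.ids))
        assert np.allclose(tt.data, dm.filter(tt.ids).data, atol=1e-9)

    def test_matches_skbio_topology(self):
        rng = np.random.default_rng(21)
        _, dm = _random_additive_tree(7, rng)
        ours = sp.neighbor_joining(dm)
        oracle = skbio.tree.nj(dm)
        assert sp.bipartitions(ours) == sp.bipartitions(oracle)

    def test_ultrametric_input_matches_upgma_topology(self):
        rng = np.random.default_rng(33)
        points = rng.normal(size=(7, 3))
        ultra = squareform(cophenet(linkage(points, method="average")))
        dm = DistanceMatrix(ultra, [f"P{i}" for i in range(7)])
        assert sp.bipartitions(sp.neighbor_joining(dm)) == sp.bipartitions(sp.upgma(dm))

    def test_star_matrix_has_zero_internal_edges(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        t = sp.neighbor_joining(DistanceMatrix(d, list("ABCD")))
        internal = [n.length for n in t.non_tips() if n.length is not None]
        assert all(abs(l) < 1e-9 for l in internal)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ["A", "B"])
        with pytest.raises(ValueError):
            sp.neighbor_joining(dm)


class TestNewick:
    def test_two_leaf_form(self):
        dm = DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ["A", "B"])
        assert sp.to_newick(sp.upgma(dm)) == "(A:0.5,B:0.5);"

    @pytest.mark.parametrize("seed", [5, 6])
    def test_round_trip_preserves_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        tree, _ = _random_additive_tree(9, rng)
        back = sp.from_newick(sp.to_newick(tree))
        assert sp.bipartitions(back) == sp.bipartitions(tree)
        ids = sorted(t.name for t in tree.tips())
        d0 = tree.tip_tip_distances(endpoints=ids)
        d1 = back.tip_tip_distances(endpoints=ids)
        assert np.allclose(d0.data, d1.data, atol=1e-12)

    def test_supports_round_trip(self, small_study):
        pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in small_study.populations]
        freqs = pops + [
            sp.AlleleFrequencyTable("extra", dict(pops[0].frequencies), dict(pops[0].n))
        ]
        t = sp.bootstrap_over_loci(freqs, n_replicates=10, seed=1)
        supports = sorted(
            n.support for n in t.non_tips() if getattr(n, "support", None) is not None
        )
        back = sp.from_newick(sp.to_newick(t))
        back_supports = sorted(
            n.support for n in back.non_tips() if getattr(n, "support", None) is not None
        )
        assert back_supports == supports

    def test_independent_parser_reads_our_output(self):
        """dendropy, as an independent Newick implementation, must agree
        on taxa and path lengths of a serialized tree."""
        import dendropy

        rng = np.random.default_rng(7)
        tree, dm = _random_additive_tree(6, rng)
        text = sp.to_newick(tree)
        dt = dendropy.Tree.get(data=text, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label for t in dt.taxon_namespace}
        assert taxa == set(dm.ids)
        for i, a in enumerate(dm.ids):
            for b in list(dm.ids)[i + 1 :]:
                ta = dt.taxon_namespace.get_taxon(a)
                tb = dt.taxon_namespace.get_taxon(b)
                assert pdm.patristic_distance(ta, tb) == pytest.approx(
                    dm[a, b], abs=1e-9
                )

    def test_metacharacter_labels_are_quoted(self):
        dm = DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ["Pop (north)", "B"])
        text = sp.to_newick(sp.upgma(dm))
        parsed = sp.from_newick(text)
        assert {t.name for t in parsed.tips()} == {"Pop (north)", "B"}


class TestBootstrap:
    def _clade_study(self):
        """Two well-separated clades of three populations each, built from
        Balding-Nichols divergence: deep split Fst 0.1, within-clade 0.005."""
        rng = np.random.default_rng(404)
        pops = []
        loci = [f"L{i:02d}" for i in range(25)]
        anc = {l: sp.sample_ancestral_frequencies(6, 1.0, rng) for l in loci}
        clade_freqs = {}
        for clade in ("X", "Y"):
            clade_freqs[clade] = {
                l: sp.diverge_balding_nichols(anc[l][1], 0.1, rng) for l in loci
            }
        for clade in ("X", "Y"):
            for i in range(3):
                freqs = {}
                for l in loci:
                    p = sp.diverge_balding_nichols(clade_freqs[clade][l], 0.005, rng)
                    freqs[l] = {
                        a: float(f) for a, f in zip(anc[l][0], p) if f > 0
                    }
                pops.append(
                    sp.AlleleFrequencyTable(f"{clade}{i}", freqs, {l: 100 for l in loci})
                )
        return pops

    def test_single_replicate_supports_are_binary(self):
        pops = self._clade_study()
        t = sp.bootstrap_over_loci(pops, n_replicates=1, seed=3)
        supports = [
            n.support for n in t.non_tips() if getattr(n, "support", None) is not None
        ]
        assert supports and all(s in (0.0, 1.0) for s in supports)

    @pytest.mark.parametrize("method", ["upgma", "nj"])
    def test_separated_clades_get_high_support(self, method):
        pops = self._clade_study()
        t = sp.bootstrap_over_loci(pops, n_replicates=100, method=method, seed=9)
        tips = frozenset(x.population_id for x in pops)
        target = frozenset({"X0", "X1", "X2"})
        anchor = min(tips)
        found = None
        for node in t.non_tips():
            side = frozenset(tip.name for tip in node.tips())
            if anchor in side:
                side = tips - side
            if side in (target, tips - target):
                found = node.support
        assert found is not None and found >= 0.95

    def test_supports_invariant_to_population_order(self):
        pops = self._clade_study()
        t1 = sp.bootstrap_over_loci(pops, n_replicates=30, seed=77)
        t2 = sp.bootstrap_over_loci(pops[::-1], n_replicates=30, seed=77)

        def support_map(t):
            tips = frozenset(x.name for x in t.tips())
            anchor = min(tips)
            out = {}
            for node in t.non_tips():
                side = frozenset(tip.name for tip in node.tips())
                if anchor in side:
                    side = tips - side
                if getattr(node, "support", None) is not None:
                    out[side] = node.support
            return out

        assert support_map(t1) == support_map(t2)

    def test_single_locus_is_degenerate(self, small_study):
        pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in small_study.populations]
        with pytest.raises(ValueError):
            sp.bootstrap_over_loci(pops, loci=[pops[0].loci[0]], n_replicates=5)


class TestPca:
    def test_two_populations_single_full_component(self, small_study):
        pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in small_study.populations[:2]]
        res = sp.pca_populations(pops)
        assert res.coordinates.shape[1] == 1
        assert res.explained[0] == pytest.approx(1.0)

    def test_duplicated_population_gets_identical_coordinates(self, small_study):
        pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in small_study.populations]
        dup = sp.AlleleFrequencyTable(
            "dup", dict(pops[0].frequencies), dict(pops[0].n)
        )
        res = sp.pca_populations(pops + [dup])
        assert np.allclose(
            res.coordinates.loc[pops[0].population_id],
            res.coordinates.loc["dup"],
            atol=1e-9,
        )

    def test_explained_matches_eigendecomposition_oracle(self):
        cfg = sp.SimConfig(
            n_populations=11, n_individuals=60, n_loci=21,
            alleles_per_locus=(4, 12), fst=0.03, seed=88,
        )
        fx = sp.make_study_fixture(cfg)
        pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in fx.populations]
        res = sp.pca_populations(pops)
        x, _, _ = sp.frequency_matrix(pops)
        centered = x - x.mean(axis=0)
        cov = centered.T @ centered / (len(pops) - 1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fractions = eig / eig.sum()
        assert np.allclose(res.explained, fractions[: len(res.explained)], atol=1e-9)
        # full-rank case: explained fractions over all components sum to 1
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(b <= a + 1e-12 for a, b in zip(res.explained, res.explained[1:]))

    def test_single_population_rejected(self, small_study):
        pops = [sp.AlleleFrequencyTable.from_genotypes(small_study.populations[0])]
        with pytest.raises(ValueError):
            sp.pca_populations(pops)
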