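import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import strpopkit as sp
from strpopkit.interpop_distance import configuration_stress


def freq_table(label, locus_freqs):
    """FrequencyTable from {locus: {label: freq}} with string allele keys."""
    freqs = {
        locus: {sp.parse_allele(str(a)): f for a, f in d.items()}
        for locus, d in locus_freqs.items()
    }
    return sp.FrequencyTable(freqs, population_label=label)


def random_tables(n_pops, n_loci=5, n_alleles=6, seed=0):
    rng = np.random.default_rng(seed)
    tables = []
    for p in range(n_pops):
        locus_freqs = {}
        for l in range(n_loci):
            v = sp.sample_frequency_vector(n_alleles, 1.0, rng)
            locus_freqs[f"L{l}"] = {8 + i: x for i, x in enumerate(v)}
        tables.append(freq_table(f"pop{p+1}", locus_freqs))
    return tables


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree with positive branch lengths, plus its metric."""
    nodes = [sp.TreeNode(name=chr(65 + i)) for i in range(n_taxa)]
    lengths = lambda: float(rng.uniform(0.1, 2.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = sp.TreeNode(children=[(nodes[i], lengths()), (nodes[j], lengths())])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = sp.TreeNode(children=[(x, lengths()) for x in nodes])
    tree = sp.Tree(root)
    return tree, sp.tree_distance_matrix(tree)


class TestAlignLoci:
    def test_intersection(self):
        t1 = freq_table("x", {"A": {8: 1.0}, "B": {8: 1.0}, "C": {8: 1.0}})
        t2 = freq_table("y", {"B": {8: 0.5, 9: 0.5}, "C": {8: 1.0}, "D": {8: 1.0}})
        al = sp.align_loci([t1, t2])
        assert al.loci == ["B", "C"]
        # allele union zero-filled
        assert al.vectors[0]["B"].tolist() == [1.0, 0.0]

    def test_21_vs_15_locus_panels(self, bahrain_freqs):
        fifteen = {
            locus: bahrain_freqs.frequencies[locus]
            for locus in bahrain_freqs.loci[:15]
        }
        other = sp.FrequencyTable(fifteen, population_label="other")
        al = sp.align_loci([bahrain_freqs, other])
        assert len(al.loci) == 15

    def test_identity_and_empty_intersection(self):
        t = random_tables(2, seed=1)
        al = sp.align_loci(t)
        assert al.loci == t[0].loci
        for vec, table in zip(al.vectors, t):
            for locus in al.loci:
                assert vec[locus].sum() == pytest.approx(1.0)
        disjoint = freq_table("z", {"Z1": {8: 1.0}})
        with pytest.raises(sp.StrDataError):
            sp.align_loci([t[0], disjoint])


class TestPairwiseFst:
    def test_identical_populations_zero(self):
        t = random_tables(1, seed=2)[0]
        t2 = sp.FrequencyTable(dict(t.frequencies), population_label="copy")
        fst = sp.pairwise_fst([t, t2])
        assert np.allclose(fst.matrix, 0.0, atol=1e-12)

    def test_nei_gst_closed_form(self):
        a = freq_table("a", {"L": {8: 0.2, 9: 0.8}})
        b = freq_table("b", {"L": {8: 0.8, 9: 0.2}})
        fst = sp.pairwise_fst([a, b])
        assert fst.matrix[0, 1] == pytest.approx((0.5 - 0.32) / 0.5, abs=1e-12)

    def test_weir_cockerham_needs_sizes(self):
        with pytest.raises(ValueError):
            sp.pairwise_fst(random_tables(2, seed=3), estimator="weir_cockerham")

    def test_monomorphic_everywhere_undefined(self):
        a = freq_table("a", {"L": {8: 1.0}})
        b = freq_table("b", {"L": {8: 1.0}})
        with pytest.raises(sp.StrDataError):
            sp.pairwise_fst([a, b])

    def test_gst_monotone_in_divergence(self):
        # seed-averaged GST increases with the Balding-Nichols F
        means = []
        loci = {f"L{i}": sp.sample_frequency_vector(6, 1.0, seed=20 + i) for i in range(10)}
        for f in (0.01, 0.05, 0.1):
            ests = []
            for s in range(5):
                cfg = sp.SimulationConfig(
                    n_individuals=300, loci=loci, fst=f, n_populations=2, seed=s
                )
                pops = sp.simulate_structured_populations(cfg)
                ests.append(sp.pairwise_fst([sp.frequency_table(g) for g in pops]).matrix[0, 1])
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]


class TestNeiDistance:
    def test_identical_populations(self):
        t = random_tables(1, seed=4)[0]
        t2 = sp.FrequencyTable(dict(t.frequencies), population_label="copy")
        for variant in ("standard_ds", "da"):
            d = sp.nei_distance([t, t2], variant=variant)
            assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles(self):
        a = freq_table("a", {"L": {8: 1.0}})
        b = freq_table("b", {"L": {9: 1.0}})
        da = sp.nei_distance([a, b], variant="da")
        assert da.matrix[0, 1] == pytest.approx(1.0)
        ds = sp.nei_distance([a, b], variant="standard_ds")
        assert np.isfinite(ds.matrix[0, 1])  # flagged maximal, not inf
        assert "capped" in ds.estimator

    def test_ds_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        tables = random_tables(8, n_loci=4, n_alleles=5, seed=5)
        d = sp.nei_distance(tables, variant="standard_ds")
        al = sp.align_loci(tables)
        for i in range(8):
            for j in range(i + 1, 8):
                jx = jy = jxy = 0.0
                for locus in al.loci:
                    x, y = al.vectors[i][locus], al.vectors[j][locus]
                    jx += (x ** 2).sum()
                    jy += (y ** 2).sum()
                    jxy += (x * y).sum()
                expected = -math.log(jxy / math.sqrt(jx * jy))
                assert d.matrix[i, j] == pytest.approx(expected, abs=1e-12)
                assert d.matrix[i, j] == d.matrix[j, i] >= 0


class TestNeighborJoining:
    def test_three_point_formulas(self):
        d = sp.DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = sp.neighbor_joining(d)
        assert sp.to_newick(tree) == "(A:0.5,B:1.5,C:2.5);"

    @pytest.mark.parametrize("n_taxa", [4, 5, 7, 10])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            _, dm = random_additive_tree(n_taxa, rng)
            recovered = sp.neighbor_joining(dm)
            back = sp.tree_distance_matrix(recovered)
            order = [back.labels.index(l) for l in dm.labels]
            assert np.allclose(back.matrix[np.ix_(order, order)], dm.matrix, atol=1e-9)

    def test_too_few_taxa(self):
        d = sp.DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            sp.neighbor_joining(d)

    def test_deterministic_on_ties(self):
        # four equidistant taxa: every Q entry ties; lowest pair must win
        m = np.ones((4, 4)) - np.eye(4)
        d = sp.DistanceMatrix(list("ABCD"), m)
        t1 = sp.to_newick(sp.neighbor_joining(d))
        t2 = sp.to_newick(sp.neighbor_joining(d))
        assert t1 == t2


class TestNewick:
    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(17)
        for n in (4, 6, 9):
            tree, dm = random_additive_tree(n, rng)
            back = sp.from_newick(sp.to_newick(tree))
            dm2 = sp.tree_distance_matrix(back)
            order = [dm2.labels.index(l) for l in dm.labels]
            assert np.allclose(dm2.matrix[np.ix_(order, order)], dm.matrix, atol=1e-9)

    def test_quoted_labels(self):
        tree = sp.Tree(sp.TreeNode(children=[
            (sp.TreeNode(name="Sri Lanka"), 1.0),
            (sp.TreeNode(name="UAE"), 2.0),
            (sp.TreeNode(name="Bahrain"), 0.5),
        ]))
        text = sp.to_newick(tree)
        assert "'Sri Lanka'" in text
        assert sorted(sp.from_newick(text).leaf_names()) == ["Bahrain", "Sri Lanka", "UAE"]

    def test_dendropy_cross_parse(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(23)
        tree, dm = random_additive_tree(6, rng)
        text = sp.to_newick(tree)
        dt = dendropy.Tree.get(data=text, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                    dm.matrix[i, j], abs=1e-6
                )


class TestNmds:
    def test_equilateral_triangle_exact(self):
        d = sp.DistanceMatrix(list("ABC"), np.ones((3, 3)) - np.eye(3))
        o = sp.nmds(d, k=2)
        assert o.stress == pytest.approx(0.0, abs=1e-9)
        assert o.rsq == pytest.approx(1.0)

    def test_self_embedding_recovery(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(9, 2))
        d = sp.DistanceMatrix([f"p{i}" for i in range(9)], squareform(pdist(pts)))
        o = sp.nmds(d, k=2, seed=0)
        assert o.stress < 0.01

    def test_deterministic(self):
        tables = random_tables(6, seed=6)
        d = sp.pairwise_fst(tables)
        o1 = sp.nmds(d, k=2, seed=1)
        o2 = sp.nmds(d, k=2, seed=1)
        assert np.array_equal(o1.coordinates, o2.coordinates)
        assert o1.stress == o2.stress

    def test_stress_non_increasing(self):
        tables = random_tables(7, seed=8)
        d = sp.nei_distance(tables, variant="da")
        o = sp.nmds(d, k=2)
        assert all(a >= b - 1e-12 for a, b in zip(o.stress_history, o.stress_history[1:]))
        assert 0.0 <= o.stress <= 1.0

    def test_stress_invariant_under_rigid_motion(self):
        tables = random_tables(6, seed=9)
        d = sp.nei_distance(tables, variant="da")
        o = sp.nmds(d, k=2)
        theta = 0.83
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = o.coordinates @ rot + np.array([3.0, -1.5])
        assert configuration_stress(d, moved) == pytest.approx(o.stress, abs=1e-9)

    def test_dimension_validation(self):
        d = sp.DistanceMatrix(list("ABC"), np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError):
            sp.nmds(d, k=3)

    def test_matches_sklearn_nonmetric_mds_quality(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.manifold import MDS

        tables = random_tables(9, seed=12)
        d = sp.pairwise_fst(tables)
        ours = sp.nmds(d, k=2, seed=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ref = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                      n_init=4, random_state=0, normalized_stress=True)
            ref.fit(d.matrix)
        # same dissimilarities, same loss family: stress must be comparable
        assert ours.stress <= ref.stress_ + 0.05


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        sp.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        sp.DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))
    d = sp.DistanceMatrix(["a", "b"], np.array([[0.0, -1e-6], [-1e-6, 0.0]]))
    assert d.matrix[0, 1] == 0.0  # negative estimates clamped
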