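"""PAV calling, classification, growth curves, Jaccard and NJ trees."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from panheat.io_formats import AccessionMeta, GeneModel
from panheat.pav import (
    PavParams,
    PresenceMatrix,
    build_matrix,
    call_presence,
    classification_summary,
    classify_genes,
    group_unique_genes,
    growth_curve,
    jaccard_matrix,
    nj_tree,
)


def _gene(length=1000, start=1):
    return GeneModel(
        gene_id="g", contig="c1", strand="+",
        start=start, end=start + length - 1,
        exons=[(start, start + length - 1)],
    )


def _cov(n_covered, depth=5, start=1):
    return {"c1": [(start, start + n_covered - 1, depth)]} if n_covered else {"c1": []}


class TestCallPresence:
    def test_850_of_1000_present(self):
        assert call_presence(_gene(1000), _cov(850))

    def test_all_zero_absent(self):
        assert not call_presence(_gene(1000), _cov(0))

    def test_exact_boundary_absent(self):
        # exactly 80% covered: strict > means absent
        assert not call_presence(_gene(1000), _cov(800))
        assert call_presence(_gene(1000), _cov(801))

    def test_depth_below_min_cov_not_counted(self):
        assert not call_presence(_gene(1000), _cov(1000, depth=4))

    def test_exon_body_only(self):
        # 2 exons of 100 bp; intron coverage must not count
        g = GeneModel(
            gene_id="g", contig="c1", strand="+", start=1, end=400,
            exons=[(1, 100), (301, 400)],
        )
        cov = {"c1": [(1, 100, 10), (101, 300, 10)]}  # exon1 + intron only
        assert not call_presence(g, cov)  # 100/200 exon bases
        cov["c1"].append((301, 381, 10))  # 181/200 = 0.905
        assert call_presence(g, cov)


class TestBuildMatrix:
    def test_depth_filter_excludes(self, sim_study):
        metas = sim_study.meta
        matrix, excluded = build_matrix(
            sim_study.models, sim_study.coverage, metas
        )
        assert {a for a, _ in excluded} == sim_study.truth.excluded_accessions
        assert len(matrix.accessions) == len(metas) - len(excluded)

    def test_matrix_equals_presence_truth(self, sim_study, sim_result):
        truth = sim_study.truth.presence_truth
        got = sim_result.matrix
        sub = truth.subset_accessions(got.accessions)
        assert got.genes == sub.genes
        assert np.array_equal(got.values, sub.values)

    def test_no_accession_passes_raises(self, sim_study):
        params = PavParams(min_depth_accession=1e9)
        with pytest.raises(ValueError, match="no accession"):
            build_matrix(sim_study.models, sim_study.coverage, sim_study.meta, params)


class TestClassify:
    def test_partition_and_private(self):
        vals = np.array(
            [[1, 1, 1], [1, 0, 1], [0, 0, 1], [1, 1, 1]], dtype=bool
        )
        m = PresenceMatrix(["g1", "g2", "g3", "g4"], ["a", "b", "c"], vals)
        core, variable, private = classify_genes(m)
        assert core == {"g1", "g4"}
        assert variable == {"g2", "g3"}
        assert private == {"g3": "c"}
        assert core | variable == set(m.genes) and not core & variable

    def test_summary_percentages(self):
        s = classification_summary(3, 1)
        assert s == {"pan_total": 4.0, "core_pct": 75.0, "variable_pct": 25.0}


class TestGroupUnique:
    def _meta(self, classes):
        return [
            AccessionMeta(f"a{i}", "Indica", c) for i, c in enumerate(classes)
        ]

    def test_examples(self):
        vals = np.array([[1, 1, 1, 1], [1, 1, 0, 0], [0, 1, 0, 0]], dtype=bool)
        m = PresenceMatrix(
            ["core", "res_only", "one_res"], [f"a{i}" for i in range(4)], vals
        )
        meta = self._meta(["HT", "T", "S", "HS"])
        got = group_unique_genes(m, meta, {"HT", "T"})
        assert got == {"res_only", "one_res"}  # core excluded: present in all

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        meta = self._meta(["HT", "HT", "T", "MT", "S", "S", "HS", "HS"])
        group = {"HT", "T"}
        for _ in range(20):
            vals = rng.random((6, 8)) < 0.5
            m = PresenceMatrix(
                [f"g{i}" for i in range(6)], [f"a{i}" for i in range(8)], vals
            )
            got = group_unique_genes(m, meta, group)
            expected = set()
            for i, g in enumerate(m.genes):
                inside = [vals[i, j] for j, mt in enumerate(meta) if mt.heat_class in group]
                outside = [vals[i, j] for j, mt in enumerate(meta) if mt.heat_class not in group]
                if any(inside) and not any(outside):
                    expected.add(g)
            assert got == expected

    def test_empty_group_raises(self):
        m = PresenceMatrix(["g"], ["a", "b"], np.ones((1, 2), bool))
        with pytest.raises(ValueError):
            group_unique_genes(m, self._meta(["HT", "T"]), set())
        with pytest.raises(ValueError, match="selects no accessions"):
            group_unique_genes(m, self._meta(["HT", "T"]), {"HS"})


class TestGrowthCurve:
    def _random_matrix(self, n_genes, n_acc, seed=0, p=0.8):
        rng = np.random.default_rng(seed)
        vals = rng.random((n_genes, n_acc)) < p
        vals[: n_genes // 2] = True  # a core fraction
        return PresenceMatrix(
            [f"g{i}" for i in range(n_genes)], [f"a{j}" for j in range(n_acc)], vals
        )

    def test_all_true_matrix_flat(self):
        m = PresenceMatrix(["g1", "g2"], list("abcd"), np.ones((2, 4), bool))
        c = growth_curve(m, fit=False)
        assert c.pan_mean == [2.0] * 4 and c.core_mean == [2.0] * 4

    def test_endpoints_match_classification(self):
        m = self._random_matrix(30, 6)
        c = growth_curve(m, fit=False)
        core, variable, _ = classify_genes(m)
        assert c.pan_mean[-1] == float(m.values.any(axis=1).sum())
        assert c.core_mean[-1] == float(len(core))
        assert c.pan_mean[0] == pytest.approx(c.core_mean[0])

    def test_sampled_equals_exhaustive_below_cap(self):
        """With the cap above C(N, k) the sampler enumerates; compare with an
        independent brute-force enumeration."""
        m = self._random_matrix(25, 5, seed=3)
        c = growth_curve(m, n_samples_per_size=1000, fit=False)
        for k, pan, core in zip(c.sample_sizes, c.pan_mean, c.core_mean):
            pans, cores = [], []
            for combo in itertools.combinations(range(5), k):
                sub = m.values[:, list(combo)]
                pans.append(sub.any(axis=1).sum())
                cores.append(sub.all(axis=1).sum())
            assert pan == pytest.approx(np.mean(pans))
            assert core == pytest.approx(np.mean(cores))

    def test_monotonicity(self, sim_result):
        c = growth_curve(sim_result.matrix, n_samples_per_size=30, seed=5, fit=False)
        assert all(a <= b + 1e-9 for a, b in zip(c.pan_mean, c.pan_mean[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(c.core_mean, c.core_mean[1:]))

    def test_fit_reasonable(self):
        m = self._random_matrix(60, 8, seed=7)
        c = growth_curve(m, n_samples_per_size=200, seed=1)
        assert c.fit_ok and c.fit_pan is not None
        a, b, cc = c.fit_pan
        pred = a * np.power(c.sample_sizes, b) + cc
        assert np.allclose(pred, c.pan_mean, rtol=0.05, atol=1.0)


class TestJaccard:
    def test_examples(self):
        vals = np.array(
            [[1, 0], [1, 1], [1, 1], [0, 1]], dtype=bool
        )  # {g1,g2,g3} vs {g2,g3,g4}
        m = PresenceMatrix(["g1", "g2", "g3", "g4"], ["a", "b"], vals)
        j = jaccard_matrix(m)
        assert j.loc["a", "b"] == pytest.approx(0.5)
        assert j.loc["a", "a"] == 1.0

    def test_identical_and_disjoint(self):
        vals = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=bool)
        m = PresenceMatrix(["g1", "g2", "g3"], ["a", "b", "c"], vals)
        j = jaccard_matrix(m)
        assert j.loc["a", "b"] == 1.0
        assert j.loc["a", "c"] == 0.0

    def test_properties_on_simulated_matrix(self, sim_result):
        j = jaccard_matrix(sim_result.matrix).to_numpy()
        assert ((j >= 0) & (j <= 1)).all()
        assert np.allclose(j, j.T)
        assert np.allclose(np.diag(j), 1.0)


class TestNjTree:
    @staticmethod
    def _additive_distances(newick, taxa):
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        labels = {t.label: t for t in tree.taxon_namespace}
        n = len(taxa)
        d = np.zeros((n, n))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    d[i, j] = pdm.distance(labels[a], labels[b])
        return pd.DataFrame(d, index=taxa, columns=taxa)

    @staticmethod
    def _rf(newick_a, newick_b, taxa):
        import dendropy

        ns = dendropy.TaxonNamespace(taxa)
        t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        return dendropy.calculate.treecompare.symmetric_difference(t1, t2)

    @pytest.mark.parametrize(
        "true_tree,taxa",
        [
            ("((A:1.0,B:2.0):1.5,(C:0.5,D:1.0):0.8);", list("ABCD")),
            (
                "(((A:1,B:1):1,(C:1,D:2):2):1,(E:1,(F:2,G:1):1):2,H:3);",
                list("ABCDEFGH"),
            ),
        ],
    )
    def test_recovers_generating_topology(self, true_tree, taxa):
        d = self._additive_distances(true_tree, taxa)
        got = nj_tree(d)
        assert self._rf(got, true_tree, taxa) == 0

    def test_identical_taxa_zero_cherry(self):
        d = pd.DataFrame(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0.5], [1, 1, 0.5, 0]],
            index=list("abcd"), columns=list("abcd"),
        )
        newick = nj_tree(d)
        assert self._rf(newick, "((a:0,b:0):1,(c:1,d:1):1);", list("abcd")) == 0

    def test_too_few_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(d)
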