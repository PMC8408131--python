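"""Network machinery: brute-force oracles, eigengene maximality, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import floramark as fm
from floramark import coexpression_network as net
from conftest import random_symmetric_adjacency


def brute_force_tom_dissimilarity(a):
    """O(n^3) triple-loop reference for the topological-overlap dissimilarity."""
    n = a.shape[0]
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = 1.0 - (L + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "cor,beta,expected",
        [(1.0, 12.0, 1.0), (-1.0, 12.0, 0.0), (0.0, 12.0, 0.5**12)],
    )
    def test_closed_form(self, cor, beta, expected):
        a = net.signed_adjacency(np.array([[1.0, cor], [cor, 1.0]]), beta)
        assert a[0, 1] == pytest.approx(expected, abs=1e-15)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            net.signed_adjacency(np.eye(2), 0.0)

    def test_raising_beta_never_increases_offdiagonal(self):
        cor = np.corrcoef(np.random.default_rng(0).normal(size=(6, 12)))
        lo, hi = net.signed_adjacency(cor, 6.0), net.signed_adjacency(cor, 12.0)
        off = ~np.eye(6, dtype=bool)
        assert (hi[off] <= lo[off] + 1e-15).all()


class TestTopologicalOverlap:
    def test_triangle_graph_fully_overlapping(self):
        a = np.ones((3, 3))
        diss = net.topological_overlap(a)
        assert np.allclose(diss, 0.0)

    def test_disconnected_pair_dissimilarity_one(self):
        a = np.eye(2)
        diss = net.topological_overlap(a)
        assert diss[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n,seed", [(6, 0), (10, 1), (10, 2)])
    def test_matches_brute_force(self, n, seed):
        a = random_symmetric_adjacency(n, seed)
        np.testing.assert_allclose(
            net.topological_overlap(a), brute_force_tom_dissimilarity(a), atol=1e-12
        )

    def test_rejects_asymmetric(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            net.topological_overlap(a)


class TestSoftThreshold:
    def test_exact_power_law_bins_fit_one(self):
        # one connectivity value per bin, frequencies proportional to 1/k:
        # log10 p(k) is then exactly linear in log10 k with slope -1
        values = 10.0 * np.arange(1, 9)
        counts = (840 / np.arange(1, 9)).astype(int)
        k = np.repeat(values, counts)
        fit, slope = net._scale_free_fit(k, n_bins=8)
        assert slope == pytest.approx(-1.0, abs=1e-12)
        assert fit == pytest.approx(1.0, abs=1e-12)

    def test_returns_first_power_crossing_cut(self, module_dataset):
        # with the cut placed below the achievable fit, the selected power
        # must be the smallest row of the fit table reaching the cut
        mat, _ = module_dataset
        beta, table = net.pick_soft_threshold(mat, r2_cut=0.5)
        assert bool(table.attrs["warning"]) is False
        first = table.loc[table["fit"] >= 0.5, "power"].iloc[0]
        assert beta == first
        assert (table.loc[table["power"] < first, "fit"] < 0.5).all()

    def test_falls_back_to_best_power_with_warning(self, module_dataset):
        mat, _ = module_dataset
        with pytest.warns(UserWarning, match="no power reached"):
            beta, table = net.pick_soft_threshold(mat, r2_cut=0.999)
        assert table.loc[table["selected"], "fit"].iloc[0] == table["fit"].max()


class TestEigengenes:
    def test_identical_genes_give_their_standardized_profile(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=10)
        mat = pd.DataFrame(np.tile(v, (5, 1)) * rng.uniform(1, 3, size=(5, 1)))
        me = net.module_eigengenes(mat, np.ones(5, dtype=int))
        r = np.corrcoef(me.loc["ME1"], v)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert np.corrcoef(me.loc["ME1"], (mat - mat.mean(axis=1).to_numpy()[:, None]).mean())[0, 1] >= 0

    def test_variance_explained_beats_random_directions(self, module_dataset):
        mat, truth = module_dataset
        genes = truth[truth["module_id"] == 1.0].index.intersection(mat.index)
        sub = mat.loc[genes]
        labels = np.ones(len(genes), dtype=int)
        me = net.module_eigengenes(sub, labels)
        z = net._standardize_rows(sub.to_numpy())
        e = me.loc["ME1"].to_numpy()
        var_e = ((z @ e) ** 2).sum()
        rng = np.random.default_rng(0)
        for _ in range(1000):
            d = rng.normal(size=len(e))
            d /= np.linalg.norm(d)
            assert ((z @ d) ** 2).sum() <= var_e + 1e-9

    def test_mirrored_halves_sign_convention(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=8)
        mat = pd.DataFrame(np.vstack([np.tile(v, (3, 1)), np.tile(-v, (3, 1))]))
        me = net.module_eigengenes(mat, np.ones(6, dtype=int))
        assert abs(np.corrcoef(me.loc["ME1"], v)[0, 1]) == pytest.approx(1.0, abs=1e-10)


class TestDetectAndMerge:
    def test_planted_blocks_recovered(self, module_dataset):
        from sklearn.metrics import adjusted_rand_score

        mat, truth = module_dataset
        cor = np.corrcoef(mat.to_numpy())
        diss = net.topological_overlap(net.signed_adjacency(cor, 12.0))
        labels = net.detect_modules(diss)
        mod = truth[truth["klass"] == "module"]
        genes = mod.index.intersection(mat.index)
        pos = mat.index.get_indexer(genes)
        ari = adjusted_rand_score(mod.loc[genes, "module_id"], labels[pos])
        assert ari >= 0.9

    def test_small_planted_block_goes_grey(self):
        rng = np.random.default_rng(0)
        block = np.tile(rng.normal(size=10), (10, 1)) + rng.normal(0, 0.05, (10, 10))
        noise = rng.normal(size=(40, 10))
        mat = pd.DataFrame(np.vstack([block, noise]))
        cor = np.corrcoef(mat.to_numpy())
        diss = net.topological_overlap(net.signed_adjacency(cor, 12.0))
        labels = net.detect_modules(diss, min_size=30)
        assert (labels[:10] == 0).all()

    def test_identical_genes_form_single_module(self):
        v = np.arange(10.0)
        mat = pd.DataFrame(np.tile(v, (40, 1)))
        diss = 1.0 - np.ones((40, 40))
        labels = net.detect_modules(diss, min_size=30)
        assert set(labels) == {1}

    def test_fewer_genes_than_min_size_all_grey(self):
        with pytest.warns(UserWarning, match="fewer genes"):
            labels = net.detect_modules(np.zeros((5, 5)), min_size=30)
        assert (labels == 0).all()

    def _two_module_matrix(self, cor_target, seed=0):
        """Two 35-gene blocks whose latent profiles correlate ~cor_target."""
        rng = np.random.default_rng(seed)
        u = rng.normal(size=12)
        w = cor_target * u + np.sqrt(1 - cor_target**2) * rng.normal(size=12)
        x = np.vstack(
            [np.tile(u, (35, 1)) + rng.normal(0, 0.01, (35, 12)),
             np.tile(w, (35, 1)) + rng.normal(0, 0.01, (35, 12))]
        )
        return pd.DataFrame(x), np.repeat([1, 2], 35)

    def test_highly_correlated_eigengenes_merged(self):
        mat, labels = self._two_module_matrix(0.95)
        merged = net.merge_modules(mat, labels, merge_height=0.25)
        assert len(set(merged) - {0}) == 1

    def test_weakly_correlated_eigengenes_kept(self):
        mat, labels = self._two_module_matrix(0.5)
        merged = net.merge_modules(mat, labels, merge_height=0.25)
        assert len(set(merged) - {0}) == 2

    def test_single_module_unchanged(self):
        mat, labels = self._two_module_matrix(0.5)
        single = np.where(labels == 1, 1, 0)
        merged = net.merge_modules(mat, single, merge_height=0.25)
        assert set(merged) == {0, 1}

    def test_post_merge_dissimilarities_exceed_height(self, module_dataset):
        mat, _ = module_dataset
        cor = np.corrcoef(mat.to_numpy())
        diss = net.topological_overlap(net.signed_adjacency(cor, 12.0))
        labels = net.merge_modules(mat, net.detect_modules(diss), 0.25)
        me = net.module_eigengenes(mat, labels)
        d = net._eigengene_dissimilarity(me)
        assert d[np.triu_indices_from(d, k=1)].min() >= 0.25


class TestMembershipAndSignificance:
    def test_gene_identical_to_eigengene(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=10)
        mat = pd.DataFrame([e, rng.normal(size=10)])
        me = pd.DataFrame([e], index=["ME1"], columns=mat.columns)
        kme, p = net.module_membership(mat, me)
        assert kme.iloc[0, 0] == pytest.approx(1.0)
        assert p.iloc[0, 0] < 1e-10

    def test_student_t_pvalue_oracle(self):
        # r = 0.97 over n = 10 columns -> two-sided t-test with 8 df
        r, n = 0.97, 10
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        expected = 2 * stats.t.sf(t, n - 2)
        rng = np.random.default_rng(5)
        # construct vectors with exact correlation r
        x = np.arange(n, dtype=float)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = rng.normal(size=n)
        z -= z.mean()
        z -= (z @ xc) * xc
        z /= np.linalg.norm(z)
        y = r * xc + np.sqrt(1 - r**2) * z
        mat = pd.DataFrame([y])
        me = pd.DataFrame([x], index=["ME1"], columns=mat.columns)
        kme, p = net.module_membership(mat, me)
        assert kme.iloc[0, 0] == pytest.approx(r, abs=1e-12)
        assert p.iloc[0, 0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(3.3e-6, rel=0.05)

    def test_constant_gene_convention(self):
        mat = pd.DataFrame([[2.0] * 8])
        me = pd.DataFrame([np.arange(8.0)], index=["ME1"], columns=mat.columns)
        kme, p = net.module_membership(mat, me)
        assert kme.iloc[0, 0] == 0.0 and p.iloc[0, 0] == 1.0

    def test_gene_significance_indicator_and_rejection(self):
        trait = np.array([1.0, 0, 0, 1, 0, 0])
        mat = pd.DataFrame([trait, np.full(6, 3.0)])
        gs = net.gene_significance(mat, trait)
        assert gs["GS"].iloc[0] == pytest.approx(1.0)
        assert gs["GS"].iloc[1] == 0.0
        with pytest.raises(ValueError, match="zero variance"):
            net.gene_significance(mat, np.ones(6))

    def test_planted_specific_gene_strong_significance(self, small_profile, small_dataset):
        _, _, truth = small_dataset
        spec = truth[truth["klass"] == "specific"].iloc[0]
        mat = np.log2(small_profile + 1.0)
        trait = (pd.Index(small_profile.columns) == spec["target_tissue"]).astype(float)
        gs = net.gene_significance(mat.loc[[spec.name]], trait)
        assert gs["GS"].iloc[0] > 0.8


class TestModuleTrait:
    def test_eigengene_equal_to_indicator(self):
        trait = pd.DataFrame([[1.0, 0, 0, 1, 0, 0]], index=["t1"])
        me = pd.DataFrame([[1.0, 0, 0, 1, 0, 0]], index=["ME1"], columns=trait.columns)
        r, p, best = net.module_trait_correlation(me, trait)
        assert r.loc["ME1", "t1"] == pytest.approx(1.0)
        assert best["t1"] == "ME1"

    def test_anchored_modules_map_to_their_tissues(self, module_dataset):
        mat, truth = module_dataset
        cor = np.corrcoef(mat.to_numpy())
        diss = net.topological_overlap(net.signed_adjacency(cor, 12.0))
        labels = net.merge_modules(mat, net.detect_modules(diss), 0.25)
        me = net.module_eigengenes(mat, labels)
        traits = net.trait_indicators(list(mat.columns))
        _, _, best = net.module_trait_correlation(me, traits)
        mod = truth[truth["klass"] == "module"]
        for mid in sorted(mod["module_id"].unique()):
            genes = mod[mod["module_id"] == mid].index.intersection(mat.index)
            detected = pd.Series(labels[mat.index.get_indexer(genes)]).mode()[0]
            anchor = mod[mod["module_id"] == mid]["target_tissue"].iloc[0]
            assert best[anchor] == f"ME{detected}"


class TestHubGenes:
    def test_threshold_rule(self):
        kme = pd.DataFrame({"ME1": [0.95, 0.85, 0.92]}, index=["a", "b", "c"])
        hubs = net.hub_genes(kme, np.array([1, 1, 1]), mm_cut=0.9)
        assert hubs[1] == ["a", "c"]

    def test_empty_module_empty_list(self):
        kme = pd.DataFrame({"ME1": [0.5]}, index=["a"])
        hubs = net.hub_genes(kme, np.array([1]), mm_cut=0.9)
        assert hubs[1] == []


def test_dendrogram_newick_parses():
    from io import StringIO
    from Bio import Phylo

    d = 1.0 - np.eye(4)
    d[0, 1] = d[1, 0] = 0.2
    nwk = net.dendrogram_newick(d, ["a", "b", "c", "d"])
    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d"]
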