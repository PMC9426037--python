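"""Consensus-NMF class discovery: factorization, consensus stability,
rank selection and cluster characterization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hlbc.discovery import (ConsensusNMF, ConsensusNMFResult,
                            ConsensusNMFResults, NoNovelClusteringError,
                            _kl_divergence, characterize_clusters,
                            nmf_factorize, select_variable_genes)
from hlbc.expression import ExpressionMatrix
from hlbc.synth import generate_expression


def _expr(values, state="normalized"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values=pd.DataFrame(
        values, index=[f"G{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])]), state=state)


class TestSelectVariableGenes:
    def test_floor_rule_small(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.uniform(0, 5, size=(9, 6)))
        assert select_variable_genes(expr, 0.33).shape[0] == 2  # floor(2.97)

    def test_floor_rule_panel_size(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.uniform(0, 5, size=(776, 4)))
        assert select_variable_genes(expr, 0.33).shape[0] == 256

    def test_constant_matrix_lexicographic_ties(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            np.ones((6, 4)), index=["Z", "B", "A", "Y", "C", "X"],
            columns=list("wxyz")), state="normalized")
        out = select_variable_genes(expr, 0.5)
        assert list(out.genes) == ["A", "B", "C"]

    def test_selects_highest_variance(self):
        vals = np.vstack([np.zeros(5), np.arange(5.0), np.arange(5.0) * 10])
        expr = _expr(vals)
        out = select_variable_genes(expr, 0.67)
        assert list(out.genes) == ["G2", "G1"]

    def test_fraction_bounds(self):
        expr = _expr(np.ones((4, 3)))
        with pytest.raises(ValueError, match="fraction"):
            select_variable_genes(expr, 0.0)
        with pytest.raises(ValueError, match="fraction"):
            select_variable_genes(expr, 1.5)


class TestNmfFactorize:
    def _exact_rank2(self, seed=0, n=30, m=20):
        rng = np.random.default_rng(seed)
        w0 = rng.uniform(0.5, 2.0, size=(n, 2))
        h0 = rng.uniform(0.5, 2.0, size=(2, m))
        return w0 @ h0

    def test_exact_factorization_recovered(self):
        v = self._exact_rank2()
        w, h = nmf_factorize(v, 2, seed=1, max_iter=5000, tol=1e-12)
        assert _kl_divergence(v, w @ h) < 1e-6

    def test_sklearn_agrees_on_exact_data(self):
        """Independent cross-check: sklearn's KL/mu NMF also drives the
        divergence to ~0 on exactly factorizable data."""
        from sklearn.decomposition import NMF

        v = self._exact_rank2(seed=2)
        w, h = nmf_factorize(v, 2, seed=3, max_iter=5000, tol=1e-12)
        sk = NMF(n_components=2, init="random", solver="mu",
                 beta_loss="kullback-leibler", max_iter=5000, tol=1e-12,
                 random_state=3)
        w_sk = sk.fit_transform(v)
        assert _kl_divergence(v, w @ h) < 1e-6
        assert _kl_divergence(v, w_sk @ sk.components_) < 1e-6

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.1, 3.0, size=(15, 12))
        w, h = nmf_factorize(v, 3, seed=5, max_iter=200)
        assert w.min() >= 0 and h.min() >= 0

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0.1, 3.0, size=(15, 12))
        w1, h1 = nmf_factorize(v, 3, seed=7, max_iter=100)
        w2, h2 = nmf_factorize(v, 3, seed=7, max_iter=100)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(h1, h2)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.1, 3.0, size=(20, 15))
        _, _, history = nmf_factorize(v, 3, seed=9, max_iter=300, tol=0,
                                      track_objective=True)
        diffs = np.diff(history)
        assert (diffs <= 1e-8).all()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nmf_factorize(np.array([[1.0, -1.0], [1.0, 1.0]]), 1)
        v = np.ones((5, 5))
        v[2] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            nmf_factorize(v, 2)
        with pytest.raises(ValueError, match="rank"):
            nmf_factorize(np.ones((3, 3)) + np.eye(3), 3)


def _block_matrix(n_per_block=(6, 6), n_genes_per_block=8, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    k = len(n_per_block)
    cols = []
    labels = []
    for b, n in enumerate(n_per_block):
        block = np.full((k * n_genes_per_block, n), 0.05)
        block[b * n_genes_per_block:(b + 1) * n_genes_per_block, :] = gap
        cols.append(block + rng.uniform(0, 0.01, block.shape))
        labels += [b + 1] * n
    return np.hstack(cols), np.array(labels)


class TestConsensus:
    def test_perfect_blocks_binary_consensus_and_unit_cophenetic(self):
        v, truth = _block_matrix()
        model = ConsensusNMF(v, k_range=[2], n_runs=8, random_state=0)
        res = model.fit()[2]
        c = res.consensus.values
        assert set(np.round(np.unique(c), 10)) <= {0.0, 1.0}
        assert res.cophenetic == pytest.approx(1.0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_consensus_matrix_contract(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 2.0, size=(20, 14))
        res = ConsensusNMF(v, k_range=[2, 3], n_runs=4, random_state=1).fit()
        for k in (2, 3):
            c = res[k].consensus.values
            assert np.allclose(c, c.T)
            assert np.allclose(np.diag(c), 1.0)
            assert c.min() >= 0 and c.max() <= 1
            assert set(res[k].labels.unique()) <= set(range(1, k + 1))

    def test_fit_determinism(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0.1, 2.0, size=(18, 12))
        a = ConsensusNMF(v, k_range=[3], n_runs=5, random_state=7).fit()
        b = ConsensusNMF(v, k_range=[3], n_runs=5, random_state=7).fit()
        pd.testing.assert_frame_equal(a[3].consensus, b[3].consensus)
        assert a[3].cophenetic == b[3].cophenetic

    def test_planted_k4_recovery_single_seed(self):
        """One seeded instance of the full discovery path: variable-gene
        selection, consensus NMF over K = 2..6, cophenetic maximal at the
        planted K = 4 and near-perfect label recovery."""
        expr, truth, _, _ = generate_expression(
            85, metagene_fractions={1: 12 / 85, 2: 28 / 85, 3: 15 / 85,
                                    4: 30 / 85}, seed=42)
        var = select_variable_genes(expr)
        res = ConsensusNMF(var, k_range=range(2, 7), n_runs=20,
                           random_state=42).fit()
        summary = res.summary()
        assert summary.loc[4, "cophenetic"] >= summary["cophenetic"].max() - 1e-12
        assert adjusted_rand_score(truth, res[4].labels) >= 0.9

    def test_invalid_rank_and_runs(self):
        v = np.ones((10, 6)) + np.eye(10, 6)
        with pytest.raises(ValueError, match="outside valid range"):
            ConsensusNMF(v, k_range=[6], n_runs=3)
        with pytest.raises(ValueError, match="n_runs"):
            ConsensusNMF(v, k_range=[2], n_runs=1)


def _fake_results(spec: dict[int, tuple[float, np.ndarray]], n: int):
    """Assemble a ConsensusNMFResults with prescribed cophenetics/labels."""
    samples = [f"S{i}" for i in range(n)]
    per_k = {}
    for k, (coph, labels) in spec.items():
        consensus = (labels[:, None] == labels[None, :]).astype(float)
        per_k[k] = ConsensusNMFResult(
            k=k, w=np.ones((4, k)), h=np.ones((k, n)),
            consensus=pd.DataFrame(consensus, index=samples, columns=samples),
            cophenetic=coph, silhouette=1.0,
            labels=pd.Series(labels, index=samples, name="cluster"),
            best_objective=0.0)
    return ConsensusNMFResults(model=None, per_k=per_k), samples


class TestRankSelection:
    def test_discards_overlapping_then_ranks_cophenetic(self):
        """K=2 mirrors the external subtyping (high ARI) and is discarded
        despite the better cophenetic; K=3 wins."""
        n = 24
        external = np.repeat([1, 2], n // 2)
        k2 = external.copy()                      # identical to external
        k3 = np.tile([1, 2, 3], n // 3)           # orthogonal
        res, samples = _fake_results({2: (0.99, k2), 3: (0.95, k3)}, n)
        ext = pd.Series(external, index=samples)
        sel = res.select_rank(ext, overlap_threshold=0.6)
        assert sel.chosen_k == 3
        assert bool(sel.table.loc[2, "discarded"])
        assert sel.table.loc[2, "overlap_ari"] > 0.6

    def test_random_external_labels_reduce_to_cophenetic_ranking(self):
        n = 24
        rng = np.random.default_rng(0)
        res, samples = _fake_results(
            {2: (0.90, np.repeat([1, 2], n // 2)),
             3: (0.97, np.tile([1, 2, 3], n // 3)),
             4: (0.80, np.tile([1, 2, 3, 4], n // 4))}, n)
        ext = pd.Series(rng.integers(1, 6, size=n), index=samples)
        sel = res.select_rank(ext, overlap_threshold=0.6)
        assert sel.chosen_k == 3
        assert not sel.table["discarded"].any()

    def test_all_overlapping_raises_no_novel_clustering(self):
        n = 12
        labels = np.repeat([1, 2], n // 2)
        res, samples = _fake_results({2: (0.99, labels)}, n)
        ext = pd.Series(labels, index=samples)
        with pytest.raises(NoNovelClusteringError):
            res.select_rank(ext, overlap_threshold=0.6)

    def test_min_k_floor(self):
        n = 24
        res, samples = _fake_results(
            {2: (0.99, np.repeat([1, 2], 12)),
             4: (0.90, np.tile([1, 2, 3, 4], 6))}, n)
        ext = pd.Series(np.tile([1, 2, 3], 8), index=samples)
        sel = res.select_rank(ext, overlap_threshold=0.99, min_k=4)
        assert sel.chosen_k == 4

    def test_missing_external_labels_error(self):
        n = 10
        res, samples = _fake_results({2: (0.9, np.repeat([1, 2], 5))}, n)
        ext = pd.Series([1] * (n - 1), index=samples[:-1])
        with pytest.raises(ValueError, match="missing"):
            res.select_rank(ext)


class TestCharacterizeClusters:
    def _clinical(self, labels):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "sample_id": labels.index,
            "pam50": rng.choice(["LumA", "LumB"], size=len(labels)),
            "grade": rng.choice(["G2", "G3"], size=len(labels)),
            "ki67_pct": rng.uniform(5, 60, size=len(labels)),
        })

    def test_report_sections_carry_cluster_sizes(self):
        sizes = [12, 28, 15, 30]
        ids = [f"S{i}" for i in range(sum(sizes))]
        labels = pd.Series(np.repeat([1, 2, 3, 4], sizes), index=ids)
        report = characterize_clusters(labels, self._clinical(labels))
        assert report.cluster_sizes.tolist() == sizes
        md = report.to_markdown()
        assert "Cluster characterization" in md

    def test_planted_enrichment_detected_in_most_simulations(self):
        """PIK3CA planted at rate 0.5 in a 30-sample cluster vs 0.2 in the
        55 remaining samples: the exact-Fisher oracle puts raw-p power at
        ~0.80, so detection is expected in at least 13 of 20 seeded runs."""
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ids = [f"S{i}" for i in range(85)]
            labels = pd.Series([1] * 30 + [2] * 55, index=ids)
            mut = np.concatenate([rng.random(30) < 0.5, rng.random(55) < 0.2])
            variants = pd.DataFrame({
                "sample_id": np.array(ids)[mut], "gene": "PIK3CA"})
            report = characterize_clusters(labels, self._clinical(labels),
                                           variants=variants, min_mutated=1)
            row = report.mutation_tests.query("cluster == 1 and gene == 'PIK3CA'")
            detected += bool((row["p"] < 0.05).any())
        assert detected >= 13

    def test_identical_feature_distribution_nothing_significant(self):
        ids = [f"S{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [2] * 20, index=ids)
        clin = self._clinical(labels)
        clin["ki67_pct"] = 30.0
        clin.loc[::2, "ki67_pct"] = 40.0        # same pattern in both clusters
        variants = pd.DataFrame({"sample_id": ids[:10] + ids[20:30],
                                 "gene": "TP53"})
        report = characterize_clusters(labels, clin, variants=variants,
                                       min_mutated=1)
        assert (report.mutation_tests["p"] > 0.99).all()

    def test_singleton_cluster_warned_and_skipped(self):
        ids = [f"S{i}" for i in range(11)]
        labels = pd.Series([1] * 10 + [2], index=ids)
        with pytest.warns(UserWarning, match="singleton"):
            report = characterize_clusters(labels, self._clinical(labels))
        assert report.skipped_clusters == [2]
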