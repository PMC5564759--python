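"""Integration stage: correlation p-values, meta-clustering, key
metabolites, bipartite export."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from netomics import integrate as ig
from netomics import network as nw
from netomics.synthetic import SimulationConfig, simulate_expression, \
    simulate_metabolites


def _planted_cm(seed: int, spec=None, n_modules=4):
    spec = spec or [(f"met{i}", i, 0.8) for i in range(1, n_modules + 1)]
    config = SimulationConfig(
        n_modules=n_modules, genes_per_module=30, n_background_genes=100,
        seed=1000 + seed, metabolite_spec=spec,
    )
    expr, labels, factors = simulate_expression(config)
    eigengenes = nw.module_eigengene(expr, labels)
    metab, _ = simulate_metabolites(factors, spec, seed=2000 + seed)
    return ig.correlate_modules_metabolites(eigengenes, metab)


class TestModuleMetaboliteCorrelation:
    def test_self_correlation_is_one_with_tiny_p(self, rng):
        eig = pd.DataFrame(rng.standard_normal((2, 30)),
                           index=["ME1", "ME2"],
                           columns=[f"s{i}" for i in range(30)])
        metab = eig.iloc[[0]].set_axis(["m"])
        cm = ig.correlate_modules_metabolites(eig, metab)
        assert cm.r.loc["ME1", "m"] == pytest.approx(1.0)
        assert cm.p.loc["ME1", "m"] < 1e-12

    def test_p_matches_t_closed_form(self):
        # independent oracle: P(|T| > t) via the regularized incomplete beta
        r, n = 0.5, 29
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = special.betainc((n - 2) / 2.0, 0.5,
                                   (n - 2) / ((n - 2) + t**2))
        assert ig.correlation_pvalue(r, n) == pytest.approx(expected, abs=1e-10)

    def test_bh_adjustment_monotone_and_dominating(self, rng):
        eig = pd.DataFrame(rng.standard_normal((6, 20)),
                           columns=[f"s{i}" for i in range(20)])
        metab = pd.DataFrame(rng.standard_normal((5, 20)),
                             columns=eig.columns)
        cm = ig.correlate_modules_metabolites(eig, metab)
        p = cm.p.to_numpy().ravel()
        q = cm.p_adj.to_numpy().ravel()
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_null_fdr_controlled(self):
        # 10x10 all-null matrices over 100 seeds: average fraction of
        # discoveries at q < 0.05 stays at or below the nominal level
        fractions = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            eig = pd.DataFrame(r.standard_normal((10, 29)),
                               columns=[f"s{i}" for i in range(29)])
            metab = pd.DataFrame(r.standard_normal((10, 29)),
                                 columns=eig.columns)
            cm = ig.correlate_modules_metabolites(eig, metab)
            fractions.append((cm.p_adj.to_numpy() < 0.05).mean())
        assert np.mean(fractions) <= 0.05 + 0.02

    def test_insufficient_overlap(self, rng):
        eig = pd.DataFrame(rng.standard_normal((2, 2)), columns=["a", "b"])
        metab = pd.DataFrame(rng.standard_normal((2, 2)), columns=["a", "b"])
        with pytest.raises(ig.InsufficientOverlapError):
            ig.correlate_modules_metabolites(eig, metab)


class TestClusterOfClusters:
    @staticmethod
    def _block_cm():
        r = pd.DataFrame(
            [[0.9, 0.0], [0.0, -0.9]],
            index=["ME1", "ME2"], columns=["metA", "metB"],
        )
        p = pd.DataFrame(0.001, index=r.index, columns=r.columns)
        return ig.ModuleMetaboliteCorrelation(r=r, p=p, p_adj=p, n_overlap=30)

    def test_block_design_pairs_metabolite_with_module(self):
        mc = ig.cluster_of_clusters(self._block_cm(), k=2)
        t = mc.entity_labels.set_index("entity_id")["cluster"]
        assert t["ME1"] == t["metA"]
        assert t["ME2"] == t["metB"]
        assert t["ME1"] != t["ME2"]

    def test_k_equal_entities_gives_singletons(self):
        mc = ig.cluster_of_clusters(self._block_cm(), k=4)
        assert mc.n_clusters == 4

    def test_k_exceeding_entities_rejected(self):
        with pytest.raises(ValueError):
            ig.cluster_of_clusters(self._block_cm(), k=5)

    def test_planted_recovery_over_seeds(self):
        hits = 0
        for seed in range(50):
            cm = _planted_cm(seed)
            mc = ig.cluster_of_clusters(cm, k=4)
            t = mc.entity_labels.set_index("entity_id")["cluster"]
            hits += int(all(t[f"ME{i}"] == t[f"met{i}"] for i in range(1, 5)))
        assert hits / 50 >= 0.90

    def test_invariant_to_entity_order_and_eigengene_sign(self):
        cm = _planted_cm(3)
        base = ig.cluster_of_clusters(cm, k=4)
        t0 = base.entity_labels.set_index("entity_id")["cluster"]

        # permute rows/columns
        r_perm = cm.r.iloc[::-1, ::-1]
        cm_perm = ig.ModuleMetaboliteCorrelation(
            r=r_perm, p=cm.p.iloc[::-1, ::-1], p_adj=cm.p_adj.iloc[::-1, ::-1],
            n_overlap=cm.n_overlap,
        )
        t1 = ig.cluster_of_clusters(cm_perm, k=4).entity_labels \
            .set_index("entity_id")["cluster"]
        # flip the sign of one eigengene (negates a row of r)
        r_flip = cm.r.copy()
        r_flip.loc["ME2"] *= -1
        cm_flip = ig.ModuleMetaboliteCorrelation(
            r=r_flip, p=cm.p, p_adj=cm.p_adj, n_overlap=cm.n_overlap
        )
        t2 = ig.cluster_of_clusters(cm_flip, k=4).entity_labels \
            .set_index("entity_id")["cluster"]

        def partition(t):
            groups = {}
            for entity, c in t.items():
                groups.setdefault(c, set()).add(entity)
            return frozenset(frozenset(g) for g in groups.values())

        assert partition(t1) == partition(t0)
        assert partition(t2) == partition(t0)


class TestKeyMetabolites:
    @staticmethod
    def _cm_and_clusters(r: pd.DataFrame):
        p = pd.DataFrame(0.01, index=r.index, columns=r.columns)
        cm = ig.ModuleMetaboliteCorrelation(r=r, p=p, p_adj=p, n_overlap=20)
        labels = pd.DataFrame(
            {
                "entity_id": list(r.index) + list(r.columns),
                "entity_type": ["module"] * len(r.index)
                + ["metabolite"] * len(r.columns),
                "cluster": [1] * (len(r.index) + len(r.columns)),
            }
        )
        mc = ig.MetaClustering(entity_labels=labels, n_clusters=1,
                               linkage_record=np.zeros((0, 4)))
        return cm, mc

    def test_argmax_of_summed_abs_correlation(self):
        r = pd.DataFrame([[0.9, 0.4], [-0.8, 0.3]], index=["ME1", "ME2"],
                         columns=["m1", "m2"])
        cm, mc = self._cm_and_clusters(r)
        keys = ig.key_metabolites(mc, cm)
        assert keys[1] == "m1"  # score 1.7 vs 0.7

    def test_single_metabolite_cluster(self):
        r = pd.DataFrame([[0.2]], index=["ME1"], columns=["only"])
        cm, mc = self._cm_and_clusters(r)
        assert ig.key_metabolites(mc, cm)[1] == "only"

    def test_score_monotone_in_correlation(self):
        r = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["ME1", "ME2"],
                         columns=["m1", "m2"])
        cm, mc = self._cm_and_clusters(r)
        r2 = r.copy()
        r2.loc["ME1", "m2"] = 0.9
        cm2, mc2 = self._cm_and_clusters(r2)
        assert ig.key_metabolites(mc2, cm2)[1] == "m2"

    def test_planted_strongest_selected(self):
        hits = 0
        spec = [("strong", 1, 0.9), ("weak1", 1, 0.4), ("weak2", 1, 0.4)]
        for seed in range(50):
            cm = _planted_cm(seed, spec=spec, n_modules=2)
            mc = ig.cluster_of_clusters(cm, k=2)
            t = mc.entity_labels.set_index("entity_id")["cluster"]
            keys = ig.key_metabolites(mc, cm)
            hits += int(keys.get(int(t["strong"])) == "strong")
        assert hits / 50 >= 0.95


class TestExportNetwork:
    @staticmethod
    def _cm():
        r = pd.DataFrame([[0.9, 0.1], [0.2, -0.8]], index=["ME1", "ME2"],
                         columns=["m1", "m2"])
        p = pd.DataFrame(0.01, index=r.index, columns=r.columns)
        return ig.ModuleMetaboliteCorrelation(r=r, p=p, p_adj=p, n_overlap=20)

    def test_threshold_zero_gives_complete_bipartite(self):
        net = ig.export_network(self._cm(), threshold=0.0)
        assert len(net.edges) == 4

    def test_threshold_one_on_noise_is_empty_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            net = ig.export_network(self._cm(), threshold=1.0)
        assert net.edges.empty and net.hubs == []

    def test_node_scores_are_summed_abs_weights(self):
        net = ig.export_network(self._cm(), threshold=0.5)
        # edges: (ME1, m1, 0.9) and (ME2, m2, -0.8)
        assert net.node_scores["ME1"] == pytest.approx(0.9)
        assert net.node_scores["m2"] == pytest.approx(0.8)

    def test_weights_bounded_and_hubs_subset(self):
        net = ig.export_network(self._cm(), threshold=0.0, hub_quantile=0.5)
        assert net.edges["weight"].abs().max() <= 1.0
        assert set(net.hubs) <= set(net.node_scores.index)
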