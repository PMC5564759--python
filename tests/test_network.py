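"""Network construction: correlation, soft threshold, TOM, modules, kME."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netomics import network as nw
from netomics.synthetic import SimulationConfig, simulate_expression

from conftest import random_adjacency, tom_bruteforce


class TestCorrelationMatrix:
    def test_matches_double_loop_oracle(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 4)),
                            index=list("abcde"), columns=list("wxyz"))
        cor = nw.correlation_matrix(expr)
        for i in expr.index:
            for j in expr.index:
                expected = np.corrcoef(expr.loc[i], expr.loc[j])[0, 1]
                assert cor.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_and_negated_genes(self, rng):
        base = rng.standard_normal(10)
        expr = pd.DataFrame([base, base, -base], index=["g", "dup", "neg"])
        cor = nw.correlation_matrix(expr)
        assert cor.loc["g", "dup"] == pytest.approx(1.0)
        assert cor.loc["g", "neg"] == pytest.approx(-1.0)

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.standard_normal((3, 8)), np.ones(8)]),
            index=["a", "b", "c", "const"],
        )
        with pytest.warns(UserWarning, match="constant"):
            cor = nw.correlation_matrix(expr)
        assert "const" not in cor.index


class TestAdjacency:
    def test_unsigned_power(self):
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = nw.adjacency(c, beta=6, network_sign="unsigned")
        assert a[0, 1] == pytest.approx(0.5**6)

    def test_unsigned_symmetric_in_sign(self):
        pos = nw.adjacency(np.array([[1.0, 0.5], [0.5, 1.0]]), 6)
        neg = nw.adjacency(np.array([[1.0, -0.5], [-0.5, 1.0]]), 6)
        assert pos[0, 1] == pytest.approx(neg[0, 1])

    def test_signed_maps_minus_one_to_zero(self):
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        a = nw.adjacency(c, beta=3, network_sign="signed")
        assert a[0, 1] == pytest.approx(0.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        c=st.floats(min_value=-0.999, max_value=0.999),
        b1=st.floats(min_value=0.5, max_value=8),
        b2=st.floats(min_value=0.5, max_value=8),
    )
    def test_raising_beta_weakly_sparsifies(self, c, b1, b2):
        lo, hi = sorted([b1, b2])
        cor = np.array([[1.0, c], [c, 1.0]])
        assert nw.adjacency(cor, hi)[0, 1] <= nw.adjacency(cor, lo)[0, 1] + 1e-12


class TestSoftThreshold:
    def test_reference_cohort_fit(self, ref_network):
        table = ref_network["fit_table"]
        assert np.isfinite(ref_network["beta"])
        good = table[(table["power"] <= 12) & (table["fit_r2"] >= 0.8)]
        assert len(good) > 0

    def test_single_candidate_forced(self, ref_network):
        cor = ref_network["cor"]
        config = nw.NetworkConfig(power_candidates=[6])
        with pytest.warns(UserWarning, match="forced"):
            beta, _ = nw.pick_soft_threshold(cor, config)
        assert beta == 6

    def test_identity_correlation_degenerate(self):
        cor = pd.DataFrame(np.eye(10))
        with pytest.raises(nw.DegenerateNetworkError):
            nw.pick_soft_threshold(cor)


class TestTopologicalOverlap:
    def test_hand_computed_three_gene_cell(self):
        a = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.2], [0.4, 0.2, 1.0]])
        tom = nw.topological_overlap(a)
        # (0.4*0.2 + 0.8) / (min(1.2, 1.0) + 1 - 0.8) = 0.88 / 1.2
        assert tom[0, 1] == pytest.approx(0.88 / 1.2, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        a = random_adjacency(rng, 20)
        tom = nw.topological_overlap(a)
        assert np.abs(tom - tom_bruteforce(a)).max() < 1e-10

    def test_zero_offdiagonal_gives_zero_tom(self):
        tom = nw.topological_overlap(np.eye(5))
        assert np.allclose(tom, np.eye(5))

    def test_clique_adjacency_gives_all_ones(self):
        tom = nw.topological_overlap(np.ones((6, 6)))
        assert np.allclose(tom, 1.0)

    def test_range_and_symmetry(self, rng):
        tom = nw.topological_overlap(random_adjacency(rng, 15))
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            nw.topological_overlap(a)


class TestDetectModules:
    def test_two_perfect_blocks(self):
        n = 10
        tom = np.full((n, n), 0.05)
        tom[:5, :5] = 0.9
        tom[5:, 5:] = 0.9
        np.fill_diagonal(tom, 1.0)
        labels = nw.detect_modules(
            pd.DataFrame(tom, index=[f"g{i}" for i in range(n)],
                         columns=[f"g{i}" for i in range(n)]),
            nw.NetworkConfig(min_module_size=3, cut_height=0.5),
        )
        assert labels.nunique() == 2
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_planted_cohort_recovery(self, ref_cohort, ref_network):
        from sklearn.metrics import adjusted_rand_score

        labels = ref_network["labels"]
        truth = ref_cohort["labels"]
        assigned = labels.index[labels != 0]
        ari = adjusted_rand_score(truth.loc[assigned], labels.loc[assigned])
        assert ari >= 0.8

    def test_cut_below_merges_leaves_all_unassigned(self, rng):
        tom = pd.DataFrame(random_adjacency(rng, 12) * 0.5)
        np.fill_diagonal(tom.values, 1.0)
        with pytest.warns(UserWarning, match="empty partition"):
            labels = nw.detect_modules(
                tom, nw.NetworkConfig(min_module_size=3, cut_height=1e-9)
            )
        assert (labels == 0).all()


class TestModuleEigengene:
    def test_identical_genes_give_perfect_correlation(self, rng):
        base = rng.standard_normal(20)
        expr = pd.DataFrame([base, base, base], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(20)])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig = nw.module_eigengene(expr, labels)
        r = np.corrcoef(eig.loc["ME1"], base)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_planted_factor_recovered(self, ref_cohort, ref_network):
        eig = ref_network["eigengenes"]
        factors = ref_cohort["factors"]
        best = [
            max(abs(np.corrcoef(eig.loc[me], factors.loc[m])[0, 1])
                for m in factors.index)
            for me in eig.index
        ]
        assert min(best) >= 0.9

    def test_sign_flip_of_module_flips_eigengene(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 15)),
                            index=list("abcd"))
        labels = pd.Series([1] * 4, index=expr.index)
        e1 = nw.module_eigengene(expr, labels)
        e2 = nw.module_eigengene(-expr, labels)
        assert np.allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-9)

    def test_eigengene_maximizes_explained_variance(self, rng):
        # against the full decomposition on a small module
        expr = pd.DataFrame(rng.standard_normal((6, 12)))
        labels = pd.Series([1] * 6, index=expr.index)
        eig = nw.module_eigengene(expr, labels).loc["ME1"].to_numpy()
        x = expr.to_numpy()
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                         keepdims=True)
        _, s, _ = np.linalg.svd(xs, full_matrices=False)
        # energy captured along the returned eigengene direction equals the
        # leading singular value's share -- the maximum over unit vectors
        u = eig / np.linalg.norm(eig)
        assert ((xs @ u) ** 2).sum() == pytest.approx(s[0] ** 2, rel=1e-9)


class TestGeneStatistics:
    def test_gs_of_self_is_one(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 10)),
                            columns=[f"s{i}" for i in range(10)])
        metab = expr.iloc[[0]].set_axis(["m"])
        gs = nw.gene_significance(expr, metab)
        assert gs.loc[0, "m"] == pytest.approx(1.0)

    def test_null_metabolite_gs_small(self, ref_cohort, rng):
        expr = ref_cohort["expr"].iloc[:100]
        metab = pd.DataFrame(rng.standard_normal((1, expr.shape[1])),
                             index=["null"], columns=expr.columns)
        gs = nw.gene_significance(expr, metab)
        assert (gs["null"].abs() < 0.5).mean() >= 0.99

    def test_insufficient_overlap_is_error(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 5)),
                            columns=[f"s{i}" for i in range(5)])
        metab = pd.DataFrame(rng.standard_normal((1, 2)),
                             columns=["s0", "s1"])
        with pytest.raises(nw.InsufficientOverlapError):
            nw.gene_significance(expr, metab)

    def test_kme_of_eigengene_clone_is_one(self, ref_network, ref_cohort):
        eig = ref_network["eigengenes"]
        expr = pd.DataFrame([eig.loc["ME1"]], index=["clone"])
        kme = nw.module_membership(expr, eig)
        assert kme.loc["clone", "ME1"] == pytest.approx(1.0)

    def test_kme_dominance_on_planted_modules(self, ref_cohort, ref_network):
        kme = ref_network["kme"]
        truth = ref_cohort["labels"]
        labels = ref_network["labels"]
        module_genes = truth[truth > 0].index
        hits = 0
        for gene in module_genes:
            own = f"ME{labels.loc[gene]}"
            if own not in kme.columns:
                continue
            hits += int(kme.columns[np.argmax(kme.loc[gene].abs().to_numpy())]
                        == own)
        assert hits / len(module_genes) >= 0.95

    def test_kme_matches_per_pair_correlation(self, rng):
        expr = pd.DataFrame(rng.standard_normal((10, 12)),
                            columns=[f"s{i}" for i in range(12)])
        labels = pd.Series([1] * 5 + [2] * 5, index=expr.index)
        eig = nw.module_eigengene(expr, labels)
        kme = nw.module_membership(expr, eig)
        for g in expr.index:
            for m in eig.index:
                expected = np.corrcoef(expr.loc[g], eig.loc[m])[0, 1]
                assert kme.loc[g, m] == pytest.approx(expected, abs=1e-10)
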