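"""Co-expression network: soft power, scale-free fit, TOM, module
detection/merging, eigengenes, module-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from llnet import network
from llnet.network import (
    NetworkConfig,
    adjacency_matrix,
    compute_eigengenes,
    connectivity,
    detect_modules,
    eigengene,
    extrapolate_module_alpha,
    merge_modules,
    module_membership_vs_significance,
    module_trait_correlation,
    replication_coexpression,
    scale_free_fit,
    select_probes_by_meta_trait,
    select_soft_power,
    tom_similarity,
)
from sklearn.metrics import adjusted_rand_score


def _block_expression(sizes, n_samples, noise=0.0, seed=0, factor_cor=None):
    """Block-structured probes x samples matrix with one factor per block."""
    r = np.random.default_rng(seed)
    rows = []
    for b, size in enumerate(sizes):
        f = r.standard_normal(n_samples)
        rows.extend(f + noise * r.standard_normal(n_samples) for _ in range(size))
    probes = [f"P{i:03d}" for i in range(sum(sizes))]
    return pd.DataFrame(rows, index=probes, columns=[f"S{i}" for i in range(n_samples)])


class TestSelectProbes:
    def test_top_fraction_count(self, rng):
        meta = pd.DataFrame({"p": rng.random(100)}, index=[f"P{i:03d}" for i in range(100)])
        assert len(select_probes_by_meta_trait(meta, 0.10)) == 10

    def test_tie_break_is_deterministic_by_probe_id(self):
        meta = pd.DataFrame(
            {"p": [0.5, 0.5, 0.5, 0.1]}, index=["Pb", "Pa", "Pc", "Pd"]
        )
        sel = select_probes_by_meta_trait(meta, 0.5)
        assert list(sel) == ["Pd", "Pa"]

    def test_gene_collapse_keeps_best_signal(self):
        meta = pd.DataFrame(
            {"p": [1e-8, 1e-5, 1e-3, 1e-2], "gene": ["G1", "G1", "G2", "G3"]},
            index=["P1", "P2", "P3", "P4"],
        )
        sel = select_probes_by_meta_trait(meta, 1.0)
        assert "P2" not in sel and "P1" in sel

    def test_planted_module_probes_ranked_into_top_fraction(self, default_dataset):
        from llnet.association import fit_meta_lipids

        expr, _, traits, truth = default_dataset
        z = {}
        for name in traits.traits:
            v = traits.data[name]
            z[name] = (v - v.mean()) / v.std()
        Y = pd.DataFrame(z)
        rows = {}
        for probe in expr.probes:
            rows[probe] = fit_meta_lipids(Y, expr.values.loc[probe])["p"]
        meta = pd.DataFrame({"p": pd.Series(rows)})
        sel = select_probes_by_meta_trait(meta, 0.10)
        m1 = truth.module_assignment[truth.module_assignment == 1].index
        # the trait-coupled module is strongly enriched in the top decile
        assert len(sel.intersection(m1)) >= 0.9 * len(m1)


class TestSoftPower:
    def test_beta_one_connectivity_equals_row_sums_minus_one(self):
        corr = np.array(
            [[1.0, 0.5, 0.2], [0.5, 1.0, -0.4], [0.2, -0.4, 1.0]]
        )
        k = connectivity(adjacency_matrix(corr, 1))
        expected = np.abs(corr).sum(axis=1) - 1
        assert np.allclose(k, expected)

    def test_adjacency_bounds_and_symmetry(self, rng):
        X = rng.standard_normal((30, 60))
        corr = np.corrcoef(X)
        a = adjacency_matrix(corr, 6)
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1
        assert np.all(np.diag(a) == 0)

    def test_chosen_power_reaches_signed_r2(self, default_dataset):
        expr, *_ = default_dataset
        corr = np.corrcoef(expr.values.to_numpy())
        beta, table = select_soft_power(corr)
        row = table[table["power"] == beta].iloc[0]
        assert row["signed_r2"] > 0.80
        qualifying = table[table["signed_r2"] > 0.80]
        assert beta == qualifying["power"].min()  # smallest qualifying power

    def test_equal_correlations_error(self):
        corr = np.full((20, 20), 0.5)
        np.fill_diagonal(corr, 1.0)
        with pytest.raises(ValueError, match="single bin|no power"):
            select_soft_power(corr, NetworkConfig(power_grid=(1,)))


class TestScaleFreeFit:
    def test_exact_power_law_scores_high(self):
        ks = []
        for k in range(1, 11):
            ks.extend([float(k)] * max(1, round(1000 * k**-2.0)))
        assert scale_free_fit(np.array(ks)) >= 0.99

    def test_increasing_degree_distribution_scores_negative(self):
        ks = []
        for k in range(1, 11):
            ks.extend([float(k)] * (k**2))
        assert scale_free_fit(np.array(ks)) < 0

    def test_matches_brute_force_binned_regression(self, rng):
        k = rng.uniform(0.1, 5.0, 400)
        ours = scale_free_fit(k)
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            kb = k[idx == b]
            if kb.size:
                xs.append(np.log10(kb.mean()))
                ys.append(np.log10(kb.size / k.size))
        slope, _, r, _, _ = stats.linregress(xs, ys)
        assert ours == pytest.approx(r**2 * -np.sign(slope), abs=1e-12)

    def test_needs_five_positive_values(self):
        with pytest.raises(ValueError, match=">= 5"):
            scale_free_fit(np.array([1.0, 2.0, 0.0]))


class TestTOM:
    def test_tom_bounds_and_diagonal(self, rng):
        corr = np.corrcoef(rng.standard_normal((25, 80)))
        tom = tom_similarity(adjacency_matrix(corr, 6))
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        off = tom[np.triu_indices(25, 1)]
        assert off.min() >= 0 and off.max() <= 1

    def test_two_noiseless_blocks_recovered_exactly(self):
        expr = _block_expression([15, 15], 50, noise=0.0, seed=1)
        corr = np.corrcoef(expr.to_numpy())
        dissim = 1 - tom_similarity(adjacency_matrix(corr, 6))
        mods = detect_modules(dissim, expr.index)
        assert mods.n_modules == 2
        assert adjusted_rand_score(
            [0] * 15 + [1] * 15, mods.assignment.to_numpy()
        ) == 1.0


class TestDetectModules:
    def test_default_synthetic_recovery(self, default_dataset):
        expr, _, _, truth = default_dataset
        corr = np.corrcoef(expr.values.to_numpy())
        beta, _ = select_soft_power(corr)
        dissim = 1 - tom_similarity(adjacency_matrix(corr, beta))
        mods = merge_modules(detect_modules(dissim, expr.probes), expr.values)
        ari = adjusted_rand_score(truth.module_assignment, mods.assignment)
        assert ari >= 0.8

    def test_shuffled_samples_produce_no_modules(self, default_dataset):
        expr, *_ = default_dataset
        found = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = expr.values.to_numpy().copy()
            for i in range(X.shape[0]):
                r.shuffle(X[i])
            corr = np.corrcoef(X)
            dissim = 1 - tom_similarity(adjacency_matrix(corr, 6))
            found += detect_modules(dissim, expr.probes).n_modules > 0
        assert found == 0

    def test_probe_order_invariance(self):
        expr = _block_expression([12, 14], 60, noise=0.6, seed=2)
        corr = np.corrcoef(expr.to_numpy())
        dissim = 1 - tom_similarity(adjacency_matrix(corr, 4))
        mods = detect_modules(dissim, expr.index)
        perm = np.random.default_rng(0).permutation(len(expr))
        mods_p = detect_modules(dissim[np.ix_(perm, perm)], expr.index[perm])
        merged = mods.assignment.reindex(expr.index)
        merged_p = mods_p.assignment.reindex(expr.index)
        assert adjusted_rand_score(merged, merged_p) == 1.0

    def test_too_few_probes_all_background(self):
        dissim = np.zeros((4, 4))
        mods = detect_modules(dissim, pd.Index(list("abcd")))
        assert mods.n_modules == 0


class TestEigengene:
    def test_identical_probes_give_common_profile(self, rng):
        profile = rng.standard_normal(50)
        sub = pd.DataFrame(
            np.tile(profile, (6, 1)), columns=[f"S{i}" for i in range(50)]
        )
        eg = eigengene(sub)
        z = (profile - profile.mean()) / profile.std(ddof=0)
        assert np.allclose(eg.to_numpy(), z, atol=1e-10)
        assert eg.std(ddof=0) == pytest.approx(1.0)

    def test_sign_flip_of_probes_flips_eigengene(self, rng):
        sub = pd.DataFrame(
            rng.standard_normal((8, 40)) + np.sin(np.arange(40)),
            columns=[f"S{i}" for i in range(40)],
        )
        eg = eigengene(sub)
        eg_neg = eigengene(-sub)
        assert np.allclose(eg.to_numpy(), -eg_neg.to_numpy(), atol=1e-10)

    def test_recovers_latent_factor(self, default_dataset):
        expr, _, _, truth = default_dataset
        for m, label in enumerate(truth.latent_factors.index, start=1):
            probes = truth.module_assignment[truth.module_assignment == m].index
            eg = eigengene(expr.values.loc[probes])
            r = np.corrcoef(eg, truth.latent_factors.loc[label])[0, 1]
            assert abs(r) >= 0.9

    def test_single_probe_errors(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            eigengene(pd.DataFrame(rng.standard_normal((1, 10))))


class TestMergeModules:
    def _assigned(self, labels, probes):
        return network.ModuleSet(pd.Series(labels, index=probes))

    def test_highly_correlated_modules_merge(self, rng):
        f = rng.standard_normal(80)
        rows = [f + 0.35 * rng.standard_normal(80) for _ in range(24)]
        expr = pd.DataFrame(rows, index=[f"P{i}" for i in range(24)],
                            columns=[f"S{i}" for i in range(80)])
        mods = self._assigned([1] * 12 + [2] * 12, expr.index)
        merged = merge_modules(mods, expr, merge_height=0.20)
        assert merged.n_modules == 1

    def test_orthogonal_modules_do_not_merge(self, rng):
        expr = _block_expression([12, 12], 100, noise=0.3, seed=4)
        mods = self._assigned([1] * 12 + [2] * 12, expr.index)
        merged = merge_modules(mods, expr, merge_height=0.20)
        assert merged.n_modules == 2

    def test_idempotent(self, default_dataset):
        expr, _, _, truth = default_dataset
        mods = self._assigned(truth.module_assignment.to_numpy(), expr.probes)
        once = merge_modules(mods, expr.values)
        twice = merge_modules(once, expr.values)
        assert twice.n_modules == once.n_modules <= mods.n_modules


class TestModuleTraitStats:
    def test_trait_equal_to_eigengene(self, rng):
        eg = pd.DataFrame(
            rng.standard_normal((1, 60)), index=[1],
            columns=[f"S{i}" for i in range(60)],
        )
        traits = pd.DataFrame({"T": eg.iloc[0]})
        out = module_trait_correlation(eg, traits)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-30

    def test_null_trait_p_uniform_over_seeds(self):
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            eg = pd.DataFrame(
                r.standard_normal((1, 80)), index=[1],
                columns=[f"S{i}" for i in range(80)],
            )
            traits = pd.DataFrame(
                {"T": r.standard_normal(80)}, index=eg.columns
            )
            pvals.append(module_trait_correlation(eg, traits)["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_association_passes_extrapolated_gate(self):
        passed = 0
        _, alpha = extrapolate_module_alpha(23, 1000, 35419)
        for seed in range(25):
            r = np.random.default_rng(seed)
            f = r.standard_normal(500)
            trait = 0.4 * f + np.sqrt(1 - 0.16) * r.standard_normal(500)
            cols = [f"S{i}" for i in range(500)]
            eg = pd.DataFrame(f[None, :], index=[1], columns=cols)
            traits = pd.DataFrame({"T": trait}, index=cols)
            out = module_trait_correlation(eg, traits, alpha=alpha)
            passed += bool(out["significant"].iloc[0])
        assert passed >= 20  # >= 80% of seeds

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((23, 1000, 35419), (814.637, 6.14e-5)),
            ((1, 1000, 1000), (1.0, 0.05)),
        ],
    )
    def test_extrapolation_worked_examples(self, args, expected):
        est, alpha = extrapolate_module_alpha(*args)
        assert est == pytest.approx(expected[0], abs=5e-4)
        assert alpha == pytest.approx(expected[1], rel=2e-3)


class TestMembershipSignificance:
    def _modules(self, expr, labels):
        ms = network.ModuleSet(pd.Series(labels, index=expr.index))
        ms.eigengenes = compute_eigengenes(ms, expr)
        return ms

    def test_graded_loadings_give_positive_kme_gs_correlation(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            f = r.standard_normal(200)
            loadings = np.linspace(0.3, 0.9, 15)
            rows = [l * f + np.sqrt(1 - l**2) * r.standard_normal(200) for l in loadings]
            expr = pd.DataFrame(rows, index=[f"P{i}" for i in range(15)],
                                columns=[f"S{i}" for i in range(200)])
            mods = self._modules(expr, [1] * 15)
            trait = pd.Series(0.5 * f + r.standard_normal(200), index=expr.columns)
            out = module_membership_vs_significance(mods, expr, trait, 1)
            hits += out.attrs["kme_gs_correlation"] > 0
        assert hits >= 19

    def test_degenerate_module_reports_nan(self, rng):
        f = rng.standard_normal(60)
        expr = pd.DataFrame(
            np.tile(f, (5, 1)), index=[f"P{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(60)],
        )
        mods = self._modules(expr, [1] * 5)
        trait = pd.Series(f, index=expr.columns)
        out = module_membership_vs_significance(mods, expr, trait, 1)
        assert np.isnan(out.attrs["kme_gs_correlation"])

    def test_background_probes_excluded(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((10, 40)), index=[f"P{i}" for i in range(10)],
            columns=[f"S{i}" for i in range(40)],
        )
        mods = self._modules(expr, [1] * 6 + [0] * 4)
        trait = pd.Series(rng.standard_normal(40), index=expr.columns)
        out = module_membership_vs_significance(mods, expr, trait, 1)
        assert len(out) == 6


class TestReplicationCoexpression:
    def test_seven_genes_yield_21_pair_gate(self, rng):
        genes = [f"G{i}" for i in range(7)]
        expr = pd.DataFrame(
            rng.standard_normal((7, 75)), index=genes,
            columns=[f"S{i}" for i in range(75)],
        )
        out = replication_coexpression(expr, genes)
        assert out.attrs["bonferroni_gate"] == pytest.approx(0.05 / 21)
        assert f"{out.attrs['bonferroni_gate']:.2e}" == "2.38e-03"
        assert len(out) == 42  # ordered pairs, both directions

    def test_identical_profiles_have_rho_one(self, rng):
        x = rng.standard_normal(50)
        expr = pd.DataFrame([x, x], index=["G1", "G2"],
                            columns=[f"S{i}" for i in range(50)])
        out = replication_coexpression(expr, ["G1", "G2"])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_matrix_rarely_significant(self, rng):
        genes = [f"G{i}" for i in range(7)]
        expr = pd.DataFrame(
            rng.standard_normal((7, 75)), index=genes,
            columns=[f"S{i}" for i in range(75)],
        )
        out = replication_coexpression(expr, genes)
        # expected significant unordered pairs = 21 * 2.38e-3 = 0.05
        assert out["significant"].sum() <= 2
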