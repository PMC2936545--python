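"""QC and normalization: replicate gates, quantile normalization, probe
filters, trait transformation, HWE exact test, Tracy-Widom PCA outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from llnet.datatypes import GenotypeDataset
from llnet.preprocess import (
    ReplicatePair,
    anderson_darling_pvalue,
    combine_replicates,
    filter_probes,
    hwe_exact_test,
    pca_outliers,
    qc_genotypes,
    qc_replicates,
    quantile_normalize,
    tracy_widom_sf,
    transform_trait,
)


def _pair(s1, s2, b1=None, b2=None, sample="S0"):
    idx = pd.Index([f"P{i}" for i in range(len(s1))])
    ones = np.ones(len(s1), dtype=int)
    return ReplicatePair(
        sample,
        pd.Series(s1, index=idx, dtype=float),
        pd.Series(s2, index=idx, dtype=float),
        pd.Series(b1 if b1 is not None else ones, index=idx),
        pd.Series(b2 if b2 is not None else ones, index=idx),
    )


class TestReplicateQC:
    def test_identical_replicates_kept_with_unit_correlations(self, rng):
        s = rng.lognormal(8, 1, 50)
        rep = qc_replicates([_pair(s, s)]).replicates.iloc[0]
        assert rep["pearson"] == pytest.approx(1.0)
        assert rep["spearman"] == pytest.approx(1.0)
        assert rep["kept"]

    def test_anticorrelated_replicates_dropped(self):
        s = np.linspace(100, 200, 30)
        report = qc_replicates([_pair(s, s[::-1])])
        row = report.replicates.iloc[0]
        assert row["pearson"] < 0.94 and not row["kept"]

    def test_degenerate_replicate_flagged(self):
        report = qc_replicates([_pair(np.full(20, 7.0), np.full(20, 7.0))])
        assert report.replicates.iloc[0]["reason"] == "degenerate"

    def test_corrupted_fraction_drops_match_direct_oracle(self, small_dataset):
        expr, *_ = small_dataset
        pairs = list(expr.replicates.values())
        report = qc_replicates(pairs)
        # oracle: quantile-normalize all log2 replicate columns directly and
        # recompute the two correlations per sample
        mat = pd.DataFrame(
            {(p.sample_id, k): np.log2(getattr(p, f"s{k}").to_numpy())
             for p in pairs for k in (1, 2)}
        )
        mat = quantile_normalize(mat)
        expected_drop = set()
        for p in pairs:
            x, y = mat[(p.sample_id, 1)], mat[(p.sample_id, 2)]
            if np.corrcoef(x, y)[0, 1] < 0.94 or stats.spearmanr(x, y).statistic < 0.60:
                expected_drop.add(p.sample_id)
        assert set(report.samples_dropped) == expected_drop
        corrupted = {p.sample_id for p in pairs if p.corrupted}
        assert expected_drop <= corrupted  # only injected corruption drops


class TestCombineReplicates:
    def test_worked_examples(self):
        assert combine_replicates(_pair([10, 10], [20, 20])).iloc[0] == 15.0
        assert combine_replicates(
            _pair([10, 10], [20, 20], b1=[3, 3], b2=[1, 1])
        ).iloc[0] == 12.5

    def test_equal_beads_is_arithmetic_mean(self, rng):
        s1, s2 = rng.lognormal(8, 1, 30), rng.lognormal(8, 1, 30)
        out = combine_replicates(_pair(s1, s2, b1=[7] * 30, b2=[7] * 30))
        assert np.allclose(out, (s1 + s2) / 2)

    def test_nonpositive_beads_error(self):
        with pytest.raises(ValueError, match="positive"):
            combine_replicates(_pair([1, 2], [3, 4], b1=[0, 1], b2=[1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_convexity(self, seed):
        r = np.random.default_rng(seed)
        s1, s2 = r.lognormal(8, 1, 10), r.lognormal(8, 1, 10)
        b1, b2 = r.integers(1, 60, 10), r.integers(1, 60, 10)
        out = combine_replicates(_pair(s1, s2, b1=b1, b2=b2)).to_numpy()
        assert (out >= np.minimum(s1, s2) - 1e-12).all()
        assert (out <= np.maximum(s1, s2) + 1e-12).all()


def _qn_oracle(df: pd.DataFrame) -> pd.DataFrame:
    """Brute-force rank-then-average quantile normalization."""
    ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    out = df.copy().astype(float)
    for c in df.columns:
        col = df[c].to_numpy()
        assigned = np.empty_like(ref)
        assigned[np.argsort(col, kind="mergesort")] = ref
        for v in np.unique(col):
            m = col == v
            assigned[m] = assigned[m].mean()
        out[c] = assigned
    return out


class TestQuantileNormalize:
    def test_permuted_columns_become_identical_multisets(self, rng):
        x = rng.standard_normal(40)
        df = pd.DataFrame({"a": x, "b": rng.permutation(x)})
        out = quantile_normalize(df)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))
        assert stats.spearmanr(df["a"], out["a"]).statistic == pytest.approx(1.0)

    def test_column_means_equal(self, rng):
        df = pd.DataFrame(rng.lognormal(0, 1, (50, 4)))
        out = quantile_normalize(df)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])

    def test_matches_brute_force_oracle_with_ties(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (9, 3)).astype(float))
        assert np.allclose(quantile_normalize(df), _qn_oracle(df))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        df = pd.DataFrame(r.standard_normal((12, 3)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_single_column_identity(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        assert quantile_normalize(df).equals(df)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


class TestFilterProbes:
    def test_rules(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["1", "X", "22", "7", "MT"],
                "globin": [False, False, True, False, False],
                "n_mappings": [1, 1, 1, 2, 1],
            },
            index=list("abcde"),
        )
        keep = filter_probes(ann)
        assert keep.tolist() == [True, False, False, False, False]

    def test_flagged_count_exact(self, small_dataset):
        expr, *_ = small_dataset
        keep = filter_probes(expr.annotations)
        n_flagged = round(0.10 * len(expr.probes))
        assert keep.sum() == len(expr.probes) - n_flagged


class TestTransformTrait:
    def test_normal_input_standardized_without_transform(self, rng):
        idx = pd.RangeIndex(400)
        x = pd.Series(rng.standard_normal(400) * 3 + 10, index=idx)
        sex = pd.Series(np.where(rng.random(400) < 0.5, "m", "f"), index=idx)
        z, meta = transform_trait(x, sex)
        for level in ("m", "f"):
            sub = z[sex == level]
            assert abs(sub.mean()) < 1e-12 and abs(sub.std(ddof=0) - 1) < 1e-12
            assert meta[level]["boxcox_lambda"] is None

    def test_lognormal_lambda_near_log_limit(self, rng):
        idx = pd.RangeIndex(500)
        x = pd.Series(rng.lognormal(1, 0.8, 500), index=idx)
        sex = pd.Series(["m"] * 500, index=idx)
        z, meta = transform_trait(x, sex)
        assert -0.2 <= meta["m"]["boxcox_lambda"] <= 0.2

    def test_transform_restores_normality(self):
        passed = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            idx = pd.RangeIndex(500)
            x = pd.Series(r.lognormal(0, 0.7, 500), index=idx)
            sex = pd.Series(["m"] * 500, index=idx)
            z, _ = transform_trait(x, sex)
            passed += anderson_darling_pvalue(z.to_numpy()) >= 0.01
        assert passed >= 38  # >= 95% of simulations

    def test_constant_trait_errors(self):
        idx = pd.RangeIndex(20)
        with pytest.raises(ValueError, match="zero variance"):
            transform_trait(
                pd.Series(np.ones(20), index=idx), pd.Series(["m"] * 20, index=idx)
            )

    def test_nonpositive_values_error_when_transform_needed(self, rng):
        idx = pd.RangeIndex(300)
        x = pd.Series(rng.lognormal(0, 1, 300) - 5, index=idx)
        sex = pd.Series(["f"] * 300, index=idx)
        with pytest.raises(ValueError, match="positive"):
            transform_trait(x, sex)

    def test_anderson_darling_matches_r_nortest(self):
        # frozen sample; reference value from R nortest::ad.test
        x = np.random.default_rng(42).lognormal(0, 0.6, 60).round(6)
        assert anderson_darling_pvalue(x) == pytest.approx(0.01023150421, rel=1e-6)


def _hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE P by full enumeration of genotype tables with the observed
    allele counts, using multinomial probabilities directly."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def prob(het):
        homr = (min(n_a, 2 * n - n_a) - het) // 2
        if min(n_a, 2 * n - n_a) == n_a:
            aa, bb = homr, n - het - homr
        else:
            bb, aa = homr, n - het - homr
        return float(
            np.exp(
                special.gammaln(n + 1)
                - special.gammaln(aa + 1)
                - special.gammaln(het + 1)
                - special.gammaln(bb + 1)
                + het * np.log(2)
                + special.gammaln(n_a + 1)
                + special.gammaln(2 * n - n_a + 1)
                - special.gammaln(2 * n + 1)
            )
        )

    rare = min(n_a, 2 * n - n_a)
    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_perfect_hwe_counts_kept(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    @pytest.mark.parametrize(
        "counts", [(25, 50, 25), (0, 50, 0), (10, 0, 10), (3, 7, 40), (0, 0, 30)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_random_tables_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 50))
            aa = int(rng.integers(0, n + 1))
            ab = int(rng.integers(0, n - aa + 1))
            bb = n - aa - ab
            assert hwe_exact_test(aa, ab, bb) == pytest.approx(
                _hwe_enumeration_oracle(aa, ab, bb), abs=1e-12
            )


def _toy_genotypes(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "chromosome": [chrom] * m,
            "position": positions if positions is not None else np.arange(1, m + 1) * 1000,
        },
        index=pd.Index([f"rs{j}" for j in range(m)], name="snp"),
    )
    return GenotypeDataset(
        pd.DataFrame(dosages, index=[f"S{i}" for i in range(n)], columns=snps.index),
        snps,
    )


class TestGenotypeQC:
    def test_high_missingness_snp_dropped(self, rng):
        dos = rng.binomial(2, 0.3, (100, 30)).astype(float)
        dos[:10, 0] = np.nan  # 10% missing at one SNP
        report, filtered = qc_genotypes(_toy_genotypes(dos))
        assert not report.snps.iloc[0]["kept"]
        assert "call_rate" in report.snps.iloc[0]["reason"]
        assert "rs0" not in filtered.snp_ids

    def test_hwe_and_maf_gates(self, rng):
        good = rng.binomial(2, 0.3, 200)
        rare = np.zeros(200)
        rare[0] = 1  # MAF 0.0025 < 0.01
        bad_hwe = np.array([0.0, 2.0] * 100)  # no heterozygotes
        report, filtered = qc_genotypes(
            _toy_genotypes(np.column_stack([good, rare, bad_hwe]))
        )
        assert report.snps["kept"].tolist() == [True, False, False]
        assert report.snps.iloc[1]["reason"] == "maf"
        assert "hwe" in report.snps.iloc[2]["reason"]

    def test_sample_call_rate_gate(self, rng):
        dos = rng.binomial(2, 0.4, (50, 40)).astype(float)
        dos[0, :4] = np.nan  # sample 0 call rate 0.9
        report, filtered = qc_genotypes(_toy_genotypes(dos))
        assert report.samples_dropped == ["S0"]
        assert filtered.dosages.shape[0] == 49


class TestPCAOutliers:
    def test_tracy_widom_tail_quantiles(self):
        # literature quantiles of the TW1 distribution
        assert tracy_widom_sf(0.9793) == pytest.approx(0.05, abs=2e-3)
        assert tracy_widom_sf(2.0234) == pytest.approx(0.01, abs=1e-3)

    def test_homogeneous_panel_has_no_outliers(self, rng):
        dos = rng.binomial(2, 0.3, (120, 300)).astype(float)
        outliers, report = pca_outliers(_toy_genotypes(dos))
        assert outliers == []

    def test_planted_subpopulation_flagged_exactly(self, rng):
        n_main, n_out, m = 500, 5, 2000
        maf = rng.uniform(0.2, 0.5, m)
        shifted = np.clip(maf + 0.3, 0.05, 0.95)
        main = rng.binomial(2, maf, (n_main, m)).astype(float)
        sub = rng.binomial(2, shifted, (n_out, m)).astype(float)
        gd = _toy_genotypes(np.vstack([main, sub]))
        outliers, report = pca_outliers(gd)
        assert outliers == [f"S{i}" for i in range(n_main, n_main + n_out)]
        assert report.tw_pvalues[0] < 0.01

    def test_deterministic(self, rng):
        dos = rng.binomial(2, 0.3, (60, 100)).astype(float)
        gd = _toy_genotypes(dos)
        assert pca_outliers(gd)[0] == pca_outliers(gd)[0]
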