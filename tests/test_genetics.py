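import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qrs.genetics import (
    GenotypeBlock,
    VariantRecord,
    acat_combine,
    beta_weight,
    burden_test,
    dispersion_test,
    fit_null_model,
    gene_combined_test,
    partition_variants,
    qc_filter,
    significance_threshold,
    single_variant_tests,
    ultra_rare_burden,
)
from qrs.genetics.vcf import blocks_to_dosage_frame, read_gene_intervals, read_vcf_blocks
from qrs.synthetic import CohortSpec, simulate_genotypes, write_vcf


def _variant(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="G")
    base.update(kw)
    return VariantRecord(**base)


class TestQC:
    def test_snv_qd_fail(self):
        assert qc_filter([_variant(qd=1.9)]) == []

    def test_indel_fs_threshold_differs(self):
        indel = _variant(alt="GT", fs=150.0)
        assert qc_filter([indel]) == [indel]  # indel FS cut is 200
        snv = _variant(fs=150.0)
        assert qc_filter([snv]) == []  # SNV FS cut is 60

    def test_absent_metrics_pass(self):
        v = _variant()
        assert qc_filter([v]) == [v]

    @pytest.mark.parametrize(
        "kw",
        [dict(mq=39.0), dict(sor=3.5), dict(mq_rank_sum=-13.0), dict(read_pos_rank_sum=-9.0)],
    )
    def test_each_snv_rule(self, kw):
        assert qc_filter([_variant(**kw)]) == []

    def test_idempotent_and_conserving(self, genotype_blocks):
        blocks, _ = genotype_blocks
        variants = [v for b in blocks.values() for v in b.variants]
        once = qc_filter(variants)
        assert qc_filter(once) == once
        removed = [v for v in variants if v not in once]
        assert len(once) + len(removed) == len(variants)


class TestBlockAndPartitions:
    def test_maf_mac_orientation(self):
        # alt frequency 0.75 -> flipped, MAF 0.25, MAC counts the minor allele
        doses = np.array([[2.0], [2.0], [1.0], [1.0]])
        b = GenotypeBlock("g", list("abcd"), doses, [_variant()])
        assert b.maf[0] == pytest.approx(0.25)
        assert b.mac[0] == 2
        assert b.flipped[0]

    def test_missing_mean_imputed_after_mac(self):
        doses = np.array([[1.0], [np.nan], [0.0], [0.0]])
        b = GenotypeBlock("g", list("abcd"), doses, [_variant()])
        assert b.mac[0] == 1  # computed on observed calls only
        assert b.dosages[1, 0] == pytest.approx(1 / 3)

    def test_partitions_disjoint_and_rules(self):
        n = 1000
        rng = np.random.default_rng(0)
        mafs = [0.05, 0.005, 0.001, 0.02]
        doses = rng.binomial(2, mafs, size=(n, 4)).astype(float)
        doses[:, 2] = 0.0
        doses[:3, 2] = 1.0  # MAC 3 -> ultra-rare
        b = GenotypeBlock("g", [f"s{i}" for i in range(n)], doses,
                          [_variant(pos=100 + i) for i in range(4)])
        parts = partition_variants(b)
        allidx = np.concatenate(list(parts.values()))
        assert len(allidx) == len(set(allidx))
        assert 2 in parts["ultra_rare"]

    def test_rare_partition_example(self):
        n = 1000
        doses = np.zeros((n, 1))
        doses[:7, 0] = 1.0  # MAF 0.0035, MAC 7 -> rare
        b = GenotypeBlock("g", [f"s{i}" for i in range(n)], doses, [_variant()])
        parts = partition_variants(b)
        assert list(parts["rare"]) == [0]

    def test_monomorphic_excluded(self):
        doses = np.zeros((10, 1))
        b = GenotypeBlock("g", [f"s{i}" for i in range(10)], doses, [_variant()])
        parts = partition_variants(b)
        assert all(len(v) == 0 for v in parts.values())

    def test_beta_weight_values(self):
        assert beta_weight(1e-9) == pytest.approx(25.0, rel=1e-6)
        assert beta_weight(0.01) == pytest.approx(25 * 0.99**24, rel=1e-12)
        # cross-check against the generic beta pdf
        assert beta_weight(0.037) == pytest.approx(stats.beta.pdf(0.037, 1, 25))
        mafs = np.linspace(0.001, 0.5, 50)
        assert (np.diff(beta_weight(mafs)) < 0).all()
        with pytest.raises(ValueError):
            beta_weight(0.0)


class TestNullModel:
    def test_gaussian_no_covariates_residuals_centered(self, rng):
        y = pd.Series(rng.standard_normal(100), index=[f"s{i}" for i in range(100)])
        null = fit_null_model(y, None, family="gaussian")
        resid = y.values - null.fitted_mean
        assert abs(resid.sum()) < 1e-8

    def test_inverse_gaussian_recovers_coefficients(self, rng):
        n = 4000
        idx = [f"s{i}" for i in range(n)]
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        mu = np.exp(1.0 + 0.3 * x1 - 0.2 * x2)
        y = pd.Series(rng.wald(mu, 20.0), index=idx)
        cov = pd.DataFrame({"x1": x1, "x2": x2}, index=idx)
        null = fit_null_model(y, cov, family="inverse-gaussian")
        assert null.family == "inverse-gaussian"
        for est, se, truth in [
            (null.coefficients[1], null.coef_se[1], 0.3),
            (null.coefficients[2], null.coef_se[2], -0.2),
        ]:
            assert abs(est - truth) < 3 * se

    def test_degenerate_covariate_equal_to_score(self, rng):
        n = 200
        idx = [f"s{i}" for i in range(n)]
        y = pd.Series(rng.standard_normal(n), index=idx)
        cov = pd.DataFrame({"self": y.values}, index=idx)
        null = fit_null_model(y, cov, family="gaussian")
        g = rng.binomial(2, 0.2, n).astype(float)
        _, _, p = null.score_test(g)
        assert p > 0.9  # nothing left to explain


class TestBattery:
    @pytest.fixture()
    def setup(self, rng):
        n = 1500
        idx = [f"s{i}" for i in range(n)]
        doses = rng.binomial(2, [0.05, 0.004, 0.003, 0.03], size=(n, 4)).astype(float)
        block = GenotypeBlock(
            "g", idx, doses, [_variant(pos=100 + i) for i in range(4)]
        )
        y = pd.Series(rng.standard_normal(n), index=idx)
        null = fit_null_model(y, None, family="gaussian")
        return null, block

    def test_single_variant_partition_equivalences(self, setup):
        """Burden, dispersion, and the single-variant test coincide for a
        one-variant partition."""
        null, block = setup
        g = block.dosages[:, [0]]
        w = beta_weight(block.maf[[0]])
        p_b = burden_test(null, g, w)
        p_d = dispersion_test(null, g, w)
        p_s = list(single_variant_tests(null, g).values())[0]
        assert p_b == pytest.approx(p_s, abs=1e-10)
        assert p_d == pytest.approx(p_s, rel=1e-6)

    def test_ultra_rare_aggregation_identity(self, rng):
        """Two disjoint singletons aggregate to the same carrier vector as a
        single variant carried by both subjects."""
        n = 400
        idx = [f"s{i}" for i in range(n)]
        y = pd.Series(rng.standard_normal(n), index=idx)
        null = fit_null_model(y, None, family="gaussian")
        g1 = np.zeros(n); g1[0] = 1
        g2 = np.zeros(n); g2[5] = 1
        both = (g1 + g2)[:, None]
        p_pair = ultra_rare_burden(null, np.column_stack([g1, g2]))
        p_single = ultra_rare_burden(null, both)
        assert p_pair == pytest.approx(p_single, abs=1e-12)

    def test_constant_burden_warns_p1(self, setup):
        null, block = setup
        g = np.ones((len(null.subjects), 1))
        with pytest.warns(UserWarning):
            assert burden_test(null, g, np.array([1.0])) == 1.0

    def test_gaussian_single_variant_matches_correlation_test(self, rng):
        n = 5000
        idx = [f"s{i}" for i in range(n)]
        y = pd.Series(rng.standard_normal(n), index=idx)
        g = rng.binomial(2, 0.3, n).astype(float)
        null = fit_null_model(y, None, family="gaussian")
        _, _, p_score = null.score_test(g)
        r, p_corr = stats.pearsonr(y.values, g)
        assert p_score == pytest.approx(p_corr, abs=1e-3)

    def test_dispersion_beats_burden_with_opposing_effects(self, rng):
        n = 2000
        idx = [f"s{i}" for i in range(n)]
        doses = rng.binomial(2, [0.008] * 6, size=(n, 6)).astype(float)
        signs = np.array([1, -1, 1, -1, 1, -1])
        y_vals = doses @ (0.6 * signs) + rng.standard_normal(n)
        y = pd.Series(y_vals, index=idx)
        null = fit_null_model(y, None, family="gaussian")
        block = GenotypeBlock("g", idx, doses, [_variant(pos=100 + i) for i in range(6)])
        w = beta_weight(np.maximum(block.maf, 1e-4))
        p_d = dispersion_test(null, block.dosages, w)
        p_b = burden_test(null, block.dosages, w)
        assert p_d < p_b

    def test_permuted_scores_break_association(self, rng):
        n = 1200
        idx = [f"s{i}" for i in range(n)]
        g = rng.binomial(2, 0.1, n).astype(float)
        y_vals = 0.8 * g + rng.standard_normal(n)
        y_perm = pd.Series(rng.permutation(y_vals), index=idx)
        null = fit_null_model(y_perm, None, family="gaussian")
        _, _, p = null.score_test(g)
        assert p > 0.001  # signal destroyed by permutation


class TestAcat:
    def test_identity_on_equal_ps(self):
        for p in (0.5, 0.01, 1e-6):
            assert acat_combine([p, p, p]) == pytest.approx(p, abs=1e-12)
        assert acat_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_singleton_identity(self):
        assert acat_combine([0.123]) == pytest.approx(0.123, abs=1e-12)

    def test_uniform_null_output(self, rng):
        reps = 10_000
        out = np.array([acat_combine(rng.random(5)) for _ in range(reps)])
        assert stats.kstest(out, "uniform").pvalue > 0.01

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            acat_combine([])

    def test_weighted_combination(self):
        # putting all weight on one p returns that p
        assert acat_combine([0.01, 0.9], weights=[1.0, 0.0]) == pytest.approx(0.01, abs=1e-12)


class TestGeneCombined:
    def test_rare_only_gene_has_no_common_p(self, rng):
        n = 1000
        idx = [f"s{i}" for i in range(n)]
        doses = rng.binomial(2, [0.004, 0.003], size=(n, 2)).astype(float)
        block = GenotypeBlock("g", idx, doses, [_variant(pos=100 + i) for i in range(2)])
        y = pd.Series(rng.standard_normal(n), index=idx)
        null = fit_null_model(y, None, family="gaussian")
        res = gene_combined_test(null, block)
        assert res.p_common is None
        assert res.p_rare is not None
        assert res.p_all is not None

    def test_all_p_in_unit_interval(self, genotype_blocks, rng):
        blocks, _ = genotype_blocks
        subjects = next(iter(blocks.values())).subjects
        y = pd.Series(rng.standard_normal(len(subjects)), index=subjects)
        null = fit_null_model(y, None, family="gaussian")
        for block in list(blocks.values())[:3]:
            res = gene_combined_test(null, block)
            for p in list(res.component_p.values()) + list(res.single_variant_p.values()):
                assert 0 < p <= 1

    def test_causal_gene_detected(self, rng):
        spec = CohortSpec(n_subjects=2000, seed=21, causal_effects={"GENE00": 0.6})
        blocks, inc = simulate_genotypes(spec)
        idx = inc.index
        y = pd.Series(inc.values + rng.standard_normal(len(idx)), index=idx)
        null = fit_null_model(y, None, family="gaussian")
        p_causal = gene_combined_test(null, blocks["GENE00"]).p_all
        p_null = gene_combined_test(null, blocks["GENE01"]).p_all
        assert p_causal < 1e-3
        assert p_causal < p_null

    def test_significance_threshold(self):
        assert significance_threshold() == pytest.approx(2.78e-6, rel=1e-3)
        assert significance_threshold(1.0, 1) == 1.0
        assert significance_threshold(0.025, 18000) == significance_threshold() / 2


class TestVcfRoundTrip:
    def test_write_read_preserves_dosages(self, tmp_path, small_spec):
        blocks, _ = simulate_genotypes(small_spec)
        sub = {g: blocks[g] for g in list(blocks)[:3]}
        vcf_path = tmp_path / "g.vcf"
        write_vcf(sub, vcf_path)
        bed = tmp_path / "genes.bed"
        with open(bed, "w") as fh:
            for gene, b in sub.items():
                lo = min(v.pos for v in b.variants) - 1
                hi = max(v.pos for v in b.variants)
                fh.write(f"1\t{lo}\t{hi}\t{gene}\n")
        back = read_vcf_blocks(vcf_path, gene_intervals=read_gene_intervals(bed))
        assert set(back) == set(sub)
        for gene in sub:
            orig, rb = sub[gene], back[gene]
            np.testing.assert_allclose(
                np.sort(rb.maf), np.sort(orig.maf), atol=1e-9
            )
            df_o = pd.DataFrame(orig.dosages, index=orig.subjects, columns=orig.variant_ids())
            df_b = pd.DataFrame(rb.dosages, index=rb.subjects, columns=rb.variant_ids())
            common = [c for c in df_o.columns if c in df_b.columns]
            np.testing.assert_allclose(df_b[common].values, df_o[common].values, atol=1e-9)

    def test_qc_failures_filtered_on_read(self, tmp_path):
        spec = CohortSpec(n_subjects=120, n_genes=2, variants_per_gene=20,
                          qc_fail_fraction=0.5, seed=5)
        blocks, _ = simulate_genotypes(spec)
        vcf_path = tmp_path / "g.vcf"
        write_vcf(blocks, vcf_path)
        bed = tmp_path / "genes.bed"
        with open(bed, "w") as fh:
            for gene, b in blocks.items():
                lo = min(v.pos for v in b.variants) - 1
                hi = max(v.pos for v in b.variants)
                fh.write(f"1\t{lo}\t{hi}\t{gene}\n")
        strict = read_vcf_blocks(vcf_path, gene_intervals=read_gene_intervals(bed), apply_qc=True)
        loose = read_vcf_blocks(vcf_path, gene_intervals=read_gene_intervals(bed), apply_qc=False)
        n_strict = sum(b.n_variants for b in strict.values())
        n_loose = sum(b.n_variants for b in loose.values())
        assert n_strict < n_loose

    def test_dosage_frame_shape(self, tmp_path, small_spec):
        blocks, _ = simulate_genotypes(small_spec)
        sub = {g: blocks[g] for g in list(blocks)[:2]}
        df = blocks_to_dosage_frame(sub)
        assert df.shape == (small_spec.n_subjects, sum(b.n_variants for b in sub.values()))
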