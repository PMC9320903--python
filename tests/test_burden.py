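import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioscan.burden import (
    compute_grm,
    compute_pc1,
    exclude_related,
    fit_burden_model,
    lrt_pvalue,
    run_at,
    select_at_variants,
    variant_fraction,
)
from trioscan.core import (
    ConsequenceClass,
    Thresholds,
    Trio,
    TrioCohort,
    VariantAnnotation,
)
from trioscan.panels import ExpressionTable

import pandas as pd

from conftest import make_callset, make_site


def expressed_table(genes):
    cols = ["4wpc", "5wpc", "6wpc", "7wpc", "8wpc"]
    df = pd.DataFrame(5.0, index=list(genes), columns=cols)
    df.index.name = "gene"
    return ExpressionTable(df)


class TestGrm:
    def test_duplicated_sample_offdiag_equals_diag(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(1, 500)).astype(float)
        G = np.vstack([g, g, rng.integers(0, 3, size=(1, 500))])
        K = compute_grm(G)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_independent_samples_offdiag_near_zero(self):
        rng = np.random.default_rng(1)
        n, M = 200, 3000
        p = rng.uniform(0.1, 0.9, size=M)
        G = rng.binomial(2, np.broadcast_to(p, (n, M))).astype(float)
        K = compute_grm(G)
        # entry sd ~ 1/sqrt(M); sample-frequency centering adds a -1/(n-1) bias
        tol = 3.0 / np.sqrt(M) + 1.0 / (n - 1)
        assert abs(K[0, 1]) < tol

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.3, size=(6, 200)).astype(float)
        K = compute_grm(G)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_monomorphic_skipped_all_monomorphic_errors(self):
        G = np.zeros((3, 5))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(G)

    def test_missing_mean_imputed(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.4, size=(5, 100)).astype(float)
        G[0, :10] = np.nan
        K = compute_grm(G)
        assert np.isfinite(K).all()


class TestExcludeRelated:
    def test_literal_rule(self):
        K = np.array(
            [
                [1.00, 0.99, 0.00],
                [0.99, 1.00, 0.01],
                [0.00, 0.01, 0.98],
            ]
        )
        assert exclude_related(K, ["a", "b", "c"]) == {"a", "b"}

    def test_no_exclusion_when_all_below_min_diag(self):
        K = np.array(
            [
                [1.00, 0.40, 0.00],
                [0.40, 1.00, 0.01],
                [0.00, 0.01, 0.98],
            ]
        )
        assert exclude_related(K, ["a", "b", "c"]) == set()

    def test_synthetic_related_pairs_recovered(self):
        """Exactly the 2k injected near-duplicate controls are excluded."""
        from trioscan.synthetic import SimConfig, simulate_cohort

        k = 3
        cfg = SimConfig(
            n_trios=5,
            n_controls=60,
            n_genes=5,
            n_common_variants=400,
            related_pairs=k,
            seed=17,
        )
        sim = simulate_cohort(cfg)
        controls = sorted(sim.cohort.controls)
        common = [
            rec.key for rec in sim.callset.records if rec.chrom == "22"
        ]
        G = sim.callset.genotype_matrix(keys=common, samples=controls)
        K = compute_grm(G)
        excluded = exclude_related(K, controls)
        expected = {s for pair in sim.truth.related_pairs for s in pair}
        assert len(expected) == 2 * k
        assert excluded == expected


class TestPc1:
    def two_blocks(self, n=60, m=300, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        p = np.where(labels[:, None] == 0, 0.15, 0.85)
        return rng.binomial(2, np.broadcast_to(p, (n, m))).astype(float), labels

    def test_separates_subpopulations(self):
        G, labels = self.two_blocks()
        pc1 = compute_pc1(G)
        r = np.corrcoef(pc1, labels)[0, 1]
        assert abs(r) > 0.9

    def test_permutation_equivariance(self):
        G, _ = self.two_blocks()
        pc1 = compute_pc1(G)
        perm = np.random.default_rng(1).permutation(G.shape[0])
        pc1_perm = compute_pc1(G[perm])
        np.testing.assert_allclose(pc1_perm, pc1[perm], atol=1e-8)

    def test_deterministic(self):
        G, _ = self.two_blocks()
        np.testing.assert_array_equal(compute_pc1(G), compute_pc1(G))

    def test_no_variants_errors(self):
        with pytest.raises(ValueError):
            compute_pc1(np.empty((5, 0)))


class TestVariantFraction:
    def test_het_cadd25(self):
        assert variant_fraction(np.array([[1.0]]), [25.0])[0] == pytest.approx(2.5)

    def test_hom_plus_het(self):
        vf = variant_fraction(np.array([[2.0, 1.0]]), [30.0, 10.0])
        assert vf[0] == pytest.approx(7.0)

    def test_no_variants_zero(self):
        vf = variant_fraction(np.zeros((3, 2)), [25.0, 30.0])
        np.testing.assert_array_equal(vf, np.zeros(3))

    def test_missing_cadd_weight_zero(self):
        vf = variant_fraction(np.array([[1.0, 1.0]]), [float("nan"), 20.0])
        assert vf[0] == pytest.approx(2.0)

    @given(
        st.integers(min_value=1, max_value=8),
        st.integers(min_value=2, max_value=10),
        st.integers(min_value=0, max_value=2**32 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_additivity_over_partitions(self, n_samples, n_vars, seed):
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 3, size=(n_samples, n_vars)).astype(float)
        cadds = rng.uniform(0, 40, size=n_vars)
        total = variant_fraction(G, cadds)
        split = rng.integers(1, n_vars) if n_vars > 1 else 1
        left = variant_fraction(G[:, :split], cadds[:split])
        right = variant_fraction(G[:, split:], cadds[split:])
        np.testing.assert_allclose(total, left + right, atol=1e-9)


class TestLrt:
    def test_equal_logliks(self):
        stat, p = lrt_pvalue(-10.0, -10.0)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi2_quantile_at_05(self):
        _, p = lrt_pvalue(-8.0795, -10.0)  # stat 3.841
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_stat_ten(self):
        stat, p = lrt_pvalue(-5.0, -10.0)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(0.001565, abs=1e-5)

    def test_full_below_reduced_errors(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-12.0, -10.0)


class TestFitBurdenModel:
    def simulate(self, n, beta1, seed=0):
        rng = np.random.default_rng(seed)
        vf = rng.exponential(1.0, n)
        pc1 = rng.normal(0, 1, n)
        eta = -0.5 + beta1 * vf + 0.4 * pc1
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        return y, vf, pc1

    def test_parameter_recovery(self):
        y, vf, pc1 = self.simulate(4000, beta1=0.8, seed=4)
        fit = fit_burden_model(y, vf, pc1)
        assert fit.converged and not fit.separated
        assert fit.beta1 == pytest.approx(0.8, abs=0.15)

    def test_relabel_flips_beta1_keeps_lrt(self):
        y, vf, pc1 = self.simulate(1500, beta1=0.5, seed=5)
        fit = fit_burden_model(y, vf, pc1)
        flipped = fit_burden_model(1.0 - y, vf, pc1)
        assert flipped.beta1 == pytest.approx(-fit.beta1, abs=1e-5)
        stat1, _ = lrt_pvalue(fit.loglik_full, fit.loglik_reduced)
        stat2, _ = lrt_pvalue(flipped.loglik_full, flipped.loglik_reduced)
        assert stat1 == pytest.approx(stat2, abs=1e-6)

    def test_all_one_class_raises(self):
        with pytest.raises(ValueError):
            fit_burden_model(np.ones(10), np.arange(10.0), np.zeros(10))

    def test_separated_data_flagged(self):
        vf = np.array([0.0] * 20 + [5.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        pc1 = np.random.default_rng(0).normal(0, 1, 40)
        fit = fit_burden_model(y, vf, pc1)
        assert fit.separated or not fit.converged


class TestRunAt:
    def build(self):
        trios = [Trio(f"P{i}", f"F{i}", f"M{i}") for i in range(4)]
        controls = [f"C{i}" for i in range(8)]
        cohort = TrioCohort(
            trios=trios,
            cases={t.proband for t in trios},
            controls=set(controls),
        )
        samples = []
        for t in trios:
            samples.extend((t.proband, t.father, t.mother))
        samples += controls
        return cohort, samples, controls

    def site_with(self, samples, carrier_gts):
        gts = [carrier_gts.get(s, 0) for s in samples]
        return make_site(gts=tuple(gts))

    def test_gate_below_five_untested(self):
        cohort, samples, controls = self.build()
        site = self.site_with(samples, {"P0": 1, "C0": 1, "C1": 1, "C2": 1})
        cs = make_callset(samples, [site])
        anns = {site.key: VariantAnnotation("G1", "missense_variant", "SNV", 0.0, 25.0)}
        expr = expressed_table(["G1"])
        pc1 = np.zeros(len(cohort.probands) + len(controls))
        pc1[: len(pc1) // 2] = 1.0  # non-constant covariate
        th = Thresholds(cohort_freq=1.0)
        res = run_at(cs, anns, expr, cohort, sorted(controls), pc1, thresholds=th)
        assert len(res) == 1
        assert res[0].allele_count == 4
        assert res[0].tested is False and res[0].note == "below gate"

    def test_cohort_frequency_guard(self):
        cohort, samples, controls = self.build()
        carriers = {s: 1 for s in cohort.probands + controls}
        site = self.site_with(samples, carriers)  # cohort AF = 0.5
        cs = make_callset(samples, [site])
        anns = {site.key: VariantAnnotation("G1", "missense_variant", "SNV", 0.0, 25.0)}
        expr = expressed_table(["G1"])
        sel = select_at_variants(cs, anns, expr, cohort.probands + sorted(controls))
        assert sel == []

    def test_unexpressed_gene_removed(self):
        cohort, samples, controls = self.build()
        site = self.site_with(samples, {"P0": 1})
        cs = make_callset(samples, [site])
        anns = {site.key: VariantAnnotation("G1", "missense_variant", "SNV", 0.0, 25.0)}
        expr = expressed_table(["OTHER"])
        sel = select_at_variants(cs, anns, expr, cohort.probands + sorted(controls))
        assert sel == []

    def test_constant_vf_untested(self):
        cohort, samples, controls = self.build()
        carriers = {s: 1 for s in cohort.probands + controls[:2]}
        site = self.site_with(samples, carriers)
        cs = make_callset(samples, [site])
        anns = {site.key: VariantAnnotation("G1", "missense_variant", "SNV", 0.0, 25.0)}
        expr = expressed_table(["G1"])
        n = len(cohort.probands) + len(controls)
        pc1 = np.arange(n, dtype=float)
        # all samples carry -> vf constant would need every sample het; here not
        # constant, so craft a truly constant case instead:
        carriers_all = {s: 1 for s in samples}
        site2 = self.site_with(samples, carriers_all)
        cs2 = make_callset(samples, [site2])
        th = Thresholds(cohort_freq=1.0)
        res = run_at(cs2, anns, expr, cohort, sorted(controls), pc1, thresholds=th)
        assert res[0].tested is False and res[0].note == "constant VF"
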