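"""Generator properties: Hardy-Weinberg structure, planted effects,
value-range invariants, and bit-reproducibility."""

import numpy as np
import pytest

from epiqtl.cohort import (
    BimodalEqtmParams,
    LinearEqtmParams,
    simulate_bisseq_amplicon,
    simulate_eqtm_pairs,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
)
from epiqtl.datatypes import TruthTable
from epiqtl.qtl import fit_association, genotype_qc, hwe_exact_test


class TestGenotypes:
    def test_hwe_class_frequencies_at_half_maf(self):
        g = simulate_genotypes(10_000, 20, maf_range=(0.5, 0.5), seed=1)
        freqs = g.genotype_counts().mean(axis=0) / 10_000
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_monomorphic_maf_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(100, 10, maf_range=(0.0, 0.5), seed=1)

    def test_simulated_variants_pass_hwe(self):
        """Simulated HWE genotypes should almost all survive the exact test."""
        g = simulate_genotypes(303, 500, maf_range=(0.05, 0.5), seed=7)
        pvals = np.array([hwe_exact_test(*c) for c in g.genotype_counts()])
        assert (pvals > 0.001).mean() >= 0.99

    def test_dosage_domain_and_missingness(self):
        g = simulate_genotypes(50, 40, seed=3, missing_rate=0.1)
        observed = g.dosages[~np.isnan(g.dosages)]
        assert np.isin(observed, [0, 1, 2]).all()
        assert 0.02 < np.isnan(g.dosages).mean() < 0.2

    def test_reproducible_under_seed(self):
        a = simulate_genotypes(30, 20, seed=11)
        b = simulate_genotypes(30, 20, seed=11)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.positions, b.positions)


class TestExpression:
    def test_noise_free_limit_recovers_dosage(self, small_genotypes):
        truth = TruthTable.from_records(
            [(small_genotypes.variant_ids[0], "gene0000", 1.0, "eqtl")]
        )
        expr = simulate_expression(
            small_genotypes, n_genes=5, planted_eqtls=truth,
            noise_sd=1e-9, seed=2,
        )
        dose = small_genotypes.dosages[:, 0]
        y = expr.column("gene0000")
        # subtract the gene baseline: residual pattern must equal the dosage
        centered = y - (y - 1.0 * dose).mean()
        assert np.allclose(centered, dose, atol=1e-6)

    def test_null_pairs_type_i_calibration(self):
        """With no planted effects, ~5% of pairs reach p<0.05."""
        g = simulate_genotypes(100, 100, seed=5)
        expr = simulate_expression(g, n_genes=10, planted_eqtls=None, seed=6)
        pvals = []
        for gi in range(10):
            for vi in range(100):
                fit = fit_association(expr.values[:, gi], g.dosages[:, vi])
                pvals.append(fit.p_nominal)
        frac = np.mean(np.array(pvals) < 0.05)
        assert abs(frac - 0.05) < 0.02

    def test_planted_slope_recovered(self):
        g = simulate_genotypes(100, 10, maf_range=(0.3, 0.3), seed=3)
        truth = TruthTable.from_records([(g.variant_ids[0], "gene0000", 0.5, "eqtl")])
        expr = simulate_expression(g, n_genes=3, planted_eqtls=truth,
                                   noise_sd=1.0, seed=3)
        fit = fit_association(expr.column("gene0000"), g.dosages[:, 0])
        # OLS SE ~ sigma / sqrt(n * 2*maf*(1-maf)) ~ 0.154; 0.25 covers ~1.6 SE
        assert abs(fit.slope - 0.5) < 0.25

    def test_absent_variant_rejected(self, small_genotypes):
        truth = TruthTable.from_records([("snp_missing", "gene0000", 1.0, "eqtl")])
        with pytest.raises(ValueError, match="absent variant"):
            simulate_expression(small_genotypes, 5, truth, seed=1)


class TestMethylation:
    def test_values_bounded(self, small_genotypes):
        m = simulate_methylation(small_genotypes, 100, seed=4, missing_rate=0.05)
        observed = m.values[~np.isnan(m.values)]
        assert observed.min() >= 0.0 and observed.max() <= 1.0

    def test_high_concentration_collapses_to_means(self, small_genotypes):
        truth = TruthTable.from_records(
            [(small_genotypes.variant_ids[0], "cg00000", 0.1, "mqtl")]
        )
        m = simulate_methylation(
            small_genotypes, 5, planted_mqtls=truth, concentration=1e6, seed=5
        )
        dose = small_genotypes.dosages[:, 0]
        vals = m.column("cg00000")
        for d in (0, 1, 2):
            grp = vals[dose == d]
            assert grp.std() < 0.005

    def test_planted_mqtl_slope(self, small_genotypes):
        g = simulate_genotypes(303, 10, maf_range=(0.3, 0.3), seed=11)
        truth = TruthTable.from_records([(g.variant_ids[0], "cg00000", 0.05, "mqtl")])
        m = simulate_methylation(g, 5, planted_mqtls=truth,
                                 concentration=100, seed=11)
        fit = fit_association(m.column("cg00000"), g.dosages[:, 0])
        assert abs(fit.slope - 0.05) < 0.02

    def test_out_of_range_shift_clipped_with_warning(self, small_genotypes):
        truth = TruthTable.from_records(
            [(small_genotypes.variant_ids[0], "cg00000", 0.6, "mqtl")]
        )
        with pytest.warns(UserWarning, match="clipped"):
            m = simulate_methylation(small_genotypes, 3, planted_mqtls=truth, seed=6)
        assert m.values.max() <= 1.0


class TestEqtmPairs:
    def test_linear_negative_coupling_gives_negative_correlation(self):
        pairs = simulate_eqtm_pairs(
            "linear", 100, 20, LinearEqtmParams(c1=-3.0), seed=8
        )
        for i in range(20):
            r = np.corrcoef(pairs.expression[:, i], pairs.methylation[:, i])[0, 1]
            assert r < 0

    def test_bimodal_omega_validation(self):
        with pytest.raises(ValueError, match="omega"):
            simulate_eqtm_pairs("bimodal", 50, 1, BimodalEqtmParams(omega=1.5), seed=1)

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError):
            simulate_eqtm_pairs("linear", 10, 1, seed=1)

    def test_bimodal_states_drive_methylation(self):
        p = BimodalEqtmParams(omega=0.5, m_low=0.15, m_high=0.85, concentration=50)
        pairs = simulate_eqtm_pairs("bimodal", 200, 1, p, seed=9)
        states = pairs.states[:, 0]
        m = pairs.methylation[:, 0]
        assert m[states].mean() > 0.7 and m[~states].mean() < 0.3


class TestBisseqAmplicon:
    def test_all_zero_probabilities(self):
        amp = simulate_bisseq_amplicon(4, 30, [0] * 4, [0] * 4, seed=1)
        assert amp.calls.sum() == 0

    def test_mean_methylation_near_targets(self):
        amp = simulate_bisseq_amplicon(6, 100, [0.1] * 6, [0.6] * 6, seed=5)
        assert abs(amp.read_fractions("A").mean() - 0.1) < 0.05
        assert abs(amp.read_fractions("B").mean() - 0.6) < 0.05

    def test_empty_amplicon_rejected(self):
        with pytest.raises(ValueError):
            simulate_bisseq_amplicon(0, 10, [], [], seed=1)

    def test_mismatched_probability_vectors(self):
        with pytest.raises(ValueError, match="equal length"):
            simulate_bisseq_amplicon(3, 10, [0.5] * 3, [0.5] * 2, seed=1)

    def test_read_counts_exact(self):
        amp = simulate_bisseq_amplicon(3, 25, [0.5] * 3, [0.5] * 3, seed=2)
        assert (amp.alleles == "A").sum() == 25
        assert (amp.alleles == "B").sum() == 25


def test_planted_eqtm_pairs_are_cis_and_coupled():
    from epiqtl.cohort import simulate_cohort

    co = simulate_cohort(
        n_samples=120, n_expression_samples=80, n_eqtm_overlap=74,
        n_variants=100, n_genes=30, n_cpgs=60,
        n_planted_eqtl=5, n_planted_mqtl=5, n_planted_eqtm=5, seed=17,
    )
    eqtm = co.truth.for_mechanism("eqtm_linear")
    assert len(eqtm) == 5
    gene_pos = dict(zip(co.expression.feature_ids, co.expression.feature_pos))
    cpg_pos = dict(zip(co.methylation.feature_ids, co.methylation.feature_pos))
    for rec in eqtm.itertuples(index=False):
        assert abs(cpg_pos[rec.source_id] - gene_pos[rec.target_id]) <= 100_000
        y = co.expression.column(rec.target_id)
        rows = [co.methylation.sample_ids.index(s) for s in co.expression.sample_ids]
        x = co.methylation.values[rows, co.methylation.feature_ids.index(rec.source_id)]
        r = np.corrcoef(y, x)[0, 1]
        assert np.sign(r) == np.sign(rec.effect_size)
        assert abs(r) > 0.3


def test_qc_survival_of_simulated_cohort():
    """Generated variants at MAF >= 5% should essentially all pass QC."""
    g = simulate_genotypes(303, 300, maf_range=(0.06, 0.5), seed=13)
    kept = genotype_qc(g)
    assert kept.n_variants >= 0.95 * g.n_variants
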