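"""QTL mapping: OLS against a first-principles oracle, exact HWE test,
cis-window boundaries, permutation FDR calibration, filters, and score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiqtl.cohort import simulate_expression, simulate_genotypes
from epiqtl.datatypes import TruthTable
from epiqtl.qtl import (
    apply_retention_filters,
    build_cis_pairs,
    fit_association,
    genotype_qc,
    genotype_shares,
    hwe_exact_test,
    map_cis_qtl,
    map_eqtm,
    permutation_fdr,
    prioritization_score,
)


def ols_oracle(y, g, covariates=None):
    """Independent normal-equations + t-CDF oracle for the predictor slope."""
    n = y.size
    cols = [np.ones(n)]
    if covariates is not None:
        cols.append(covariates)
    cols.append(g)
    x = np.column_stack(cols)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = beta[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta[-1], p


class TestHweExact:
    def test_perfect_proportions(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygote_extreme(self):
        assert hwe_exact_test(0, 100, 0) < 0.001

    def test_symmetry_in_homozygote_labels(self):
        assert hwe_exact_test(10, 40, 50) == pytest.approx(hwe_exact_test(50, 40, 10))


class TestGenotypeQc:
    def test_monomorphic_removed(self):
        g = simulate_genotypes(100, 5, seed=1)
        g.dosages[:, 0] = 0.0
        kept = genotype_qc(g)
        assert g.variant_ids[0] not in kept.variant_ids

    def test_low_call_rate_removed(self):
        g = simulate_genotypes(100, 5, seed=2)
        g.dosages[:10, 1] = np.nan
        kept = genotype_qc(g, call_rate_min=0.95)
        assert g.variant_ids[1] not in kept.variant_ids

    def test_hwe_failure_removed(self):
        g = simulate_genotypes(100, 5, seed=3)
        g.dosages[:, 2] = 1.0  # every sample heterozygous
        kept = genotype_qc(g)
        assert g.variant_ids[2] not in kept.variant_ids


class TestCisPairs:
    @pytest.mark.parametrize(
        "anchor,snp,window,included,distance",
        [
            (1_000_000, 2_000_000, 1_000_000, True, 1_000_000),   # closed boundary
            (1_000_000, 2_000_001, 1_000_000, False, None),       # boundary + 1
            (100_000, 25_000, 75_000, True, -75_000),             # upstream edge
        ],
    )
    def test_window_boundaries(self, anchor, snp, window, included, distance):
        anchors = pd.DataFrame(
            {"feature_id": ["f"], "chrom": ["chrS"], "pos": [anchor]}
        )
        variants = pd.DataFrame(
            {"variant_id": ["v"], "chrom": ["chrS"], "pos": [snp]}
        )
        pairs = build_cis_pairs(anchors, variants, window)
        if included:
            assert len(pairs) == 1
            assert pairs["distance"].iloc[0] == distance
        else:
            assert pairs.empty

    def test_cross_chromosome_never_paired(self):
        anchors = pd.DataFrame({"feature_id": ["f"], "chrom": ["chr1"], "pos": [100]})
        variants = pd.DataFrame({"variant_id": ["v"], "chrom": ["chr2"], "pos": [100]})
        assert build_cis_pairs(anchors, variants, 10**9).empty


class TestFitAssociation:
    def test_perfect_fit(self):
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        fit = fit_association(g.astype(float), g.astype(float))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_predictor(self, rng):
        g = rng.normal(size=60)
        y = rng.normal(size=60)
        x = np.column_stack([np.ones(60), g])
        y = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        fit = fit_association(y, g)
        assert abs(fit.slope) < 1e-10

    def test_matches_first_principles_oracle(self, rng):
        """1000 random instances at n=50: slope and p to 1e-8."""
        for _ in range(1000):
            n = 50
            g = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(g) == 0:
                continue
            cov = rng.normal(size=(n, 2))
            y = rng.normal(size=n) + 0.3 * g + cov @ rng.normal(size=2)
            fit = fit_association(y, g, cov)
            slope_o, p_o = ols_oracle(y, g, cov)
            assert fit.slope == pytest.approx(slope_o, abs=1e-8)
            assert fit.p_nominal == pytest.approx(p_o, abs=1e-8)

    def test_constant_predictor_flagged_untestable(self):
        fit = fit_association(np.arange(30.0), np.ones(30))
        assert fit.untestable

    def test_complete_case_handling(self, rng):
        g = rng.integers(0, 3, 80).astype(float)
        y = rng.normal(size=80) + 0.5 * g
        y_miss = y.copy()
        y_miss[:5] = np.nan
        fit_full = fit_association(y[5:], g[5:])
        fit_miss = fit_association(y_miss, g)
        assert fit_miss.slope == pytest.approx(fit_full.slope, abs=1e-12)
        assert fit_miss.n == 75


class TestPermutationFdr:
    @staticmethod
    def _single_pair_setup(n=60, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(n, 1)).astype(float)
        y = (g * 2.0 + rng.normal(0, 0.01, size=(n, 1)))
        pairs = pd.DataFrame(
            {"target_id": ["t0"], "variant_id": ["v0"], "distance": [0]}
        )
        return y, g, pairs

    def test_empirical_floor_with_overwhelming_signal(self):
        y, g, pairs = self._single_pair_setup()
        per_target, _ = permutation_fdr(
            y, g, pairs, ["t0"], ["v0"], n_perm=100, seed=1
        )
        assert per_target["p_empirical"].iloc[0] == pytest.approx(1 / 101)

    def test_null_empirical_p_uniform(self):
        """200 null targets: empirical p follows the discrete uniform."""
        rng = np.random.default_rng(4)
        n, t = 50, 200
        y = rng.normal(size=(n, t))
        g = rng.integers(0, 3, size=(n, 5)).astype(float)
        tids = [f"t{i}" for i in range(t)]
        vids = [f"v{i}" for i in range(5)]
        pairs = pd.DataFrame(
            [(ti, vi, 0) for ti in tids for vi in vids],
            columns=["target_id", "variant_id", "distance"],
        )
        per_target, _ = permutation_fdr(y, g, pairs, tids, vids,
                                        n_perm=200, seed=5)
        ks = stats.kstest(per_target["p_empirical"], "uniform")
        assert ks.pvalue > 0.01

    def test_bh_step_up_against_hand_computation(self):
        # hand-computed BH: p*(m/rank) with step-up monotonicity
        from statsmodels.stats.multitest import multipletests
        q = multipletests(np.array([0.001, 0.01, 0.02, 0.8]), method="fdr_bh")[1]
        assert np.allclose(q, [0.004, 0.02, 0.0266666667, 0.8])

    def test_nominal_matches_fit_association(self):
        rng = np.random.default_rng(6)
        n = 70
        y = rng.normal(size=(n, 1))
        g = rng.integers(0, 3, size=(n, 3)).astype(float)
        cov = rng.normal(size=(n, 2))
        pairs = pd.DataFrame(
            {"target_id": ["t0"] * 3, "variant_id": ["v0", "v1", "v2"],
             "distance": [0, 0, 0]}
        )
        _, nominal = permutation_fdr(y, g, pairs, ["t0"], ["v0", "v1", "v2"],
                                     covariates=cov, n_perm=100, seed=7)
        for j in range(3):
            ref = fit_association(y[:, 0], g[:, j], cov)
            row = nominal[nominal["variant_id"] == f"v{j}"].iloc[0]
            assert row["slope"] == pytest.approx(ref.slope, abs=1e-8)
            assert row["p_nominal"] == pytest.approx(ref.p_nominal, abs=1e-8)

    def test_reproducible_under_seed(self):
        y, g, pairs = self._single_pair_setup(seed=3)
        a, _ = permutation_fdr(y, g, pairs, ["t0"], ["v0"], n_perm=150, seed=9)
        b, _ = permutation_fdr(y, g, pairs, ["t0"], ["v0"], n_perm=150, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestFiltersAndScore:
    def test_retention_examples(self):
        table = pd.DataFrame(
            {
                "slope": [0.06, 0.06, 0.05],
                "share_AA": [0.50, 0.96, 0.4],
                "share_AB": [0.30, 0.03, 0.4],
                "share_BB": [0.20, 0.01, 0.2],
            }
        )
        out = apply_retention_filters(table)
        assert out["flags"].iloc[0] == ""
        assert "share_fail" in out["flags"].iloc[1]
        assert "slope_fail" in out["flags"].iloc[2]  # strict > at 0.05

    def test_share_rule_lenient(self):
        table = pd.DataFrame(
            {"slope": [0.1], "share_AA": [0.94], "share_AB": [0.05],
             "share_BB": [0.01]}
        )
        strict = apply_retention_filters(table)
        lenient = apply_retention_filters(table, share_rule="any_nonref")
        assert "share_fail" in strict["flags"].iloc[0]
        assert lenient["flags"].iloc[0] == ""

    def test_genotype_shares_complete_case(self):
        d = np.array([0, 0, 1, 2, np.nan])
        assert genotype_shares(d) == pytest.approx((0.5, 0.25, 0.25))

    def test_score_zero_cases(self):
        assert prioritization_score(1.0, 0.8, 100) == 0.0
        assert prioritization_score(0.2, 0.0, 100) == 0.0

    def test_score_distance_zero(self):
        assert prioritization_score(0.0, 0.5, 0) == pytest.approx(
            0.5 / np.log(2), rel=1e-12
        )

    def test_score_monotonicity(self, rng):
        p = rng.random(50)
        slope = rng.normal(size=50)
        dist = rng.integers(0, 10**6, 50)
        base = prioritization_score(p, slope, dist)
        assert (prioritization_score(np.minimum(p + 0.1, 1), slope, dist) <= base + 1e-15).all()
        assert (prioritization_score(p, slope * 1.5, dist) >= base - 1e-15).all()
        assert (prioritization_score(p, slope, dist + 1000) <= base + 1e-15).all()


class TestHighLevelMapping:
    def test_sample_reordering_invariance(self):
        g = simulate_genotypes(60, 40, seed=21)
        truth = TruthTable.from_records([(g.variant_ids[0], "gene0000", 2.0, "eqtl")])
        expr = simulate_expression(g, 10, truth, noise_sd=0.5, seed=22)
        res1 = map_cis_qtl(expr, g, window_bp=10**7, n_perm=100, n_pcs=2, seed=3)
        # shuffle sample order in both matrices
        perm = np.random.default_rng(0).permutation(60)
        expr2 = expr.subset_samples([expr.sample_ids[i] for i in perm])
        g2 = g.subset_samples([g.sample_ids[i] for i in perm])
        res2 = map_cis_qtl(expr2, g2, window_bp=10**7, n_perm=100, n_pcs=2, seed=3)
        pd.testing.assert_frame_equal(res1.associations, res2.associations)

    def test_planted_eqtl_found_and_scored(self):
        g = simulate_genotypes(100, 50, seed=31)
        truth = TruthTable.from_records([(g.variant_ids[5], "gene0000", 2.0, "eqtl")])
        expr = simulate_expression(g, 10, truth, noise_sd=0.5, seed=32)
        res = map_cis_qtl(expr, g, window_bp=10**7, n_perm=200, n_pcs=0, seed=33)
        row = res.associations.set_index("target_id").loc["gene0000"]
        assert row["variant_id"] == g.variant_ids[5]
        assert row["q_value"] < 0.05
        assert row["score"] > 0

    def test_eqtm_mapping_runs_and_flags_slope(self):
        rng = np.random.default_rng(44)
        from epiqtl.datatypes import PhenotypeMatrix
        n = 74
        meth_vals = rng.beta(2, 2, size=(n, 3))
        expr_vals = np.column_stack(
            [5 + 4 * meth_vals[:, 0] + rng.normal(0, 0.5, n),
             rng.normal(5, 1, n)]
        )
        samples = [f"S{i}" for i in range(n)]
        expr = PhenotypeMatrix(samples, ["g0", "g1"], expr_vals,
                               np.array(["chrS", "chrS"], dtype=object),
                               np.array([50_000, 500_000]), kind="expression")
        meth = PhenotypeMatrix(samples, ["c0", "c1", "c2"], meth_vals,
                               np.array(["chrS"] * 3, dtype=object),
                               np.array([60_000, 90_000, 505_000]),
                               kind="methylation")
        res = map_eqtm(expr, meth, window_bp=100_000, n_perm=100, n_pcs=0, seed=9)
        row = res.associations.set_index("target_id").loc["g0"]
        assert row["cpg_id"] == "c0"
        assert row["q_value"] < 0.05
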