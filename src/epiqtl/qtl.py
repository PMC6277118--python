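"""Cis-QTL and eQTM mapping.

Per-pair ordinary least squares with covariates, a per-target permutation
pass (null statistic = best nominal p over the target's cis pairs),
Benjamini-Hochberg correction of the empirical p-values across targets,
genotype-share and slope retention filters, and the association
prioritization score

    score = (1 - p) * |slope| / ln(|distance| + 2).

The permutation pass uses the Frisch-Waugh identity: phenotype and
predictors are residualized against the covariates once, after which the
partial correlation yields the same t statistic as the full model
(df = n - n_covariates - 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, PhenotypeMatrix

__all__ = [
    "hwe_exact_test",
    "genotype_qc",
    "build_cis_pairs",
    "AssocFit",
    "fit_association",
    "phenotype_pcs",
    "permutation_fdr",
    "apply_retention_filters",
    "prioritization_score",
    "genotype_shares",
    "map_cis_qtl",
    "map_eqtm",
    "QtlResult",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test on heterozygote counts.

    Enumerates all heterozygote counts compatible with the observed allele
    pool and sums the probabilities of configurations no more likely than
    the observed one (two-sided exact test).
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_aa, n_bb) + n_ab  # minor allele count
    # heterozygote count must share parity with the minor-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    n_common = 2 * n - n_rare
    # log P(n_het | allele counts) under HWE, up to a shared constant
    n_rare_hom = (n_rare - het_values) // 2
    n_common_hom = (n_common - het_values) // 2
    logp = (
        het_values * np.log(2.0)
        - special.gammaln(het_values + 1)
        - special.gammaln(n_rare_hom + 1)
        - special.gammaln(n_common_hom + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_ab][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.001,
    maf_min: float = 0.05,
) -> GenotypeMatrix:
    """Drop variants failing call-rate, HWE exact-test, or MAF thresholds."""
    for name, thr in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                      ("hwe_p_min", hwe_p_min)):
        if not 0.0 < thr < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    counts = genotypes.genotype_counts()
    hwe_p = np.array([hwe_exact_test(*c) for c in counts])
    keep = (
        (genotypes.call_rate() >= call_rate_min)
        & (hwe_p >= hwe_p_min)
        & (genotypes.maf() >= maf_min)
    )
    if not keep.any():
        logger.warning("genotype_qc removed every variant")
    return genotypes.subset_variants(keep)


# ---------------------------------------------------------------------------
# Cis pairing
# ---------------------------------------------------------------------------

def build_cis_pairs(
    anchors: pd.DataFrame,
    variants: pd.DataFrame,
    window_bp: int,
) -> pd.DataFrame:
    """All (target, variant) pairs with |variant_pos - anchor_pos| <= window_bp.

    ``anchors`` needs columns (feature_id, chrom, pos); ``variants`` needs
    (variant_id, chrom, pos). Distance is signed: variant_pos - anchor_pos.
    The window is a closed interval.
    """
    out = []
    for chrom, vgrp in variants.groupby("chrom", sort=False):
        agrp = anchors[anchors["chrom"] == chrom]
        if agrp.empty:
            continue
        vpos = vgrp["pos"].to_numpy()
        order = np.argsort(vpos, kind="stable")
        vpos_sorted = vpos[order]
        vids = vgrp["variant_id"].to_numpy()[order]
        for fid, apos in zip(agrp["feature_id"], agrp["pos"]):
            lo = np.searchsorted(vpos_sorted, apos - window_bp, side="left")
            hi = np.searchsorted(vpos_sorted, apos + window_bp, side="right")
            for k in range(lo, hi):
                out.append((fid, vids[k], int(vpos_sorted[k] - apos)))
    return pd.DataFrame(out, columns=["target_id", "variant_id", "distance"])


# ---------------------------------------------------------------------------
# Single-pair OLS
# ---------------------------------------------------------------------------

@dataclass
class AssocFit:
    slope: float
    p_nominal: float
    n: int
    df_resid: int
    untestable: bool = False


def fit_association(
    phenotype: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AssocFit:
    """OLS of phenotype on [intercept, covariates, predictor], complete-case.

    Returns the predictor slope and its two-sided t-test p-value. Constant
    predictor or phenotype is flagged untestable (distinct from p = 1).
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(predictor, dtype=float)
    c = None if covariates is None else np.asarray(covariates, dtype=float)
    if c is not None and c.ndim == 1:
        c = c[:, None]
    mask = ~(np.isnan(y) | np.isnan(g))
    if c is not None:
        mask &= ~np.isnan(c).any(axis=1)
    y, g = y[mask], g[mask]
    c = None if c is None else c[mask]
    k = 0 if c is None else c.shape[1]
    if y.size < k + 3:
        raise ValueError(f"need at least {k + 3} complete observations, got {y.size}")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        return AssocFit(np.nan, np.nan, y.size, y.size - k - 2, untestable=True)
    design = np.column_stack([np.ones(y.size)] + ([c] if c is not None else []) + [g])
    fit = sm.OLS(y, design).fit()
    return AssocFit(
        slope=float(fit.params[-1]),
        p_nominal=float(fit.pvalues[-1]),
        n=int(y.size),
        df_resid=int(fit.df_resid),
    )


def phenotype_pcs(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading principal components of a samples x features matrix
    (hidden-factor covariates). Missing entries are mean-imputed per feature
    for the decomposition only."""
    x = np.asarray(values, dtype=float).copy()
    col_mean = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(x))
    x[nan_rows, nan_cols] = col_mean[nan_cols]
    x -= x.mean(axis=0)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs <= 0:
        return np.empty((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


# ---------------------------------------------------------------------------
# Vectorized nominal statistics + permutation FDR
# ---------------------------------------------------------------------------

def _residualize(x: np.ndarray, q: np.ndarray | None) -> np.ndarray:
    """Remove intercept + covariate projection. ``q`` is an orthonormal basis."""
    x = x - x.mean(axis=0, keepdims=True)
    if q is not None:
        x = x - q @ (q.T @ x)
    return x


def _covariate_basis(covariates: np.ndarray | None) -> np.ndarray | None:
    if covariates is None or covariates.shape[1] == 0:
        return None
    c = covariates - covariates.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(c)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _corr_to_p(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def permutation_fdr(
    phenotypes: np.ndarray,
    predictors: np.ndarray,
    pairs: pd.DataFrame,
    target_ids: list[str],
    predictor_ids: list[str],
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target permutation FDR over grouped cis pairs.

    For each target, phenotype values are permuted across samples ``n_perm``
    times; the null statistic is the minimum nominal p over the target's cis
    pairs per permutation, and

        p_empirical = (1 + #{null min-p <= observed min-p}) / (n_perm + 1).

    Benjamini-Hochberg is applied across targets. Returns
    (per_target, nominal_all). Missing predictor entries are mean-imputed for
    this vectorized pass; per-target missing phenotypes are dropped
    (complete-case per target).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y_all = np.asarray(phenotypes, dtype=float)
    x_all = np.asarray(predictors, dtype=float)
    if np.isnan(x_all).any():
        col_mean = np.nanmean(x_all, axis=0)
        idx = np.nonzero(np.isnan(x_all))
        x_all = x_all.copy()
        x_all[idx] = col_mean[idx[1]]
        logger.warning("missing predictor entries mean-imputed for the permutation pass")
    t_lookup = {t: i for i, t in enumerate(target_ids)}
    p_lookup = {p: i for i, p in enumerate(predictor_ids)}
    rng = np.random.default_rng(seed)
    n = y_all.shape[0]

    nominal_rows = []
    target_rows = []
    grouped = pairs.groupby("target_id", sort=True)
    for tid in sorted(t_lookup, key=lambda t: t_lookup[t]):
        if tid not in grouped.groups:
            logger.info("target %s has no cis pairs; skipped", tid)
            continue
        grp = grouped.get_group(tid)
        y = y_all[:, t_lookup[tid]]
        mask = ~np.isnan(y)
        cols = np.array([p_lookup[v] for v in grp["variant_id"]])
        yc = y[mask]
        gc = x_all[np.ix_(mask, cols)]
        cov = None if covariates is None else covariates[mask]
        q = _covariate_basis(cov)
        k = 0 if q is None else q.shape[1]
        df = yc.size - k - 2
        if df < 1:
            logger.info("target %s has insufficient complete samples; skipped", tid)
            continue
        ry = _residualize(yc[:, None], q)[:, 0]
        rg = _residualize(gc, q)
        g_norm = np.linalg.norm(rg, axis=0)
        testable = g_norm > 1e-12
        y_norm = np.linalg.norm(ry)
        if y_norm <= 1e-12 or not testable.any():
            logger.info("target %s is constant after residualization; skipped", tid)
            continue
        rg_unit = np.where(testable, 1.0, np.nan) * rg / np.where(testable, g_norm, 1.0)
        r_obs = (ry / y_norm) @ np.nan_to_num(rg_unit)
        r_obs[~testable] = 0.0
        p_obs = _corr_to_p(r_obs, df)
        p_obs[~testable] = np.nan
        # slopes on the original scale
        with np.errstate(invalid="ignore"):
            slopes = r_obs * y_norm / np.where(testable, g_norm, np.nan)
        for j, rec in enumerate(grp.itertuples(index=False)):
            nominal_rows.append(
                (tid, rec.variant_id, rec.distance, slopes[j], p_obs[j])
            )
        # permutation null on |r|: min-p == max |r| at shared df
        best = int(np.nanargmin(np.where(testable, p_obs, np.inf)))
        obs_max_r = abs(r_obs[best])
        perm_idx = np.argsort(rng.random((n_perm, yc.size)), axis=1)
        ry_perm = (ry / y_norm)[perm_idx]                       # (n_perm, n)
        null_r = np.abs(ry_perm @ np.nan_to_num(rg_unit)).max(axis=1)
        p_emp = (1.0 + np.sum(null_r >= obs_max_r - 1e-15)) / (n_perm + 1.0)
        target_rows.append(
            (
                tid,
                grp["variant_id"].iloc[best],
                int(grp["distance"].iloc[best]),
                float(slopes[best]),
                float(p_obs[best]),
                float(p_emp),
            )
        )

    nominal = pd.DataFrame(
        nominal_rows,
        columns=["target_id", "variant_id", "distance", "slope", "p_nominal"],
    )
    per_target = pd.DataFrame(
        target_rows,
        columns=["target_id", "variant_id", "distance", "slope", "p_nominal", "p_empirical"],
    )
    if len(per_target):
        per_target["q_value"] = multipletests(
            per_target["p_empirical"].to_numpy(), method="fdr_bh"
        )[1]
    else:
        per_target["q_value"] = pd.Series(dtype=float)
    return per_target, nominal


# ---------------------------------------------------------------------------
# Filters and score
# ---------------------------------------------------------------------------

def genotype_shares(dosages: np.ndarray) -> tuple[float, float, float]:
    """Proportions of genotype classes 0/1/2 among complete cases."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return (np.nan, np.nan, np.nan)
    return tuple(float(np.mean(d == g)) for g in (0, 1, 2))


def apply_retention_filters(
    table: pd.DataFrame,
    min_share: float = 0.05,
    min_slope: float = 0.05,
    share_rule: str = "all_observed",
) -> pd.DataFrame:
    """Add share_fail / slope_fail flags.

    ``share_rule='all_observed'`` (default): every *observed* genotype class
    must have share >= min_share. ``share_rule='any_nonref'``: at least one
    non-reference class must reach min_share (the lenient reading).
    Slope passes only if |slope| > min_slope (strict).
    """
    if share_rule not in ("all_observed", "any_nonref"):
        raise ValueError("share_rule must be 'all_observed' or 'any_nonref'")
    out = table.copy()
    share_cols = ["share_AA", "share_AB", "share_BB"]
    has_shares = all(c in out.columns for c in share_cols)
    flags = []
    for rec in out.itertuples(index=False):
        f = set()
        if has_shares:
            shares = [getattr(rec, c) for c in share_cols]
            if not any(np.isnan(s) for s in shares):
                observed = [s for s in shares if s > 0]
                if share_rule == "all_observed":
                    ok = all(s >= min_share for s in observed)
                else:
                    ok = any(s >= min_share for s in shares[1:])
                if not ok:
                    f.add("share_fail")
        if not (abs(rec.slope) > min_slope):
            f.add("slope_fail")
        flags.append(";".join(sorted(f)))
    out["flags"] = flags
    return out


def prioritization_score(p_nominal, slope, distance):
    """score = (1 - p) * |slope| / ln(|distance| + 2); finite and >= 0."""
    p = np.asarray(p_nominal, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    s = np.abs(np.asarray(slope, dtype=float))
    d = np.abs(np.asarray(distance, dtype=float))
    out = (1.0 - p) * s / np.log(d + 2.0)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# High-level mapping
# ---------------------------------------------------------------------------

@dataclass
class QtlResult:
    """Mapping output: per-target best associations plus the full nominal table."""

    associations: pd.DataFrame   # one row per target (best cis pair)
    nominal: pd.DataFrame        # all tested pairs
    mode: str

    def significant(self, q_threshold: float = 0.05, apply_filters: bool = True) -> pd.DataFrame:
        sig = self.associations[self.associations["q_value"] < q_threshold]
        if apply_filters and "flags" in sig.columns:
            sig = sig[~sig["flags"].str.contains("fail", na=False)]
        return sig


def _canonical_order(sample_ids: list[str]) -> np.ndarray:
    return np.argsort(np.asarray(sample_ids, dtype=object))


def map_cis_qtl(
    phenotype: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    window_bp: int,
    n_perm: int = 1000,
    n_pcs: int = 10,
    seed: int = 0,
    min_share: float = 0.05,
    min_slope: float = 0.05,
    mode: str = "eqtl",
) -> QtlResult:
    """Full cis-QTL scan: pairing, covariate PCs, permutation FDR, filters, score.

    Samples are intersected between the two matrices and processed in
    canonical (sorted-id) order so results do not depend on input ordering.
    """
    shared = sorted(set(phenotype.sample_ids) & set(genotypes.sample_ids))
    if not shared:
        raise ValueError("no shared samples between phenotype and genotype matrices")
    ph = phenotype.subset_samples(shared)
    gt = genotypes.subset_samples(shared)
    pairs = build_cis_pairs(
        ph.feature_frame().rename(columns={"pos": "pos"}),
        gt.variant_frame()[["variant_id", "chrom", "pos"]],
        window_bp,
    )
    covariates = phenotype_pcs(ph.values, n_pcs)
    per_target, nominal = permutation_fdr(
        ph.values,
        gt.dosages,
        pairs,
        target_ids=list(ph.feature_ids),
        predictor_ids=list(gt.variant_ids),
        covariates=covariates,
        n_perm=n_perm,
        seed=seed,
    )
    vidx = {v: i for i, v in enumerate(gt.variant_ids)}
    shares = np.array(
        [genotype_shares(gt.dosages[:, vidx[v]]) for v in per_target["variant_id"]]
    ) if len(per_target) else np.empty((0, 3))
    per_target[["share_AA", "share_AB", "share_BB"]] = shares
    per_target = apply_retention_filters(per_target, min_share, min_slope)
    per_target["score"] = prioritization_score(
        per_target["p_nominal"].to_numpy(),
        per_target["slope"].to_numpy(),
        per_target["distance"].to_numpy(),
    ) if len(per_target) else np.array([])
    return QtlResult(associations=per_target, nominal=nominal, mode=mode)


def map_eqtm(
    expression: PhenotypeMatrix,
    methylation: PhenotypeMatrix,
    window_bp: int = 100_000,
    n_perm: int = 1000,
    n_pcs: int = 10,
    seed: int = 0,
    min_slope: float = 0.05,
) -> QtlResult:
    """Expression ~ methylation cis associations (gene TSS vs CpG, +/- window).

    The predictor is the CpG beta value; genotype-share filters do not apply.
    """
    shared = sorted(set(expression.sample_ids) & set(methylation.sample_ids))
    if not shared:
        raise ValueError("no shared samples between expression and methylation")
    ex = expression.subset_samples(shared)
    me = methylation.subset_samples(shared)
    pairs = build_cis_pairs(
        ex.feature_frame(),
        me.feature_frame().rename(columns={"feature_id": "variant_id"}),
        window_bp,
    )
    covariates = phenotype_pcs(ex.values, n_pcs)
    per_target, nominal = permutation_fdr(
        ex.values,
        me.values,
        pairs,
        target_ids=list(ex.feature_ids),
        predictor_ids=list(me.feature_ids),
        covariates=covariates,
        n_perm=n_perm,
        seed=seed,
    )
    per_target = apply_retention_filters(per_target, min_slope=min_slope)
    per_target["score"] = prioritization_score(
        per_target["p_nominal"].to_numpy(),
        per_target["slope"].to_numpy(),
        per_target["distance"].to_numpy(),
    ) if len(per_target) else np.array([])
    per_target.rename(columns={"variant_id": "cpg_id"}, inplace=True)
    return QtlResult(associations=per_target, nominal=nominal.rename(
        columns={"variant_id": "cpg_id"}), mode="eqtm")
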