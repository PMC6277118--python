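"""Permutation enrichment, the pi1 sharing statistic, and MAD variability classes.

Enrichment of a candidate locus set against a genomic feature is assessed
against a null built by repeatedly drawing |candidates| loci without
replacement from the assayed universe; the empirical p-value is
#{Y_k > X}/k (with an optional +1-corrected variant used for reporting).
pi1 = 1 - pi0 estimates the fraction of non-null tests from a p-value
distribution (Storey-style lambda extrapolation). Feature variability is
summarized by median absolute deviation and split into quartile classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PhenotypeMatrix

__all__ = [
    "EnrichmentResult",
    "permutation_enrichment",
    "Pi1Result",
    "estimate_pi1",
    "mad_variability_classes",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    observed_overlap: int
    candidate_size: int
    universe_size: int
    null_overlaps: np.ndarray
    k: int
    empirical_p: float            # #{Y_k > X} / k
    empirical_p_corrected: float  # (1 + #{Y_k >= X}) / (k + 1)
    obs_exp_ratio: float
    degenerate: bool = False


def _interval_membership(
    loci: pd.DataFrame, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean per locus: does it fall inside any interval?

    BED semantics (0-based half-open): a locus at 1-based position p
    overlaps [start, end) iff start <= p - 1 < end.
    """
    member = np.zeros(len(loci), dtype=bool)
    for chrom, igrp in intervals.groupby("chrom", sort=False):
        sel = loci["chrom"] == chrom
        if not sel.any():
            continue
        starts = igrp["start"].to_numpy()
        ends = igrp["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # merge overlapping intervals so one searchsorted suffices
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        pos0 = loci.loc[sel, "pos"].to_numpy() - 1  # to 0-based
        idx = np.searchsorted(ms, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < me[np.clip(idx, 0, len(me) - 1)])
        member[np.flatnonzero(sel.to_numpy())] = ok
    return member


def permutation_enrichment(
    candidates: list[str],
    universe: pd.DataFrame,
    feature,
    k: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation enrichment of ``candidates`` within ``universe``.

    ``universe`` is a DataFrame with a locus_id column and, when ``feature``
    is an interval table, chrom/pos columns. ``feature`` is either a set of
    locus ids (label set) or a DataFrame of BED intervals
    (chrom, start, end; 0-based half-open).
    """
    if k < 100:
        raise ValueError("k must be >= 100")
    cand = list(candidates)
    if not cand:
        raise ValueError("candidate set is empty")
    uni_ids = universe["locus_id"].to_numpy()
    if not set(cand) <= set(uni_ids):
        raise ValueError("candidates must be a subset of the universe")
    if isinstance(feature, pd.DataFrame):
        member = _interval_membership(universe, feature)
    else:
        fset = set(feature)
        member = np.fromiter((lid in fset for lid in uni_ids), dtype=bool,
                             count=len(uni_ids))
    lookup = {lid: i for i, lid in enumerate(uni_ids)}
    cand_idx = np.array([lookup[c] for c in cand])
    x = int(member[cand_idx].sum())
    degenerate = bool(member.all())
    if degenerate:
        logger.warning("feature covers the entire universe; enrichment undefined")
    rng = np.random.default_rng(seed)
    n = len(cand)
    member_float = member.astype(float)
    null = np.empty(k, dtype=int)
    for j in range(k):
        draw = rng.choice(len(uni_ids), size=n, replace=False)
        null[j] = int(member_float[draw].sum())
    emp = float(np.sum(null > x) / k)
    emp_corr = float((1 + np.sum(null >= x)) / (k + 1))
    mean_null = float(null.mean())
    ratio = float(x / mean_null) if mean_null > 0 else np.inf
    return EnrichmentResult(
        observed_overlap=x,
        candidate_size=n,
        universe_size=len(uni_ids),
        null_overlaps=null,
        k=k,
        empirical_p=emp,
        empirical_p_corrected=emp_corr,
        obs_exp_ratio=ratio,
        degenerate=degenerate,
    )


@dataclass
class Pi1Result:
    pvalues: np.ndarray
    lambda_grid: np.ndarray
    pi0_curve: np.ndarray
    pi0_estimate: float
    pi1: float


def estimate_pi1(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> Pi1Result:
    """Storey-style pi1 = 1 - pi0 from a p-value distribution.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) over the lambda grid;
    the final pi0 is a cubic least-squares smooth of the curve evaluated at
    the largest lambda, clipped to [0, 1]. The fit is weighted by
    sqrt(1 - lambda): Var[pi0(lambda)] grows like 1/(1 - lambda), so these
    are inverse-standard-deviation weights. Falls back to pi0(0.5) when the
    smooth is degenerate.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    grid = (np.arange(0.05, 0.951, 0.05) if lambda_grid is None
            else np.asarray(lambda_grid, dtype=float))
    if ((grid <= 0) | (grid >= 1)).any():
        raise ValueError("lambda grid must lie in (0, 1)")
    m = p.size
    pi0_curve = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if grid.size >= 4 and np.ptp(pi0_curve) > 0:
        coeffs = np.polyfit(grid, pi0_curve, 3, w=np.sqrt(1.0 - grid))
        pi0 = float(np.polyval(coeffs, grid.max()))
    else:
        pi0 = float(pi0_curve[np.argmin(np.abs(grid - 0.5))])
    if not np.isfinite(pi0):
        pi0 = float(pi0_curve[np.argmin(np.abs(grid - 0.5))])
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Result(
        pvalues=p,
        lambda_grid=grid,
        pi0_curve=pi0_curve,
        pi0_estimate=pi0,
        pi1=1.0 - pi0,
    )


def mad_variability_classes(
    matrix: PhenotypeMatrix | np.ndarray,
    feature_ids: list[str] | None = None,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Per-feature MAD and quartile variability class.

    Quartile boundaries of the MAD distribution assign classes
    Q1 -> none, Q2 -> low, Q3 -> medium, Q4 -> high. ``scale`` multiplies
    the raw MAD (1.0 raw, 1.4826 for normal consistency). All-missing
    features are excluded with a log entry.
    """
    if isinstance(matrix, PhenotypeMatrix):
        values = matrix.values
        feature_ids = list(matrix.feature_ids)
    else:
        values = np.asarray(matrix, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(values.shape[1])]
    keep = ~np.isnan(values).all(axis=0)
    if not keep.all():
        logger.info("excluding %d all-missing features", int((~keep).sum()))
    values = values[:, keep]
    ids = [f for f, k in zip(feature_ids, keep) if k]
    if values.shape[1] < 4:
        raise ValueError("need at least 4 features for quartile classes")
    mad = stats.median_abs_deviation(values, axis=0, scale=1.0 / scale,
                                     nan_policy="omit")
    q25, q50, q75 = np.quantile(mad, [0.25, 0.5, 0.75])
    labels = np.array(["none", "low", "medium", "high"], dtype=object)
    cls = labels[np.searchsorted([q25, q50, q75], mad, side="left")]
    return pd.DataFrame({"feature_id": ids, "mad": mad, "quartile_class": cls})
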