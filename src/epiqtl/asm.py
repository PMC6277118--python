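"""Haplotype-dependent allele-specific methylation (hap-ASM) from bis-seq reads.

Deep amplicon coverage drives rank-test p-values toward zero, so the
allele comparison is bootstrapped: each iteration subsamples a fixed
number of reads per allele (default 20, without replacement within an
iteration), computes per-read fractional methylation and a two-sample
Wilcoxon rank-sum test across alleles, and the amplicon statistic is the
median p and median methylation difference over iterations (default
1000). An amplicon is called hap-ASM when |dMeth| > 20%, more than 3 CpGs
show a per-CpG allele difference above 20%, and p < 0.05 (all strict).
A binomial test on which allele carries the low-methylation state across
heterozygous samples distinguishes haplotype-dependent ASM from
imprinting (imprinting is blind to haplotype, so the low allele should be
random).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AmpliconReadSet

__all__ = [
    "AmpliconAsmResult",
    "bootstrap_asm_test",
    "call_amplicon_asm",
    "allele_bias_binomial",
    "concordance_450k",
    "rank_sum_p_matrix",
]

MIN_COVERAGE = 100          # minimum DNA fragments for testing
DELTA_THRESHOLD = 0.20      # |allele methylation difference| gate (strict >)
MIN_ASM_CPGS = 3            # required count of ASM CpGs (strict >)
P_THRESHOLD = 0.05          # Wilcoxon gate (strict <)


@dataclass
class AmpliconAsmResult:
    amplicon_id: str
    delta_meth: float         # allele B mean - allele A mean (median over bootstraps)
    p_wilcoxon: float         # median bootstrap p
    n_asm_cpgs: int           # full-data CpGs with |per-CpG allele diff| > threshold
    asm_call: bool
    n_reads_a: int
    n_reads_b: int
    n_boot: int
    reads_per_draw: int
    seed: int


def rank_sum_p_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Wilcoxon rank-sum p (normal approximation with tie
    correction and continuity correction).

    ``x`` is (B, n1) and ``y`` is (B, n2); returns (B,) p-values. Matches
    scipy's asymptotic Mann-Whitney U test.
    """
    b, n1 = x.shape
    n2 = y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction: sum over tied groups of (t^3 - t)
    sorted_vals = np.sort(combined, axis=1)
    new_group = np.ones_like(sorted_vals, dtype=bool)
    new_group[:, 1:] = sorted_vals[:, 1:] != sorted_vals[:, :-1]
    tie_term = np.empty(b)
    for i in range(b):  # group sizes differ per row
        _, counts = np.unique(sorted_vals[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var_u = np.maximum(var_u, 1e-300)
    z = (np.abs(u1 - mu) - 0.5) / np.sqrt(var_u)
    z = np.maximum(z, 0.0)
    return np.minimum(1.0, 2.0 * stats.norm.sf(z))


def bootstrap_asm_test(
    reads: AmpliconReadSet,
    n_boot: int = 1000,
    reads_per_draw: int = 20,
    seed: int = 0,
    min_coverage: int = MIN_COVERAGE,
) -> AmpliconAsmResult:
    """Bootstrap Wilcoxon comparison of per-read methylation between alleles."""
    fracA = reads.read_fractions("A")
    fracB = reads.read_fractions("B")
    nA, nB = fracA.size, fracB.size
    for name, cnt in (("A", nA), ("B", nB)):
        if cnt < reads_per_draw:
            raise ValueError(
                f"allele {name} has {cnt} reads; need >= {reads_per_draw}"
            )
    if nA + nB < min_coverage:
        raise ValueError(
            f"coverage {nA + nB} below the {min_coverage}-fragment minimum"
        )
    rng = np.random.default_rng(seed)
    # Subsampling is applied to the *sorted* per-read fractions, so results
    # are invariant to read order; with equal allele coverage the same index
    # draw is applied to both alleles, making the label-swap antisymmetry of
    # delta_meth (and the invariance of p) exact rather than distributional.
    fracA_sorted = np.sort(fracA)
    fracB_sorted = np.sort(fracB)
    drawsA = np.empty((n_boot, reads_per_draw))
    drawsB = np.empty((n_boot, reads_per_draw))
    for j in range(n_boot):
        idx = rng.choice(nA, size=reads_per_draw, replace=False)
        drawsA[j] = fracA_sorted[idx]
        if nB == nA:
            drawsB[j] = fracB_sorted[idx]
        else:
            drawsB[j] = fracB_sorted[rng.choice(nB, size=reads_per_draw, replace=False)]
    deltas = drawsB.mean(axis=1) - drawsA.mean(axis=1)
    pvals = rank_sum_p_matrix(drawsA, drawsB)
    delta_med = float(np.median(deltas))
    p_med = float(np.median(pvals))
    # full-data per-CpG allele differences
    with np.errstate(invalid="ignore"):
        cpg_a = np.nanmean(reads.reads_for_allele("A"), axis=0)
        cpg_b = np.nanmean(reads.reads_for_allele("B"), axis=0)
    n_asm = int(np.nansum(np.abs(cpg_b - cpg_a) > DELTA_THRESHOLD))
    return AmpliconAsmResult(
        amplicon_id=reads.amplicon_id,
        delta_meth=delta_med,
        p_wilcoxon=p_med,
        n_asm_cpgs=n_asm,
        asm_call=call_amplicon_asm(delta_med, n_asm, p_med),
        n_reads_a=nA,
        n_reads_b=nB,
        n_boot=n_boot,
        reads_per_draw=reads_per_draw,
        seed=seed,
    )


def call_amplicon_asm(delta_meth: float, n_asm_cpgs: int, p: float) -> bool:
    """hap-ASM call: |dMeth| > 0.20 AND n_asm_cpgs > 3 AND p < 0.05 (strict)."""
    for v in (delta_meth, p):
        if not np.isfinite(v):
            raise ValueError("inputs must be finite")
    return bool(
        abs(delta_meth) > DELTA_THRESHOLD
        and n_asm_cpgs > MIN_ASM_CPGS
        and p < P_THRESHOLD
    )


def allele_bias_binomial(n_a_low: int, n_het: int) -> float:
    """Two-sided exact binomial test of the low-methylated allele being
    allele A in ``n_a_low`` of ``n_het`` heterozygous samples (null 0.5).
    A small p indicates a haplotype-linked asymmetry, ruling out imprinting."""
    if n_het == 0:
        raise ValueError("no heterozygous samples")
    if n_a_low > n_het:
        raise ValueError("n_a_low cannot exceed n_het")
    return float(stats.binomtest(n_a_low, n_het, 0.5, alternative="two-sided").pvalue)


def concordance_450k(
    amplicon_means: dict[str, float] | pd.Series,
    array_betas: dict[str, float] | pd.Series,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Per-sample concordance between bis-seq amplicon mean methylation and
    the array beta value: concordant iff |difference| <= tolerance."""
    amp = pd.Series(amplicon_means, dtype=float)
    arr = pd.Series(array_betas, dtype=float)
    shared = amp.index.intersection(arr.index)
    if shared.empty:
        raise ValueError("no overlapping samples")
    diff = (amp[shared] - arr[shared]).abs()
    out = pd.DataFrame(
        {
            "sample_id": shared,
            "bisseq_mean": amp[shared].to_numpy(),
            "array_beta": arr[shared].to_numpy(),
            "abs_diff": diff.to_numpy(),
            "concordant": (diff <= tolerance).to_numpy(),
        }
    )
    out.attrs["fraction_concordant"] = float(out["concordant"].mean())
    return out
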