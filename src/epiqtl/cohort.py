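"""Synthetic multi-omic cohort generator.

Emulates the structure of a placental QTL study: a genotyped cohort
(default 303 samples) assayed for CpG methylation, an expression subset
(default 80 samples, 74 overlapping with methylation), Hardy-Weinberg
genotypes on one synthetic chromosome, planted additive cis effects,
beta-distributed methylation with optional gap-signal (cluster) probes,
linear and two-state expression-methylation pairs, and targeted bis-seq
amplicons with planted allele-specific methylation.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AmpliconReadSet, GenotypeMatrix, PhenotypeMatrix, TruthTable

__all__ = [
    "DEFAULT_CHROM",
    "DEFAULT_CHROM_LENGTH",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_methylation",
    "simulate_eqtm_pairs",
    "simulate_bisseq_amplicon",
    "simulate_cohort",
    "EqtmPairSet",
    "Cohort",
]

DEFAULT_CHROM = "chrS"
DEFAULT_CHROM_LENGTH = 10_000_000

# Cohort sizes mirror the study design: 303 genotyped/methylation samples,
# 80 expression samples, 74 in the overlap used for eQTM mapping.
N_METHYLATION_SAMPLES = 303
N_EXPRESSION_SAMPLES = 80
N_EQTM_OVERLAP = 74


def _beta_ab(mean: np.ndarray, concentration: float) -> tuple[np.ndarray, np.ndarray]:
    """Convert (mean, concentration) to beta shape parameters a = mu*kappa, b = (1-mu)*kappa."""
    mean = np.asarray(mean, dtype=float)
    return mean * concentration, (1.0 - mean) * concentration


def simulate_genotypes(
    n_samples: int = N_METHYLATION_SAMPLES,
    n_variants: int = 1000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    seed: int = 0,
    missing_rate: float = 0.0,
    chrom: str = DEFAULT_CHROM,
) -> GenotypeMatrix:
    """Draw independent Hardy-Weinberg variants at MAFs uniform in ``maf_range``.

    Positions are uniform on [1, chrom_length]. Missingness, if requested,
    is injected completely at random.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5] (monomorphic variants undefined)")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    # HWE: dosage = sum of two Bernoulli(alt freq) allele draws.
    dosages = (
        rng.binomial(1, mafs, size=(n_samples, n_variants))
        + rng.binomial(1, mafs, size=(n_samples, n_variants))
    ).astype(float)
    if missing_rate > 0:
        dosages[rng.random((n_samples, n_variants)) < missing_rate] = np.nan
    positions = np.sort(rng.integers(1, chrom_length + 1, size=n_variants))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_variants)]
    # alt differs from ref
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, size=n_variants)) % 4]
    return GenotypeMatrix(
        sample_ids=[f"S{i:04d}" for i in range(n_samples)],
        variant_ids=[f"snp{i:05d}" for i in range(n_variants)],
        chrom=np.full(n_variants, chrom, dtype=object),
        positions=positions,
        ref_allele=ref,
        alt_allele=alt,
        dosages=dosages,
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    n_genes: int = 200,
    planted_eqtls: TruthTable | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    cis_window: int = 1_000_000,
    sample_ids: list[str] | None = None,
) -> PhenotypeMatrix:
    """Additive-allelic expression: value = baseline + effect x dosage + noise.

    Planted genes take their TSS uniformly inside the cis window of their
    planted variant; unplanted genes are pure noise around a gene-specific
    baseline with random TSS.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    planted = planted_eqtls.for_mechanism("eqtl") if planted_eqtls is not None else None
    rng = np.random.default_rng(seed)
    geno = genotypes if sample_ids is None else genotypes.subset_samples(sample_ids)
    n_samples = geno.n_samples
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    chrom0 = geno.chrom[0] if geno.n_variants else DEFAULT_CHROM
    max_pos = int(geno.positions.max()) if geno.n_variants else DEFAULT_CHROM_LENGTH

    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = baselines[None, :] + rng.normal(0.0, noise_sd, size=(n_samples, n_genes))
    tss = rng.integers(1, max_pos + 1, size=n_genes)
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-").astype(object)

    if planted is not None and len(planted):
        vlookup = {v: i for i, v in enumerate(geno.variant_ids)}
        glookup = {g: i for i, g in enumerate(gene_ids)}
        for rec in planted.itertuples(index=False):
            if rec.source_id not in vlookup:
                raise ValueError(f"planted eQTL references absent variant {rec.source_id}")
            if rec.target_id not in glookup:
                raise ValueError(f"planted eQTL references absent gene {rec.target_id}")
            vi, gi = vlookup[rec.source_id], glookup[rec.target_id]
            dose = geno.dosages[:, vi]
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
            values[:, gi] += rec.effect_size * dose
            vpos = int(geno.positions[vi])
            lo = max(1, vpos - cis_window)
            tss[gi] = rng.integers(lo, vpos + cis_window + 1)
    return PhenotypeMatrix(
        sample_ids=list(geno.sample_ids),
        feature_ids=gene_ids,
        values=values,
        feature_chrom=np.full(n_genes, chrom0, dtype=object),
        feature_pos=tss,
        strand=strand,
        kind="expression",
    )


def _baseline_methylation_means(n: int, rng: np.random.Generator) -> np.ndarray:
    """CpG-level mean methylation enriched for low and intermediate levels."""
    u = rng.random(n)
    means = np.empty(n)
    low = u < 0.45
    mid = (u >= 0.45) & (u < 0.75)
    high = u >= 0.75
    means[low] = rng.beta(2.0, 14.0, size=low.sum())       # ~0.12
    means[mid] = rng.uniform(0.25, 0.65, size=mid.sum())
    means[high] = rng.beta(14.0, 2.0, size=high.sum())     # ~0.88
    return np.clip(means, 0.02, 0.98)


def simulate_methylation(
    genotypes: GenotypeMatrix,
    n_cpgs: int = 500,
    planted_mqtls: TruthTable | None = None,
    concentration: float = 50.0,
    gap_fraction: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    cis_window: int = 75_000,
    sample_ids: list[str] | None = None,
) -> PhenotypeMatrix:
    """Beta-distributed methylation with genotype-shifted means for planted mQTLs.

    A ``gap_fraction`` subset of CpGs is generated as genotype-determined
    clusters separated by >= 0.1 in beta value, mimicking the gap-signal
    (cluster) probes driven by underlying variants on methylation arrays.
    Planted ids are recorded in ``meta['gap_cpg_ids']`` and
    ``meta['mqtl_cpg_ids']``.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if not 0.0 <= gap_fraction <= 1.0:
        raise ValueError("gap_fraction must lie in [0, 1]")
    planted = planted_mqtls.for_mechanism("mqtl") if planted_mqtls is not None else None
    rng = np.random.default_rng(seed)
    geno = genotypes if sample_ids is None else genotypes.subset_samples(sample_ids)
    n_samples = geno.n_samples
    cpg_ids = [f"cg{i:05d}" for i in range(n_cpgs)]
    chrom0 = geno.chrom[0] if geno.n_variants else DEFAULT_CHROM
    max_pos = int(geno.positions.max()) if geno.n_variants else DEFAULT_CHROM_LENGTH

    base_means = _baseline_methylation_means(n_cpgs, rng)
    means = np.tile(base_means, (n_samples, 1))
    positions = rng.integers(1, max_pos + 1, size=n_cpgs)

    mqtl_ids: list[str] = []
    if planted is not None and len(planted):
        vlookup = {v: i for i, v in enumerate(geno.variant_ids)}
        clookup = {c: i for i, c in enumerate(cpg_ids)}
        for rec in planted.itertuples(index=False):
            if rec.source_id not in vlookup:
                raise ValueError(f"planted mQTL references absent variant {rec.source_id}")
            if rec.target_id not in clookup:
                raise ValueError(f"planted mQTL references absent CpG {rec.target_id}")
            vi, ci = vlookup[rec.source_id], clookup[rec.target_id]
            dose = geno.dosages[:, vi]
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
            # planted CpGs get an intermediate baseline so a typical planted
            # shift (2 x effect_size) stays inside the valid mean range
            base_means[ci] = rng.uniform(0.2, 0.6)
            shifted = base_means[ci] + rec.effect_size * dose
            if (shifted <= 0.01).any() or (shifted >= 0.99).any():
                warnings.warn(
                    f"planted mQTL shift for {rec.target_id} clipped to (0.01, 0.99)",
                    stacklevel=2,
                )
            means[:, ci] = np.clip(shifted, 0.01, 0.99)
            vpos = int(geno.positions[vi])
            positions[ci] = rng.integers(max(1, vpos - cis_window), vpos + cis_window + 1)
            mqtl_ids.append(rec.target_id)

    a, b = _beta_ab(means, concentration)
    values = rng.beta(a, b)

    # Gap probes: tight genotype-determined clusters with guaranteed separation.
    n_gap = int(round(gap_fraction * n_cpgs))
    candidates = [i for i in range(n_cpgs) if cpg_ids[i] not in set(mqtl_ids)]
    gap_idx = rng.choice(candidates, size=n_gap, replace=False) if n_gap else np.array([], int)
    gap_ids = [cpg_ids[i] for i in gap_idx]
    if n_gap:
        # pick driver variants with reasonably common minor allele so every
        # genotype cluster is populated
        mafs = geno.maf()
        good = np.flatnonzero(mafs >= 0.2)
        if good.size == 0:
            good = np.arange(geno.n_variants)
        drivers = rng.choice(good, size=n_gap, replace=True)
        for ci, vi in zip(gap_idx, drivers):
            dose = geno.dosages[:, vi]
            dose = np.where(np.isnan(dose), 0.0, dose)
            base = rng.uniform(0.10, 0.40)
            centers = base + 0.25 * dose
            draw = rng.beta(*_beta_ab(centers, 800.0))
            # clamp within +/-0.04 of cluster centre so inter-cluster gaps
            # stay >= 0.25 - 0.08 = 0.17 > 0.1 by construction
            values[:, ci] = np.clip(draw, centers - 0.04, centers + 0.04)

    values = np.clip(values, 0.0, 1.0)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return PhenotypeMatrix(
        sample_ids=list(geno.sample_ids),
        feature_ids=cpg_ids,
        values=values,
        feature_chrom=np.full(n_cpgs, chrom0, dtype=object),
        feature_pos=positions,
        kind="methylation",
        meta={"gap_cpg_ids": gap_ids, "mqtl_cpg_ids": mqtl_ids},
    )


@dataclass
class LinearEqtmParams:
    """Latent cell-fraction model: a continuous mixture of methylated and
    unmethylated cell states drives both methylation and expression."""

    a: float = 2.0            # Beta shape of the latent fraction
    b: float = 2.0
    meth_concentration: float = 150.0  # beta noise around the latent fraction
    c0: float = 6.0           # expression intercept
    c1: float = -3.0          # expression units per unit fraction (sign = direction)
    e_sd: float = 0.8


@dataclass
class BimodalEqtmParams:
    """Two-state model: samples occupy a low- or high-methylation state with
    correspondingly switched expression."""

    omega: float = 0.5        # probability of the high-methylation state
    m_low: float = 0.15
    m_high: float = 0.85
    concentration: float = 50.0
    e_low: float = 2.0
    e_high: float = 6.0
    e_sd: float = 0.8
    anticorrelated: bool = False  # if True, high methylation pairs with low expression


@dataclass
class EqtmPairSet:
    """Paired expression/methylation columns plus planting ground truth."""

    expression: np.ndarray   # (n_samples, n_pairs)
    methylation: np.ndarray  # (n_samples, n_pairs)
    mode: str                # "linear" | "bimodal"
    truth: TruthTable
    states: np.ndarray | None = None  # bimodal: latent state per (sample, pair)

    @property
    def n_pairs(self) -> int:
        return self.expression.shape[1]


def simulate_eqtm_pairs(
    mode: str,
    n_samples: int = N_EQTM_OVERLAP,
    n_pairs: int = 1,
    params: LinearEqtmParams | BimodalEqtmParams | None = None,
    seed: int = 0,
) -> EqtmPairSet:
    """Generate expression-methylation pairs under the linear (cell-mixture)
    or bimodal (two-state) generative model."""
    if n_samples < 20:
        raise ValueError("need at least 20 samples per pair")
    rng = np.random.default_rng(seed)
    shape = (n_samples, n_pairs)
    if mode == "linear":
        p = params or LinearEqtmParams()
        if not isinstance(p, LinearEqtmParams):
            raise TypeError("linear mode requires LinearEqtmParams")
        frac = rng.beta(p.a, p.b, size=shape)
        meth = rng.beta(*_beta_ab(np.clip(frac, 0.02, 0.98), p.meth_concentration))
        expr = p.c0 + p.c1 * frac + rng.normal(0.0, p.e_sd, size=shape)
        states = None
        mech = "eqtm_linear"
    elif mode == "bimodal":
        p = params or BimodalEqtmParams()
        if not isinstance(p, BimodalEqtmParams):
            raise TypeError("bimodal mode requires BimodalEqtmParams")
        if not 0.0 < p.omega < 1.0:
            raise ValueError("omega must lie in (0, 1)")
        states = rng.random(shape) < p.omega   # True = high-methylation state
        m_mean = np.where(states, p.m_high, p.m_low)
        meth = rng.beta(*_beta_ab(m_mean, p.concentration))
        if p.anticorrelated:
            e_mean = np.where(states, p.e_low, p.e_high)
        else:
            e_mean = np.where(states, p.e_high, p.e_low)
        expr = rng.normal(e_mean, p.e_sd)
        mech = "eqtm_bimodal"
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'linear' or 'bimodal')")
    truth = TruthTable(
        pd.DataFrame(
            {
                "source_id": [f"cg_pair{i:04d}" for i in range(n_pairs)],
                "target_id": [f"gene_pair{i:04d}" for i in range(n_pairs)],
                "effect_size": np.nan,
                "mechanism": mech,
            }
        )
    )
    return EqtmPairSet(
        expression=expr, methylation=np.clip(meth, 0.0, 1.0), mode=mode,
        truth=truth, states=states,
    )


def simulate_bisseq_amplicon(
    n_cpgs: int,
    reads_per_allele: int,
    p_meth_alleleA,
    p_meth_alleleB,
    seed: int = 0,
    amplicon_id: str = "amp000",
    het_snp_id: str = "rs_sim",
) -> AmpliconReadSet:
    """Per-read Bernoulli CpG calls for a two-allele bis-seq amplicon."""
    if n_cpgs < 1:
        raise ValueError("amplicon must contain at least one CpG")
    if reads_per_allele < 1:
        raise ValueError("need at least one read per allele")
    pA = np.atleast_1d(np.asarray(p_meth_alleleA, dtype=float))
    pB = np.atleast_1d(np.asarray(p_meth_alleleB, dtype=float))
    if pA.shape != pB.shape:
        raise ValueError("per-CpG probability vectors must have equal length")
    for name, p in (("A", pA), ("B", pB)):
        if p.size not in (1, n_cpgs):
            raise ValueError(
                f"allele {name} probability vector has length {p.size}, expected {n_cpgs}"
            )
    pA = np.broadcast_to(pA, (n_cpgs,))
    pB = np.broadcast_to(pB, (n_cpgs,))
    for p in (pA, pB):
        if (p < 0).any() or (p > 1).any():
            raise ValueError("methylation probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    callsA = rng.binomial(1, pA, size=(reads_per_allele, n_cpgs)).astype(float)
    callsB = rng.binomial(1, pB, size=(reads_per_allele, n_cpgs)).astype(float)
    calls = np.vstack([callsA, callsB])
    alleles = np.array(["A"] * reads_per_allele + ["B"] * reads_per_allele)
    return AmpliconReadSet(
        amplicon_id=amplicon_id,
        het_snp_id=het_snp_id,
        read_ids=[f"read{i:05d}" for i in range(2 * reads_per_allele)],
        alleles=alleles,
        cpg_positions=np.arange(1, n_cpgs + 1) * 10,
        calls=calls,
    )


@dataclass
class Cohort:
    """A bundled synthetic study: genotypes, phenotypes, and ground truth."""

    genotypes: GenotypeMatrix
    expression: PhenotypeMatrix
    methylation: PhenotypeMatrix
    truth: TruthTable
    expression_samples: list[str] = field(default_factory=list)
    eqtm_samples: list[str] = field(default_factory=list)


def simulate_cohort(
    n_samples: int = N_METHYLATION_SAMPLES,
    n_expression_samples: int = N_EXPRESSION_SAMPLES,
    n_eqtm_overlap: int = N_EQTM_OVERLAP,
    n_variants: int = 1000,
    n_genes: int = 100,
    n_cpgs: int = 300,
    n_planted_eqtl: int = 20,
    n_planted_mqtl: int = 30,
    n_planted_eqtm: int = 0,
    eqtl_effect: float = 1.0,
    mqtl_effect: float = 0.08,
    eqtm_effect: float = 5.0,
    expression_noise_sd: float = 1.0,
    methylation_concentration: float = 50.0,
    gap_fraction: float = 0.0,
    seed: int = 0,
) -> Cohort:
    """End-to-end synthetic study with planted cis effects.

    The expression matrix covers a subset of the genotyped cohort
    (first ``n_expression_samples`` samples); the eQTM overlap is the first
    ``n_eqtm_overlap`` of those. Planted eQTM pairs couple a gene's
    expression to a CpG's methylation (``eqtm_effect`` expression units per
    beta unit) and move the CpG into the gene's cis window; they use genes
    and CpGs not already carrying planted QTL effects.
    """
    rng = np.random.default_rng(seed)
    geno = simulate_genotypes(
        n_samples=n_samples, n_variants=n_variants, seed=int(rng.integers(2**31))
    )
    records = []
    ev = rng.choice(n_variants, size=n_planted_eqtl + n_planted_mqtl, replace=False)
    for k in range(n_planted_eqtl):
        records.append((geno.variant_ids[ev[k]], f"gene{k:04d}", eqtl_effect, "eqtl"))
    for k in range(n_planted_mqtl):
        records.append(
            (geno.variant_ids[ev[n_planted_eqtl + k]], f"cg{k:05d}", mqtl_effect, "mqtl")
        )
    truth = TruthTable.from_records(records)

    expr_samples = geno.sample_ids[:n_expression_samples]
    expr = simulate_expression(
        geno,
        n_genes=n_genes,
        planted_eqtls=truth,
        noise_sd=expression_noise_sd,
        seed=int(rng.integers(2**31)),
        sample_ids=expr_samples,
    )
    meth = simulate_methylation(
        geno,
        n_cpgs=n_cpgs,
        planted_mqtls=truth,
        concentration=methylation_concentration,
        gap_fraction=gap_fraction,
        seed=int(rng.integers(2**31)),
    )
    if n_planted_eqtm:
        if n_planted_eqtl + n_planted_eqtm > n_genes:
            raise ValueError("not enough genes for the requested eQTM planting")
        taken_cpgs = set(meth.meta["mqtl_cpg_ids"]) | set(meth.meta["gap_cpg_ids"])
        free_cpgs = [c for c in meth.feature_ids if c not in taken_cpgs]
        if n_planted_eqtm > len(free_cpgs):
            raise ValueError("not enough CpGs for the requested eQTM planting")
        meth_sample_idx = {s: i for i, s in enumerate(meth.sample_ids)}
        rows = [meth_sample_idx[s] for s in expr_samples]
        eqtm_records = []
        for k in range(n_planted_eqtm):
            gene_id = f"gene{n_planted_eqtl + k:04d}"
            cpg_id = free_cpgs[k]
            gi = expr.feature_ids.index(gene_id)
            ci = meth.feature_ids.index(cpg_id)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            # eQTM CpGs are drawn as highly variable loci (low concentration):
            # expression-coupled CpGs sit in the top variability quartile
            mu = rng.uniform(0.3, 0.6)
            meth.values[:, ci] = rng.beta(*_beta_ab(mu, 8.0), size=meth.n_samples)
            beta_vals = meth.values[rows, ci]
            expr.values[:, gi] += sign * eqtm_effect * beta_vals
            # move the CpG into the gene's cis window
            tss = int(expr.feature_pos[gi])
            meth.feature_pos[ci] = rng.integers(max(1, tss - 50_000), tss + 50_001)
            eqtm_records.append((cpg_id, gene_id, sign * eqtm_effect, "eqtm_linear"))
        truth = TruthTable(
            pd.concat(
                [truth.records,
                 pd.DataFrame(eqtm_records, columns=list(TruthTable.REQUIRED))],
                ignore_index=True,
            )
        )
    return Cohort(
        genotypes=geno,
        expression=expr,
        methylation=meth,
        truth=truth,
        expression_samples=list(expr_samples),
        eqtm_samples=list(expr_samples[:n_eqtm_overlap]),
    )
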