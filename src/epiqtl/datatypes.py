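"""Core in-memory containers shared across the toolkit.

Conventions
-----------
* Genotypes are additive alternate-allele dosages in {0, 1, 2}; missing
  entries are ``NaN`` in the float storage array.
* Phenotype matrices are oriented samples x features; methylation values
  are beta values in [0, 1], expression values are unbounded (log2 scale).
* All coordinates are 1-based chromosome positions; BED output converts
  to 0-based half-open on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "TruthTable",
    "AmpliconReadSet",
]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with variant metadata."""

    sample_ids: list[str]
    variant_ids: list[str]
    chrom: np.ndarray          # str per variant
    positions: np.ndarray      # int, 1-based
    ref_allele: np.ndarray     # single-nucleotide str per variant
    alt_allele: np.ndarray
    dosages: np.ndarray        # float (n_samples, n_variants); NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage shape does not match sample/variant ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per variant."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant (complete cases)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant."""
        aaf = self.alt_allele_freq()
        return np.minimum(aaf, 1.0 - aaf)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of genotype classes 0/1/2 (complete cases)."""
        counts = np.zeros((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            counts[:, g] = np.nansum(self.dosages == g, axis=0)
        return counts

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {v: i for i, v in enumerate(self.variant_ids)}
            idx = np.array([lookup[v] for v in mask_or_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            chrom=self.chrom,
            positions=self.positions,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            dosages=self.dosages[idx, :],
        )

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom,
                "pos": self.positions,
                "ref": self.ref_allele,
                "alt": self.alt_allele,
                "maf": self.maf(),
            }
        )


@dataclass
class PhenotypeMatrix:
    """Samples x features matrix of expression or methylation values."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray           # float (n_samples, n_features); NaN = missing
    feature_chrom: np.ndarray    # str per feature
    feature_pos: np.ndarray      # int anchor (TSS for genes, CpG site for probes)
    strand: np.ndarray | None = None   # '+'/'-' per feature (genes)
    kind: str = "expression"     # "expression" | "methylation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("value shape does not match sample/feature ids")
        if self.kind == "methylation":
            observed = self.values[~np.isnan(self.values)]
            if observed.size and ((observed < 0).any() or (observed > 1).any()):
                raise ValueError("methylation values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "chrom": self.feature_chrom,
                "pos": self.feature_pos,
            }
        )
        if self.strand is not None:
            out["strand"] = self.strand
        return out

    def to_frame(self) -> pd.DataFrame:
        """Features x samples frame (the on-disk TSV orientation)."""
        return pd.DataFrame(
            self.values.T, index=self.feature_ids, columns=self.sample_ids
        )

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]

    def subset_samples(self, sample_ids: list[str]) -> "PhenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return PhenotypeMatrix(
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            values=self.values[idx, :],
            feature_chrom=self.feature_chrom,
            feature_pos=self.feature_pos,
            strand=self.strand,
            kind=self.kind,
            meta=dict(self.meta),
        )


@dataclass
class TruthTable:
    """Planted-effect ground truth for recovery tests.

    ``records`` columns: source_id (variant or CpG), target_id (gene or CpG),
    effect_size (slope units per alt allele, or per methylation unit),
    mechanism in {eqtl, mqtl, eqtm_linear, eqtm_bimodal}.
    """

    records: pd.DataFrame

    REQUIRED = ("source_id", "target_id", "effect_size", "mechanism")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"truth table missing columns: {missing}")

    @classmethod
    def from_records(cls, records: list[tuple]) -> "TruthTable":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    @classmethod
    def empty(cls) -> "TruthTable":
        return cls(pd.DataFrame(columns=list(cls.REQUIRED)))

    def for_mechanism(self, mechanism: str) -> pd.DataFrame:
        return self.records[self.records["mechanism"] == mechanism]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AmpliconReadSet:
    """Per-read CpG methylation calls for one bis-seq amplicon.

    ``calls`` is (n_reads, n_cpgs) with entries in {0, 1, NaN}; every read
    carries an allele label 'A' (reference haplotype) or 'B' (alternate).
    """

    amplicon_id: str
    het_snp_id: str
    read_ids: list[str]
    alleles: np.ndarray        # 'A'/'B' per read
    cpg_positions: np.ndarray  # 1-based, ordered
    calls: np.ndarray          # float (n_reads, n_cpgs)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.alleles = np.asarray(self.alleles)
        if self.calls.shape != (len(self.read_ids), len(self.cpg_positions)):
            raise ValueError("call matrix shape does not match reads/CpGs")
        if not np.isin(self.alleles, ["A", "B"]).all():
            raise ValueError("allele labels must be 'A' or 'B'")
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, [0.0, 1.0]).all():
            raise ValueError("CpG calls must be 0/1 or missing")

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def reads_for_allele(self, allele: str) -> np.ndarray:
        return self.calls[self.alleles == allele, :]

    def read_fractions(self, allele: str) -> np.ndarray:
        """Per-read fractional methylation (mean over observed CpGs)."""
        calls = self.reads_for_allele(allele)
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=1)
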