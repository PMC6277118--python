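"""Generate a synthetic multi-omic cohort and write it to disk.

Builds a study with the design's sample structure — 303 genotyped samples
assayed for methylation, an 80-sample expression subset, 74 samples in the
eQTM overlap — with planted cis-eQTLs and cis-mQTLs, then writes the
matrices in their exchange formats (VCF, TSV, BED, truth TSV).
"""

from pathlib import Path

from epiqtl import io
from epiqtl.cohort import simulate_cohort

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)

cohort = simulate_cohort(
    n_samples=303,
    n_expression_samples=80,
    n_eqtm_overlap=74,
    n_variants=400,
    n_genes=80,
    n_cpgs=300,
    n_planted_eqtl=20,
    n_planted_mqtl=30,
    gap_fraction=0.05,
    seed=1,
)

io.write_genotype_vcf(cohort.genotypes, out / "genotypes.vcf")
io.write_phenotype_tsv(cohort.expression, out / "expression.tsv")
io.write_phenotype_tsv(cohort.methylation, out / "methylation.tsv")
io.write_feature_bed(
    cohort.expression.feature_ids,
    cohort.expression.feature_chrom,
    cohort.expression.feature_pos,
    out / "gene_tss.bed",
)
io.write_truth_tsv(cohort.truth, out / "truth.tsv")

print(f"genotypes: {cohort.genotypes.n_samples} samples x "
      f"{cohort.genotypes.n_variants} variants, "
      f"mean MAF {cohort.genotypes.maf().mean():.3f}")
print(f"expression: {cohort.expression.n_samples} samples x "
      f"{cohort.expression.n_features} genes")
print(f"methylation: {cohort.methylation.n_samples} samples x "
      f"{cohort.methylation.n_features} CpGs "
      f"({len(cohort.methylation.meta['gap_cpg_ids'])} planted gap probes)")
print(f"planted effects: {len(cohort.truth)} "
      f"(ground truth written to {out / 'truth.tsv'})")
# The truth table is what downstream recovery tests score against; the
# gap-probe ids let probe-QC sensitivity be measured exactly.
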