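"""Readers and writers for the toolkit's on-disk formats.

* Phenotype matrices: TSV, features as rows, samples as columns, first
  column the feature id.
* Feature positions: BED (0-based half-open single-base intervals).
* Genotypes: minimal VCF v4.2 (CHROM POS ID REF ALT QUAL FILTER INFO
  FORMAT=GT) read back through cyvcf2, or a TSV dosage matrix.
* Truth tables and per-read amplicon CpG calls: TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AmpliconReadSet, GenotypeMatrix, PhenotypeMatrix, TruthTable

__all__ = [
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_feature_bed",
    "read_feature_bed",
    "write_genotype_vcf",
    "read_genotype_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_amplicon_reads_tsv",
    "read_amplicon_reads_tsv",
    "read_probe_design_tsv",
    "write_probe_annotation_tsv",
]

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_phenotype_tsv(matrix: PhenotypeMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_phenotype_tsv(
    path: str | Path,
    positions: pd.DataFrame,
    kind: str = "expression",
) -> PhenotypeMatrix:
    """``positions`` supplies (feature_id, chrom, pos[, strand])."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    pos = positions.set_index("feature_id").loc[frame.index]
    return PhenotypeMatrix(
        sample_ids=list(frame.columns),
        feature_ids=list(frame.index),
        values=frame.to_numpy().T,
        feature_chrom=pos["chrom"].to_numpy(),
        feature_pos=pos["pos"].to_numpy(),
        strand=pos["strand"].to_numpy() if "strand" in pos.columns else None,
        kind=kind,
    )


def write_feature_bed(
    feature_ids, chroms, positions, path: str | Path
) -> None:
    """1-based anchor positions become 0-based half-open single-base records."""
    with open(path, "w") as fh:
        for fid, chrom, pos in zip(feature_ids, chroms, positions):
            fh.write(f"{chrom}\t{int(pos) - 1}\t{int(pos)}\t{fid}\n")


def read_feature_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "feature_id"],
    )
    bed["pos"] = bed["start"] + 1  # back to 1-based anchor
    return bed[["feature_id", "chrom", "pos", "start", "end"]]


def write_genotype_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted(set(genotypes.chrom))
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        order = np.lexsort((genotypes.positions, genotypes.chrom.astype(str)))
        for j in order:
            gts = "\t".join(
                _GT_CODES.get(d, "./.") for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.positions[j]}\t"
                f"{genotypes.variant_ids[j]}\t{genotypes.ref_allele[j]}\t"
                f"{genotypes.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    vids, chroms, positions, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        vids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else "N")
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(3 in some builds), 2/3 handling below
        dos = np.array(
            [sum(a for a in gt[:2] if a >= 0) if gt[0] >= 0 else np.nan
             for gt in var.genotypes],
            dtype=float,
        )
        rows.append(dos)
    vcf.close()
    return GenotypeMatrix(
        sample_ids=samples,
        variant_ids=vids,
        chrom=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=int),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosages=np.array(rows, dtype=float).T,
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        genotypes.dosages.T,
        index=genotypes.variant_ids,
        columns=genotypes.sample_ids,
    )
    meta = genotypes.variant_frame().set_index("variant_id")
    out = pd.concat([meta[["chrom", "pos", "ref", "alt"]], frame], axis=1)
    out.to_csv(path, sep="\t", index_label="variant_id")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = ["chrom", "pos", "ref", "alt"]
    sample_cols = [c for c in frame.columns if c not in meta_cols]
    return GenotypeMatrix(
        sample_ids=sample_cols,
        variant_ids=list(frame.index),
        chrom=frame["chrom"].to_numpy(dtype=object),
        positions=frame["pos"].to_numpy(dtype=int),
        ref_allele=frame["ref"].to_numpy(dtype=object),
        alt_allele=frame["alt"].to_numpy(dtype=object),
        dosages=frame[sample_cols].to_numpy(dtype=float).T,
    )


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    truth.records.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> TruthTable:
    return TruthTable(pd.read_csv(path, sep="\t"))


def read_probe_design_tsv(path: str | Path):
    """Probe-design TSV (probe_id, chrom, cpg_pos, strand, probe_type) ->
    list of ProbeAnnotation."""
    from .probes import ProbeAnnotation

    table = pd.read_csv(path, sep="\t")
    return [
        ProbeAnnotation(
            probe_id=str(rec.probe_id),
            chrom=str(rec.chrom),
            cpg_pos=int(rec.cpg_pos),
            strand=str(getattr(rec, "strand", "+")),
            probe_type=str(getattr(rec, "probe_type", "II")),
        )
        for rec in table.itertuples(index=False)
    ]


def write_probe_annotation_tsv(probes, path: str | Path) -> None:
    """Annotation table mirroring the SNP-probe / cross-reactive / gap-probe
    lists: one row per probe with flags and disposition."""
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "chrom": [p.chrom for p in probes],
            "cpg_pos": [p.cpg_pos for p in probes],
            "snp_in_probe": [p.snp_in_probe for p in probes],
            "snp_ids": [";".join(p.snp_ids) for p in probes],
            "cross_reactive": [p.cross_reactive for p in probes],
            "gap_probe": [p.gap_probe for p in probes],
            "gap_group_sizes": [
                ";".join(map(str, p.gap_group_sizes)) for p in probes
            ],
            "disposition": [p.disposition for p in probes],
        }
    ).to_csv(path, sep="\t", index=False)


def write_amplicon_reads_tsv(reads: AmpliconReadSet, path: str | Path) -> None:
    rows = []
    for i, rid in enumerate(reads.read_ids):
        for j, pos in enumerate(reads.cpg_positions):
            call = reads.calls[i, j]
            if np.isnan(call):
                continue
            rows.append(
                (reads.amplicon_id, reads.het_snp_id, rid,
                 reads.alleles[i], int(pos), int(call))
            )
    pd.DataFrame(
        rows,
        columns=["amplicon_id", "het_snp_id", "read_id", "allele", "cpg_pos", "call"],
    ).to_csv(path, sep="\t", index=False)


def read_amplicon_reads_tsv(path: str | Path) -> list[AmpliconReadSet]:
    table = pd.read_csv(path, sep="\t")
    out = []
    for amp_id, grp in table.groupby("amplicon_id", sort=True):
        positions = np.sort(grp["cpg_pos"].unique())
        pos_idx = {p: j for j, p in enumerate(positions)}
        read_ids = list(dict.fromkeys(grp["read_id"]))
        read_idx = {r: i for i, r in enumerate(read_ids)}
        calls = np.full((len(read_ids), len(positions)), np.nan)
        alleles = np.empty(len(read_ids), dtype=object)
        for rec in grp.itertuples(index=False):
            calls[read_idx[rec.read_id], pos_idx[rec.cpg_pos]] = rec.call
            alleles[read_idx[rec.read_id]] = rec.allele
        out.append(
            AmpliconReadSet(
                amplicon_id=str(amp_id),
                het_snp_id=str(grp["het_snp_id"].iloc[0]),
                read_ids=read_ids,
                alleles=alleles.astype(str),
                cpg_positions=positions,
                calls=calls,
            )
        )
    return out
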