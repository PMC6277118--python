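"""Annotate methylation probes at risk of artifact.

Three risk classes: a common SNP inside the probe's 20 bp upstream window
(excluding bisulfite-equivalent C/T variants) excludes a probe;
membership in a cross-reactivity blacklist excludes it; a gap signal
(clustered beta values, usually variant-driven) only flags it.
"""

import numpy as np
import pandas as pd

from epiqtl.cohort import simulate_genotypes, simulate_methylation
from epiqtl.probes import (
    ProbeAnnotation,
    annotate_associations,
    annotate_probes,
    flag_cross_reactive,
    flag_snp_probes,
)

genotypes = simulate_genotypes(n_samples=303, n_variants=60, seed=4)
meth = simulate_methylation(genotypes, n_cpgs=120, gap_fraction=0.1, seed=5)

probes = [
    ProbeAnnotation(pid, chrom, int(pos))
    for pid, chrom, pos in zip(meth.feature_ids, meth.feature_chrom, meth.feature_pos)
]
variants = genotypes.variant_frame()
# plant one A/G variant 5 bp upstream of the second probe's CpG and one
# bisulfite-equivalent C/T variant next to the third (exempt by rule)
variants = pd.concat([
    variants,
    pd.DataFrame({
        "variant_id": ["rs_demo_ag", "rs_demo_ct"],
        "chrom": [probes[1].chrom, probes[2].chrom],
        "pos": [probes[1].cpg_pos - 5, probes[2].cpg_pos - 5],
        "ref": ["A", "C"], "alt": ["G", "T"], "maf": [0.2, 0.2],
    }),
], ignore_index=True)
flag_snp_probes(probes, variants, window_bp=20, maf_min=0.01)
flag_cross_reactive(probes, blacklist={meth.feature_ids[0]})
annotate_probes(probes, meth.values, meth.feature_ids)

n_snp = sum(p.snp_in_probe for p in probes)
n_gap = sum(p.gap_probe for p in probes)
n_excluded = sum(p.disposition == "excluded" for p in probes)
print(f"{len(probes)} probes: {n_snp} SNP-in-probe, 1 cross-reactive, "
      f"{n_gap} gap probes -> {n_excluded} excluded, "
      f"{sum(p.disposition == 'flagged' for p in probes)} flagged only")
planted_gaps = set(meth.meta["gap_cpg_ids"])
found = {p.probe_id for p in probes if p.gap_probe}
print(f"gap detection recovered {len(found & planted_gaps)}/{len(planted_gaps)} "
      "planted cluster probes")

# Splitting an association table into stringent vs annotated-full sets:
assocs = pd.DataFrame({"cpg_id": meth.feature_ids,
                       "slope": np.full(len(probes), 0.1)})
stringent, full = annotate_associations(assocs, probes)
print(f"association table: {len(full)} annotated rows, "
      f"{len(stringent)} survive the stringent (exclusion) criteria")
# Gap probes stay in the stringent set with a flag; excluded probes do not.
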