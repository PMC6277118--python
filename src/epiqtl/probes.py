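"""Methylation-array probe quality control.

Three at-risk classes for array probes:

1. SNP probes — a common variant overlaps the interrogated CpG or sits in
   the probe-body window upstream of it (toward the probe 3' end, plus the
   single-base-extension position for type I probes). Variants whose allele
   pair is {C, T} on the probe strand are exempt: after bisulfite
   conversion they cannot change probe binding. Sufficient for exclusion.
2. Cross-reactive probes — membership in a published blacklist. Sufficient
   for exclusion.
3. Gap probes — beta values form discrete clusters (typically driven by an
   underlying variant). Flag only, never exclude; gaps carried by outlier
   groups (size <= ceil(cutoff * n)) are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeAnnotation",
    "flag_snp_probes",
    "flag_cross_reactive",
    "detect_gap_signals",
    "GapSignal",
    "annotate_probes",
    "annotate_associations",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ProbeAnnotation:
    probe_id: str
    chrom: str
    cpg_pos: int            # 1-based position of the interrogated CpG
    strand: str = "+"       # probe strand
    probe_type: str = "II"  # 'I' | 'II'
    snp_in_probe: bool = False
    snp_ids: list[str] = field(default_factory=list)
    cross_reactive: bool = False
    gap_probe: bool = False
    gap_group_sizes: list[int] = field(default_factory=list)

    @property
    def disposition(self) -> str:
        if self.snp_in_probe or self.cross_reactive:
            return "excluded"
        if self.gap_probe:
            return "flagged"
        return "clean"


def _is_ct_pair(ref: str, alt: str, strand: str) -> bool:
    """True if the allele pair is {C, T} on the probe strand (bisulfite-equivalent)."""
    if strand == "-":
        ref, alt = _COMPLEMENT.get(ref, "N"), _COMPLEMENT.get(alt, "N")
    return {ref.upper(), alt.upper()} == {"C", "T"}


def flag_snp_probes(
    probes: list[ProbeAnnotation],
    variants: pd.DataFrame,
    window_bp: int = 20,
    maf_min: float = 0.01,
) -> list[ProbeAnnotation]:
    """Flag probes with a common variant in the CpG or the upstream window.

    ``variants`` needs columns (variant_id, chrom, pos, ref, alt, maf).
    "Upstream" runs from the interrogated CpG toward the probe 3' end:
    positions [cpg_pos - window, cpg_pos] for '+' probes and
    [cpg_pos, cpg_pos + window] for '-' probes. Type I probes additionally
    check the single-base-extension position one base beyond the window edge.
    Variants whose alleles are {C, T} on the probe strand are exempt.
    """
    common = variants[variants["maf"] > maf_min]
    for probe in probes:
        if probe.cpg_pos is None:
            raise ValueError(f"probe {probe.probe_id} lacks coordinates")
        extension = 1 if probe.probe_type == "I" else 0
        if probe.strand == "-":
            lo, hi = probe.cpg_pos, probe.cpg_pos + window_bp + extension
        else:
            lo, hi = probe.cpg_pos - window_bp - extension, probe.cpg_pos
        # CpG dinucleotide occupies two bases; include the partner base too
        hits = common[
            (common["chrom"] == probe.chrom)
            & (common["pos"] >= min(lo, probe.cpg_pos))
            & (common["pos"] <= max(hi, probe.cpg_pos + 1))
        ]
        offending = [
            rec.variant_id
            for rec in hits.itertuples(index=False)
            if not _is_ct_pair(rec.ref, rec.alt, probe.strand)
        ]
        if offending:
            probe.snp_in_probe = True
            probe.snp_ids = sorted(set(probe.snp_ids) | set(offending))
    return probes


def flag_cross_reactive(
    probes: list[ProbeAnnotation], blacklist: set[str] | list[str]
) -> list[ProbeAnnotation]:
    """Mark probes present in a cross-reactivity blacklist."""
    blacklist = set(blacklist)
    for probe in probes:
        if probe.probe_id in blacklist:
            probe.cross_reactive = True
    return probes


@dataclass
class GapSignal:
    is_gap: bool
    n_groups: int
    group_sizes: list[int]


def detect_gap_signals(
    beta: np.ndarray,
    gap_min: float = 0.05,
    outlier_cutoff: float = 0.01,
) -> GapSignal:
    """Cluster detection in a per-sample beta vector.

    Sorted values are split wherever consecutive values differ by more than
    ``gap_min``; groups of size <= ceil(outlier_cutoff * n) are discarded as
    outlier-driven. A gap signal requires >= 2 surviving groups.
    """
    x = np.asarray(beta, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("all beta values are missing")
    if (x < 0).any() or (x > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    if x.size < 20:
        raise ValueError("need at least 20 non-missing beta values")
    xs = np.sort(x)
    breaks = np.flatnonzero(np.diff(xs) > gap_min)
    sizes = np.diff(np.concatenate([[0], breaks + 1, [xs.size]])).tolist()
    threshold = math.ceil(outlier_cutoff * x.size)
    kept = [s for s in sizes if s > threshold]
    return GapSignal(is_gap=len(kept) >= 2, n_groups=len(kept), group_sizes=kept)


def annotate_probes(
    probes: list[ProbeAnnotation],
    beta_matrix: np.ndarray | None = None,
    probe_ids: list[str] | None = None,
    gap_min: float = 0.05,
    outlier_cutoff: float = 0.01,
) -> list[ProbeAnnotation]:
    """Run gap detection across a samples x probes beta matrix and set flags."""
    if beta_matrix is None:
        return probes
    if probe_ids is None:
        raise ValueError("probe_ids required with a beta matrix")
    lookup = {p: i for i, p in enumerate(probe_ids)}
    for probe in probes:
        j = lookup.get(probe.probe_id)
        if j is None:
            continue
        sig = detect_gap_signals(beta_matrix[:, j], gap_min, outlier_cutoff)
        probe.gap_probe = sig.is_gap
        probe.gap_group_sizes = sig.group_sizes
    return probes


def annotate_associations(
    associations: pd.DataFrame,
    probes: list[ProbeAnnotation],
    probe_column: str = "cpg_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split associations into (stringent, annotated_full) tables.

    Associations on excluded probes (SNP-in-probe or cross-reactive) are
    removed from the stringent set but kept, flagged, in the full table;
    gap-probe associations are flagged only and retained in both.
    Unresolvable probe ids pass through with a warning flag column empty.
    """
    lookup = {p.probe_id: p for p in probes}
    flags = []
    excluded = []
    for pid in associations[probe_column]:
        probe = lookup.get(pid)
        if probe is None:
            flags.append("")
            excluded.append(False)
            continue
        f = set()
        if probe.snp_in_probe:
            f.add("at_risk_probe")
        if probe.cross_reactive:
            f.add("cross_reactive")
        if probe.gap_probe:
            f.add("gap_probe")
        flags.append(";".join(sorted(f)))
        excluded.append(probe.disposition == "excluded")
    full = associations.copy()
    if "flags" in full.columns:
        joined = [
            ";".join(sorted(set(filter(None, (a or "").split(";"))) |
                            set(filter(None, b.split(";")))))
            for a, b in zip(full["flags"], flags)
        ]
        full["flags"] = joined
    else:
        full["flags"] = flags
    stringent = full[~np.asarray(excluded)].copy()
    return stringent, full
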