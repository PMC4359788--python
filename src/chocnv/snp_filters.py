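"""Hard filters for variant calls, coding-effect annotation and the
mutational spectrum.

Because 15-20% of CHO genes are haploid, a depth filter pegged to the
diploid median would discard most variants on single-copy genes.  The
filter therefore admits two call types with different depth demands:

* **homozygous** — total depth >= 0.25x the median CDS depth and at least
  90% of reads supporting the alternate allele (permissive on depth, so
  haploid genes at half coverage still qualify);
* **heterozygous** — total depth >= 0.75x the median CDS depth and both
  alleles supported by at least 40% of reads.

The two rules are mutually exclusive: a call with alt fraction >= 0.9 has
ref fraction <= 0.1 < 0.4.  Kept SNPs closer than 5 bp to any other call
(kept or not, SNP or indel) are removed — both members of a close pair —
and calls present in a reference self-alignment blacklist are subtracted.

The substitution spectrum counts the 12 directed substitutions on the
reference strand and collapses the complement-pair transitions into
GC->AT (G->A + C->T) and AT->GC (A->G + T->C); their ratio is the EMS
mutagenesis signature.  An optional mode additionally pools the G->T/C->A
transversions into the GC->AT class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .io_formats import GeneAnnotation, VariantCall

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

EFFECTS = ("synonymous", "missense", "nonsense", "frameshift_indel", "inframe_indel", "noncoding")


@dataclass(frozen=True)
class SnpFilterConfig:
    hom_min_depth_factor: float = 0.25  # x median CDS depth
    hom_min_alt_fraction: float = 0.90
    het_min_depth_factor: float = 0.75
    het_min_allele_fraction: float = 0.40  # both ref and alt
    proximity_bp: int = 5  # calls closer than this are removed
    blacklist: frozenset[tuple[str, int, str, str]] = frozenset()

    def __post_init__(self) -> None:
        for frac in (self.hom_min_alt_fraction, self.het_min_allele_fraction):
            if not (0 < frac <= 1):
                raise ValueError("fractions must lie in (0, 1]")
        if self.proximity_bp < 0:
            raise ValueError("proximity_bp must be >= 0")


DEFAULT_FILTER = SnpFilterConfig()


def filter_variants(
    calls: Sequence[VariantCall],
    median_cds_depth: float,
    config: SnpFilterConfig = DEFAULT_FILTER,
) -> tuple[list[VariantCall], dict[tuple, str]]:
    """Apply the zygosity, proximity and blacklist filters.

    Returns ``(kept, rejections)`` where kept calls carry their zygosity
    label and ``rejections`` maps each rejected call's key to the first rule
    it failed (``depth``, ``allele_fraction``, ``proximity``, ``blacklist``).
    Every input call lands in exactly one of the two.
    """
    if median_cds_depth <= 0:
        raise ValueError("median_cds_depth must be positive")
    hom_min = config.hom_min_depth_factor * median_cds_depth
    het_min = config.het_min_depth_factor * median_cds_depth

    kept: dict[tuple, VariantCall] = {}
    rejections: dict[tuple, str] = {}
    for call in calls:
        alt_frac = call.alt_fraction
        ref_frac = 1.0 - alt_frac
        hom_frac_ok = alt_frac >= config.hom_min_alt_fraction
        het_frac_ok = (
            alt_frac >= config.het_min_allele_fraction
            and ref_frac >= config.het_min_allele_fraction
        )
        if hom_frac_ok and call.total_depth >= hom_min:
            zygosity = "homozygous"
        elif het_frac_ok and call.total_depth >= het_min:
            zygosity = "heterozygous"
        else:
            # fraction pattern decides which rule applied; if it fits one,
            # the failure was that rule's depth bar
            rejections[call.key] = (
                "depth" if (hom_frac_ok or het_frac_ok) else "allele_fraction"
            )
            continue
        kept[call.key] = VariantCall(
            scaffold=call.scaffold,
            pos=call.pos,
            ref=call.ref,
            alt=call.alt,
            total_depth=call.total_depth,
            alt_depth=call.alt_depth,
            is_indel=call.is_indel,
            zygosity=zygosity,
        )

    # proximity: a kept SNP within < proximity_bp of ANY other input call
    # (kept or rejected, SNP or indel) is removed; spacing is |pos difference|
    positions: dict[str, list[int]] = {}
    for call in calls:
        positions.setdefault(call.scaffold, []).append(call.pos)
    for arr in positions.values():
        arr.sort()
    for key, call in list(kept.items()):
        arr = positions[call.scaffold]
        i = int(np.searchsorted(arr, call.pos))
        near = False
        for j in range(i - 2, i + 3):
            if 0 <= j < len(arr) and arr[j] != call.pos:
                if abs(arr[j] - call.pos) < config.proximity_bp:
                    near = True
                    break
        # duplicate positions (multi-allelic splits) do not count as neighbors
        if near:
            rejections[key] = "proximity"
            del kept[key]

    for key in list(kept):
        if key in config.blacklist:
            rejections[key] = "blacklist"
            del kept[key]

    return list(kept.values()), rejections


# ---------------------------------------------------------------------------
# coding-effect annotation
# ---------------------------------------------------------------------------

def _scaffold_to_cds(gene: GeneAnnotation, pos0: int) -> int | None:
    """Coding-strand CDS index of a 0-based scaffold position, or None."""
    offset = 0
    for start, end in gene.cds_intervals:
        if start <= pos0 < end:
            idx = offset + (pos0 - start)
            return gene.cds_length - 1 - idx if gene.strand == "-" else idx
        offset += end - start
    return None


def annotate_cds_effect(call: VariantCall, gene: GeneAnnotation) -> str:
    """Coding effect of a call on a gene with a CDS sequence.

    SNP effects come from standard-genetic-code translation of the affected
    codon; indels are frameshifting iff their net length change is not a
    multiple of 3.  Calls outside the CDS intervals are ``noncoding``.
    """
    if gene.cds_sequence is None:
        raise ValueError(f"{gene.gene_id}: no CDS sequence")
    if gene.cds_length % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length not a multiple of 3")
    cds_idx = _scaffold_to_cds(gene, call.pos - 1)
    if cds_idx is None:
        return "noncoding"
    if call.is_indel:
        net = len(call.alt) - len(call.ref)
        return "frameshift_indel" if net % 3 != 0 else "inframe_indel"

    alt = call.alt if gene.strand == "+" else call.alt.translate(_COMPLEMENT)
    ref = call.ref if gene.strand == "+" else call.ref.translate(_COMPLEMENT)
    seq = gene.cds_sequence.upper()
    if seq[cds_idx] != ref:
        raise ValueError(
            f"{gene.gene_id}: reference mismatch at CDS index {cds_idx} "
            f"({seq[cds_idx]} != {ref})"
        )
    codon_start = cds_idx - cds_idx % 3
    old_codon = seq[codon_start : codon_start + 3]
    new_codon = list(old_codon)
    new_codon[cds_idx % 3] = alt
    new_codon = "".join(new_codon)
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    return "missense"


def describe_aa_change(call: VariantCall, gene: GeneAnnotation) -> str | None:
    """Protein-level description like ``Thr137Arg`` for a coding SNP."""
    from Bio.SeqUtils import seq3

    if call.is_indel:
        return None
    cds_idx = _scaffold_to_cds(gene, call.pos - 1)
    if cds_idx is None:
        return None
    alt = call.alt if gene.strand == "+" else call.alt.translate(_COMPLEMENT)
    seq = gene.cds_sequence.upper()
    codon_start = cds_idx - cds_idx % 3
    old_codon = seq[codon_start : codon_start + 3]
    new_codon = list(old_codon)
    new_codon[cds_idx % 3] = alt
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq("".join(new_codon)).translate())
    return f"{seq3(old_aa)}{codon_start // 3 + 1}{seq3(new_aa)}"


# ---------------------------------------------------------------------------
# mutational spectrum
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionSpectrum:
    counts: dict[tuple[str, str], int]
    include_transversions: bool = False
    skipped: int = 0

    @property
    def gc_to_at(self) -> int:
        total = self.counts[("G", "A")] + self.counts[("C", "T")]
        if self.include_transversions:
            total += self.counts[("G", "T")] + self.counts[("C", "A")]
        return total

    @property
    def at_to_gc(self) -> int:
        total = self.counts[("A", "G")] + self.counts[("T", "C")]
        if self.include_transversions:
            total += self.counts[("A", "C")] + self.counts[("T", "G")]
        return total

    @property
    def ratio(self) -> float | None:
        """GC->AT / AT->GC count ratio; None (undefined) when the
        denominator is zero."""
        return self.gc_to_at / self.at_to_gc if self.at_to_gc else None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def substitution_spectrum(
    calls: Iterable[VariantCall], include_transversions: bool = False
) -> SubstitutionSpectrum:
    """Directed substitution counts (reference strand) of the kept SNPs.

    Indels and calls with non-ACGT alleles are skipped and counted in
    ``skipped``.
    """
    counts = {(r, a): 0 for r in "ACGT" for a in "ACGT" if r != a}
    skipped = 0
    for call in calls:
        if call.is_indel:
            skipped += 1
            continue
        key = (call.ref.upper(), call.alt.upper())
        if key not in counts:
            skipped += 1
            continue
        counts[key] += 1
    return SubstitutionSpectrum(
        counts=counts, include_transversions=include_transversions, skipped=skipped
    )


def bias_ttest(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float, str]:
    """Equal-variance two-sample t-test on per-sample spectrum ratios.

    Returns ``(t, two-sided p, stars)`` with stars at p < 0.05 (*),
    p < 0.01 (**) and p < 0.001 (***).
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(group1, group2, equal_var=True)
    if math.isnan(t):  # zero pooled variance, identical groups
        t, p = 0.0, 1.0
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return float(t), float(p), stars
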