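"""Copy-number classification of genes and CNV comparison between genomes.

Classes are assigned from normalized depth (copy-number scale):

* **deleted** — depth ~0 while the reference genome clearly carries the gene
  (reference normalized depth > 0.95);
* **unresolved** — depth ~0 in the sample *and* in the reference, so nothing
  can be said (the always-zero genes of the annotation);
* **haploid** — depth in (0, 1.3);
* **diploid** — depth in [1.3, 2.7);
* **amplified** — depth >= 2.7 (three or more copies).

The 1.3 and 2.7 cut points sit at the local density minima between the
haploid/diploid and diploid/triploid coverage peaks of a 33x genome.  Exact
boundary values are assigned upward (half-open intervals).  Pairwise CNV
calls use the raw normalized depths, not the class labels: a gene is a CNV
between two genomes when its normalized depth differs by more than 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth_profiling import GeneDepthTable
from .io_formats import GeneAnnotation

CLASSES = ("deleted", "haploid", "diploid", "amplified", "unresolved")

#: class label -> integer copy number reported in summaries (amplified = ">2")
CLASS_COPY_NUMBER = {"deleted": 0, "haploid": 1, "diploid": 2, "amplified": 3}


@dataclass(frozen=True)
class ClassificationThresholds:
    deleted_ref_min: float = 0.95  # reference depth above which absence means deletion
    haploid_max: float = 1.3
    diploid_max: float = 2.7
    cnv_diff: float = 0.95  # pairwise CNV depth-difference rule
    zero_tol: float = 0.05  # below this a normalized depth counts as "~0"

    def __post_init__(self) -> None:
        if not (0 < self.haploid_max < self.diploid_max):
            raise ValueError("need 0 < haploid_max < diploid_max")
        if self.cnv_diff <= 0:
            raise ValueError("cnv_diff must be positive")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class CopyNumberProfile:
    """Per-sample gene classification plus the normalized depths it came from."""

    sample_id: str
    classes: pd.Series  # gene_id -> class label
    normalized: pd.Series  # gene_id -> normalized depth

    def summary(self) -> dict[str, int]:
        return summarize_profile(self)

    @property
    def resolved_genes(self) -> pd.Index:
        return self.classes.index[self.classes != "unresolved"]


def classify_copy_number(
    norm_depth: float,
    ref_norm_depth: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Classify one gene from its normalized depth and the reference's."""
    if norm_depth < 0 or ref_norm_depth < 0:
        raise ValueError("normalized depths must be non-negative")
    t = thresholds
    if norm_depth <= t.zero_tol:
        return "deleted" if ref_norm_depth > t.deleted_ref_min else "unresolved"
    if norm_depth < t.haploid_max:
        return "haploid"
    if norm_depth < t.diploid_max:
        return "diploid"
    return "amplified"


def classify_profile(
    table: GeneDepthTable,
    reference: GeneDepthTable | None = None,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> CopyNumberProfile:
    """Classify every gene of a sample.

    When no reference sample is supplied an all-diploid pseudo-reference is
    assumed (every gene at normalized depth 2), so any absent gene counts as
    deleted rather than unresolved.
    """
    depths = table.normalized
    if reference is None:
        ref = pd.Series(2.0, index=depths.index)
    else:
        missing = depths.index.difference(reference.normalized.index)
        if len(missing):
            raise ValueError(f"reference lacks {len(missing)} genes: {list(missing[:5])}")
        ref = reference.normalized.reindex(depths.index)
    t = thresholds
    d = depths.to_numpy()
    r = ref.to_numpy()
    labels = np.select(
        [
            (d <= t.zero_tol) & (r > t.deleted_ref_min),
            d <= t.zero_tol,
            d < t.haploid_max,
            d < t.diploid_max,
        ],
        ["deleted", "unresolved", "haploid", "diploid"],
        default="amplified",
    )
    return CopyNumberProfile(
        sample_id=table.sample_id,
        classes=pd.Series(labels, index=depths.index),
        normalized=depths.copy(),
    )


def summarize_profile(profile: CopyNumberProfile) -> dict[str, int]:
    """Class counts: CN=0 / CN=1 / CN=2 / CN>2, unresolved reported separately."""
    counts = profile.classes.value_counts()
    return {
        "cn0": int(counts.get("deleted", 0)),
        "cn1": int(counts.get("haploid", 0)),
        "cn2": int(counts.get("diploid", 0)),
        "cn3plus": int(counts.get("amplified", 0)),
        "unresolved": int(counts.get("unresolved", 0)),
    }


def compare_profiles(
    profile_a: CopyNumberProfile,
    profile_b: CopyNumberProfile,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> tuple[set[str], set[str], set[str]]:
    """Genes reduced / increased / unchanged in *b* relative to *a*.

    A gene counts as reduced when ``depth_a - depth_b > cnv_diff`` and as
    increased when ``depth_b - depth_a > cnv_diff`` (strict inequalities).
    Genes unresolved in either profile are excluded entirely.
    """
    if set(profile_a.classes.index) != set(profile_b.classes.index):
        diff = set(profile_a.classes.index) ^ set(profile_b.classes.index)
        raise ValueError(f"gene universes differ by {len(diff)} genes: {sorted(diff)[:5]}")
    usable = profile_a.resolved_genes.intersection(profile_b.resolved_genes)
    a = profile_a.normalized.reindex(usable)
    b = profile_b.normalized.reindex(usable)
    delta = a - b
    # strict ">" at the threshold, robust to binary rounding of 0.95
    reduced = set(usable[delta > thresholds.cnv_diff + 1e-9])
    increased = set(usable[-delta > thresholds.cnv_diff + 1e-9])
    unchanged = set(usable) - reduced - increased
    return reduced, increased, unchanged


def assign_chromosome(
    hits: Mapping[str, Sequence[tuple[str, float]]],
    cutoff: float = 0.05,
) -> tuple[dict[str, str], set[str]]:
    """Chromosome of each gene from a precomputed similarity-hit table.

    The best hit is the one with minimal E-value at or below ``cutoff``;
    genes without a qualifying hit map to "unplaced".  E-value ties break to
    the lexicographically smallest chromosome and flag the gene ambiguous.
    """
    assignment: dict[str, str] = {}
    ambiguous: set[str] = set()
    for gene_id, gene_hits in hits.items():
        qualifying = [(e, chrom) for chrom, e in gene_hits if e <= cutoff]
        if not qualifying:
            assignment[gene_id] = "unplaced"
            continue
        qualifying.sort()
        best_e = qualifying[0][0]
        tied = [chrom for e, chrom in qualifying if e == best_e]
        if len(tied) > 1:
            ambiguous.add(gene_id)
        assignment[gene_id] = min(tied)
    return assignment, ambiguous


def chromosome_signature(
    profiles: Mapping[str, CopyNumberProfile],
    annotation: Sequence[GeneAnnotation],
    reference: CopyNumberProfile,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-chromosome CNV percentages for each sample versus the reference.

    Returns a DataFrame indexed by sample with a two-level column per
    chromosome: the percentage of that chromosome's resolvable genes in the
    reduced (resp. increased) set of the sample/reference comparison.
    Chromosome labels come from the annotation, where chromosomes nine and
    ten are a single merged "9/10" label.
    """
    chrom_of = {g.gene_id: g.chromosome for g in annotation}
    chromosomes = sorted({g.chromosome for g in annotation})
    rows = {}
    for sample_id, profile in profiles.items():
        reduced, increased, unchanged = compare_profiles(
            reference, profile, thresholds
        )
        usable = reduced | increased | unchanged
        row = {}
        for chrom in chromosomes:
            genes = {g for g in usable if chrom_of.get(g) == chrom}
            n = len(genes)
            row[(chrom, "pct_reduced")] = 100.0 * len(genes & reduced) / n if n else 0.0
            row[(chrom, "pct_increased")] = 100.0 * len(genes & increased) / n if n else 0.0
        rows[sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame.sort_index(axis=1)
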