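"""Synthetic multi-sample CHO-like genomes with known ground truth.

The generator emulates the statistical structure the depth-based analysis
assumes: a universe of ~20,661 protein-coding genes (~1.7 kb CDS on
average) laid out on scaffolds assigned to 11 chromosome labels, per-sample
integer copy numbers for every gene, per-base sequencing depth that is
Poisson around ``copy_number x (diploid_median_depth / 2)``, and variant
calls whose zygosity follows gene copy number and whose substitution
spectrum carries a tunable GC->AT excess (the EMS mutagenesis signature).

Copy-number presets reproduce the per-class gene counts observed for the
nine sequenced CHO cell lines plus the Chinese hamster reference
(:data:`CELL_LINE_PRESETS`).  Because the cell lines share a clonal history,
preset copy-number maps are built hierarchically: a block of CNV events
common to every CHO line, blocks shared within lineage groups (the CHO-K1
family; DXB11 and its F435 transfectant; CHO-S and C0101; DG44 alone), and
private per-line events topping each class up to its exact target count.
Distances between the resulting profiles therefore recover the lineage
grouping, while each sample's marginal class counts match its preset row.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DepthTrack, GeneAnnotation, VariantCall

CHROMOSOME_LABELS = ("1", "2", "3", "4", "5", "6", "7", "8", "9/10", "X", "unplaced")

#: per-class gene counts (CN=0, CN=1, CN=2, CN>2) observed for the hamster
#: reference and the nine sequenced CHO cell lines; each row sums to 20,661
CELL_LINE_PRESETS: dict[str, tuple[int, int, int, int]] = {
    "C_griseus": (0, 0, 20661, 0),
    "CHO-K1_ATCC": (30, 3773, 15305, 1553),
    "CHO-K1_ECACC": (57, 4039, 13310, 3255),
    "CHO-K1_PF": (54, 3356, 15059, 2192),
    "CHO-K1_SF": (48, 3073, 15453, 2087),
    "CHO_DXB11": (44, 3586, 15267, 1764),
    "F435": (53, 3888, 14306, 2414),
    "CHO_DG44": (62, 4219, 13967, 2413),
    "CHO-S": (47, 3024, 15603, 1987),
    "C0101": (37, 3544, 15088, 1992),
}

#: lineage groups sharing CNV events beyond the pan-CHO block
LINEAGE_GROUPS: dict[str, tuple[str, ...]] = {
    "K1": ("CHO-K1_ATCC", "CHO-K1_ECACC", "CHO-K1_PF", "CHO-K1_SF"),
    "DX": ("CHO_DXB11", "F435"),
    "S": ("CHO-S", "C0101"),
    "DG": ("CHO_DG44",),
}

_SHARE_ALL = 0.65  # fraction of the minimum class count shared by every CHO line
_SHARE_GROUP = 0.75  # fraction of the remaining minimum shared within a lineage group

_BASES = np.array(list("ACGT"))
_EMS_PAIRS = {("G", "A"), ("C", "T")}  # the GC->AT transitions EMS favors


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic genome; defaults mirror the study conditions."""

    n_genes: int = 20661
    mean_cds_length: int = 1700  # bp; gamma-distributed, min 300, multiple of 3
    diploid_median_depth: float = 33.0  # x-coverage of a CN=2 gene
    overdispersion: float = 0.0  # 0 = Poisson; >0 adds var = mu + od*mu^2
    ems_bias: float = 1.0  # weight multiplier on G->A / C->T substitutions
    het_fraction: float = 0.5  # fraction of diploid-gene variants heterozygous
    snp_rate: float = 6e-4  # per CDS base
    indel_rate: float = 1e-5  # per CDS base
    blacklist_fraction: float = 0.0  # artifact calls also emitted to a blacklist
    genes_per_scaffold: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.diploid_median_depth <= 0:
            raise ValueError("diploid_median_depth must be positive")
        if self.overdispersion < 0 or self.ems_bias <= 0:
            raise ValueError("overdispersion >= 0 and ems_bias > 0 required")

    @property
    def haploid_depth(self) -> float:
        """Mean depth of a single-copy gene: half the diploid median."""
        return self.diploid_median_depth / 2.0


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Generate the gene universe with CDS sequences.

    CDS lengths are gamma(shape=4) with the configured mean, floored at
    300 bp and rounded to a codon multiple.  Scaffolds carry
    ``genes_per_scaffold`` genes each and rotate through the chromosome
    labels; 30% of genes get two CDS exons separated by a 150 bp intron, and
    strands alternate so both orientations are exercised downstream.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    lengths = rng.gamma(shape=4.0, scale=config.mean_cds_length / 4.0, size=n)
    lengths = np.maximum(300, (np.round(lengths / 3).astype(int) * 3))
    two_exon = rng.random(n) < 0.3
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    genes: list[GeneAnnotation] = []
    n_scaffolds = math.ceil(n / config.genes_per_scaffold)
    gene_idx = 0
    width = len(str(n - 1))
    for s in range(n_scaffolds):
        scaffold = f"scaffold_{s:05d}"
        chromosome = CHROMOSOME_LABELS[s % len(CHROMOSOME_LABELS)]
        cursor = 200  # leading intergenic margin
        for _ in range(config.genes_per_scaffold):
            if gene_idx >= n:
                break
            length = int(lengths[gene_idx])
            if two_exon[gene_idx] and length >= 600:
                exon1 = (length // 2) // 3 * 3
                intervals = (
                    (cursor, cursor + exon1),
                    (cursor + exon1 + 150, cursor + length + 150),
                )
                span = length + 150
            else:
                intervals = ((cursor, cursor + length),)
                span = length
            seq = "".join(rng.choice(_BASES, size=length))
            genes.append(
                GeneAnnotation(
                    gene_id=f"g{gene_idx:0{width}d}",
                    scaffold=scaffold,
                    chromosome=chromosome,
                    cds_intervals=intervals,
                    strand=str(strands[gene_idx]),
                    cds_sequence=seq,
                )
            )
            cursor += span + 300  # intergenic gap
            gene_idx += 1
    return genes


def generate_go_table(
    annotation: Sequence[GeneAnnotation],
    config: SimulationConfig,
    n_terms: int = 50,
    mean_terms_per_gene: float = 2.0,
    planted: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Random flat gene -> GO-term annotation.

    Terms are assigned independently per gene (Poisson number of terms,
    uniform term choice).  ``planted`` optionally forces specific genes to
    carry specific terms, so enrichment recovery can be tested against a
    known signal.
    """
    rng = _rng(config, 5)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    table: dict[str, set[str]] = {}
    for gene in annotation:
        k = min(rng.poisson(mean_terms_per_gene), n_terms)
        if k:
            table[gene.gene_id] = set(rng.choice(terms, size=k, replace=False))
    if planted:
        for gene_id, forced in planted.items():
            table.setdefault(gene_id, set()).update(forced)
    return {g: frozenset(t) for g, t in table.items()}


def scaffold_lengths(annotation: Sequence[GeneAnnotation]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for g in annotation:
        end = g.cds_intervals[-1][1] + 200
        lengths[g.scaffold] = max(lengths.get(g.scaffold, 0), end)
    return lengths


# ---------------------------------------------------------------------------
# copy-number presets
# ---------------------------------------------------------------------------

def preset_counts(sample: str, n_genes: int) -> tuple[int, int, int, int]:
    """Preset class counts, rescaled proportionally when ``n_genes != 20661``."""
    counts = CELL_LINE_PRESETS[sample]
    total = sum(counts)
    if n_genes == total:
        return counts
    scaled = [round(c * n_genes / total) for c in counts[:3]]
    scaled.append(n_genes - sum(scaled))
    return tuple(scaled)  # type: ignore[return-value]


def preset_cn_maps(
    config: SimulationConfig, samples: Sequence[str] | None = None
) -> dict[str, dict[str, int]]:
    """Copy-number maps for the requested preset samples.

    Hierarchical event sharing (pan-CHO, lineage-group, private blocks)
    makes related lines share most of their CNVs while each sample's class
    counts hit its preset exactly.  Amplified genes get CN=3, the smallest
    copy number consistent with the CN>2 class.
    """
    if samples is None:
        samples = list(CELL_LINE_PRESETS)
    unknown = set(samples) - set(CELL_LINE_PRESETS)
    if unknown:
        raise ValueError(f"unknown presets: {sorted(unknown)}")
    rng = _rng(config, 2)
    n = config.n_genes
    width = len(str(n - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    cho_lines = [s for s in samples if s != "C_griseus"]
    counts = {s: preset_counts(s, n) for s in samples}
    class_cn = {0: 0, 1: 1, 3: 3}  # class index in counts tuple -> copy number
    class_slot = {0: 0, 1: 1, 3: 3}

    pool = rng.permutation(n)
    cursor = 0
    cn: dict[str, np.ndarray] = {s: np.full(n, 2, dtype=np.int16) for s in samples}
    assigned: dict[str, np.ndarray] = {s: np.zeros(n, dtype=bool) for s in samples}

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        block = pool[cursor : cursor + k]
        cursor += k
        return block

    remaining_need = {s: {c: counts[s][0 if c == 0 else (1 if c == 1 else 3)] for c in (0, 1, 3)} for s in samples}

    if cho_lines:
        for c in (0, 1, 3):
            slot = 0 if c == 0 else (1 if c == 1 else 3)
            m_all = int(_SHARE_ALL * min(counts[s][slot] for s in cho_lines))
            if m_all > 0:
                block = take(m_all)
                for s in cho_lines:
                    cn[s][block] = class_cn[c]
                    assigned[s][block] = True
                    remaining_need[s][c] -= m_all
            for group_lines in LINEAGE_GROUPS.values():
                members = [s for s in group_lines if s in cho_lines]
                if not members:
                    continue
                m_group = int(_SHARE_GROUP * min(remaining_need[s][c] for s in members))
                if m_group <= 0:
                    continue
                block = take(m_group)
                for s in members:
                    cn[s][block] = class_cn[c]
                    assigned[s][block] = True
                    remaining_need[s][c] -= m_group

    # private top-up: each line draws from its own permutation of the genes
    # it has not yet used, so lines may coincide by chance (homoplasy) but a
    # line never assigns two classes to one gene
    for s in cho_lines:
        free = np.flatnonzero(~assigned[s])
        order = rng.permutation(free)
        offset = 0
        for c in (0, 1, 3):
            need = remaining_need[s][c]
            if need < 0:
                raise ValueError(f"{s}: sharing blocks exceed class-{c} target")
            block = order[offset : offset + need]
            offset += need
            cn[s][block] = class_cn[c]
            assigned[s][block] = True

    return {s: dict(zip(gene_ids, map(int, cn[s]))) for s in samples}


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------

def simulate_depth(
    annotation: Sequence[GeneAnnotation],
    cn_map: Mapping[str, int],
    config: SimulationConfig,
    sample_id: str = "sample",
    stream: int = 0,
) -> DepthTrack:
    """Per-base depth ~ Poisson(cn * haploid_depth) over each gene's span.

    Intergenic bases sit at the diploid background.  With
    ``overdispersion > 0`` a negative binomial with variance
    ``mu + overdispersion * mu^2`` replaces the Poisson.  Genes with copy
    number 0 get exactly zero depth over their whole span.
    """
    for gene in annotation:
        if cn_map[gene.gene_id] < 0:
            raise ValueError(f"{gene.gene_id}: negative copy number")
    rng = _rng(config, 3, stream)
    h = config.haploid_depth
    lengths = scaffold_lengths(annotation)
    track = DepthTrack(sample_id=sample_id)
    lam: dict[str, np.ndarray] = {
        s: np.full(length, 2.0 * h) for s, length in lengths.items()
    }
    for gene in annotation:
        span = (gene.cds_intervals[0][0], gene.cds_intervals[-1][1])
        lam[gene.scaffold][span[0] : span[1]] = cn_map[gene.gene_id] * h
    for scaffold, mu in lam.items():
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            rate = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.size) / shape, 0.0)
            depths = rng.poisson(mu * rate)
        else:
            depths = rng.poisson(mu)
        track.depths[scaffold] = depths.astype(np.int32)
    return track


def simulate_gene_depths(
    annotation: Sequence[GeneAnnotation],
    cn_map: Mapping[str, int],
    config: SimulationConfig,
    stream: int = 0,
) -> dict[str, float]:
    """Per-gene median CDS depth drawn directly, without materializing a track.

    Statistically identical to running :func:`simulate_depth` followed by the
    per-gene median (same per-base model, CDS bases only); used for large
    multi-sample simulations where full tracks would dominate memory.
    """
    rng = _rng(config, 3, stream)
    h = config.haploid_depth
    medians: dict[str, float] = {}
    for gene in annotation:
        cn = cn_map[gene.gene_id]
        if cn < 0:
            raise ValueError(f"{gene.gene_id}: negative copy number")
        size = gene.cds_length
        mu = cn * h
        if mu == 0:
            medians[gene.gene_id] = 0.0
            continue
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            rate = rng.gamma(shape, 1.0, size=size) / shape
            depths = rng.poisson(mu * rate)
        else:
            depths = rng.poisson(mu, size=size)
        medians[gene.gene_id] = float(np.median(depths))
    return medians


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------

def substitution_weights(ems_bias: float) -> dict[tuple[str, str], float]:
    """Unnormalized weight of each directed substitution given its ref base.

    Within a ref base the three alternatives are equally likely except that
    the EMS-favored transitions G->A and C->T carry weight ``ems_bias``.
    """
    weights = {}
    for ref in "ACGT":
        for alt in "ACGT":
            if alt == ref:
                continue
            weights[(ref, alt)] = ems_bias if (ref, alt) in _EMS_PAIRS else 1.0
    return weights


def expected_spectrum_ratio(base_fractions: Mapping[str, float], ems_bias: float) -> float:
    """Expected GC->AT / AT->GC transition-count ratio under the generator.

    Computed by enumerating the per-base category probabilities: a site with
    ref base b mutates to alt a with probability w(b,a)/sum_a' w(b,a').
    """
    w = substitution_weights(ems_bias)
    p = {
        pair: base_fractions[pair[0]]
        * w[pair]
        / sum(w[(pair[0], a)] for a in "ACGT" if a != pair[0])
        for pair in w
    }
    return (p[("G", "A")] + p[("C", "T")]) / (p[("A", "G")] + p[("T", "C")])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _cds_to_scaffold(gene: GeneAnnotation, cds_index: int) -> int:
    """0-based scaffold coordinate of 0-based coding-strand CDS index."""
    if gene.strand == "-":
        cds_index = gene.cds_length - 1 - cds_index
    for start, end in gene.cds_intervals:
        span = end - start
        if cds_index < span:
            return start + cds_index
        cds_index -= span
    raise IndexError("CDS index out of range")


def simulate_variants(
    annotation: Sequence[GeneAnnotation],
    cn_map: Mapping[str, int],
    config: SimulationConfig,
    stream: int = 0,
) -> tuple[list[VariantCall], pd.DataFrame, list[VariantCall]]:
    """Variant calls over CDS regions, with a ground-truth table.

    Returns ``(calls, truth, blacklist)``.  SNP count per gene is binomial
    in its CDS length; positions are kept >= 6 bp apart within a gene so the
    proximity filter does not erase intended calls.  Zygosity follows copy
    number: haploid-gene variants are homozygous (alt fraction near 1 at the
    haploid depth), diploid-gene variants are heterozygous with probability
    ``het_fraction`` (alt depth binomial at fraction 0.5) and homozygous
    otherwise.  A ``blacklist_fraction`` of extra artifact calls is emitted
    both in the call list and in the returned blacklist, emulating variants
    that a reference self-alignment would also produce.
    """
    rng = _rng(config, 4, stream)
    h = config.haploid_depth
    weights = substitution_weights(config.ems_bias)
    calls: list[VariantCall] = []
    truth_rows: list[dict] = []
    blacklist: list[VariantCall] = []

    def emit(gene: GeneAnnotation, cds_idx: int, is_indel: bool, artifact: bool) -> None:
        cn = cn_map[gene.gene_id]
        seq = gene.cds_sequence
        coding_ref = seq[cds_idx]
        scaffold_pos0 = _cds_to_scaffold(gene, cds_idx)
        ref = coding_ref if gene.strand == "+" else coding_ref.translate(_COMPLEMENT)
        if is_indel:
            net = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            ins = "".join(rng.choice(_BASES, size=abs(net)))
            alt = ref + ins if net > 0 else ref
            ref_allele = ref if net > 0 else ref + ins
            category = "indel"
        else:
            alts = [a for a in "ACGT" if a != ref]
            w = np.array([weights[(ref, a)] for a in alts])
            alt = str(rng.choice(np.array(alts), p=w / w.sum()))
            ref_allele = ref
            category = f"{ref}>{alt}"
        if cn == 1 or (cn >= 3):
            zygosity, alt_p, depth_mu = "homozygous", 0.98, cn * h
        elif rng.random() < config.het_fraction:
            zygosity, alt_p, depth_mu = "heterozygous", 0.5, cn * h
        else:
            zygosity, alt_p, depth_mu = "homozygous", 0.98, cn * h
        total = max(1, int(rng.poisson(depth_mu)))
        alt_depth = int(rng.binomial(total, alt_p))
        call = VariantCall(
            scaffold=gene.scaffold,
            pos=scaffold_pos0 + 1,
            ref=ref_allele,
            alt=alt,
            total_depth=total,
            alt_depth=alt_depth,
            is_indel=is_indel,
        )
        calls.append(call)
        if artifact:
            blacklist.append(call)
        truth_rows.append(
            {
                "scaffold": call.scaffold,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "gene_id": gene.gene_id,
                "zygosity": "artifact" if artifact else zygosity,
                "category": category,
                "copy_number": cn,
            }
        )

    for gene in annotation:
        cn = cn_map[gene.gene_id]
        if cn == 0 or gene.cds_sequence is None:
            continue
        n_snp = rng.binomial(gene.cds_length, config.snp_rate)
        n_indel = rng.binomial(gene.cds_length, config.indel_rate)
        n_black = rng.binomial(n_snp, config.blacklist_fraction) if n_snp else 0
        total_sites = n_snp + n_indel + n_black
        if total_sites == 0:
            continue
        positions = np.sort(rng.choice(gene.cds_length - 1, size=min(total_sites, gene.cds_length - 1), replace=False))
        spaced = [int(positions[0])] if len(positions) else []
        for p in positions[1:]:
            if p - spaced[-1] >= 6:
                spaced.append(int(p))
        kinds = (["snp"] * n_snp + ["indel"] * n_indel + ["artifact"] * n_black)[: len(spaced)]
        for cds_idx, kind in zip(spaced, kinds):
            emit(gene, cds_idx, is_indel=(kind == "indel"), artifact=(kind == "artifact"))

    calls.sort(key=lambda c: (c.scaffold, c.pos))
    truth = pd.DataFrame(
        truth_rows,
        columns=["scaffold", "pos", "ref", "alt", "gene_id", "zygosity", "category", "copy_number"],
    ).sort_values(["scaffold", "pos"], ignore_index=True)
    return calls, truth, blacklist
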