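"""Readers and writers for the external formats the pipeline touches.

All coordinate conversion happens here, at the boundary:

* gene annotation tables are BED-like, **0-based half-open**;
* depth tracks (``genomeCoverageBed -d`` dialect) and VCF are **1-based**.

Internally every interval is 0-based half-open and every point position is
stored 1-based only inside :class:`VariantCall` (mirroring VCF), with helpers
to convert.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import dendropy


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: the unit of every per-gene statistic.

    ``cds_intervals`` are 0-based half-open scaffold coordinates, sorted and
    non-overlapping.  ``cds_sequence``, when present, is the coding-strand
    nucleotide sequence and must match the total interval length.
    """

    gene_id: str
    scaffold: str
    chromosome: str  # "1".."8", "9/10", "X" or "unplaced"
    cds_intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start < 0 or end <= start:
                raise ValueError(f"{self.gene_id}: bad interval ({start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: intervals overlap or unsorted")
            prev_end = end
        if self.cds_length < 1:
            raise ValueError(f"{self.gene_id}: empty CDS")
        if self.cds_sequence is not None and len(self.cds_sequence) != self.cds_length:
            raise ValueError(
                f"{self.gene_id}: cds_sequence length {len(self.cds_sequence)} "
                f"!= interval total {self.cds_length}"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def gc_fraction(self) -> float | None:
        if not self.cds_sequence:
            return None
        seq = self.cds_sequence.upper()
        return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class DepthTrack:
    """Per-base sequencing depth, one dense vector per scaffold."""

    sample_id: str
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def scaffold_depth(self, scaffold: str) -> np.ndarray | None:
        return self.depths.get(scaffold)


@dataclass(frozen=True)
class VariantCall:
    """A single called variant (one ALT allele), positions 1-based as in VCF."""

    scaffold: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    is_indel: bool = False
    zygosity: str | None = None  # set by the SNP filter

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.scaffold}:{self.pos}: ref == alt")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"{self.scaffold}:{self.pos}: alt_depth > total_depth "
                f"({self.alt_depth} > {self.total_depth})"
            )
        if not self.is_indel and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(f"{self.scaffold}:{self.pos}: SNP alleles must be length 1")

    @property
    def alt_fraction(self) -> float:
        return self.alt_depth / self.total_depth if self.total_depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.scaffold, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# depth tracks (genomeCoverageBed -d dialect)
# ---------------------------------------------------------------------------

def read_depth_track(path: str | os.PathLike, sample_id: str) -> DepthTrack:
    """Read a 3-column per-base depth TSV (scaffold, 1-based pos, depth).

    Positions must be contiguous from 1 within each scaffold: gaps are a
    parse error, never silently zero-filled.  The per-interval ``-bga``
    dialect (4 columns) is rejected.
    """
    track = DepthTrack(sample_id=sample_id)
    current: str | None = None
    values: list[int] = []

    def flush() -> None:
        if current is not None:
            track.depths[current] = np.asarray(values, dtype=np.int32)

    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (genomeCoverageBed -d), "
                    f"got {len(parts)}"
                )
            scaffold, pos_s, depth_s = parts
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            if scaffold != current:
                if scaffold in track.depths:
                    raise FormatError(f"{path}:{lineno}: scaffold {scaffold} not contiguous")
                flush()
                current = scaffold
                values = []
            expected = len(values) + 1
            if pos != expected:
                raise FormatError(
                    f"{path}:{lineno}: non-contiguous position {pos} on {scaffold} "
                    f"(expected {expected})"
                )
            values.append(depth)
    flush()
    return track


def write_depth_track(track: DepthTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for scaffold in track.depths:
            for i, depth in enumerate(track.depths[scaffold], 1):
                handle.write(f"{scaffold}\t{i}\t{int(depth)}\n")


# ---------------------------------------------------------------------------
# gene annotation table (BED-like TSV + optional CDS FASTA)
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "scaffold", "chromosome", "strand", "cds_intervals"]


def read_gene_table(
    path: str | os.PathLike, fasta: str | os.PathLike | None = None
) -> list[GeneAnnotation]:
    """Read the gene annotation TSV; intervals are 0-based half-open
    ``start-end`` pairs joined by commas.  Duplicate gene ids are rejected.

    ``fasta`` optionally supplies coding-strand CDS sequences keyed by gene id.
    """
    sequences: dict[str, str] = {}
    if fasta is not None:
        from Bio import SeqIO

        for record in SeqIO.parse(str(fasta), "fasta"):
            sequences[record.id] = str(record.seq).upper()

    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise FormatError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(handle, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, scaffold, chromosome, strand, intervals_s = line.split("\t")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            intervals = tuple(
                (int(a), int(b))
                for a, b in (part.split("-") for part in intervals_s.split(","))
            )
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    scaffold=scaffold,
                    chromosome=chromosome,
                    strand=strand,
                    cds_intervals=intervals,
                    cds_sequence=sequences.get(gene_id),
                )
            )
    return genes


def write_gene_table(
    genes: Sequence[GeneAnnotation],
    path: str | os.PathLike,
    fasta: str | os.PathLike | None = None,
) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            intervals = ",".join(f"{a}-{b}" for a, b in g.cds_intervals)
            handle.write(
                f"{g.gene_id}\t{g.scaffold}\t{g.chromosome}\t{g.strand}\t{intervals}\n"
            )
    if fasta is not None:
        with open(fasta, "w") as handle:
            for g in genes:
                if g.cds_sequence:
                    handle.write(f">{g.gene_id}\n{g.cds_sequence}\n")


# ---------------------------------------------------------------------------
# variants (minimal VCF v4.2 subset)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt...)">
##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indel call">
"""


def read_variants(path: str | os.PathLike) -> tuple[list[VariantCall], list[str]]:
    """Read variant calls from a VCF with INFO/DP and INFO/AD.

    Returns ``(calls, skip_log)``.  Multi-allelic records are split into one
    call per ALT, alt depth taken from the matching AD slot; records with no
    ALT are skipped and logged.  Missing depth fields are an error.
    """
    calls: list[VariantCall] = []
    skipped: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts or rec.alts == (".",):
                skipped.append(f"{rec.chrom}:{rec.pos} no ALT allele")
                continue
            info = rec.info
            if "DP" not in info or "AD" not in info:
                raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks DP/AD")
            total_depth = int(info["DP"])
            ad = tuple(int(x) for x in info["AD"])
            if len(ad) != 1 + len(rec.alts):
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} AD has {len(ad)} slots "
                    f"for {len(rec.alts)} ALT alleles"
                )
            for i, alt in enumerate(rec.alts):
                is_indel = len(rec.ref) != len(alt)
                calls.append(
                    VariantCall(
                        scaffold=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        total_depth=total_depth,
                        alt_depth=ad[1 + i],
                        is_indel=is_indel,
                    )
                )
    return calls, skipped


def write_variants(
    calls: Iterable[VariantCall],
    path: str | os.PathLike,
    filters: Mapping[tuple, str] | None = None,
) -> None:
    """Write calls as a minimal VCF; ``filters`` optionally maps a call key
    to the FILTER string naming the rule it failed (PASS otherwise)."""
    filters = filters or {}
    calls = list(calls)
    with open(path, "w") as handle:
        handle.write(_VCF_HEADER)
        for scaffold in sorted({c.scaffold for c in calls}):
            handle.write(f"##contig=<ID={scaffold}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            flt = filters.get(c.key, "PASS")
            info = f"DP={c.total_depth};AD={c.total_depth - c.alt_depth},{c.alt_depth}"
            if c.is_indel:
                info += ";INDEL"
            handle.write(
                f"{c.scaffold}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{flt}\t{info}\n"
            )


# ---------------------------------------------------------------------------
# GO annotation flat file (gene_id TAB comma-separated GO ids)
# ---------------------------------------------------------------------------

def read_go_table(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    table: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            gene_id, terms_s = parts
            terms = frozenset(t for t in terms_s.split(",") if t)
            if not all(terms):
                raise FormatError(f"{path}:{lineno}: empty GO term id")
            table[gene_id] = terms
    return table


def write_go_table(table: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for gene_id in table:
            handle.write(f"{gene_id}\t{','.join(sorted(table[gene_id]))}\n")


# ---------------------------------------------------------------------------
# trees and matrices
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    labels = [
        leaf.taxon.label if leaf.taxon is not None else leaf.label
        for leaf in tree.leaf_node_iter()
    ]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
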