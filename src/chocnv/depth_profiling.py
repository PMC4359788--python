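"""Per-gene depth statistics on the copy-number scale.

The per-gene raw depth is the median sequencing depth over every CDS base of
the gene (all CDS intervals pooled, introns excluded).  Normalizing each raw
depth by half the genome-wide median of the per-gene medians puts genes on a
copy-number scale where a diploid gene scores ~2: a genome sequenced to a
diploid median of 33x shows modes near 1.0 (16.5x, haploid), 2.0 (33x) and
3.0 (49.5x, triploid).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .io_formats import DepthTrack, GeneAnnotation

log = logging.getLogger(__name__)

#: fallback class boundaries (haploid/diploid, diploid/triploid) on the
#: normalized-depth scale, used when mode detection finds fewer than 3 modes
DEFAULT_BOUNDARIES = (1.3, 2.7)


@dataclass
class GeneDepthTable:
    """Per-sample table of raw and normalized per-gene depths.

    ``uncovered`` lists genes whose scaffold was absent from the depth track;
    they carry normalized depth 0 but are excluded from the genome median so
    that missing data is never mistaken for deletion.
    """

    sample_id: str
    raw: pd.Series  # gene_id -> raw median CDS depth
    normalized: pd.Series  # gene_id -> depth on the copy-number scale
    uncovered: frozenset[str] = frozenset()

    @property
    def gene_ids(self) -> pd.Index:
        return self.raw.index


def gene_median_depth(
    track: DepthTrack, annotation: Sequence[GeneAnnotation]
) -> tuple[dict[str, float], set[str]]:
    """Median depth over every CDS base of each gene.

    Returns ``(medians, uncovered)`` where *uncovered* holds genes whose
    scaffold is missing from the track.  The even-count median is the mean of
    the two middle values (numpy's convention).
    """
    medians: dict[str, float] = {}
    uncovered: set[str] = set()
    for gene in annotation:
        depths = track.scaffold_depth(gene.scaffold)
        if depths is None:
            uncovered.add(gene.gene_id)
            continue
        parts = []
        for start, end in gene.cds_intervals:
            if end > len(depths):
                raise ValueError(
                    f"{gene.gene_id}: CDS interval ({start},{end}) exceeds "
                    f"scaffold {gene.scaffold} length {len(depths)}"
                )
            parts.append(depths[start:end])
        pooled = parts[0] if len(parts) == 1 else np.concatenate(parts)
        medians[gene.gene_id] = float(np.median(pooled))
    return medians, uncovered


def normalize_depths(
    raw: Mapping[str, float],
    sample_id: str = "",
    uncovered: set[str] | None = None,
) -> GeneDepthTable:
    """Normalize per-gene raw depths by 0.5x their genome-wide median.

    The median over covered genes of the normalized depth is exactly 2.0 by
    construction; the transform is invariant under rescaling of all raws.
    """
    uncovered = uncovered or set()
    raw_series = pd.Series(dict(raw), dtype=float).sort_index()
    if raw_series.empty:
        raise ValueError("no covered genes")
    genome_median = float(raw_series.median())
    if genome_median <= 0:
        raise ValueError("no usable coverage: genome median depth is 0")
    normalized = raw_series / (0.5 * genome_median)
    if uncovered:
        pad = pd.Series(0.0, index=sorted(uncovered))
        raw_series = pd.concat([raw_series, pad]).sort_index()
        normalized = pd.concat([normalized, pad]).sort_index()
    return GeneDepthTable(
        sample_id=sample_id,
        raw=raw_series,
        normalized=normalized,
        uncovered=frozenset(uncovered),
    )


def profile_sample(
    track: DepthTrack, annotation: Sequence[GeneAnnotation]
) -> GeneDepthTable:
    """Convenience: per-gene medians followed by normalization."""
    medians, uncovered = gene_median_depth(track, annotation)
    return normalize_depths(medians, sample_id=track.sample_id, uncovered=uncovered)


def depth_histogram(
    table: GeneDepthTable, bin_width: float = 0.05
) -> pd.DataFrame:
    """Histogram of normalized depths as (bin_left, count) rows."""
    values = table.normalized.to_numpy()
    upper = max(4.0, float(values.max()) + bin_width)
    edges = np.arange(0.0, upper + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})


def find_class_boundaries(
    table: GeneDepthTable,
    bandwidth: float = 0.1,
    min_mode_height: float = 0.02,
) -> tuple[float, float]:
    """Locate the haploid/diploid and diploid/triploid class boundaries.

    A Gaussian-kernel density of the normalized depths (absolute bandwidth
    ``bandwidth``) is scanned for modes above ``min_mode_height`` (a fraction
    of the maximum density).  Using the three lowest non-zero modes, the
    boundaries are the density minima between consecutive mode pairs.  With
    fewer than three detected modes the defaults ``(1.3, 2.7)`` are returned
    with a warning.
    """
    values = table.normalized.to_numpy()
    values = values[values > 0.2]  # the deleted-gene mode at 0 is not a class boundary
    if len(values) < 100 or np.ptp(values) < 1e-9:
        warnings.warn("too few genes or degenerate depths; using default boundaries")
        return DEFAULT_BOUNDARIES
    kde = gaussian_kde(values, bw_method=bandwidth / values.std(ddof=1))
    grid = np.linspace(0.2, max(3.5, values.max()), 1024)
    density = kde(grid)
    peaks, _ = find_peaks(density, height=min_mode_height * density.max())
    if len(peaks) < 3:
        warnings.warn(
            f"only {len(peaks)} depth modes detected; "
            f"falling back to default boundaries {DEFAULT_BOUNDARIES}"
        )
        return DEFAULT_BOUNDARIES
    modes = grid[peaks[:3]]
    boundaries = []
    for lo, hi in zip(modes[:-1], modes[1:]):
        window = (grid > lo) & (grid < hi)
        boundaries.append(float(grid[window][np.argmin(density[window])]))
    return (boundaries[0], boundaries[1])
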