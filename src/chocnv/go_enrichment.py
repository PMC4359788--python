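"""Fisher's-exact GO-term enrichment among amplified or reduced genes.

For each sample the gene sets with copy number reduced or increased versus
the reference (the >0.95 normalized-depth difference rule) are tested
against every GO term for over-representation.  The enrichment p-value is
the one-sided hypergeometric tail P(X >= observed overlap); a term is
included in the report when its p-value falls below the cutoff (0.01) in
at least one sample/direction.  No multiple-testing correction enters the
inclusion rule; Benjamini-Hochberg q-values are reported as supplementary
columns only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ploidy import ClassificationThresholds, CopyNumberProfile, DEFAULT_THRESHOLDS, compare_profiles

log = logging.getLogger(__name__)


def fisher_enrichment(
    term_genes: set[str],
    changed_genes: set[str],
    universe: set[str],
    two_sided: bool = False,
) -> float:
    """Enrichment p-value of a term among the changed genes.

    One-sided by default: the upper hypergeometric tail P(X >= k) with k the
    term/changed overlap, drawing |changed| genes from a universe containing
    |term| marked genes.  ``two_sided=True`` gives Fisher's two-sided test.
    """
    if not universe:
        raise ValueError("empty universe")
    if not term_genes <= universe or not changed_genes <= universe:
        raise ValueError("term and changed gene sets must be subsets of the universe")
    n_universe = len(universe)
    n_term = len(term_genes)
    n_changed = len(changed_genes)
    k = len(term_genes & changed_genes)
    if two_sided:
        table = [
            [k, n_term - k],
            [n_changed - k, n_universe - n_term - n_changed + k],
        ]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(stats.hypergeom.sf(k - 1, n_universe, n_term, n_changed))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    sample: str
    direction: str  # "amplified" | "reduced"
    overlap: int
    term_size: int
    changed_size: int
    universe_size: int
    p_value: float
    included: bool


def enrichment_screen(
    profiles: Mapping[str, CopyNumberProfile],
    reference: CopyNumberProfile,
    go_table: Mapping[str, frozenset[str]],
    p_cutoff: float = 0.01,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Screen every GO term in every sample and direction.

    The universe per sample is the set of genes resolvable in both that
    sample and the reference.  A term is *included* when its p-value beats
    ``p_cutoff`` in at least one sample/direction; all per-sample rows of
    included terms are returned (long format), with BH q-values per
    sample/direction as a supplementary column.
    """
    known_genes = set(reference.classes.index)
    annotated = {g: t for g, t in go_table.items() if g in known_genes}
    dropped = len(go_table) - len(annotated)
    if dropped:
        log.warning("%d GO-annotated genes absent from the gene universe; ignored", dropped)
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in annotated.items():
        for term in terms:
            term_to_genes.setdefault(term, set()).add(gene)

    rows: list[dict] = []
    for sample_id, profile in profiles.items():
        reduced, increased, unchanged = compare_profiles(reference, profile, thresholds)
        universe = reduced | increased | unchanged
        for direction, changed in (("reduced", reduced), ("amplified", increased)):
            for term, genes in sorted(term_to_genes.items()):
                term_in_universe = genes & universe
                if not term_in_universe:
                    continue
                p = fisher_enrichment(term_in_universe, changed, universe, two_sided)
                rows.append(
                    {
                        "term": term,
                        "sample": sample_id,
                        "direction": direction,
                        "overlap": len(term_in_universe & changed),
                        "term_size": len(term_in_universe),
                        "changed_size": len(changed),
                        "universe_size": len(universe),
                        "p_value": p,
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term", "sample", "direction", "overlap", "term_size",
            "changed_size", "universe_size", "p_value",
        ],
    )
    if frame.empty:
        frame["q_value"] = pd.Series(dtype=float)
        frame["included"] = pd.Series(dtype=bool)
        return frame
    frame["q_value"] = np.nan
    for _, idx in frame.groupby(["sample", "direction"]).groups.items():
        frame.loc[idx, "q_value"] = multipletests(
            frame.loc[idx, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    included_terms = set(frame.loc[frame["p_value"] < p_cutoff, "term"])
    frame["included"] = frame["term"].isin(included_terms)
    return (
        frame[frame["included"]]
        .sort_values(["term", "sample", "direction"], ignore_index=True)
    )
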