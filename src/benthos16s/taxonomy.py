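"""Consensus taxonomy assignment from tabular similarity hits.

For every OTU the pipeline (1) excludes low-scoring hits (bitscore / alignment
length thresholds), (2) keeps only hits within a bitscore margin of the best
hit, (3) collapses the surviving subject lineages to their lowest common
ancestor, and (4) trims the consensus lineage to the rank permitted by the
best retained percent identity under a strict rank-wise cutoff ladder
(species > 98%, genus > 95%, family > 90%, order > 85%, class > 80%,
phylum > 75%). The outcome is deterministic and invariant to hit order.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .io_model import (
    RANKS,
    RANK_INDEX,
    FilterConfig,
    Lineage,
    SimilarityHit,
    TaxonomyAssignment,
)

__all__ = [
    "threshold_filter",
    "margin_filter",
    "lowest_common_ancestor",
    "trim_by_identity",
    "assign_taxonomy",
    "group_hits_by_query",
]


def threshold_filter(
    hits: Sequence[SimilarityHit], config: FilterConfig
) -> list[SimilarityHit]:
    """Drop low-scoring hits.

    Under ``low_score_rule="or"`` (default) a hit is excluded when EITHER its
    bitscore is below ``bitscore_min`` OR its alignment length is below
    ``alen_min``; under ``"and"`` only hits failing both are excluded.
    """
    if config.low_score_rule == "or":
        return [
            h
            for h in hits
            if h.bitscore >= config.bitscore_min
            and h.alignment_length >= config.alen_min
        ]
    return [
        h
        for h in hits
        if not (
            h.bitscore < config.bitscore_min
            and h.alignment_length < config.alen_min
        )
    ]


def margin_filter(
    hits: Sequence[SimilarityHit], config: FilterConfig
) -> list[SimilarityHit]:
    """Keep hits whose bitscore is within ``margin_fraction`` of the best.

    The boundary is inclusive (``bitscore >= (1 - margin) * max``), so the
    top-scoring hit always survives.
    """
    if not hits:
        return []
    cutoff = (1.0 - config.margin_fraction) * max(h.bitscore for h in hits)
    return [h for h in hits if h.bitscore >= cutoff]


def lowest_common_ancestor(lineages: Sequence[Lineage]) -> Lineage:
    """Longest common prefix of ranked lineages.

    Comparison is rank-wise exact string match, stopping at the first
    disagreement or the first rank unnamed in any lineage. Fully disjoint
    lineages yield the empty (unassigned) lineage.
    """
    if not lineages:
        raise ValueError("lowest_common_ancestor requires at least one lineage")
    min_depth = min(lin.depth for lin in lineages)
    first = lineages[0]
    common = 0
    for i in range(min_depth):
        name = first.names[i]
        if all(lin.names[i] == name for lin in lineages[1:]):
            common = i + 1
        else:
            break
    return first.truncate(common)


def _permitted_depth(identity: float, config: FilterConfig) -> int:
    """Deepest number of ranks an identity permits under the cutoff ladder."""
    # ranks below domain, shallow to deep; cutoffs strictly decrease with depth
    for rank in reversed(RANKS[1:]):  # species .. phylum
        if identity > config.identity_cutoffs[rank]:
            return RANK_INDEX[rank] + 1
    return 1 if config.retain_domain else 0


def trim_by_identity(
    lineage: Lineage, identity: float, config: FilterConfig
) -> Lineage:
    """Truncate a lineage to the deepest rank its identity permits.

    Cutoffs are strict (an identity of exactly 98.0 does not reach species).
    An identity at or below the phylum cutoff yields the empty lineage unless
    ``config.retain_domain`` keeps a bare domain label.
    """
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    return lineage.truncate(_permitted_depth(identity, config))


def group_hits_by_query(
    hits: Iterable[SimilarityHit],
) -> dict[str, list[SimilarityHit]]:
    grouped: dict[str, list[SimilarityHit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    return dict(grouped)


def assign_taxonomy(
    hits_by_otu: Mapping[str, Sequence[SimilarityHit]],
    config: FilterConfig | None = None,
) -> list[TaxonomyAssignment]:
    """Run the full filter -> margin -> LCA -> trim cascade per OTU.

    Hits flagged lineage-missing cannot contribute a lineage and are set
    aside before filtering (their count is not part of the audit trail).
    OTUs with zero retained hits come back unassigned with an empty lineage.
    Output order follows the mapping's key order; the per-OTU result is
    invariant to permutation of its hit list.
    """
    config = config or FilterConfig()
    out: list[TaxonomyAssignment] = []
    for otu_id, raw_hits in hits_by_otu.items():
        usable = [h for h in raw_hits if not h.lineage_missing]
        retained = threshold_filter(usable, config)
        n_threshold = len(retained)
        retained = margin_filter(retained, config)
        n_margin = len(retained)
        if retained:
            max_identity = max(h.pct_identity for h in retained)
            lca = lowest_common_ancestor([h.lineage for h in retained])
            lineage = trim_by_identity(lca, max_identity, config)
            lca_rank = lca.deepest_rank
        else:
            max_identity = 0.0
            lineage = Lineage()
            lca_rank = "unassigned"
        out.append(
            TaxonomyAssignment(
                otu_id=otu_id,
                lineage=lineage,
                assigned_rank=lineage.deepest_rank,
                n_hits_input=len(usable),
                n_hits_after_threshold=n_threshold,
                n_hits_after_margin=n_margin,
                max_identity=max_identity,
                lca_rank=lca_rank,
            )
        )
    return out
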