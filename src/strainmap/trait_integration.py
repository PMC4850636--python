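"""Cross-trait integration: composite gene scores and rankings.

Each gene's score is the sum over traits of -log10 of its gene-level
p-value, so genes with several strong associations rank highest.  When
FDR filters are supplied, a (gene, trait) association that was removed
contributes 0 instead of -log10(p) — removal is per trait, not a global
deletion of the gene.  Untested (gene, trait) pairs also contribute 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fdr_permutation import FdrResult
from .haplotype_mapping import TraitGeneResult

__all__ = ["GeneScore", "score_genes", "rank_genes", "DEFAULT_P_FLOOR"]

DEFAULT_P_FLOOR = 1e-300


@dataclass
class GeneScore:
    """Composite score of one gene across traits.

    ``contributions`` maps every supplied trait to its -log10(p) term
    (0 for removed or untested traits); ``score`` is their exact sum.
    ``rank`` is assigned by :func:`rank_genes`.
    """

    gene_name: str
    contributions: dict[str, float]
    score: float
    n_traits_contributing: int
    rank: int | None = None
    # bookkeeping for the rank table
    trait_p: dict[str, float | None] = field(default_factory=dict)
    trait_fdr_p: dict[str, float | None] = field(default_factory=dict)
    trait_removed: dict[str, bool | None] = field(default_factory=dict)


def score_genes(
    per_trait: Mapping[str, Sequence[TraitGeneResult]],
    filters: Mapping[str, Sequence[FdrResult]] | None = None,
    p_floor: float = DEFAULT_P_FLOOR,
) -> list[GeneScore]:
    """Combine per-trait gene p-values into composite scores.

    Every trait must cover the same gene universe; if ``filters`` is
    given it must cover the same (gene, trait) pairs.  Genes whose score
    is 0 in every trait are dropped from the output.
    """
    if not per_trait:
        raise ValueError("no traits supplied")
    traits = list(per_trait.keys())
    universe: list[str] | None = None
    by_trait: dict[str, dict[str, TraitGeneResult]] = {}
    for t in traits:
        d = {r.gene_name: r for r in per_trait[t]}
        genes = sorted(d)
        if universe is None:
            universe = genes
        elif genes != universe:
            raise ValueError(
                f"trait {t!r} covers a different gene universe"
            )
        by_trait[t] = d
    filt_by_trait: dict[str, dict[str, FdrResult]] = {}
    if filters is not None:
        for t in traits:
            if t not in filters:
                raise ValueError(f"no filter results for trait {t!r}")
            d = {r.gene_name: r for r in filters[t]}
            if sorted(d) != universe:
                raise ValueError(
                    f"filter for trait {t!r} covers a different gene universe"
                )
            filt_by_trait[t] = d
    out = []
    assert universe is not None
    for gene in universe:
        contributions: dict[str, float] = {}
        trait_p: dict[str, float | None] = {}
        trait_fdr_p: dict[str, float | None] = {}
        trait_removed: dict[str, bool | None] = {}
        for t in traits:
            res = by_trait[t][gene]
            trait_p[t] = res.p_orig
            fr = filt_by_trait[t].get(gene) if filters is not None else None
            trait_fdr_p[t] = fr.fdr_p if fr is not None else None
            trait_removed[t] = fr.removed if fr is not None else None
            if res.p_orig is None or (fr is not None and fr.removed):
                contributions[t] = 0.0
            else:
                contributions[t] = -math.log10(max(res.p_orig, p_floor))
        score = sum(contributions.values())
        if score == 0.0:
            continue
        out.append(
            GeneScore(
                gene_name=gene,
                contributions=contributions,
                score=score,
                n_traits_contributing=sum(
                    1 for v in contributions.values() if v > 0
                ),
                trait_p=trait_p,
                trait_fdr_p=trait_fdr_p,
                trait_removed=trait_removed,
            )
        )
    return out


def rank_genes(scores: Sequence[GeneScore]) -> list[GeneScore]:
    """Sort by descending score (ties by gene name) and assign ranks 1..m."""
    if not scores:
        raise ValueError("no scores to rank")
    ranked = sorted(scores, key=lambda g: (-g.score, g.gene_name))
    for i, gs in enumerate(ranked, start=1):
        gs.rank = i
    return ranked
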