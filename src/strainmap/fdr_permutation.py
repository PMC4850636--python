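"""Gene-wise permutation FDR filtering.

The strain -> phenotype assignment is permuted B times (default 1,000)
and the genome-wide scan is re-run on every permuted copy, giving each
gene a list of B permuted gene-level p-values.  The gene's FDR p-value
is the number of permuted p-values strictly smaller than its original
p-value, divided by B; a (gene, trait) association with FDR p > alpha
(default 0.005, i.e. the gene matched randomised data more than five
times in a thousand) is removed.

All genes within a trait share the same B permutations, and the drawn
permutation indices are kept on the run object so any gene's FDR p is
independently recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import MappingConfig
from .haplotype_mapping import TraitGeneResult, _ScanContext
from .panel_io import GeneAnnotation, GenotypeMatrix, PanelValidationError

__all__ = [
    "PermutationRun",
    "FdrResult",
    "run_permutations",
    "gene_fdr",
    "apply_filter",
    "DEFAULT_B",
    "DEFAULT_ALPHA",
]

DEFAULT_B = 1000
DEFAULT_ALPHA = 0.005


@dataclass
class PermutationRun:
    """B permuted genome-wide scans for one trait."""

    trait_name: str
    B: int
    seed: int
    strain_order: tuple[str, ...]
    perm_indices: np.ndarray  # (B, n_strains) int
    permuted_p: dict[str, np.ndarray]  # gene -> (B,) p-values

    def __post_init__(self) -> None:
        for gene, p in self.permuted_p.items():
            if len(p) != self.B:
                raise ValueError(
                    f"gene {gene}: {len(p)} permuted p-values, expected {self.B}"
                )


@dataclass
class FdrResult:
    gene_name: str
    trait_name: str
    p_orig: float | None
    k: int  # exceedance count: permuted p strictly below p_orig
    B: int
    fdr_p: float  # k / B exactly
    removed: bool  # fdr_p > alpha
    alpha: float
    reason: str | None = None  # "untested" for genes with no blocks


def run_permutations(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    trait_values: Mapping[str, float],
    B: int = DEFAULT_B,
    seed: int = 0,
    config: MappingConfig | None = None,
    trait_name: str = "",
    context: _ScanContext | None = None,
) -> PermutationRun:
    """Scan B uniformly random strain-label permutations genome-wide.

    The identity permutation is not excluded (its probability is
    negligible at panel sizes of interest).  Genes with no overlapping
    blocks contribute p = 1 under every permutation.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or MappingConfig()
    unknown = [s for s in trait_values if s not in genotypes.panel.strain_ids]
    if unknown:
        raise PanelValidationError(
            f"strain(s) with phenotype but no genotype: {sorted(unknown)}"
        )
    strains = [s for s in genotypes.panel if s in trait_values]
    if context is not None:
        if context.strain_order != tuple(strains):
            raise PanelValidationError(
                "precomputed context strain set does not match trait values"
            )
        ctx = context
    else:
        ctx = _ScanContext(genotypes, annotation, strains, config)
    y = np.array([trait_values[s] for s in ctx.strain_order])
    n = len(y)
    rng = np.random.default_rng(seed)
    perm_indices = np.stack([rng.permutation(n) for _ in range(B)])
    Y = y[perm_indices]  # (B, n)
    _, P, _ = ctx.block_pvalues(Y)
    gene_p = ctx.gene_pvalues(P)
    permuted_p = {}
    for gene in annotation.gene_names:
        permuted_p[gene] = gene_p.get(gene, np.ones(B)).copy()
    return PermutationRun(
        trait_name=trait_name,
        B=B,
        seed=seed,
        strain_order=ctx.strain_order,
        perm_indices=perm_indices,
        permuted_p=permuted_p,
    )


def gene_fdr(
    p_orig: float,
    permuted_p: Sequence[float] | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    gene_name: str = "",
    trait_name: str = "",
) -> FdrResult:
    """FDR p-value for one gene: ``#{p_b < p_orig} / B``.

    Counting uses strict inequality, so permuted p-values tied with the
    original do not count against the gene.  The gene is removed iff
    ``fdr_p > alpha``.
    """
    permuted_p = np.asarray(permuted_p, dtype=float)
    B = len(permuted_p)
    if B == 0:
        raise ValueError("permuted_p is empty")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    k = int(np.sum(permuted_p < p_orig))
    fdr_p = k / B
    return FdrResult(
        gene_name=gene_name,
        trait_name=trait_name,
        p_orig=float(p_orig),
        k=k,
        B=B,
        fdr_p=fdr_p,
        removed=fdr_p > alpha,
        alpha=alpha,
    )


def apply_filter(
    results: Sequence[TraitGeneResult],
    run: PermutationRun,
    alpha: float = DEFAULT_ALPHA,
) -> list[FdrResult]:
    """Filter mapped genes by their permutation FDR p-values.

    Untested genes (no overlapping blocks) are passed through as removed
    with reason ``"untested"``.
    """
    out = []
    for res in results:
        if res.gene_name not in run.permuted_p:
            raise KeyError(
                f"gene {res.gene_name!r} absent from permutation run"
            )
        if res.status == "untested" or res.p_orig is None:
            out.append(
                FdrResult(
                    gene_name=res.gene_name,
                    trait_name=res.trait_name,
                    p_orig=None,
                    k=run.B,
                    B=run.B,
                    fdr_p=1.0,
                    removed=True,
                    alpha=alpha,
                    reason="untested",
                )
            )
            continue
        fr = gene_fdr(
            res.p_orig,
            run.permuted_p[res.gene_name],
            alpha=alpha,
            gene_name=res.gene_name,
            trait_name=res.trait_name,
        )
        out.append(fr)
    return out
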