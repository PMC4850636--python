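"""Haplotype-block enumeration and block/gene association testing.

Blocks are sliding windows of ``window_size`` consecutive SNPs (stride 1)
on one chromosome.  The allele strings over a window partition the
strains into haplotype groups; strains with a missing call anywhere in
the window sit that block out.  Each block is tested against a trait by
one-way fixed-effects ANOVA of strain-level means across haplotype
groups, and a gene's p-value is the minimum block p over all blocks
overlapping the (flanked) gene interval — deliberately uncorrected
within the gene, because the permutation FDR stage is the correction.

Identical strain partitions are deduplicated before testing (the ANOVA
depends only on the partition), which leaves every per-block p-value
unchanged while avoiding redundant work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .config import MappingConfig
from .panel_io import (
    MISSING,
    GeneAnnotation,
    GeneRecord,
    GenotypeMatrix,
    PanelValidationError,
)

__all__ = [
    "HaplotypeBlock",
    "BlockAssociation",
    "TraitGeneResult",
    "BlockSkippedError",
    "enumerate_blocks",
    "block_association",
    "gene_pvalue",
    "map_trait",
    "anova_oneway",
]


class BlockSkippedError(ValueError):
    """A block cannot be tested against the given trait values."""


@dataclass
class HaplotypeBlock:
    """A window of consecutive SNPs plus the induced strain partition.

    ``labels`` assigns each strain of the full panel a haplotype-group id
    in ``0..n_groups-1`` (group ids in order of first occurrence along the
    panel), or -1 for strains excluded because of a missing call.
    """

    chromosome: str
    site_index_range: tuple[int, int]  # half-open indices into the site list
    start: int  # genomic 0-based, position of first site
    end: int  # genomic, position of last site + 1 (half-open)
    labels: np.ndarray  # (n_strains,) int32
    n_groups: int
    hap_strings: tuple[str, ...]  # one allele string per group id
    strain_ids: tuple[str, ...]  # full panel, aligned with labels

    @property
    def width(self) -> int:
        a, b = self.site_index_range
        return b - a

    @property
    def tested_strains(self) -> tuple[str, ...]:
        return tuple(
            s for s, l in zip(self.strain_ids, self.labels) if l >= 0
        )

    @property
    def haplotypes(self) -> dict[str, set[str]]:
        """Haplotype string -> set of strains carrying it."""
        out: dict[str, set[str]] = {h: set() for h in self.hap_strings}
        for s, l in zip(self.strain_ids, self.labels):
            if l >= 0:
                out[self.hap_strings[l]].add(s)
        return out


@dataclass
class BlockAssociation:
    block: HaplotypeBlock
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False  # within-group SS == 0 with between SS > 0


@dataclass
class TraitGeneResult:
    """Gene-level association for one trait: min p over overlapping blocks."""

    gene_name: str
    trait_name: str
    p_orig: float | None
    best_block: HaplotypeBlock | None
    n_blocks_tested: int
    status: str = "tested"  # "tested" | "untested"


# ---------------------------------------------------------------------------
# block enumeration
# ---------------------------------------------------------------------------


def _canonical_labels(win: np.ndarray) -> tuple[np.ndarray, int, list[str]]:
    """Partition strains by identical allele strings over a window.

    Returns per-strain group labels (-1 for strains with a missing call),
    the number of groups, and the allele string of each group.  Group ids
    follow first occurrence along the strain axis, which makes the
    labelling canonical: two windows induce equal label vectors iff they
    induce the same partition.
    """
    n = win.shape[0]
    labels = np.full(n, -1, dtype=np.int32)
    seen: dict[bytes, int] = {}
    strings: list[str] = []
    for i in range(n):
        row = win[i]
        if (row == MISSING).any():
            continue
        key = row.tobytes()
        g = seen.get(key)
        if g is None:
            g = len(seen)
            seen[key] = g
            strings.append("".join(str(int(a)) for a in row))
        labels[i] = g
    return labels, len(seen), strings


def enumerate_blocks(
    genotypes: GenotypeMatrix,
    window_size: int = 3,
    min_group_size: int = 2,
) -> list[HaplotypeBlock]:
    """Enumerate candidate haplotype blocks over all chromosomes.

    A window survives only if, after dropping strains with missing calls,
    it has >= 2 haplotype groups, its largest group has at least
    ``min_group_size`` strains, and a one-way ANOVA would retain at least
    one within-group degree of freedom.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    blocks: list[HaplotypeBlock] = []
    strain_ids = tuple(genotypes.panel)
    calls = genotypes.calls
    for chrom, lo, hi in genotypes.chromosome_ranges():
        for a in range(lo, hi - window_size + 1):
            b = a + window_size
            labels, g, strings = _canonical_labels(calls[:, a:b])
            if g < 2:
                continue
            counts = np.bincount(labels[labels >= 0], minlength=g)
            if counts.max() < min_group_size:
                continue
            n_tested = int(counts.sum())
            if n_tested - g < 1:
                continue
            blocks.append(
                HaplotypeBlock(
                    chromosome=chrom,
                    site_index_range=(a, b),
                    start=int(genotypes.pos[a]),
                    end=int(genotypes.pos[b - 1]) + 1,
                    labels=labels,
                    n_groups=g,
                    hap_strings=tuple(strings),
                    strain_ids=strain_ids,
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# ANOVA engine
# ---------------------------------------------------------------------------

# relative tolerance for declaring a sum of squares zero
_SS_RTOL = 1e-12


def anova_oneway(
    labels: np.ndarray,
    Y: np.ndarray,
    p_floor: float = 1e-300,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised one-way fixed-effects ANOVA over many blocks and traits.

    Parameters
    ----------
    labels
        ``(n_blocks, n)`` integer group labels, -1 = excluded strain.
        Labels must be contiguous ``0..g-1`` per row.
    Y
        ``(m, n)`` trait value matrix (m trait vectors / permutations).

    Returns
    -------
    F, p, degenerate — each ``(n_blocks, m)``.  Blocks with zero
    within-group SS and positive between-group SS get ``p = p_floor``
    and the degenerate flag; blocks with no variance at all get
    ``F = 0, p = 1``.
    """
    labels = np.atleast_2d(np.asarray(labels))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_blocks, n = labels.shape
    m = Y.shape[0]
    if Y.shape[1] != n:
        raise ValueError("labels and Y disagree on the number of strains")
    n_groups = labels.max(axis=1) + 1
    F = np.zeros((n_blocks, m))
    P = np.ones((n_blocks, m))
    D = np.zeros((n_blocks, m), dtype=bool)
    Y2 = Y * Y
    for g in np.unique(n_groups):
        if g < 2:
            raise ValueError("every block needs >= 2 groups")
        idx = np.flatnonzero(n_groups == g)
        lab = labels[idx]
        tested = lab >= 0
        onehot = np.zeros((len(idx), n, g))
        bi, si = np.nonzero(tested)
        onehot[bi, si, lab[bi, si]] = 1.0
        counts = onehot.sum(axis=1)  # (b, g)
        if (counts == 0).any():
            raise ValueError("non-contiguous group labels")
        N = counts.sum(axis=1)  # (b,)
        dfw = N - g
        if (dfw < 1).any():
            raise ValueError("df_within < 1 for some block")
        sums = np.einsum("mn,bng->bmg", Y, onehot)  # (b, m, g)
        grand = sums.sum(axis=2)  # (b, m)
        sumsq = tested @ Y2.T  # (b, m): sum of y^2 over tested strains
        corr = grand * grand / N[:, None]
        sst = np.maximum(sumsq - corr, 0.0)
        ssb = np.maximum(
            (sums * sums / counts[:, None, :]).sum(axis=2) - corr, 0.0
        )
        ssb = np.minimum(ssb, sst)
        ssw = sst - ssb
        tol = _SS_RTOL * np.maximum(sst, np.finfo(float).tiny)
        dfb = g - 1
        ok = ssw > tol
        degen = (~ok) & (ssb > tol)
        flat = ~ok & ~degen
        f = np.zeros_like(sst)
        np.divide(ssb / dfb, ssw / dfw[:, None], out=f, where=ok)
        p = np.ones_like(sst)
        p[ok] = stats.f.sf(
            f[ok], dfb, np.broadcast_to(dfw[:, None], f.shape)[ok]
        )
        f[degen] = np.inf
        p[degen] = p_floor
        f[flat] = 0.0
        p[flat] = 1.0
        F[idx], P[idx], D[idx] = f, p, degen
    return F, P, D


def _restrict_labels(
    labels: np.ndarray, keep: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict block labels to a strain subset and re-canonicalise.

    Returns the relabelled ``(n_blocks, n_keep)`` matrix and a boolean
    mask of blocks that remain testable (>= 2 groups, df_within >= 1).
    """
    sub = labels[:, keep]
    out = np.full_like(sub, -1)
    viable = np.zeros(len(sub), dtype=bool)
    for b in range(len(sub)):
        row = sub[b]
        mapping: dict[int, int] = {}
        for j, l in enumerate(row):
            if l < 0:
                continue
            g = mapping.get(l)
            if g is None:
                g = len(mapping)
                mapping[l] = g
            out[b, j] = g
        g = len(mapping)
        n_tested = int((row >= 0).sum())
        viable[b] = g >= 2 and (n_tested - g) >= 1
    return out, viable


# ---------------------------------------------------------------------------
# single-block / single-gene operations
# ---------------------------------------------------------------------------


def block_association(
    block: HaplotypeBlock,
    trait_values: Mapping[str, float],
    p_floor: float = 1e-300,
) -> BlockAssociation:
    """One-way ANOVA of a trait across one block's haplotype groups."""
    keep = np.array(
        [s in trait_values for s in block.strain_ids], dtype=bool
    )
    labels, viable = _restrict_labels(block.labels[None, :], keep)
    if not viable[0]:
        raise BlockSkippedError(
            f"block {block.chromosome}:{block.start}-{block.end}: fewer "
            "than 2 haplotype groups (or no residual df) among phenotyped "
            "strains"
        )
    y = np.array(
        [trait_values[s] for s, k in zip(block.strain_ids, keep) if k]
    )
    F, P, D = anova_oneway(labels, y[None, :], p_floor=p_floor)
    g = int(labels.max()) + 1
    n_tested = int((labels[0] >= 0).sum())
    return BlockAssociation(
        block=block,
        f_statistic=float(F[0, 0]),
        df_between=g - 1,
        df_within=n_tested - g,
        p_value=float(P[0, 0]),
        degenerate=bool(D[0, 0]),
    )


def _overlaps(block: HaplotypeBlock, gene: GeneRecord, flank: int) -> bool:
    return (
        block.chromosome == gene.chromosome
        and block.start < gene.end + flank
        and block.end > gene.start - flank
    )


def gene_pvalue(
    gene: GeneRecord,
    blocks: Sequence[BlockAssociation],
    flank: int = 10_000,
    trait_name: str = "",
) -> TraitGeneResult:
    """Aggregate block associations to a gene: minimum p over overlaps.

    The left-most overlapping block attaining the minimum is reported as
    ``best_block``.  A gene with zero overlapping blocks is returned in
    an explicit ``"untested"`` state, never with a silent p of 1.
    """
    best: BlockAssociation | None = None
    n = 0
    for assoc in blocks:
        if not _overlaps(assoc.block, gene, flank):
            continue
        n += 1
        if best is None or assoc.p_value < best.p_value:
            best = assoc
    if best is None:
        return TraitGeneResult(
            gene_name=gene.name,
            trait_name=trait_name,
            p_orig=None,
            best_block=None,
            n_blocks_tested=0,
            status="untested",
        )
    return TraitGeneResult(
        gene_name=gene.name,
        trait_name=trait_name,
        p_orig=best.p_value,
        best_block=best.block,
        n_blocks_tested=n,
        status="tested",
    )


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------


class _ScanContext:
    """Genotype-only state reused across traits and permutations.

    Blocks, their restricted/deduplicated partitions and the block->gene
    overlap lists depend only on genotypes, annotation and config, so a
    context built once serves the original trait and every permuted copy.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        annotation: GeneAnnotation,
        strains: Sequence[str],
        config: MappingConfig,
        blocks: Sequence[HaplotypeBlock] | None = None,
    ):
        if len(annotation) == 0:
            raise PanelValidationError("no genes in annotation")
        if len(strains) < 3:
            raise PanelValidationError(
                f"need >= 3 phenotyped strains, got {len(strains)}"
            )
        self.strains = tuple(strains)
        self.config = config
        if blocks is None:
            blocks = enumerate_blocks(
                genotypes, config.window_size, config.min_group_size
            )
        strain_set = set(strains)
        keep = np.array(
            [s in strain_set for s in genotypes.panel], dtype=bool
        )
        order = [s for s in genotypes.panel if s in strain_set]
        # column order after restriction follows the panel; remember it
        self.strain_order = tuple(order)
        if blocks:
            all_labels = np.stack([b.labels for b in blocks])
            if keep.all():
                # viability was already enforced at enumeration time
                restricted = all_labels
                viable = np.ones(len(blocks), dtype=bool)
            else:
                restricted, viable = _restrict_labels(all_labels, keep)
        else:
            restricted = np.zeros((0, int(keep.sum())), dtype=np.int32)
            viable = np.zeros(0, dtype=bool)
        self.blocks = [b for b, v in zip(blocks, viable) if v]
        labels = restricted[viable]
        # deduplicate identical partitions; ANOVA runs once per partition
        if len(labels):
            _, self._uniq_index, self._inverse = np.unique(
                labels, axis=0, return_index=True, return_inverse=True
            )
            self._uniq_labels = labels[self._uniq_index]
        else:
            self._uniq_labels = labels
            self._inverse = np.zeros(0, dtype=np.intp)
        self.annotation = annotation
        b_chrom = np.array([b.chromosome for b in self.blocks], dtype=object)
        b_start = np.array([b.start for b in self.blocks], dtype=np.int64)
        b_end = np.array([b.end for b in self.blocks], dtype=np.int64)
        flank = config.flank_bp
        self.gene_blocks: dict[str, np.ndarray] = {}
        for gene in annotation:
            hit = (
                (b_chrom == gene.chromosome)
                & (b_start < gene.end + flank)
                & (b_end > gene.start - flank)
            )
            self.gene_blocks[gene.name] = np.flatnonzero(hit)

    def block_pvalues(
        self, Y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-block F/p/degenerate for ``Y`` of shape (m, n_strains).

        Columns of ``Y`` must follow :attr:`strain_order`.
        """
        if not self.blocks:
            m = np.atleast_2d(Y).shape[0]
            z = np.zeros((0, m))
            return z, z, z.astype(bool)
        F, P, D = anova_oneway(
            self._uniq_labels, Y, p_floor=self.config.p_floor
        )
        return F[self._inverse], P[self._inverse], D[self._inverse]

    def gene_pvalues(self, block_p: np.ndarray) -> dict[str, np.ndarray]:
        """Min-p aggregation per gene; untested genes are absent."""
        out = {}
        for gene, idx in self.gene_blocks.items():
            if len(idx):
                out[gene] = block_p[idx].min(axis=0)
        return out


def map_trait(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    trait_values: Mapping[str, float],
    config: MappingConfig | None = None,
    trait_name: str = "",
    blocks: Sequence[HaplotypeBlock] | None = None,
    context: "_ScanContext | None" = None,
) -> list[TraitGeneResult]:
    """Map one trait genome-wide: block ANOVA + per-gene min-p.

    Deterministic given inputs and config; the order of gene records does
    not affect any p-value.  A precomputed ``context`` (genotype-only
    state) may be passed to amortise block enumeration across traits; it
    must have been built for the same strain set.
    """
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
        ctx = _ScanContext(
            genotypes, annotation, strains, config, blocks=blocks
        )
    y = np.array([trait_values[s] for s in ctx.strain_order])
    _, P, _ = ctx.block_pvalues(y[None, :])
    results = []
    for gene in annotation:
        idx = ctx.gene_blocks[gene.name]
        if len(idx) == 0:
            results.append(
                TraitGeneResult(gene.name, trait_name, None, None, 0, "untested")
            )
            continue
        p = P[idx, 0]
        best_local = int(np.argmin(p))  # first index = left-most block
        results.append(
            TraitGeneResult(
                gene_name=gene.name,
                trait_name=trait_name,
                p_orig=float(p[best_local]),
                best_block=ctx.blocks[int(idx[best_local])],
                n_blocks_tested=len(idx),
                status="tested",
            )
        )
    return results
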