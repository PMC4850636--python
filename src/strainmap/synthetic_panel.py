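"""Synthetic inbred-strain panels with known ground truth.

Generates block-structured genotypes (each gene carries a configurable
number of planted haplotype blocks), strain-level trait values with a
planted causal effect transmitted through one designated block's
haplotype grouping, and long-format behavioural records from which the
derivation formulas recover the generating strain-level values.

Every gene is placed on its own synthetic chromosome so that sliding
windows never straddle two genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    GeneAnnotation,
    GeneRecord,
    GenotypeMatrix,
    PhenotypeTable,
    StrainPanel,
)
from .phenotype_derivation import DEFAULT_DOSES, TRAIT_NAMES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_behavior",
    "BehaviorTruth",
]

_SITE_SPACING = 150  # bp between planted SNPs
_FIRST_POS = 10_000  # 0-based position of the first SNP on each chromosome


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated strain panel."""

    seed: int = 0
    n_strains: int = 24
    genes: tuple[tuple[str, int], ...] = (
        ("gene_causal", 5),
        ("gene_null", 5),
    )  # (name, n_blocks)
    causal_gene: str = "gene_causal"
    causal_traits: tuple[str, ...] = ("mechanical_oih", "tolerance", "weight_change")
    effect_size: float = 2.0  # group-mean shift in units of noise SD
    noise_sd: float = 1.0
    n_haplotypes_per_block: int = 2
    block_width: int = 3  # SNPs per planted block
    traits: tuple[str, ...] = TRAIT_NAMES
    group_skew: float = 0.0  # 0 = balanced groups; >0 inflates group 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in simulation config")
        if self.causal_gene not in names:
            raise ValueError(
                f"causal gene {self.causal_gene!r} not among declared genes"
            )
        unknown = set(self.causal_traits) - set(self.traits)
        if unknown:
            raise ValueError(f"unknown causal trait(s): {sorted(unknown)}")
        if self.n_haplotypes_per_block < 2:
            raise ValueError("need >= 2 haplotypes per block")
        if self.n_strains < self.n_haplotypes_per_block + 1:
            raise ValueError(
                f"{self.n_strains} strains cannot fill "
                f"{self.n_haplotypes_per_block} haplotype groups with df to spare"
            )
        if 2 ** self.block_width < self.n_haplotypes_per_block:
            raise ValueError(
                "block_width too small for the requested number of haplotypes"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    causal_gene: str
    causal_block_index: int  # index among the causal gene's planted blocks
    causal_chromosome: str
    causal_span: tuple[int, int]  # genomic 0-based half-open
    causal_strains: tuple[str, ...]  # strains carrying the effect haplotype
    causal_traits: tuple[str, ...]
    effect_size: float
    noise_sd: float


def _gene_chromosome(name: str) -> str:
    return f"chr_{name}"


def _assign_groups(
    rng: np.random.Generator, n_strains: int, g: int, skew: float
) -> np.ndarray:
    """Random (near-)balanced assignment of strains to g haplotype groups."""
    weights = np.ones(g)
    weights[0] += skew
    targets = np.floor(weights / weights.sum() * n_strains).astype(int)
    targets = np.maximum(targets, 1)
    while targets.sum() < n_strains:
        targets[np.argmin(targets / weights)] += 1
    while targets.sum() > n_strains:
        targets[np.argmax(targets / weights)] -= 1
    labels = np.repeat(np.arange(g), targets)
    return labels[rng.permutation(n_strains)]


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GeneAnnotation, PhenotypeTable, GroundTruth]:
    """Simulate genotypes, gene intervals, trait values and ground truth.

    Per gene, ``n_blocks`` planted windows of ``block_width`` SNPs whose
    allele strings split the strains into ``n_haplotypes_per_block``
    groups.  Trait values are ``effect_size * noise_sd`` for strains in
    the causal group on causal traits, plus N(0, noise_sd) strain-level
    noise; all draws come from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    strains = tuple(f"S{i + 1:03d}" for i in range(n))
    panel = StrainPanel(strains)
    w, g = config.block_width, config.n_haplotypes_per_block

    chrom, pos, site_id, ref, alt, call_cols = [], [], [], [], [], []
    gene_records = []
    causal_labels: np.ndarray | None = None
    causal_span: tuple[int, int] | None = None
    # emit genes in chromosome order so the site table is born sorted
    for gene_name, n_blocks in sorted(
        config.genes, key=lambda it: _gene_chromosome(it[0])
    ):
        c = _gene_chromosome(gene_name)
        n_sites = n_blocks * w
        positions = _FIRST_POS + _SITE_SPACING * np.arange(n_sites)
        for b in range(n_blocks):
            labels = _assign_groups(rng, n, g, config.group_skew)
            # distinct allele strings, one per group
            codes = rng.choice(2 ** w, size=g, replace=False)
            strings = (
                (codes[:, None] >> np.arange(w - 1, -1, -1)) & 1
            ).astype(np.int8)
            block_calls = strings[labels]  # (n_strains, w)
            for j in range(w):
                call_cols.append(block_calls[:, j])
            if gene_name == config.causal_gene and b == 0:
                causal_labels = labels
                lo = int(positions[0])
                hi = int(positions[w - 1]) + 1
                causal_span = (lo, hi)
        chrom.extend([c] * n_sites)
        pos.extend(int(p) for p in positions)
        site_id.extend(f"{c}_s{j}" for j in range(n_sites))
        ref.extend(["A"] * n_sites)
        alt.extend(["G"] * n_sites)
        gene_records.append(
            GeneRecord(gene_name, c, int(positions[0]), int(positions[-1]) + 1)
        )
    calls = np.stack(call_cols, axis=1)
    genotypes = GenotypeMatrix.from_arrays(
        panel, chrom, pos, site_id, ref, alt, calls
    )
    annotation = GeneAnnotation(tuple(gene_records))

    assert causal_labels is not None and causal_span is not None
    causal_mask = causal_labels == 0
    data = {}
    for trait in config.traits:
        values = rng.normal(0.0, config.noise_sd, size=n)
        if trait in config.causal_traits:
            values = values + (
                config.effect_size * config.noise_sd * causal_mask
            )
        data[trait] = values
    phenotypes = PhenotypeTable(
        pd.DataFrame(data, index=pd.Index(strains, name="strain"))
    )
    truth = GroundTruth(
        causal_gene=config.causal_gene,
        causal_block_index=0,
        causal_chromosome=_gene_chromosome(config.causal_gene),
        causal_span=causal_span,
        causal_strains=tuple(s for s, m in zip(strains, causal_mask) if m),
        causal_traits=config.causal_traits,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
    )
    return genotypes, annotation, phenotypes, truth


# ---------------------------------------------------------------------------
# behavioural records
# ---------------------------------------------------------------------------


@dataclass
class BehaviorTruth:
    """Generating strain-level values behind simulated behavioural records."""

    values: pd.DataFrame  # index = strain, columns = TRAIT_NAMES


def simulate_behavior(
    n_strains: int = 24,
    seed: int = 0,
    mpe_noise_sd: float = 0.0,
    threshold_noise_sd: float = 0.0,
    doses: Sequence[float] = DEFAULT_DOSES,
    baseline_latency: float = 3.0,
    cutoff_latency: float = 10.0,
    hill_slope: float = 1.5,
) -> tuple[pd.DataFrame, BehaviorTruth]:
    """Simulate long-format behavioural records for ``n_strains`` strains.

    Tail-flick latencies follow a log-logistic dose-response with a
    strain-specific pre-treatment ED50 and a post-treatment ED50 shifted
    by the strain's tolerance fold change; thresholds, weights and jump
    counts realise the remaining traits.  With both noise SDs at 0 the
    derivation formulas recover the generating values exactly.
    """
    rng = np.random.default_rng(seed)
    strains = [f"S{i + 1:03d}" for i in range(n_strains)]
    doses = np.asarray(doses, dtype=float)
    rows = []
    truth_rows = {}
    for s in strains:
        ed50_pre = float(np.exp(rng.normal(np.log(4.0), 0.3)))
        fold = float(np.exp(rng.normal(np.log(2.5), 0.5)))
        ed50_post = ed50_pre * fold
        mech_base = 1.2
        mech_frac = float(np.clip(rng.normal(0.55, 0.15), 0.1, 1.3))
        therm_base = 9.0
        therm_frac = float(np.clip(rng.normal(0.7, 0.1), 0.2, 1.3))
        tail_base = 4.0
        tail_frac = float(np.clip(rng.normal(0.75, 0.1), 0.2, 1.3))
        w_initial = 25.0
        w_pct = float(rng.normal(-6.0, 2.5))
        jumps = int(rng.poisson(rng.gamma(4.0, 5.0)))

        for phase, ed50 in (("pre", ed50_pre), ("post", ed50_post)):
            for d in doses:
                if d == 0:
                    latency = baseline_latency
                else:
                    mpe = 100.0 / (1.0 + (ed50 / d) ** hill_slope)
                    if mpe_noise_sd > 0:
                        mpe += rng.normal(0.0, mpe_noise_sd)
                    mpe = float(np.clip(mpe, 0.0, 100.0))
                    latency = baseline_latency + mpe / 100.0 * (
                        cutoff_latency - baseline_latency
                    )
                rows.append((s, "tailflick_latency", phase, float(d), latency))

        def _noisy(x: float) -> float:
            if threshold_noise_sd > 0:
                return max(x + float(rng.normal(0, threshold_noise_sd)), 1e-6)
            return x

        rows.append((s, "mech_threshold", "baseline", 0.0, mech_base))
        rows.append((s, "mech_threshold", "post", 0.0, _noisy(mech_base * mech_frac)))
        rows.append((s, "thermal_hindpaw_latency", "baseline", 0.0, therm_base))
        rows.append(
            (s, "thermal_hindpaw_latency", "post", 0.0, _noisy(therm_base * therm_frac))
        )
        rows.append((s, "tailflick_oih_latency", "baseline", 0.0, tail_base))
        rows.append(
            (s, "tailflick_oih_latency", "post", 0.0, _noisy(tail_base * tail_frac))
        )
        rows.append((s, "weight", "initial", 0.0, w_initial))
        rows.append((s, "weight", "final", 0.0, w_initial * (1 + w_pct / 100.0)))
        rows.append((s, "jumps", "post", 0.0, float(jumps)))
        truth_rows[s] = {
            "mechanical_oih": mech_frac,
            "thermal_oih": therm_frac,
            "tailflick_oih": tail_frac,
            "tolerance": fold,
            "dependence": float(jumps),
            "weight_change": w_pct,
        }
    records = pd.DataFrame(
        rows, columns=["strain", "assay", "phase", "dose", "value"]
    )
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")[list(TRAIT_NAMES)]
    truth.index.name = "strain"
    return records, BehaviorTruth(values=truth)
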