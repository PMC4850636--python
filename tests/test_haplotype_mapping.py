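import math

import numpy as np
import pytest
from scipy import stats

from strainmap.config import MappingConfig
from strainmap.haplotype_mapping import (
    BlockAssociation,
    BlockSkippedError,
    HaplotypeBlock,
    anova_oneway,
    block_association,
    enumerate_blocks,
    gene_pvalue,
    map_trait,
)
from strainmap.panel_io import GeneAnnotation, GeneRecord
from strainmap.synthetic_panel import SimulationConfig, simulate_panel
from tests.conftest import make_matrix


def brute_force_anova(groups):
    """Independent one-way ANOVA oracle: explicit sums of squares."""
    k = len(groups)
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand_mean = sum(all_vals) / n
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        mean_g = sum(g) / len(g)
        ssb += len(g) * (mean_g - grand_mean) ** 2
        ssw += sum((v - mean_g) ** 2 for v in g)
    df_between = k - 1
    df_within = n - k
    f = (ssb / df_between) / (ssw / df_within)
    p = stats.f.sf(f, df_between, df_within)
    return f, p


class TestEnumerateBlocks:
    def test_window_count(self):
        gm = make_matrix(
            {
                "A": "0101",
                "B": "0101",
                "C": "0110",
                "D": "0110",
                "E": "1010",
                "F": "1010",
            }
        )
        blocks = enumerate_blocks(gm, window_size=3, min_group_size=1)
        assert len(blocks) == 2  # two length-3 windows over 4 sites
        assert [b.site_index_range for b in blocks] == [(0, 3), (1, 4)]

    def test_monomorphic_window_discarded(self):
        gm = make_matrix({"A": "000", "B": "000", "C": "000", "D": "000"})
        assert enumerate_blocks(gm, window_size=3) == []

    def test_hand_enumerated_partition(self):
        # per-strain calls over 3 sites: {000,000,000,111,111,110}
        gm = make_matrix(
            {
                "A": "000",
                "B": "000",
                "C": "000",
                "D": "111",
                "E": "111",
                "F": "110",
            }
        )
        blocks = enumerate_blocks(gm, window_size=3, min_group_size=3)
        assert len(blocks) == 1
        (block,) = blocks
        haps = block.haplotypes
        assert sorted(len(v) for v in haps.values()) == [1, 2, 3]
        assert haps["000"] == {"A", "B", "C"}
        assert haps["111"] == {"D", "E"}
        assert haps["110"] == {"F"}
        # df_within = 6 - 3 = 3 >= 1, largest group 3 >= min_group_size
        assert enumerate_blocks(gm, window_size=3, min_group_size=4) == []

    def test_missing_call_excludes_strain(self):
        gm = make_matrix(
            {"A": "00.", "B": "000", "C": "111", "D": "111", "E": "000"}
        )
        (block,) = enumerate_blocks(gm, window_size=3)
        assert "A" not in block.tested_strains
        assert set(block.tested_strains) == {"B", "C", "D", "E"}

    def test_blocks_partition_tested_strains(self):
        rng = np.random.default_rng(0)
        calls = {
            f"S{i}": "".join(rng.choice(["0", "1", "."], p=[0.45, 0.45, 0.1], size=8))
            for i in range(10)
        }
        gm = make_matrix(calls)
        for block in enumerate_blocks(gm, window_size=3):
            groups = list(block.haplotypes.values())
            union = set().union(*groups)
            assert union == set(block.tested_strains)
            assert sum(len(g) for g in groups) == len(union)  # disjoint
            assert len(groups) >= 2


class TestBlockAssociation:
    def _block(self, calls):
        gm = make_matrix(calls)
        (block,) = enumerate_blocks(gm, window_size=len(next(iter(calls.values()))))
        return block

    def test_matches_oracle(self):
        block = self._block(
            {"A": "000", "B": "000", "C": "000", "D": "111", "E": "111", "F": "111"}
        )
        values = {"A": 1.0, "B": 1.2, "C": 0.8, "D": 3.0, "E": 3.2, "F": 2.8}
        assoc = block_association(block, values)
        f_exp, p_exp = brute_force_anova([[1.0, 1.2, 0.8], [3.0, 3.2, 2.8]])
        assert assoc.f_statistic == pytest.approx(f_exp, abs=1e-10)
        assert assoc.p_value == pytest.approx(p_exp, abs=1e-10)
        assert assoc.df_between == 1 and assoc.df_within == 4

    def test_all_identical_values(self):
        block = self._block(
            {"A": "000", "B": "000", "C": "000", "D": "111", "E": "111", "F": "111"}
        )
        assoc = block_association(block, {s: 2.0 for s in "ABCDEF"})
        assert assoc.f_statistic == 0.0
        assert assoc.p_value == 1.0
        assert not assoc.degenerate

    def test_perfect_separation_clamped(self):
        block = self._block({"A": "0", "B": "0", "C": "1", "D": "1"})
        assoc = block_association(
            block, {"A": 1.0, "B": 1.0, "C": 2.0, "D": 2.0}, p_floor=1e-300
        )
        assert assoc.degenerate
        assert assoc.p_value == 1e-300
        assert math.isfinite(-math.log10(assoc.p_value))

    def test_skip_when_one_group_left(self):
        block = self._block(
            {"A": "000", "B": "000", "C": "000", "D": "111", "E": "111", "F": "111"}
        )
        with pytest.raises(BlockSkippedError):
            block_association(block, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestAnovaEngineOracle:
    def test_thousand_random_groupings(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(6, 30))
            g = int(rng.integers(2, 6))
            labels = np.concatenate(
                [np.arange(g), rng.integers(0, g, size=n - g)]
            )
            rng.shuffle(labels)
            y = rng.normal(size=n)
            F, P, _ = anova_oneway(labels[None, :], y[None, :])
            groups = [list(y[labels == j]) for j in range(g)]
            f_exp, p_exp = brute_force_anova(groups)
            assert abs(F[0, 0] - f_exp) <= 1e-10 * max(1.0, abs(f_exp))
            assert abs(P[0, 0] - p_exp) <= 1e-10

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        y = rng.normal(size=10)
        F, P, _ = anova_oneway(labels[None, :], y[None, :])
        res = stats.f_oneway(*[y[labels == j] for j in range(3)])
        assert F[0, 0] == pytest.approx(res.statistic, rel=1e-12)
        assert P[0, 0] == pytest.approx(res.pvalue, rel=1e-9)

    def test_excluded_strains_ignored(self):
        labels = np.array([0, 0, 1, 1, -1, -1])
        y = np.array([1.0, 1.2, 3.0, 2.8, 99.0, -99.0])
        F, P, _ = anova_oneway(labels[None, :], y[None, :])
        f_exp, p_exp = brute_force_anova([[1.0, 1.2], [3.0, 2.8]])
        assert F[0, 0] == pytest.approx(f_exp, abs=1e-10)
        assert P[0, 0] == pytest.approx(p_exp, abs=1e-10)


def _assoc(chrom, start, end, p):
    block = HaplotypeBlock(
        chromosome=chrom,
        site_index_range=(0, 1),
        start=start,
        end=end,
        labels=np.array([0, 0, 1, 1]),
        n_groups=2,
        hap_strings=("0", "1"),
        strain_ids=("A", "B", "C", "D"),
    )
    return BlockAssociation(block, 1.0, 1, 2, p)


class TestGenePvalue:
    def test_minimum_over_overlaps(self):
        gene = GeneRecord("g", "chr1", 1000, 2000)
        assocs = [
            _assoc("chr1", 1100, 1200, 0.2),
            _assoc("chr1", 1300, 1400, 0.01),
            _assoc("chr1", 1500, 1600, 0.5),
        ]
        res = gene_pvalue(gene, assocs, flank=0)
        assert res.p_orig == 0.01
        assert res.n_blocks_tested == 3
        assert res.best_block.start == 1300

    def test_untested_sentinel(self):
        gene = GeneRecord("g", "chr2", 1000, 2000)
        res = gene_pvalue(gene, [_assoc("chr1", 1100, 1200, 0.2)], flank=0)
        assert res.status == "untested"
        assert res.p_orig is None and res.best_block is None

    def test_flank_extends_overlap(self):
        gene = GeneRecord("g", "chr1", 1000, 2000)
        far = [_assoc("chr1", 5000, 5100, 0.03)]
        assert gene_pvalue(gene, far, flank=0).status == "untested"
        assert gene_pvalue(gene, far, flank=10_000).p_orig == 0.03

    def test_tie_reports_leftmost(self):
        gene = GeneRecord("g", "chr1", 0, 10_000)
        assocs = [
            _assoc("chr1", 2000, 2100, 0.01),
            _assoc("chr1", 1000, 1100, 0.01),
        ]
        # left-most given left-to-right input order (enumeration order)
        assocs.sort(key=lambda a: a.block.start)
        res = gene_pvalue(gene, assocs, flank=0)
        assert res.best_block.start == 1000

    def test_min_p_monotone_in_overlapping_blocks(self):
        gene = GeneRecord("g", "chr1", 0, 10_000)
        assocs = []
        last = None
        for i, p in enumerate([0.7, 0.3, 0.9, 0.05, 0.4]):
            assocs.append(_assoc("chr1", 100 * i, 100 * i + 50, p))
            now = gene_pvalue(gene, assocs, flank=0).p_orig
            if last is not None:
                assert now <= last
            last = now

    def test_planted_effect_detected(self):
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed,
                genes=(("gene_causal", 5), ("gene_null", 5)),
                effect_size=2.0,
                causal_traits=("mechanical_oih",),
            )
            gm, ann, pheno, _ = simulate_panel(cfg)
            res = map_trait(gm, ann, pheno.trait_values("mechanical_oih"))
            p = next(r.p_orig for r in res if r.gene_name == "gene_causal")
            hits += p < 0.05
        assert hits >= 95


class TestMapTrait:
    def _panel(self, seed=11):
        cfg = SimulationConfig(
            seed=seed, genes=(("gene_causal", 4), ("gene_null", 4))
        )
        return simulate_panel(cfg)

    def test_causal_gene_wins(self):
        wins = 0
        for seed in range(20):
            gm, ann, pheno, _ = self._panel(seed)
            res = map_trait(gm, ann, pheno.trait_values("tolerance"))
            by_gene = {r.gene_name: r.p_orig for r in res}
            wins += by_gene["gene_causal"] < by_gene["gene_null"]
        assert wins >= 15

    def test_gene_order_invariance(self):
        gm, ann, pheno, _ = self._panel()
        values = pheno.trait_values("tolerance")
        res_fwd = map_trait(gm, ann, values)
        rev = GeneAnnotation(tuple(reversed(ann.records)))
        res_rev = map_trait(gm, rev, values)
        fwd = {r.gene_name: r.p_orig for r in res_fwd}
        bwd = {r.gene_name: r.p_orig for r in res_rev}
        assert fwd == bwd

    def test_deterministic(self):
        gm, ann, pheno, _ = self._panel()
        values = pheno.trait_values("tolerance")
        a = map_trait(gm, ann, values)
        b = map_trait(gm, ann, values)
        assert [(r.gene_name, r.p_orig, r.n_blocks_tested) for r in a] == [
            (r.gene_name, r.p_orig, r.n_blocks_tested) for r in b
        ]

    def test_polymorphic_gene_min_p_stochastically_smaller(self):
        # the inflation the FDR stage exists to correct: under the null,
        # a 200-block gene attains smaller min-p than a 5-block gene
        small_wins = 0
        p5, p200 = [], []
        for seed in range(500):
            cfg = SimulationConfig(
                seed=seed,
                genes=(("gene_causal", 5), ("gene_null", 200)),
                effect_size=0.0,
            )
            gm, ann, pheno, _ = simulate_panel(cfg)
            res = map_trait(gm, ann, pheno.trait_values("dependence"))
            by_gene = {r.gene_name: r.p_orig for r in res}
            p5.append(by_gene["gene_causal"])
            p200.append(by_gene["gene_null"])
        p5, p200 = np.array(p5), np.array(p200)
        assert np.median(p200) < np.median(p5)
        assert (p200 < p5).mean() > 0.9
        u = stats.mannwhitneyu(p200, p5, alternative="less")
        assert u.pvalue < 1e-10

    def test_config_window_size(self):
        # fully polymorphic fixture: every window of every width survives
        gm = make_matrix(
            {
                "A": "000",
                "B": "000",
                "C": "011",
                "D": "011",
                "E": "101",
                "F": "110",
            }
        )
        assert len(enumerate_blocks(gm, window_size=1)) == 3
        assert len(enumerate_blocks(gm, window_size=2)) == 2
        assert len(enumerate_blocks(gm, window_size=3)) == 1
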