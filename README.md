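# strainmap

Haplotype-block association mapping for inbred strain panels, with
gene-wise permutation FDR filtering and cross-trait score integration.

Inbred strains are homozygous, so each strain contributes one genotype
and one strain-level mean per trait. The pipeline:

1. **Haplotype-block mapping** — sliding windows of consecutive SNPs
   (default width 3, stride 1) partition the strains into haplotype
   groups; each block is tested against a trait by one-way ANOVA of
   strain means across groups. A gene's p-value is the minimum block p
   over all blocks overlapping the gene ± a flank (default 10 kb).
2. **Gene-wise permutation FDR** — the strain → phenotype assignment is
   permuted B times (default 1,000) and the genome-wide scan re-run on
   every permuted copy. A gene's FDR p is the fraction of permuted scans
   in which it beat its own original p-value (strict inequality); any
   (gene, trait) association with FDR p > 0.005 is removed. This
   corrects the min-p inflation that makes highly polymorphic genes
   (many blocks) look significant by chance.
3. **Trait integration** — each gene's composite score is
   `sum over traits of -log10(p)`, with removed or untested traits
   contributing 0; genes are ranked by descending score.

The package also derives the six behavioural traits from raw records
(%MPE, log-logistic ED50 fits and tolerance fold change, hyperalgesia as
fraction of baseline threshold, % weight change, withdrawal jump counts)
and ships a simulator that generates panels with planted causal effects
for end-to-end validation.

## File formats

* **Genotypes (TSV, project dialect)** — tab-separated; header
  `chrom  pos  id  ref  alt  <strain...>`; one row per SNP; `pos` is
  1-based; calls are `0` (ref), `1` (alt) or `.` (missing; `NA`
  accepted). Inbred panels are homozygous: no heterozygous code exists.
* **Genotypes (VCF 4.x)** — biallelic SNPs only; `0/0 → 0`, `1/1 → 1`,
  anything else (het, `./.`) → missing; other records skipped with a
  warning.
* **Phenotypes (CSV)** — `strain` column plus one column per trait;
  empty cells mean "strain not measured for this trait".
* **Genes (BED)** — 0-based half-open, name field = gene name.
* All coordinates are 0-based half-open internally; conversion happens
  only at the file boundary.

## CLI

```sh
strainmap simulate  --config sim.yaml --out-dir data/ [--with-behavior]
strainmap phenotypes --behavior behavior.csv --out phenotypes.csv
strainmap map       --genotypes g.tsv --phenotypes p.csv --genes genes.bed \
                    --trait tolerance --out maps/tolerance.map.tsv
strainmap fdr       --genotypes g.tsv --phenotypes p.csv --genes genes.bed \
                    --trait tolerance --permutations 1000 --alpha 0.005 \
                    --seed 7 --out filters/tolerance.fdr.tsv
strainmap integrate --results-dir maps/ --filters-dir filters/ --out-dir ranks/
strainmap rank      --scores ranks/ranks_unfiltered.tsv --out reranked.tsv
```

`integrate` emits `ranks_unfiltered.tsv` and `ranks_filtered.tsv` so the
before/after-FDR rankings can be compared directly. Every output
directory gets a `manifest.json` (parameters, seeds, input/output
digests) sufficient to reproduce the run bit-for-bit; seeds are
mandatory for `simulate` (in the YAML config) and `fdr` (`--seed`).
Mapping parameters (`window_size`, `min_group_size`, `flank_bp`,
`p_floor`) can be overridden with a YAML file passed via `--config`.

Example simulation config:

```yaml
seed: 17
n_strains: 24
genes:
  - {name: gene_causal, n_blocks: 5}
  - {name: gene_null, n_blocks: 200}
causal_gene: gene_causal
causal_traits: [tolerance, mechanical_oih, weight_change]
effect_size: 2.0
```

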