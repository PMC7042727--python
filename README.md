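# famvar

Family-based whole-genome variant prioritization, parametric linkage power
analysis, and brain expression-correlation analysis — a tested, reusable
pipeline exercised end-to-end on synthetic pedigree genotypes and synthetic
expression matrices.

## What it does

* **`famvar.pedigree`** — pedigree data model and validation, trio Mendelian
  consistency checks, method-of-moments kinship estimation, and a counter of
  phase-resolvable ("informative") carrier meioses.
* **`famvar.funnel`** — the ordered variant-prioritization funnel: union of
  per-genome call sets → VQHIGH quality filter → IBS-window shared-haplotype
  regions between the two cases → dominant-model segregation filter →
  population-rarity filter (≤ 1%) → exonic/non-synonymous classes →
  commonly-mutated-gene exclusion → brain-expressed genes → pathogenicity
  vote (loss-of-function, or ≥ 5 of 8 predictors deleterious and ≥ 2 of 4
  conservation scores) → candidate flags from a known-gene list and a
  protein-interaction neighborhood. Every stage is recorded in an audit
  report with monotone survivor counts.
* **`famvar.linkage`** — exact single-locus parametric pedigree likelihood
  (Elston–Stewart peeling over joint disease–marker haplotypes, vectorized
  over replicate batches and a recombination-fraction grid), LOD scores, and
  a paramlink-style power simulation: the maximal LOD over thousands of
  fully linked simulated markers. A deliberately naive full-joint
  enumeration oracle ships alongside for verification.
* **`famvar.expression`** — quantile normalization, the detection-p call-rate
  gate, probe averaging to gene signals, OLS pair fits (Pearson r, adjusted
  R², slope p), an anchor-gene target screen, and the Fisher-z contrast of
  two correlations.
* **`famvar.simulate`** — seeded generators for all inputs: gene-dropped
  pedigree genotypes with a planted fully-penetrant dominant variant and a
  complete truth record (founder-haplotype origins, IBD segments),
  annotation tables with configurable per-stage retention, and
  bivariate-normal probe-level expression matrices.
* **`famvar.io` / `famvar.cli`** — PED, a VCF 4.2 subset (GT + a `VQ`
  quality flag), annotation/marker/network/expression TSVs, gene lists,
  YAML run configuration, and the `famvar` command-line interface.

The ten-member study family ships as an editable PED fixture
(`famvar/data/family.ped`, loaded by `famvar.datasets.load_study_pedigree`).

## CLI

```sh
# simulate a family call set with a planted dominant variant
famvar simulate --ped family.ped --planted-founder 100 --seed 1 --out sim/

# run the prioritization funnel
famvar funnel --vcf sim/calls.vcf --annot sim/annotations.tsv \
    --cmd-genes sim/cmd_genes.txt --brain-genes sim/brain_genes.txt \
    --nd-genes sim/nd_genes.txt --network sim/network.tsv \
    --cases 102,200 --controls 122,123 --out funnel/

# pedigree power: maximal LOD over 10,000 simulated fully linked markers
famvar power --ped family.ped --model 0.0001,0.0001,1.0,1.0 \
    --typed 102,122,123,200,201,202 --n 10000 --seed 1

# single-point LOD scores for markers in a TSV
famvar lod --ped family.ped --marker markers.tsv

# anchor-gene expression screen
famvar expr --matrix e.matrix.tsv --detp e.detp.tsv --samples e.samples.tsv \
    --probemap e.probes.tsv --anchor ADAM17

# everything from one YAML config
famvar run-all --config run.yaml
```

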