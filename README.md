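# leafnet

Analysis toolkit for transcription-factor (TF) binding compendia: from
per-TF ChIP-seq peak calls to a regulatory network and sequence-level
models of binding.

The package covers:

- **synthetic benchmarks** (`leafnet.synthetic`) — genomes, gene
  annotation, open chromatin, per-TF peak sets, variants and a second
  species, all with planted ground truth (motifs, edges, modules,
  co-binding, enrichment, conservation) so every stage is testable offline;
- **peak operations** (`leafnet.peaks`) — QC filtering (replicate Pearson
  >= 0.8, NSC >= 1.05, RSC >= 0.8), summit-based merging into binding loci
  (300 bp gap), occupancy, per-chromosome overlap permutation tests,
  distance-to-gene classification (proximal < 2 kb);
- **target inference** (`leafnet.tip`) — TIP-style binding profiles around
  TSSs, z-score/p-value target calling at BH FDR 5%, network assembly with
  −log10(p) edge weights, pathway-regulator ranking, Fisher term enrichment;
- **topology** (`leafnet.topology`) — discrete power-law fits with
  bootstrap goodness-of-fit (Clauset-style), 99th-percentile hub calling,
  Louvain modules and a 1000-graph degree-preserving rewired null;
- **sequence models** (`leafnet.seqmodel`) — bag-of-k-mers (collapsed
  7-mers, TF-IDF, L2 logistic regression, 5-fold CV), per-base occlusion
  and saturation-mutagenesis maps, TF clustering by k-mer weights
  (Spearman/Ward), top-k-mer vs PWM matching (13.28-bit / 1e−4 rule with
  an exact DP null);
- **co-localization** (`leafnet.coloc`) — normalized-rank matrices
  ((R−r)/(R−1)), column-permutation negatives, rule-ensemble learning
  (boosted shallow trees → threshold rules → L1 logistic), relative
  importance (RI, 0–100) and proximal-vs-distal differential importance;
- **variant enrichment** (`leafnet.enrich`) — SNP density profiles around
  summits, matched control regions (≥ 5 kb away, two L/2 flanks),
  Beta(1,1) beta-binomial posterior fold enrichment with 95% credible
  intervals, proximal/distal stratification, BH GWAS hit calling;
- **conservation** (`leafnet.conservation`) — applying TF sequence models
  to syntenic open chromatin of a second species, conserved-edge
  fractions, TF-to-TF vs TF-to-non-TF Fisher contrast, cross-species
  model-match correlations.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(planted-truth recovery with stated tolerances); the other files are
per-module unit and property tests, including exact comparisons against
brute-force oracles (summit merging, BH, Fisher, modularity Q, occlusion
maps).

## CLI

```bash
leafnet simulate --outdir sim --seed 7            # synthetic benchmark to disk
leafnet peaks merge sim/peaks/*.narrowPeak --out loci.bed
leafnet peaks occupancy sim/peaks/*.narrowPeak
leafnet peaks test --query loci.bed --reference sim/genome.open_chromatin.bed \
    --genome sim/genome.fa
leafnet network infer sim/peaks/*.narrowPeak --gff sim/genome.gff3 \
    --fdr 0.05 --out edges.tsv
leafnet topology fit --edges edges.tsv
leafnet topology modules --edges edges.tsv --n-null 1000
leafnet seqmodel train --peaks sim/peaks/g0000.narrowPeak \
    --genome sim/genome.fa --out model.json
leafnet coloc ri --focus sim/peaks/g0000.narrowPeak \
    --partners sim/peaks/g0001.narrowPeak --partners sim/peaks/g0002.narrowPeak \
    --gff sim/genome.gff3
leafnet enrich eqtl --variants sim/variants.tsv --loci loci.bed \
    --gff sim/genome.gff3 --genome sim/genome.fa
```

`leafnet simulate` accepts a YAML config with `genome:`, `landscape:`,
`peaks:`, `variants:` and `second_species:` sections mapping directly onto
the generator keyword arguments.

## Conventions

All coordinates are 0-based, half-open internally; GFF3 is converted on
read/write. Peak membership in a region is decided by the summit. Formats
exchanged on disk: FASTA, GFF3, BED6, narrowPeak (summit offset in column
10), TSV (variants, synteny, QC metrics, edges), MEME minimal (PWMs),
JSON (models, truth sets, reports).
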