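# prescan

A toolkit for regulatory-motif analysis of disease expression data:

- **motif_dictionary** — parse binding-site matrices (JASPAR-style counts,
  MEME-style probabilities, TRANSFAC-like tables), convert counts to
  probabilities with a split pseudocount (default 0.80), trim uninformative
  flanks (IC > 0.25, two-consecutive-column rule with a relaxed fallback,
  minimum width 4), and remove redundancy in two stages (same-consensus
  deduplication, then single-linkage collapse of near-identical matrices).
- **kmer_tools** — per-motif k-mer preference profiles (all 64 3-mers and
  256 4-mers; max-of-min probability over both orientations),
  nearest-neighbor DNA-binding-domain enrichment (Fisher's exact test), and
  motif clustering with per-branch discriminative k-mers.
- **deg_calling** — paired lesional/uninvolved differential expression:
  within-dataset QC Z-score filtering (|Z| > 3.5), inverted-signature label
  swap detection, signed-rank testing of paired differences with
  Benjamini-Hochberg adjustment, fold-change gates (> 1.50 / < 0.67) and
  per-dataset median-FC consistency.
- **promoter_scan** — TSS-proximal region extraction (5 kb upstream to
  500 bp downstream) with interval masking, log2(p/f) weight matrices,
  match calling at ψ/ψmax ≥ 0.80 on both strands with merging of
  overlapping hits, and the gene × motif match matrix.
- **enrichment** — per-motif semiparametric logistic regression of DEG
  membership on log10 match count (linear, Wald Z) and log10 scanned length
  (penalized spline); motifs with FDR < 0.10 and Z > 0 form the enriched
  ("response element") sets; cross-linking of enriched motifs with
  TF-encoding DEGs.
- **snp_effects** — risk-allele effects on motif matches
  ((ψ_R − ψ_NR)/ψmax over all SNP-overlapping windows, both strands),
  engendered/disrupted classification (0.85/0.75 bands), panel summaries,
  motif-group comparisons, resampling nulls and candidate-site filtering.
- **cdodn_design** — enumeration of all orderings × orientations of
  consensus blocks (n!·2ⁿ designs), dictionary screening, ranking by mean
  enrichment Z with specificity tie-breaking, and decoy specificity
  profiling.
- **synthetic_data** — seeded generators for every input above with ground
  truth: motif families, promoters with planted instances, paired
  expression with planted DEGs/outliers/label swaps, and SNP panels
  engineered to disrupt or engender matches.

## CLI

```sh
prescan synth all --seed 7 --out bundle/          # synthetic inputs + truth
prescan dict build --in motifs/ --out dict/       # parse + curate dictionary
prescan kmer profile --dict dict/ --out profiles.tsv
prescan kmer cluster --dict dict/ --out clusters.tsv
prescan deg call --expr expr.tsv --meta samples.tsv --out degs.tsv
prescan scan --genome genome.fa --tss tss.tsv --dict dict/ --out matrix.tsv
prescan enrich --matrix matrix.tsv --degs degs.tsv --out enrichment.tsv
prescan snp score --dict dict/ --snps snps.tsv --out effects.tsv
prescan snp summarize --dict dict/ --snps snps.tsv
prescan cdodn design --blocks blocks.fa --dict dict/ --z z.tsv --out designs.tsv
prescan cdodn profile --seq TGTTTACGGGACTTTCC --dict dict/
```

All tabular formats are plain TSV; genomes are FASTA, masks are BED.

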