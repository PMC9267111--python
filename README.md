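# cubkit

Codon usage bias (CUB) analysis of viral coding sequences and their host
genes, as a tested, reusable pipeline:

- **seqio** — FASTA input, labelling, and CDS validation (length > 300 nt,
  ATG start, stop end, no internal stops, no degenerate bases).
- **composition** — A/C/G/T/GC percentages, positional GC1/GC2/GC3/GC12
  (with the neutrality-plot codon exclusions) and GC3s (CodonW convention).
- **cub_metrics** — codon counting, RSCU (59 codons; over > 1.6 / under
  < 0.6), Wright's effective number of codons (ENc, CodonW fallbacks,
  capped at 61) and the expected ENc–GC3s curve
  `2 + s + 29/(s² + (1 − s)²)`.
- **selection_pressure** — PR2 bias coordinates pooled over the eight
  four-codon families, GC12-on-GC3 neutrality regression (optional 1.5×IQR
  outlier filter), ENc-vs-expected flags, Pearson/Spearman correlation.
- **dinucleotide** — relative dinucleotide abundance ρ_xy over overlapping
  windows (over > 1.23 / under < 0.78).
- **similarity** — joint virus+host RSCU PCA (mean-centered, unscaled,
  deterministic axis signs), circle-based selection of host genes with
  virus-like codon usage (cluster centroid or per-virus radius-0.3 circles),
  and a zero-copy-tRNA codon usage report.
- **enrichment** — upper-tail hypergeometric GO-term enrichment against the
  annotated background (raw p < 0.01 default, optional BH adjustment) and
  term-set comparison.
- **synthetic_data** — generator of valid CDS with controllable GC3,
  within-family bias strength, CpG depletion (calibrated so the expected
  ρ_CG equals the requested factor) and planted virus-like host genes.
- **cli** — `cubkit` command with subcommands tying the stages together.

## CLI

```sh
# simulate a planted-structure study
cubkit simulate --out-dir study/ --n-host-genes 1000 --n-viruses 10 \
    --similar-fraction 0.05 --host-gc3 0.35 --virus-gc3 0.60 --seed 7

# per-sequence metric tables (validation, composition, RSCU, ENc, PR2, rho)
cubkit metrics --fasta study/virus.fasta --origin virus --out-dir tables/

# per-host neutrality regressions, PR2 and dinucleotide tables
cubkit neutrality --fasta study/virus.fasta --out neutrality.tsv
cubkit pr2 --fasta study/virus.fasta --out pr2.tsv
cubkit dinuc --fasta study/virus.fasta --out dinuc.tsv

# joint RSCU PCA, circle selection and (optionally) enrichment
cubkit pca-select --virus-fasta study/virus.fasta --host-fasta study/host.fasta \
    --annotation annotation.tsv --out-dir selection/

# enrichment of an arbitrary gene list
cubkit enrich --genes genes.txt --annotation annotation.tsv --out enrichment.tsv
```

All tables are TSV with fixed column orders; every run directory gets a
`run_log.json` with the resolved configuration. Exit codes: 0 success,
1 usage error, 2 data error.

File formats: label TSV (`id`, `origin`, `host_species`, `genome_type`,
`family`), annotation TSV (`gene<TAB>term[<TAB>term name]`), tRNA table TSV
(`codon`, `copy_number`), gene lists one id per line.

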