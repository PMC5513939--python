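# mircascade

A tested, reusable pipeline for nominating disease-associated miRNAs from
cross-dataset small RNA-seq comparisons, together with downstream seed-based
target analysis and gene-set enrichment:

1. **Quantification** — count perfectly aligned reads (edit distance 0, same
   strand, full containment) over annotated miRNA loci, scale to reads per
   million (RPM), keep miRNAs with mean RPM above 5.
2. **Candidate cascade** — a miRNA is a candidate if it changes by more than
   50% in both human case/control datasets, or at least two-fold in one while
   staying within a ±20% no-change band in the other; it must then change by
   more than 25% in the mouse dataset, in the same direction as both human
   datasets, and have no paralog (another catalog miRNA with the same
   nucleotide 2–8 seed).
3. **Seed targets** — seed extraction, reverse-complement seed-match motifs
   and TargetScan-style site scanning (6mer / 7mer-A1 / 7mer-m8 / 8mer).
4. **Target enrichment** — genes down-regulated below 0.8-fold are
   intersected with a predicted-target list and tested against gene sets with
   a locally implemented upper-tail hypergeometric test (top-10 ranking, with
   an extra Benjamini–Hochberg column).
5. **Group statistics** — ΔΔCt relative quantification (RQ = 2^(−ΔΔCt)
   normalized to a reference RNA), equal-variance two-tailed t-test, exact /
   normal-approximation Wilcoxon rank-sum test and Bonferroni correction.
6. **Synthetic data** — fully seeded generators (negative-binomial counts
   with planted fold changes, UTRs with planted seed sites, expression-ratio
   tables with planted down-regulation, gene sets with one planted enriched
   term, Ct tables with a planted RQ fold change) so that every stage is
   testable offline.

## CLI

All functionality is exposed through the `mircascade` command:

```sh
mircascade quantify  --sam reads.sam --bed mirnas.bed --sample-id s1 --out counts.tsv
mircascade normalize --counts counts.tsv --out rpm.tsv
mircascade select    --rpm1 rpm1.tsv --groups1 g1.tsv --rpm2 rpm2.tsv --groups2 g2.tsv \
                     --rpm-mouse rpmm.tsv --groups-mouse gm.tsv \
                     --mirna-fasta mirnas.fasta --report selection.tsv
mircascade scan      --mirna-fasta mirnas.fasta --utr-fasta utrs.fasta --out sites.tsv
mircascade enrich    --ratios ratios.tsv --cutoff 0.8 --targets targets.txt \
                     --gmt sets.gmt --top 10 --out enrichment.tsv
mircascade qpcr      --table ct.tsv --calibrator untreated --out rq.tsv
mircascade simulate  --config sim.yaml --seed 1 --outdir bundle/
mircascade run-all   --config run.yaml
```

`run-all` reads a YAML file with an `inputs:` mapping (count tables, group
tables, miRNA FASTA, optional UTR FASTA, expression-ratio table, target gene
list, GMT file), optional `thresholds:` overrides and an `outdir:`; it writes
every intermediate table plus `report.json` with the funnel of set sizes at
each stage. Exit codes: 0 success, 2 configuration error, 3 stage failure.

File conventions: genomic intervals are 0-based half-open in memory (BED
native; SAM converted on read), the only table dialect is TSV with a header
row, and group tables have columns `sample_id` and `group` with values
`case`/`control`.

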