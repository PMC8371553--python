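# methylwindow

A whole-genome bisulfite sequencing (WGBS) differential-methylation pipeline
with an "estrogen critical window" gene classification, driven end-to-end by
a synthetic-data generator so every stage is testable without external data.

Stages:

1. **simulate** — toy genome with CpG-boosted islands (FASTA), gene models
   (BED12), islands (BED3), a 3-age x {control, treated} x 2-library-kit
   cohort (TSV sample sheet), per-site true methylomes on the logit scale
   (baseline per context + age + kit + planted treatment effects), binomial
   counts at Poisson coverage, and optionally ungapped bisulfite reads
   (minimal SAM) with incomplete conversion in a configurable fraction of
   reads.
2. **call** — strand-aware CpG/CHG/CHH context classification, a
   lone-cytosine conversion-QC read filter (reads whose fraction of
   cytosines outside CG/GC dinucleotides exceeds 5% are removed), and
   per-site methylated/unmethylated tallies written as a 1-based
   cytosine-report TSV.
3. **diff** — per-site binomial logistic regression of
   (methylated, unmethylated) counts on group + library-kit covariate,
   1-df likelihood-ratio test (score-test fallback under separation),
   hyper/hypo direction at raw p < 0.01 from the difference in unweighted
   mean per-sample fractions. A BH-adjusted q column is emitted but unused
   downstream.
4. **annotate** — promoter (±1 kb of TSS, strand-oriented) > exon > intron >
   intergenic precedence with nearest-TSS gene assignment, plus CpG
   island / shore (2 kb) / shelf (2–4 kb) / open-sea zoning.
5. **window** — per-gene directional calls (≥ N significant sites, default
   1), then set algebra across the three treatment contrasts:
   genes hypomethylated by treatment in young AND middle-age, split into
   aged-non-responsive ("critical window" candidates) and
   responsive-in-all-ages.
6. **enrich** — hypergeometric over-representation of result gene sets
   against GMT collections with Benjamini–Hochberg FDR.

## CLI

```sh
# full pipeline on a synthetic cohort; writes stage outputs + report.json
methylwindow run --config config.toml --seed 1 --out runs/demo

# individual stages
methylwindow simulate --config config.toml --out sim --reads
methylwindow call --genome sim/genome.fa --sam sim/reads/YC1.sam \
    --sample-id YC1 --out YC1.cytosine_report.tsv
methylwindow diff --counts-dir sim/counts --samples sim/samples.tsv \
    --test AT --ref AC --out AT-AC.tsv
methylwindow annotate --sites AT-AC.tsv --genes sim/genes.bed \
    --islands sim/islands.bed --out AT-AC.annotated.tsv
methylwindow window --young YT-YC.tsv --middle MT-MC.tsv --aged AT-AC.tsv \
    --context CpG --out critical_window.tsv
methylwindow enrich --genes genes.txt --gmt sets.gmt --out enrichment.tsv
```

The TOML config has one table per stage (`[simulation]`, `[unite]`,
`[annotation]`, `[enrichment]`, `[pipeline]`); flags override config keys.
Example:

```toml
[simulation]
genome_length = 100000
n_chromosomes = 2
gc_content = 0.4
n_genes = 20
gene_length = 2000
coverage_mean = 30.0
seed = 1

[simulation.group_sizes]
YC = 4
YT = 6
MC = 4
MT = 6
AC = 4
AT = 7

[unite]
min_coverage = 10

[pipeline]
alpha_site = 0.01
```

All six standard contrasts (AC-YC, AC-MC, MC-YC, YT-YC, MT-MC, AT-AC) run by
default; `report.json` carries, per contrast and context, total/hyper/hypo
counts with per-chromosome, per-feature (promoter / gene body / intergenic)
and per-island-zone decompositions, and the critical-window set sizes. With
a fixed seed the report is byte-identical across reruns.

## Layout

```
src/methylwindow/
  simulate.py   genome/cohort/methylome/read generator (+ presets.py scenarios)
  calling.py    context classification, conversion filter, methylation calling
  diff.py       per-site binomial GLM testing, Fisher enumeration oracle
  annotate.py   genic features and island zones
  window.py     gene calls and critical-window set algebra
  enrich.py     hypergeometric over-representation + BH
  pipeline.py   orchestration and run report
  cli.py        click CLI
  io.py         FASTA / BED / SAM / TSV / GMT readers and writers
```
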