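# bulkmap

Bulked-segregant mapping from pooled sequencing data: Δ(allele-index)
genome scans with LOESS-smoothed Monte-Carlo confidence thresholds,
candidate-region calling and gene annotation, conjunctive intersection of
DNA-based and RNA-based candidate sets, fixed-dispersion exact-test DEG
calling between bulks, and 2^-ΔΔCt relative quantification for qPCR
validation panels. A built-in F₂-cross simulator (Haldane map function,
phenotype-based bulk composition, Poisson/binomial read sampling,
negative-binomial expression counts) provides ground-truthed synthetic
experiments for every stage.

## Layout

| module | what it does |
| --- | --- |
| `bulkmap.simdata` | F₂ genotype simulation, bulk assignment, pooled depth and NB count simulation |
| `bulkmap.io_formats` | VCF 4.2 (GT:AD:DP), GFF3, counts/qPCR TSV readers and writers |
| `bulkmap.bsa_scan` | variant filtering, per-bulk allele index and Δ, sliding windows, LOESS, null thresholds, region calling |
| `bulkmap.region_annotate` | gene-overlap annotation of regions, conjunctive gene-set intersection |
| `bulkmap.expression` | FPKM, conditional NB exact test at fixed dispersion, BH FDR, DEG calls, 2^-ΔΔCt |
| `bulkmap.pipeline` / `bulkmap.cli` | YAML-configured end-to-end runs with a reproducibility manifest |

## CLI

```bash
bulkmap simulate --config sim.yaml --out simdir/      # synthetic experiment (VCF, GFF3, counts)
bulkmap scan --vcf in.vcf --roles roles.yaml \
  --window 100000 --step 10000 --confidence 0.99 --out scandir/
bulkmap annotate --regions scandir/regions.tsv --gff3 genes.gff3 --out genes.tsv
bulkmap deg --counts counts.tsv --dispersion 0.1 --out deg.tsv
bulkmap qpcr --table ct.tsv --reference-gene actin \
  --calibrator-sample FP --calibrator-part apical --out rel.tsv
bulkmap run --config run.yaml                         # full pipeline + manifest.json
```

`roles.yaml` maps VCF sample names to the four roles, e.g.
`{R01: parent1, R02: parent2, R03: bulkA, R04: bulkB}`. Bulk A is the
trait-positive bulk; Δ = index(bulkA) − index(bulkB) with ALT as the
bulk-A-parent allele.

Statistical defaults follow the analysis being reproduced: depth filter
`> 5×` on both bulks, opposite-homozygous parents required, 99%
Monte-Carlo threshold, fixed NB dispersion 0.1, |log₂FC| ≥ 1 with
FDR < 0.05. All are configurable.

The threshold null defaults to per-variant Binomial(depth, ½)
resampling; setting `ThresholdConfig.n_per_bulk` switches to a full
bulk-sampling null that also simulates the finite bulks' genotypes along
the genetic map before the read draw (better calibrated for small
bulks).

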