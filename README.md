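# varbank

A relational variant warehouse for exome/genome sequencing studies: import
VCF call sets into an embedded SQLite store, attach versioned annotations
from pluggable offline sources, and filter variants with composable AND/OR
decision trees — including Mendelian-inheritance, cohort-occurrence,
gene-burden and gene-panel filters — with retrospective re-annotation,
change logging, summary reporting and genome-build liftover.

## The problem

Whole-exome sequencing of a patient yields tens of thousands of candidate
variants; finding the handful that matter requires combining genotype
quality, gene context, population frequency, clinical assertions and family
structure. `varbank` is the second-stage tool for that task: it warehouses
normalized variants once per cohort, links them to per-sample genotype
calls carrying the GATK quality vector (QUAL, GQ, GT, AD, QD, MQ, FS and
the BaseQ/MQ/ReadPos rank sums, plus the verbatim FILTER string such as a
VQSR tranche label), and lets the analyst compose filters over any of it.

Core concepts:

* **Variant identity** — the normalized 5-tuple *(build, chrom, pos, ref,
  alt)*, with shared ref/alt context trimmed to the minimal representation
  (suffix first, then prefix, position advanced; at least one base kept).
  Multiallelic records are split into biallelic changes with per-allele AD.
* **Versioned annotation** — each source (frequency tables, clinical
  assertions, gene models, prediction scores) annotates only variants
  missing a record from it; on a new release every variant is re-annotated,
  superseded values are archived (never deleted), every change is logged,
  and changes that gain a high-impact coding effect (frameshift, stopgain,
  splicing) or turn pathogenic in a clinical source are flagged as
  putatively interesting.
* **Filter trees** — atoms (`gq >= 30`, `location == exonic`,
  `global_maf < 0.01`, ...) grouped into arbitrarily nested AND/OR nodes;
  transcript-level atoms pass a variant if *any* transcript satisfies them;
  each atom carries an explicit missing-value policy. Trees serialize to
  JSON and can be saved/reloaded from the store.
* **Inheritance models** — de novo (child carries, both parents reference),
  recessive (child homozygous, both parents heterozygous) and dominant
  (every affected family member carries, no unaffected member does),
  driven by father/mother/sibling links and affected flags from a PED-like
  file.
* **Cohort filters** — occurrence bounds (carrier-sample counts over a
  sample selection) and gene mutation burden (distinct carrier samples per
  gene), plus in-silico gene panels of transcript identifiers with
  private/public sharing.
* **Liftover** — UCSC chain-file conversion to a new genome build with a
  manual-curation queue for failures (unmapped, split across blocks,
  strand flips, reference changes); the old build stays readable with its
  final annotations frozen.

## Worked example

Generate a synthetic trio (25 variants: 5 each of de novo, recessive,
dominant, inherited-benign and common classes on the 100 kb contig `chrT`),
register the pedigree, import, annotate and pull out the de novo variants:

```bash
varbank fixtures trio --seed 1 --out-dir demo
varbank fixtures gene-model --seed 1 --out-dir demo
cd demo
cat > config.yaml <<'YAML'
database: store.db
build: hg19
sources:
- {name: frequencies, version: v1, kind: table, path: freq.tsv}
- {name: refseq_genes, version: v1, kind: gene_model, path: genes.bed,
   cds_fasta: cds.fa}
YAML
varbank samples --config config.yaml --ped trio.ped --sidecar trio_sidecar.tsv
varbank import --config config.yaml --sample CHILD  --vcf trio.vcf
varbank import --config config.yaml --sample FATHER --vcf trio.vcf
varbank import --config config.yaml --sample MOTHER --vcf trio.vcf
varbank annotate --config config.yaml
varbank filter --config config.yaml --sample CHILD --denovo
```

The import step prints one summary per sample — hom-ref records are skipped
by default, so the parents import fewer calls than the child:

```
{"sample": "CHILD", "build": "hg19", "records_read": 25, "variants_imported": 25, "multiallelic_split": 0, "skipped": {}}
{"sample": "FATHER", "build": "hg19", "records_read": 25, "variants_imported": 15, "multiallelic_split": 0, "skipped": {"non-variant": 10}}
```

and the de novo filter returns exactly the five planted de novo variants,
position-ordered, each with an IGV locus link (±25 bp window):

```
[{"chrom": "chrT", "pos": 9271, "ref": "G", "alt": "C", "locus": "chrT:9246-9296"},
 {"chrom": "chrT", "pos": 16455, "ref": "C", "alt": "A", "locus": "chrT:16430-16480"},
 {"chrom": "chrT", "pos": 18611, "ref": "C", "alt": "G", "locus": "chrT:18586-18636"},
 {"chrom": "chrT", "pos": 50756, "ref": "A", "alt": "C", "locus": "chrT:50731-50781"},
 {"chrom": "chrT", "pos": 92204, "ref": "C", "alt": "A", "locus": "chrT:92179-92229"}]
```

`varbank stats` summarizes the call set — transition/transversion counts,
known (has an rsID) vs novel, SNP vs indel, and the MAF histogram:

```
{"tr": 6, "tv": 19, "trtv_ratio": 0.3157894736842105, "known": 14,
 "novel": 11, "snp": 25, "indel": 0,
 "maf_bin_edges": [0.0, 0.001, 0.01, 0.05, 0.1, 0.5],
 "maf_histogram": [0, 0, 1, 1, 12], "maf_missing": 11}
```

(The fixture draws ref/alt uniformly, so its Tr/Tv ratio sits near the
random expectation of 0.5, not the ~2–3 seen in real call sets.)

Other subcommands: `update-annotations` (new source release with archival,
change log and interesting-change flagging), `panel create/list/share/apply`,
`export` (wide or compact CSV), `liftover` (`--chain ... --to hg38`), and
`filter --scheme scheme.json` for saved filter trees. Everything the CLI
does is a thin wrapper over the library (`varbank.filters`,
`varbank.annotation`, `varbank.liftover`, ...).

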