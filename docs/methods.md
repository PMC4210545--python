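# Methods

This note documents the conventions, defaults and deliberate simplifications
behind `varbank`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Variant identity and normalization

A variant is the 5-tuple *(build, chrom, pos, ref, alt)* with `pos` 1-based
at the first changed base and plain A/C/G/T alleles (symbolic and breakend
alleles are skipped at import with a reason). Identity requires a canonical
representation, so shared ref/alt context is trimmed to the minimal
representation: the shared suffix is removed first, then the shared prefix
with the position advanced, always keeping at least one base per allele.
This is the standard minimal-representation algorithm and is a fixed point
after one application; the test suite checks it against an oracle that
enumerates every prefix/suffix trim and picks the shortest representation
(ties broken toward the smallest position).

**No left-alignment.** Trimming needs no reference FASTA, so import does
not left-align indels in repeat tracts. Two call sets representing the same
indel at different anchor points in a homopolymer will produce two variant
rows. This is a known limitation, accepted so that import works from a VCF
alone.

Multiallelic records are split into one biallelic change per ALT. The
genotype is re-expressed relative to the retained allele (carrying any copy
of another ALT counts toward hom_ref of this one), and AD is projected to
(ref depth, this allele's depth). Half-calls such as `./1` count as het; a
fully missing GT imports as genotype `missing` so occurrence counting stays
explicit; haploid calls (`GT 1`, male X) count as hom_alt. Hom-ref records
are skipped by default (summary reason `non-variant`), retained with
`keep_homref`.

Quality fields (QUAL, GQ, AD, QD, MQ, FS, three rank sums, FILTER) are
stored exactly when present and as SQL NULL when absent — never as sentinel
numbers. The allelic ratio is derived as `ad_alt / (ad_ref + ad_alt)` and
undefined at zero depth.

## Store

A single-file SQLite database holds samples, variants, the call link table,
projects with role grants (read_only < edit < admin), annotations with full
history, the change log, filter schemes, panels, the liftover curation
queue and the audit journal. The schema is versioned via a migration table.
Choices worth naming:

* a sample belongs to exactly one project (multi-project membership is not
  modelled);
* parent links are checked for cycles, sibling links are stored
  symmetrically;
* deleting a project either cascades or refuses — it never silently orphans
  calls;
* users are plain string identifiers; only the authorization model is
  implemented, not authentication;
* retired genome builds are flagged read-only and every write path checks
  the flag.

## Annotation engine

A source is *(name, version, lookup)* where `lookup` maps a batch of
variants to per-field values. All shipped providers are offline and
table-driven (tab-delimited tables keyed on chrom/pos/ref/alt, plus the
gene-model provider); adapters shelling out to live services would plug in
through the same contract.

The annotate cycle collects variants with **no active record** from a
source, queries the provider, and stores results at the source's current
version. Variants the provider knows nothing about receive an explicit
no-hit sentinel record, so the cycle is idempotent and never re-queries
them forever — re-running immediately annotates zero.

A release update re-annotates every stored variant of the current build.
Unchanged values keep their record (and its original version label);
changed values retire the old record (`active=0`, `retired_at` set — the
archive is append-only) and insert a new one; each changed (variant,
source, field) yields exactly one change-log entry per run, including
transitions to/from absence. A partial uniqueness index enforces at most
one active record per (variant, source, field) at the database level.
Version labels are ordered by registration time; re-registering a known
label is rejected.

**Putatively interesting changes**: a change is flagged when an `effect`
field gains a high-impact term it did not carry before — the term set is
{frameshift, stopgain, splicing} — or when a clinical-significance field
moves into {pathogenic, likely_pathogenic} from outside it. The clinical
vocabulary is the five ACMG-style classes with free-text passthrough. Both
field lists and term sets are parameters of `flag_interesting`.

## Gene models and coding effects

Transcripts load from BED12 (blocks = exons, thick interval = CDS, name =
`transcript_id|gene_symbol`), with spliced CDS sequences attached from a
FASTA keyed by transcript id. Locations per transcript: `exonic`, `utr`
(exonic outside the CDS of a coding transcript), `splicing` (intronic
within 2 bp of an exon boundary — the window is a declared convention,
configurable), `intronic`, `upstream`/`downstream` (within 1 kb, oriented
by strand). A variant touching no transcript annotates as `intergenic`.

Coding effects: SNVs in the CDS are classified by codon substitution
(synonymous / missense / stopgain / stoploss, via Biopython translation,
strand-aware); indels touching the CDS are `frameshift` when the length
change is not a multiple of 3, else `inframe`. A coding transcript without
a CDS sequence yields effect `unavailable`. The acceptance suite checks 200
random planted SNVs/indels against an oracle that rebuilds the mutated
chromosome, re-extracts the spliced CDS (coordinates shifted past the
edit) and translates it in full.

Per-transcript values are stored pipe-joined in one active record per
field (escaped, reversible), which keeps the single-active-record invariant
while giving filter atoms ANY-transcript semantics: a stopgain in one of
three transcripts passes `effect == stopgain`.

## Filter engine

Atoms name a field (call quality, variant property, or any stored
annotation field, bare or `source.field`-qualified), an operator
(eq/ne/lt/le/gt/ge/contains/in_set/is_missing/not_missing) and a value.
Because the behaviour of missing annotations in comparisons is the single
most consequential free choice in such a system, every atom carries an
explicit `missing_policy`: `exclude` (default — missing fails the atom) or
`include`. Groups are AND/OR with unbounded nesting; evaluation is by set
algebra per atom (AND = intersection, OR = union), independent of child
order, and is tested against a brute-force per-variant tree walk on random
trees. Schemes serialize to JSON with a schema version; field names bind
late, at evaluation time, so a saved scheme referencing a since-removed
annotation loads fine and fails validation (naming the field) only when
evaluated.

Inheritance filters are genotype predicates over pedigree links:

* *de novo*: child het/hom_alt and both parents hom_ref; the
  `require_called_parents` flag decides whether an absent/missing parental
  genotype disqualifies (strict, library default) or counts as
  non-carrying (CLI default, since imports skip hom-ref records);
* *recessive*: child hom_alt, father het, mother het;
* *dominant*: strict co-segregation — every affected family member
  (child, parents, registered siblings) carries, every unaffected one is
  hom_ref or uncalled; a missing call in an affected member excludes.

Occurrence filtering counts carrier **samples** (het or hom_alt), not
alleles — a hom_alt carrier counts once; the allele-counting alternative
is noted and not implemented. Burden counts **distinct** carrier samples
per gene over a sample selection. Panels match on transcript id with the
version suffix ignored, or on the gene symbol the panel transcripts resolve
to through the gene-model index. Compound-heterozygote detection is out of
scope. Male X calls of `GT 1` are treated as hom_alt — a documented
simplification; no pseudo-autosomal handling.

## Reporting

Transitions are A↔G and C↔T; the Tr/Tv ratio is reported as undefined
(None) when there are no transversions, never as infinity. "Known" means
an rsID annotation is present (dbSNP-style); treating ClinVar presence as
known would be the alternative reading. The MAF histogram uses bin edges
(0, 0.001, 0.01, 0.05, 0.1, 0.5] with a separate missing bin; edges are
configurable. Multi-transcript export cells join with `|` (literal pipes
escaped, so joining is reversible); CSV is RFC 4180. IGV loci take a ±25 bp
window clamped at position 1. Results paginate in batches of 100 by
default; pages concatenate to the full (chrom, pos)-ordered result exactly.

## Liftover

Chains parse from the UCSC format with coordinates kept 0-based half-open
internally, converted at the variant boundary; segment sums are validated
against the declared intervals. A position maps through the covering
aligned segment of the highest-scoring covering chain; positions in source
gaps report `unmapped`; a variant whose reference span crosses a segment
boundary reports `split_across_blocks` (truncation would silently change
the allele, so spans are failed, not clipped). Chains targeting the minus
strand would require reverse-complementing both alleles; rather than
guess, these report `strand_flip_unsupported`. Store conversion inserts
converted variants (and copies of their genotype calls) under the new
build, queues every failure for manual curation, retires the old build
read-only with its annotations frozen, and re-annotates the new
coordinates from the configured sources. Reference verification on the new
build runs only when target sequences are supplied (`ref_changed` on
mismatch). Multi-hop conversions are out of scope.

## Synthetic data

All fixtures live on a 100 kb synthetic contig `chrT` (`chrL` after
liftover) so no coordinate collides with a real genome, and all randomness
flows from one explicitly seeded generator — identical seeds give
byte-identical files.

* **Trio**: `n_per_class` variants (default 5) for each of five genotype
  patterns — de novo (het / hom_ref / hom_ref), recessive (hom_alt / het /
  het), dominant (het / het / hom_ref, with child and father affected),
  inherited-benign (het / hom_ref / het) and common (het in all three).
  The patterns are exactly the filter definitions and are mutually
  exclusive, so each class must be recovered with 100% precision and
  recall. GATK-style fields are drawn from plausible ranges (GQ 30–99,
  QUAL 50–3000, AD consistent with genotype, depth 20–60).
* **Gene models**: a three-exon plus-strand transcript with a 399 bp
  planted open reading frame, an overlapping second transcript of the same
  gene with different exon usage (for ANY-transcript tests), a non-coding
  transcript, and a minus-strand single-exon transcript with a 300 bp ORF.
  CDS bases are written into the contig, so planted SNVs have correct
  reference alleles.
* **Cohort**: exactly `n_carriers` carrier samples in a shared gene, the
  first carrying two distinct variants there (so distinct-sample burden
  counting is exercised), everyone with background variants outside genes.
* **Annotation releases**: two versions of a knowledge table cycling
  through six planted scenarios (stopgain gain, frameshift gain,
  pathogenic transition, MAF drift, benign effect change, no change), each
  labelled with whether it must appear in the change log and whether it
  must be flagged.
* **Chains**: 3–5 aligned segments with random source and target gaps,
  plus the exact inverse chain, so round trips and gap failures are both
  exercised.

What the fixtures do **not** emulate: linkage disequilibrium, realistic
site-frequency spectra or Tr/Tv ratios, sequencing-error profiles,
multi-family cohorts, or structural variation. Passing tests therefore
demonstrate the correctness of the warehouse logic (identity, versioning,
filtering semantics, coordinate arithmetic), not calling accuracy on real
data.

## Problem sizes

The acceptance checks use a 500-variant store with 200 random trees
(depth ≤ 4, ≤ 10 atoms), 20 trio seeds × 25 variants, 30-variant
annotation-update fixtures over two release cycles, 1,000 random liftover
positions, and 200 random coding changes — sizes chosen so the full battery
runs in seconds while every code path and boundary (gaps, missing values,
ties) is still hit.
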