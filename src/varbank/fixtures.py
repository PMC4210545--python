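"""Deterministic synthetic data with known ground truth.

Everything lives on a synthetic 100 kb contig named ``chrT`` (and ``chrL``
after liftover) so no coordinate ever collides with a real genome.  A single
``random.Random(seed)`` drives all randomness: the same seed reproduces the
same bytes.

Generators cover: trio VCFs realizing planted inheritance classes, pedigree
files, gene models with CDS sequences planted into the contig, cohort VCFs
with a known number of carriers in a shared gene, versioned annotation
tables with planted (and labelled) changes, chain files with their inverse,
and random filter trees for oracle testing.

The genotype patterns the trio generator plants are exactly the class
definitions the inheritance filters implement, so each class must be
recovered with full precision and recall:

====================  ======  =======  =======
class                 child   father   mother
====================  ======  =======  =======
de_novo               het     hom_ref  hom_ref
recessive             hom_alt het      het
dominant              het     het      hom_ref
inherited_benign      het     hom_ref  het
control_common        het     het      het
====================  ======  =======  =======

(child and father are the affected members).
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .models import Transcript

CONTIG = "chrT"
CONTIG_LENGTH = 100_000
LIFTED_CONTIG = "chrL"

TRIO_SAMPLES = ("CHILD", "FATHER", "MOTHER")
TRIO_CLASSES = (
    "de_novo", "recessive", "dominant", "inherited_benign", "control_common",
)

_CLASS_GENOTYPES = {
    "de_novo": ("het", "hom_ref", "hom_ref"),
    "recessive": ("hom_alt", "het", "het"),
    "dominant": ("het", "het", "hom_ref"),
    "inherited_benign": ("het", "hom_ref", "het"),
    "control_common": ("het", "het", "het"),
}

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


# -- low-level helpers ---------------------------------------------------


def generate_contig(seed: int, length: int = CONTIG_LENGTH) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(_BASES) for _ in range(length))


def _vcf_header(samples: Sequence[str], contig: str = CONTIG) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={CONTIG_LENGTH}>",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias">',
        '##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="Rank sum">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Rank sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,'
        'Description="Rank sum">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
        'Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def _genotype_columns(rng: random.Random, genotype: str) -> str:
    depth = rng.randint(20, 60)
    gq = rng.randint(30, 99)
    if genotype == "hom_ref":
        gt, ad = "0/0", f"{depth},0"
    elif genotype == "het":
        alt = rng.randint(depth * 3 // 10, depth * 7 // 10)
        gt, ad = "0/1", f"{depth - alt},{alt}"
    elif genotype == "hom_alt":
        gt, ad = "1/1", f"0,{depth}"
    else:
        return "./.:.:."
    return f"{gt}:{ad}:{gq}"


def _info_column(rng: random.Random) -> str:
    return (
        f"QD={rng.uniform(2, 35):.2f};MQ={rng.uniform(40, 60):.2f};"
        f"FS={rng.uniform(0, 10):.3f};"
        f"BaseQRankSum={rng.uniform(-3, 3):.3f};"
        f"MQRankSum={rng.uniform(-3, 3):.3f};"
        f"ReadPosRankSum={rng.uniform(-3, 3):.3f}"
    )


def _random_snv(rng: random.Random) -> Tuple[str, str]:
    ref = rng.choice(_BASES)
    alt = rng.choice([b for b in _BASES if b != ref])
    return ref, alt


# -- trio ----------------------------------------------------------------


@dataclass
class TrioTruth:
    """Planted inheritance classes and the genotypes realizing them."""

    seed: int
    classes: Dict[str, List[Tuple[str, int, str, str]]]
    genotypes: Dict[Tuple[str, int, str, str], Tuple[str, str, str]]

    def variants_of(self, cls: str) -> List[Tuple[str, int, str, str]]:
        return list(self.classes[cls])


def generate_trio(
    seed: int, n_per_class: int = 5
) -> Tuple[str, TrioTruth]:
    """Multi-sample VCF (CHILD, FATHER, MOTHER) realizing the class table.

    Reproducible: the same seed yields byte-identical output.
    """
    rng = random.Random(seed)
    total = n_per_class * len(TRIO_CLASSES)
    positions = sorted(rng.sample(range(1_000, CONTIG_LENGTH - 1_000), total))
    assignment = [cls for cls in TRIO_CLASSES for _ in range(n_per_class)]
    rng.shuffle(assignment)
    truth = TrioTruth(
        seed=seed, classes={cls: [] for cls in TRIO_CLASSES}, genotypes={}
    )
    lines = [_vcf_header(TRIO_SAMPLES)]
    for pos, cls in zip(positions, assignment):
        ref, alt = _random_snv(rng)
        key = (CONTIG, pos, ref, alt)
        genos = _CLASS_GENOTYPES[cls]
        truth.classes[cls].append(key)
        truth.genotypes[key] = genos
        qual = rng.uniform(50, 3000)
        cols = [
            CONTIG, str(pos), ".", ref, alt, f"{qual:.2f}", "PASS",
            _info_column(rng), "GT:AD:GQ",
        ] + [_genotype_columns(rng, g) for g in genos]
        lines.append("\t".join(cols) + "\n")
    return "".join(lines), truth


def trio_pedigree() -> str:
    """PED-like file for the trio; CHILD and FATHER are affected."""
    rows = [
        ("FAM1", "CHILD", "FATHER", "MOTHER", "1", "2"),
        ("FAM1", "FATHER", "0", "0", "1", "2"),
        ("FAM1", "MOTHER", "0", "0", "2", "1"),
    ]
    return "".join("\t".join(r) + "\n" for r in rows)


def trio_sidecar() -> str:
    """Sidecar with HPO terms and control flags for the trio samples."""
    rows = [
        ("sample_id", "hpo_terms", "is_control"),
        ("CHILD", "HP:0001250,HP:0004322", "0"),
        ("FATHER", "HP:0001250", "0"),
        ("MOTHER", "", "1"),
    ]
    return "".join("\t".join(r) + "\n" for r in rows)


# -- gene model ----------------------------------------------------------


@dataclass
class GeneModelFixture:
    seed: int
    contig_sequence: str
    transcripts: List[Transcript]
    bed12: str
    cds_fasta: str
    contig_fasta: str

    def transcript(self, transcript_id: str) -> Transcript:
        for tx in self.transcripts:
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)


def _random_cds(rng: random.Random, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES) for _ in range(3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _to_bed12(tx: Transcript) -> str:
    start0 = tx.start - 1
    sizes = ",".join(str(e - s + 1) for s, e in tx.exons)
    offsets = ",".join(str(s - tx.start) for s, _ in tx.exons)
    thick_start = (tx.cds_start - 1) if tx.is_coding else start0
    thick_end = tx.cds_end if tx.is_coding else start0
    cols = [
        tx.chrom, str(start0), str(tx.end),
        f"{tx.transcript_id}|{tx.gene_symbol}", "0", tx.strand,
        str(thick_start), str(thick_end), "0",
        str(len(tx.exons)), sizes, offsets,
    ]
    return "\t".join(cols)


def generate_gene_model(seed: int) -> GeneModelFixture:
    """Synthetic gene models planted into the contig sequence.

    * NM_0001|GENE1: plus strand, three exons, 399 bp CDS (built as
      ATG...TAA with no internal stop);
    * NR_0001|NCRNA1: two-exon non-coding transcript;
    * NM_0003|GENE1: second GENE1 transcript overlapping NM_0001 with
      different exon usage (for ANY-transcript semantics);
    * NM_0002|GENE2: minus strand single-exon transcript, 300 bp CDS.
    """
    rng = random.Random(seed)
    contig = list(generate_contig(seed + 1))

    tx1 = Transcript(
        "NM_0001", "GENE1", "refseq", CONTIG, "+",
        exons=[(10_001, 10_200), (10_401, 10_600), (10_801, 11_000)],
        cds_start=10_101, cds_end=10_899,
    )
    cds1 = _random_cds(rng, 133)  # 399 bp
    offset = 0
    for s, e in tx1.coding_segments():
        for i in range(e - s + 1):
            contig[s - 1 + i] = cds1[offset + i]
        offset += e - s + 1
    tx1.cds_sequence = cds1

    tx2 = Transcript(
        "NR_0001", "NCRNA1", "refseq", CONTIG, "+",
        exons=[(20_001, 20_300), (20_501, 20_700)],
    )

    tx3 = Transcript(
        "NM_0003", "GENE1", "refseq", CONTIG, "+",
        exons=[(10_001, 10_200), (10_801, 11_000)],
        cds_start=10_101, cds_end=10_880,
    )
    # CDS read back from the contig (shares planted bases with NM_0001)
    parts = []
    for s, e in tx3.coding_segments():
        parts.append("".join(contig[s - 1: e]))
    tx3.cds_sequence = "".join(parts)

    tx4 = Transcript(
        "NM_0002", "GENE2", "refseq", CONTIG, "-",
        exons=[(40_001, 40_450)],
        cds_start=40_101, cds_end=40_400,
    )
    cds4 = _random_cds(rng, 100)  # 300 bp, translation order
    genomic = _revcomp(cds4)
    for i, base in enumerate(genomic):
        contig[40_101 - 1 + i] = base
    tx4.cds_sequence = cds4

    transcripts = [tx1, tx2, tx3, tx4]
    contig_seq = "".join(contig)
    bed12 = "".join(_to_bed12(tx) + "\n" for tx in transcripts)
    cds_fasta = "".join(
        f">{tx.transcript_id}\n{tx.cds_sequence}\n"
        for tx in transcripts
        if tx.cds_sequence
    )
    contig_lines = [f">{CONTIG}"]
    for i in range(0, len(contig_seq), 80):
        contig_lines.append(contig_seq[i: i + 80])
    return GeneModelFixture(
        seed=seed,
        contig_sequence=contig_seq,
        transcripts=transcripts,
        bed12=bed12,
        cds_fasta=cds_fasta,
        contig_fasta="\n".join(contig_lines) + "\n",
    )


# -- cohort --------------------------------------------------------------


@dataclass
class CohortTruth:
    seed: int
    shared_gene: str
    carriers: List[str]
    gene_variants: Dict[str, List[Tuple[str, int, str, str]]]
    background_variants: Dict[str, List[Tuple[str, int, str, str]]]


def generate_cohort(
    seed: int,
    n_samples: int,
    shared_gene: str = "GENE1",
    n_carriers: int = 3,
    gene_model: Optional[GeneModelFixture] = None,
) -> Tuple[Dict[str, str], CohortTruth]:
    """Per-sample VCFs planting exactly ``n_carriers`` carriers in the
    shared gene; the first carrier gets two distinct variants there (a
    distinct-sample burden count must still see one carrier)."""
    if n_carriers > n_samples:
        raise ValueError("n_carriers cannot exceed n_samples")
    rng = random.Random(seed)
    gm = gene_model or generate_gene_model(seed)
    gene_exons = [
        (s, e)
        for tx in gm.transcripts
        if tx.gene_symbol == shared_gene
        for (s, e) in tx.exons
    ]
    if not gene_exons:
        raise ValueError(f"no transcript of {shared_gene!r} in the model")
    samples = [f"S{i + 1}" for i in range(n_samples)]
    carriers = samples[:n_carriers]
    vcfs: Dict[str, str] = {}
    truth = CohortTruth(
        seed=seed, shared_gene=shared_gene, carriers=carriers,
        gene_variants={}, background_variants={},
    )
    used_positions = set()

    def fresh_pos(lo: int, hi: int) -> int:
        while True:
            p = rng.randint(lo, hi)
            if p not in used_positions:
                used_positions.add(p)
                return p

    for idx, sample in enumerate(samples):
        records = []
        gene_vs: List[Tuple[str, int, str, str]] = []
        bg_vs: List[Tuple[str, int, str, str]] = []
        if sample in carriers:
            n_in_gene = 2 if idx == 0 else 1
            for _ in range(n_in_gene):
                s, e = rng.choice(gene_exons)
                pos = fresh_pos(s, e)
                ref = gm.contig_sequence[pos - 1]
                alt = rng.choice([b for b in _BASES if b != ref])
                gene_vs.append((CONTIG, pos, ref, alt))
        pos = fresh_pos(60_000, 90_000)
        ref = gm.contig_sequence[pos - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        bg_vs.append((CONTIG, pos, ref, alt))
        for chrom, p, r, a in sorted(gene_vs + bg_vs, key=lambda t: t[1]):
            qual = rng.uniform(50, 3000)
            records.append(
                "\t".join(
                    [
                        chrom, str(p), ".", r, a, f"{qual:.2f}", "PASS",
                        _info_column(rng), "GT:AD:GQ",
                        _genotype_columns(rng, "het"),
                    ]
                )
                + "\n"
            )
        vcfs[sample] = _vcf_header([sample]) + "".join(records)
        truth.gene_variants[sample] = gene_vs
        truth.background_variants[sample] = bg_vs
    return vcfs, truth


# -- annotation releases -------------------------------------------------


@dataclass
class AnnotationUpdateFixture:
    """Two releases of a 'knowledge' source with labelled planted changes."""

    source_name: str
    v1: str  # TSV text, version label "v1"
    v2: str  # TSV text, version label "v2"
    changed: set  # {(chrom,pos,ref,alt,field)} expected in the change log
    interesting: set  # subset expected to be flagged


def generate_annotation_update(
    seed: int, variant_keys: Sequence[Tuple[str, int, str, str]]
) -> AnnotationUpdateFixture:
    """Plant one change scenario per variant, cycling through:

    0. effect synonymous -> stopgain        (flagged)
    1. effect missense -> frameshift        (flagged)
    2. clinical uncertain -> pathogenic     (flagged)
    3. global_maf 0.010 -> 0.011            (changed, not flagged)
    4. effect synonymous -> missense        (changed, not flagged)
    5. nothing changes
    """
    rng = random.Random(seed)
    header = "chrom\tpos\tref\talt\teffect\tclinical_significance\t" \
             "global_maf\trsid\n"
    rows1, rows2 = [], []
    changed, interesting = set(), set()
    for i, key in enumerate(variant_keys):
        chrom, pos, ref, alt = key
        rsid = f"rs{rng.randint(10_000, 999_999)}"
        scenario = i % 6
        eff1, eff2 = "synonymous", "synonymous"
        clin1, clin2 = "uncertain_significance", "uncertain_significance"
        maf1 = maf2 = f"{rng.uniform(0.001, 0.4):.3f}"
        if scenario == 0:
            eff1, eff2 = "synonymous", "stopgain"
            changed.add(key + ("effect",))
            interesting.add(key + ("effect",))
        elif scenario == 1:
            eff1, eff2 = "missense", "frameshift"
            changed.add(key + ("effect",))
            interesting.add(key + ("effect",))
        elif scenario == 2:
            clin1, clin2 = "uncertain_significance", "pathogenic"
            changed.add(key + ("clinical_significance",))
            interesting.add(key + ("clinical_significance",))
        elif scenario == 3:
            maf1, maf2 = "0.010", "0.011"
            changed.add(key + ("global_maf",))
        elif scenario == 4:
            eff1, eff2 = "synonymous", "missense"
            changed.add(key + ("effect",))
        base = f"{chrom}\t{pos}\t{ref}\t{alt}"
        rows1.append(f"{base}\t{eff1}\t{clin1}\t{maf1}\t{rsid}\n")
        rows2.append(f"{base}\t{eff2}\t{clin2}\t{maf2}\t{rsid}\n")
    return AnnotationUpdateFixture(
        source_name="knowledge",
        v1=header + "".join(rows1),
        v2=header + "".join(rows2),
        changed=changed,
        interesting=interesting,
    )


def generate_frequency_table(
    seed: int,
    variant_keys: Sequence[Tuple[str, int, str, str]],
    known_fraction: float = 0.6,
) -> str:
    """Frequency source TSV: rsid + global and two population MAFs for a
    random subset of the variants (the rest stay novel)."""
    rng = random.Random(seed)
    lines = ["chrom\tpos\tref\talt\trsid\tglobal_maf\teur_maf\tafr_maf\n"]
    for key in variant_keys:
        if rng.random() > known_fraction:
            continue
        chrom, pos, ref, alt = key
        maf = rng.uniform(0.0005, 0.45)
        lines.append(
            f"{chrom}\t{pos}\t{ref}\t{alt}\trs{rng.randint(10**4, 10**6)}\t"
            f"{maf:.4f}\t{maf * rng.uniform(0.5, 1.5):.4f}\t"
            f"{maf * rng.uniform(0.5, 1.5):.4f}\n"
        )
    return "".join(lines)


# -- chains --------------------------------------------------------------


def generate_chain_pair(seed: int) -> Tuple[str, str]:
    """A multi-segment chain chrT -> chrL and its exact inverse.

    Segment sizes and gaps are random but seed-deterministic; both source
    and target gaps are present so unmapped positions exist.
    """
    rng = random.Random(seed)
    n_segments = rng.randint(3, 5)
    sizes = [rng.randint(5_000, 20_000) for _ in range(n_segments)]
    ds = [rng.randint(500, 3_000) for _ in range(n_segments - 1)] + [0]
    dt = [rng.randint(500, 3_000) for _ in range(n_segments - 1)] + [0]
    s_start = rng.randint(100, 2_000)
    t_start = rng.randint(100, 2_000)
    s_end = s_start + sum(sizes) + sum(ds)
    t_end = t_start + sum(sizes) + sum(dt)
    t_size = max(CONTIG_LENGTH, t_end + 1_000)

    def render(s_chrom, s_size, s0, s1, t_chrom, tsize, t0, t1, gs, gt):
        lines = [
            f"chain 1000 {s_chrom} {s_size} + {s0} {s1} "
            f"{t_chrom} {tsize} + {t0} {t1} 1"
        ]
        for i, size in enumerate(sizes):
            if i < n_segments - 1:
                lines.append(f"{size} {gs[i]} {gt[i]}")
            else:
                lines.append(f"{size}")
        return "\n".join(lines) + "\n\n"

    forward = render(
        CONTIG, CONTIG_LENGTH, s_start, s_end,
        LIFTED_CONTIG, t_size, t_start, t_end, ds, dt,
    )
    inverse = render(
        LIFTED_CONTIG, t_size, t_start, t_end,
        CONTIG, CONTIG_LENGTH, s_start, s_end, dt, ds,
    )
    return forward, inverse


# -- random filter trees -------------------------------------------------

FILTER_CORPUS_FIELDS: Dict[str, tuple] = {
    # field -> (kind, candidate comparison values)
    "gq": ("number", (30, 50, 70, 90)),
    "qd": ("number", (2, 5, 10, 20)),
    "mq": ("number", (40, 50, 58)),
    "global_maf": ("number", (0.001, 0.01, 0.05, 0.1)),
    "genotype": ("text", ("het", "hom_alt")),
    "effect": (
        "text", ("synonymous", "missense", "stopgain", "frameshift"),
    ),
    "location": ("text", ("exonic", "intronic", "splicing", "intergenic")),
    "gene_symbol": ("text", ("GENE1", "GENE2", "NCRNA1")),
}


def random_filter_atom(rng: random.Random):
    """One random atom over the corpus fields (for oracle testing)."""
    from .filters import FilterNode

    field_name = rng.choice(sorted(FILTER_CORPUS_FIELDS))
    kind, values = FILTER_CORPUS_FIELDS[field_name]
    if kind == "number":
        op = rng.choice(["lt", "le", "gt", "ge", "eq"])
    else:
        op = rng.choice(["eq", "ne", "contains", "in_set"])
    value = rng.choice(values)
    if op == "in_set":
        k = rng.randint(1, min(3, len(values)))
        value = sorted(rng.sample(list(values), k))
    if op == "contains":
        value = str(value)[: rng.randint(2, max(2, len(str(value))))]
    policy = rng.choice(["exclude", "exclude", "include"])
    return FilterNode.make_atom(
        field_name=field_name, operator=op, value=value,
        missing_policy=policy,
    )


def random_filter_tree(
    rng: random.Random, max_depth: int = 4, max_atoms: int = 10
):
    """Random AND/OR tree with bounded depth and atom count."""
    from .filters import FilterNode

    budget = [rng.randint(1, max_atoms)]

    def build(depth: int):
        budget[0] -= 1
        if depth >= max_depth or budget[0] <= 0 or rng.random() < 0.4:
            return random_filter_atom(rng)
        n_children = rng.randint(1, 3)
        children = [build(depth + 1) for _ in range(n_children)]
        return FilterNode.make_group(rng.choice(["AND", "OR"]), children)

    return build(1)


def generate_filter_corpus(
    seed: int, n_variants: int = 500
) -> Tuple[str, str]:
    """Single-sample VCF plus a 'knowledge' annotation table exercising
    every corpus field, with deliberate gaps (missing annotations) so the
    missing-value policies are hit."""
    rng = random.Random(seed)
    positions = sorted(
        rng.sample(range(1_000, CONTIG_LENGTH - 1_000), n_variants)
    )
    vcf_lines = [_vcf_header(["S1"])]
    ann_lines = [
        "chrom\tpos\tref\talt\tglobal_maf\teffect\tlocation\tgene_symbol\n"
    ]
    for pos in positions:
        ref, alt = _random_snv(rng)
        qual = rng.uniform(50, 3000)
        genotype = rng.choice(["het", "het", "hom_alt"])
        vcf_lines.append(
            "\t".join(
                [
                    CONTIG, str(pos), ".", ref, alt, f"{qual:.2f}", "PASS",
                    _info_column(rng), "GT:AD:GQ",
                    _genotype_columns(rng, genotype),
                ]
            )
            + "\n"
        )
        if rng.random() < 0.85:  # 15% stay unannotated
            maf = (
                f"{rng.uniform(0.0001, 0.45):.4f}"
                if rng.random() < 0.8
                else "."
            )
            effect = rng.choice(
                ["synonymous", "missense", "stopgain", "frameshift", "."]
            )
            location = rng.choice(
                ["exonic", "intronic", "splicing", "intergenic"]
            )
            gene = rng.choice(["GENE1", "GENE2", "NCRNA1", "."])
            ann_lines.append(
                f"{CONTIG}\t{pos}\t{ref}\t{alt}\t{maf}\t{effect}\t"
                f"{location}\t{gene}\n"
            )
    return "".join(vcf_lines), "".join(ann_lines)
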