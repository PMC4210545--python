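"""Core domain records.

The identity of the whole system is the normalized variant: the 5-tuple
(build, chrom, pos, ref, alt) with ``pos`` 1-based at the first changed base.
Genotype calls attach one sample's genotype and its GATK quality vector to a
variant; any quality field may be absent and is then ``None``, never a
sentinel number.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")
GENDERS = ("male", "female", "unknown")
ROLES = ("read_only", "edit", "admin")
ROLE_RANK = {r: i for i, r in enumerate(ROLES)}

_ALLELE_RE = re.compile(r"^[ACGT]+$")


def validate_alleles(ref: str, alt: str) -> None:
    """Reject symbolic, empty, lowercase or identical alleles."""
    for name, allele in (("ref", ref), ("alt", alt)):
        if not allele or not _ALLELE_RE.match(allele):
            raise ValidationError(
                f"{name} allele {allele!r} is not a plain A/C/G/T sequence"
            )
    if ref == alt:
        raise ValidationError(f"ref and alt are identical ({ref!r})")


@dataclass(frozen=True)
class Variant:
    """A normalized genomic change on a named genome build."""

    build: str
    chrom: str
    pos: int  # 1-based, first changed base
    ref: str
    alt: str
    variant_id: Optional[int] = None

    def __post_init__(self) -> None:
        validate_alleles(self.ref, self.alt)
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def end(self) -> int:
        """Last reference base affected (1-based, inclusive)."""
        return self.pos + len(self.ref) - 1

    def key(self) -> tuple:
        return (self.build, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeCall:
    """Per-(sample, variant) genotype plus the GATK quality vector.

    ``None`` means the field was absent from the VCF; it is stored as NULL
    and surfaces as ``None`` again on retrieval.
    """

    sample_id: str
    variant_id: int
    genotype: str
    qual: Optional[float] = None
    gq: Optional[float] = None
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    qd: Optional[float] = None
    mq: Optional[float] = None
    fs: Optional[float] = None
    base_q_rank_sum: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    filter_status: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")

    @property
    def allelic_ratio(self) -> Optional[float]:
        """ad_alt / (ad_ref + ad_alt); None when depths are absent or zero."""
        if self.ad_ref is None or self.ad_alt is None:
            return None
        depth = self.ad_ref + self.ad_alt
        if depth <= 0:
            return None
        return self.ad_alt / depth

    @property
    def is_carrier(self) -> bool:
        return self.genotype in ("het", "hom_alt")


@dataclass
class Sample:
    sample_id: str
    project_id: int
    display_name: Optional[str] = None
    gender: str = "unknown"
    hpo_terms: tuple = ()
    is_control: bool = False
    affected: bool = False
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sibling_ids: tuple = ()
    bam_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")


@dataclass
class Project:
    project_id: int
    name: str
    grants: dict = field(default_factory=dict)  # user_id -> role


@dataclass
class UserClassification:
    variant_id: int
    sample_id: str
    inheritance_note: Optional[str] = None
    validation_status: Optional[str] = None
    diagnostic_class: Optional[str] = None
    free_text: Optional[str] = None


@dataclass
class ImportSummary:
    sample_id: str
    build: str
    n_records_read: int = 0
    n_variants_imported: int = 0
    n_multiallelic_split: int = 0
    skipped: dict = field(default_factory=dict)  # reason -> count

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


@dataclass
class AnnotationRecord:
    variant_id: int
    source_name: str
    field_name: str
    value: Optional[str]
    source_version: str
    active: bool
    created_at: str
    retired_at: Optional[str] = None
    record_id: Optional[int] = None


@dataclass
class ChangeLogEntry:
    variant_id: int
    source_name: str
    field_name: str
    old_value: Optional[str]
    new_value: Optional[str]
    old_version: Optional[str]
    new_version: str
    timestamp: str
    interesting: bool = False
    entry_id: Optional[int] = None


@dataclass
class Transcript:
    """One transcript of a gene model.

    Exons are 1-based inclusive intervals sorted by start and non-overlapping;
    the CDS interval, when present, lies within the transcript span.  The CDS
    sequence, when supplied, is the spliced coding sequence in translation
    order (already reverse-complemented for minus-strand transcripts).
    """

    transcript_id: str
    gene_symbol: str
    nomenclature: str  # refseq | ensembl | ucsc
    chrom: str
    strand: str  # + | -
    exons: Sequence[tuple]  # [(start, end), ...] 1-based inclusive
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons {e1} >= {s2}"
                )
        for s, e in exons:
            if s > e:
                raise ValidationError(f"{self.transcript_id}: empty exon {s}-{e}")
        object.__setattr__(self, "exons", tuple(exons))
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start <= self.cds_end <= self.end):
                raise ValidationError(
                    f"{self.transcript_id}: CDS outside transcript span"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def coding_segments(self) -> list:
        """Genomic (start, end) pieces of the CDS, ascending order."""
        if not self.is_coding:
            return []
        segs = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                segs.append((s2, e2))
        return segs


@dataclass
class TranscriptAnnotation:
    """Per-transcript consequence of one variant."""

    transcript_id: str
    gene_symbol: str
    nomenclature: str
    location: str  # exonic|intronic|splicing|utr|upstream|downstream
    effect: Optional[str] = None  # synonymous|missense|stopgain|stoploss|
    #                               frameshift|inframe|noncoding|unavailable
    cds_pos: Optional[int] = None  # 1-based position in CDS for exonic SNVs


@dataclass
class VariantSummarySet:
    tr_count: int
    tv_count: int
    trtv_ratio: Optional[float]
    n_known: int
    n_novel: int
    n_snp: int
    n_indel: int
    maf_bin_edges: tuple
    maf_histogram: tuple  # len(edges) - 1 counts
    n_maf_missing: int


@dataclass
class ConversionFailure:
    variant: Variant
    reason: str  # unmapped | split_across_blocks | ref_changed |
    #              strand_flip_unsupported


@dataclass
class ConversionReport:
    n_converted: int
    failures: list = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.failures)
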