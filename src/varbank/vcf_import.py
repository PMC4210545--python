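"""VCF 4.x import.

Records are split into biallelic changes, trimmed to their minimal
representation and loaded into the store together with the per-sample GATK
quality vector (QUAL, GQ, GT, AD plus the INFO fields QD, MQ, FS and the
three rank sums) and the verbatim FILTER column.

Trimming removes context bases shared between REF and ALT: the shared suffix
is removed first, then the shared prefix with the position advanced, always
retaining at least one base in each allele.  No reference FASTA is consulted,
so indels in repeat tracts are not left-aligned; identical changes imported
through different padded representations collapse only when their trimmed
forms agree.

Hom-ref records are skipped by default (reason ``non-variant``); half-calls
such as ``./1`` count as heterozygous and a fully missing GT is imported with
genotype ``missing`` so that occurrence counting stays explicit.
"""
from __future__ import annotations

import gzip
import io
import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pysam

from .errors import (
    BuildConflictError,
    FormatError,
    NotFoundError,
    ValidationError,
)
from .models import GenotypeCall, ImportSummary, validate_alleles
from .store import VariantStore

log = logging.getLogger(__name__)

_SYMBOLIC = ("<", ">", "[", "]", ".", "*")

_INFO_FIELDS = {
    "QD": "qd",
    "MQ": "mq",
    "FS": "fs",
    "BaseQRankSum": "base_q_rank_sum",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
}


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple:
    """Trim shared context to the minimal representation.

    Returns ``(chrom, pos', ref', alt')`` with the shared suffix removed
    first, then the shared prefix (advancing ``pos``), keeping at least one
    base in each allele.  Idempotent.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical; nothing to normalize")
    # suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def is_symbolic(allele: str) -> bool:
    return any(ch in allele for ch in _SYMBOLIC) or not allele


@dataclass
class SplitCall:
    """One biallelic change projected out of a VCF record for one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    ad_ref: Optional[int]
    ad_alt: Optional[int]
    gq: Optional[float]
    qual: Optional[float]
    qd: Optional[float]
    mq: Optional[float]
    fs: Optional[float]
    base_q_rank_sum: Optional[float]
    mq_rank_sum: Optional[float]
    read_pos_rank_sum: Optional[float]
    filter_status: Optional[str]


def _as_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, tuple):
        value = value[0] if value else None
        if value is None:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        log.warning("unparsable numeric field value %r; stored missing", value)
        return None


def _as_int(value) -> Optional[int]:
    f = _as_float(value)
    return None if f is None else int(f)


def genotype_for_allele(alleles: Sequence[Optional[int]], alt_index: int) -> str:
    """Re-express a GT tuple relative to one ALT allele.

    ``alleles`` holds VCF allele indices (``None`` = missing).  A fully
    missing GT maps to ``missing``; a half-call carrying the allele counts as
    het; a haploid call of the allele (male X) counts as hom_alt.
    """
    known = [a for a in alleles if a is not None]
    if not known:
        return "missing"
    count = sum(1 for a in known if a == alt_index)
    ploidy = len(alleles)
    if count == 0:
        return "hom_ref"
    if count >= 2 or (ploidy == 1 and count == 1):
        return "hom_alt"
    return "het"


def _filter_string(rec) -> Optional[str]:
    keys = list(rec.filter.keys())
    if not keys:
        return None
    return ";".join(keys)


def extract_gatk_fields(rec, sample: str) -> list:
    """Project a parsed VCF record into per-ALT :class:`SplitCall` objects.

    One entry per ALT allele; AD is re-expressed as (ref depth, that allele's
    depth).  Site-level INFO fields are carried onto every split entry.
    Missing or unparsable fields become ``None``.
    """
    sdata = rec.samples[sample]
    alleles = sdata.get("GT", (None,))
    if alleles is None:
        alleles = (None,)
    ad = sdata.get("AD")
    gq = _as_float(sdata.get("GQ"))
    info = {}
    for theirs, ours in _INFO_FIELDS.items():
        try:
            raw = rec.info.get(theirs)
        except (KeyError, ValueError):
            raw = None  # field not declared in this VCF's header
        info[ours] = _as_float(raw)
    qual = rec.qual if rec.qual is not None else None
    filt = _filter_string(rec)
    out = []
    alts = rec.alts or ()
    for i, alt in enumerate(alts, start=1):
        ad_ref = ad_alt = None
        if ad is not None and len(ad) > i and ad[0] is not None:
            ad_ref = _as_int(ad[0])
            ad_alt = _as_int(ad[i])
        out.append(
            SplitCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                genotype=genotype_for_allele(alleles, i),
                ad_ref=ad_ref,
                ad_alt=ad_alt,
                gq=gq,
                qual=qual,
                filter_status=filt,
                **info,
            )
        )
    return out


def split_multiallelic(rec, sample: str) -> list:
    """Alias of :func:`extract_gatk_fields`; a k-ALT record yields k
    biallelic projections (k = 1 returns the record's single change)."""
    return extract_gatk_fields(rec, sample)


def _open_variant_file(source: Union[str, Path, io.IOBase]):
    """Open a path, gzip path or text stream as a pysam VariantFile."""
    if isinstance(source, (str, Path)):
        path = str(source)
        try:
            return pysam.VariantFile(path), None
        except ValueError as exc:
            raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    # stream: spool to a temp file so pysam/htslib can seek
    text = source.read()
    if isinstance(text, bytes):
        try:
            text = gzip.decompress(text).decode()
        except (OSError, gzip.BadGzipFile):
            text = text.decode()
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".vcf", delete=False
    )
    tmp.write(text)
    tmp.close()
    try:
        return pysam.VariantFile(tmp.name), tmp.name
    except ValueError as exc:
        raise FormatError(f"cannot parse VCF stream: {exc}") from exc


def import_vcf(
    store: VariantStore,
    sample_id: str,
    vcf: Union[str, Path, io.IOBase],
    declared_build: str,
    sample_column: Optional[str] = None,
    keep_homref: bool = False,
    overwrite: bool = True,
) -> ImportSummary:
    """Load one sample column of a VCF into the store, atomically.

    The declared genome build must agree with the store's current build
    (set on first import); a mismatch raises :class:`BuildConflictError`
    before anything is written.
    """
    store._require_sample(sample_id)
    current = store.current_build
    if current is None:
        store.set_current_build(declared_build)
    elif current != declared_build:
        raise BuildConflictError(
            f"declared build {declared_build!r} conflicts with the store's "
            f"current build {current!r}; nothing imported"
        )

    vf, tmp_name = _open_variant_file(vcf)
    try:
        header_samples = list(vf.header.samples)
        if not header_samples:
            raise FormatError("VCF has no sample columns (#CHROM header line)")
        column = sample_column or sample_id
        if column not in header_samples:
            if sample_column is None and len(header_samples) == 1:
                column = header_samples[0]
            else:
                raise NotFoundError(
                    f"sample column {column!r} not in VCF "
                    f"(has {header_samples})"
                )

        summary = ImportSummary(sample_id=sample_id, build=declared_build)
        staged = []
        for rec in vf:
            summary.n_records_read += 1
            alts = rec.alts or ()
            if not alts:
                summary.skipped["no-alt"] = summary.skipped.get("no-alt", 0) + 1
                continue
            if is_symbolic(rec.ref) or any(is_symbolic(a) for a in alts):
                summary.skipped["symbolic"] = (
                    summary.skipped.get("symbolic", 0) + 1
                )
                continue
            pieces = extract_gatk_fields(rec, column)
            if len(pieces) > 1:
                summary.n_multiallelic_split += 1
            for piece in pieces:
                if piece.genotype == "hom_ref" and not keep_homref:
                    summary.skipped["non-variant"] = (
                        summary.skipped.get("non-variant", 0) + 1
                    )
                    continue
                # normalize and validate now, so the write phase below
                # cannot fail on malformed data (all-or-nothing import)
                try:
                    chrom, pos, ref, alt = normalize_variant(
                        piece.chrom, piece.pos, piece.ref.upper(),
                        piece.alt.upper(),
                    )
                    validate_alleles(ref, alt)
                except (ValueError, ValidationError):
                    summary.skipped["malformed-allele"] = (
                        summary.skipped.get("malformed-allele", 0) + 1
                    )
                    continue
                piece.chrom, piece.pos, piece.ref, piece.alt = (
                    chrom, pos, ref, alt,
                )
                staged.append(piece)
    finally:
        vf.close()
        if tmp_name:
            Path(tmp_name).unlink(missing_ok=True)

    for piece in staged:
        vid = store.upsert_variant(
            declared_build, piece.chrom, piece.pos, piece.ref, piece.alt
        )
        call = GenotypeCall(
            sample_id=sample_id,
            variant_id=vid,
            genotype=piece.genotype,
            qual=piece.qual,
            gq=piece.gq,
            ad_ref=piece.ad_ref,
            ad_alt=piece.ad_alt,
            qd=piece.qd,
            mq=piece.mq,
            fs=piece.fs,
            base_q_rank_sum=piece.base_q_rank_sum,
            mq_rank_sum=piece.mq_rank_sum,
            read_pos_rank_sum=piece.read_pos_rank_sum,
            filter_status=piece.filter_status,
        )
        store.store_call(call, overwrite=overwrite)
        summary.n_variants_imported += 1
    return summary
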