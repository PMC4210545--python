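"""Gene models and per-transcript variant consequences.

Transcripts are loaded from a BED12-like file (blocks = exons, thick
interval = CDS) with the name column carrying ``transcript_id|gene_symbol``;
CDS sequences come from a FASTA keyed by transcript id.  An interval tree
per chromosome answers overlap queries.

Consequence calling:

* location: ``exonic`` (touches an exon), ``utr`` (exonic but outside the
  CDS of a coding transcript), ``splicing`` (intronic within ``splice_window``
  bases of an exon boundary; default 2, configurable), ``intronic``,
  ``upstream``/``downstream`` (within ``flank`` bases of the transcript span,
  relative to transcript orientation).
* coding effect, for transcripts with a CDS sequence: SNVs are classified by
  codon substitution (synonymous / missense / stopgain / stoploss); indels
  touching the CDS are ``frameshift`` when the length change is not a
  multiple of 3, else ``inframe``.  Without a CDS sequence the effect is
  ``unavailable``.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import FormatError, ValidationError
from .models import Transcript, TranscriptAnnotation, Variant

HIGH_IMPACT_EFFECTS = frozenset({"frameshift", "stopgain", "splicing"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def load_bed12(
    path_or_lines, nomenclature: str = "refseq"
) -> List[Transcript]:
    """Read transcripts from a BED12-like file.

    Columns: chrom, chromStart (0-based), chromEnd, name
    (``transcript_id|gene_symbol``), score, strand, thickStart, thickEnd,
    itemRgb, blockCount, blockSizes, blockStarts.  thickStart == thickEnd
    marks a non-coding transcript.
    """
    if isinstance(path_or_lines, (str, bytes)) and str(path_or_lines) and (
        "\n" not in str(path_or_lines)
    ):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    elif isinstance(path_or_lines, str):
        lines = path_or_lines.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in path_or_lines]
    out = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise FormatError(
                f"line {lineno}: expected 12 BED columns, got {len(parts)}"
            )
        chrom = parts[0]
        start0 = int(parts[1])
        name = parts[3]
        strand = parts[5]
        thick_start0, thick_end0 = int(parts[6]), int(parts[7])
        n_blocks = int(parts[9])
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(f"line {lineno}: block count mismatch")
        exons = [
            (start0 + off + 1, start0 + off + size)
            for off, size in zip(offsets, sizes)
        ]
        if "|" in name:
            tid, gene = name.split("|", 1)
        else:
            tid = gene = name
        cds_start = cds_end = None
        if thick_end0 > thick_start0:
            cds_start, cds_end = thick_start0 + 1, thick_end0
        out.append(
            Transcript(
                transcript_id=tid,
                gene_symbol=gene,
                nomenclature=nomenclature,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return out


def attach_cds_sequences(
    transcripts: Sequence[Transcript], fasta_path_or_handle
) -> None:
    """Attach spliced CDS sequences from a FASTA keyed by transcript id."""
    records = SeqIO.to_dict(SeqIO.parse(fasta_path_or_handle, "fasta"))
    for tx in transcripts:
        rec = records.get(tx.transcript_id)
        if rec is not None:
            tx.cds_sequence = str(rec.seq).upper()


class GeneModelIndex:
    """Overlap index over a set of transcripts (one genome build)."""

    def __init__(self, transcripts: Iterable[Transcript], flank: int = 1000):
        self.flank = flank
        self.transcripts: List[Transcript] = list(transcripts)
        self._trees: Dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            # half-open interval including the flank for up/downstream hits
            tree.addi(tx.start - flank, tx.end + flank + 1, tx)

    def by_id(self, transcript_id: str) -> Optional[Transcript]:
        base = transcript_id.split(".")[0]
        for tx in self.transcripts:
            if tx.transcript_id.split(".")[0] == base:
                return tx
        return None

    def overlapping(self, chrom: str, start: int, end: int) -> List[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))


def cds_coordinate(tx: Transcript, pos: int) -> Optional[int]:
    """1-based position within the spliced CDS, in translation order.

    ``None`` when ``pos`` does not fall inside a coding segment.
    """
    segs = tx.coding_segments()
    offset = 0
    if tx.strand == "+":
        for s, e in segs:
            if s <= pos <= e:
                return offset + (pos - s) + 1
            offset += e - s + 1
    else:
        for s, e in reversed(segs):
            if s <= pos <= e:
                return offset + (e - pos) + 1
            offset += e - s + 1
    return None


def _snv_effect(tx: Transcript, pos: int, ref: str, alt: str) -> tuple:
    """(effect, cds_pos) for a single-base substitution inside the CDS."""
    cpos = cds_coordinate(tx, pos)
    if cpos is None:
        return ("unavailable", None)
    if not tx.cds_sequence:
        return ("unavailable", cpos)
    cds = tx.cds_sequence
    if cpos > len(cds):
        return ("unavailable", cpos)
    if tx.strand == "+":
        ref_c, alt_c = ref, alt
    else:
        ref_c = ref.translate(_COMPLEMENT)
        alt_c = alt.translate(_COMPLEMENT)
    codon_idx = (cpos - 1) // 3
    within = (cpos - 1) % 3
    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    if len(codon) < 3:
        return ("unavailable", cpos)
    new_codon = codon[:within] + alt_c + codon[within + 1:]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        return ("synonymous", cpos)
    if new_aa == "*":
        return ("stopgain", cpos)
    if old_aa == "*":
        return ("stoploss", cpos)
    return ("missense", cpos)


def classify_variant(
    variant: Variant,
    index: GeneModelIndex,
    splice_window: int = 2,
) -> List[TranscriptAnnotation]:
    """Per-transcript consequences of one variant.

    Returns one :class:`TranscriptAnnotation` per transcript whose span
    (plus flank) the variant touches; an empty list means intergenic.
    """
    start, end = variant.pos, variant.end
    out = []
    for tx in index.overlapping(variant.chrom, start, end):
        ann = _classify_for_transcript(variant, tx, splice_window, index.flank)
        if ann is not None:
            out.append(ann)
    return out


def _classify_for_transcript(
    variant: Variant,
    tx: Transcript,
    splice_window: int,
    flank: int,
) -> Optional[TranscriptAnnotation]:
    start, end = variant.pos, variant.end

    def make(location, effect=None, cds_pos=None):
        return TranscriptAnnotation(
            transcript_id=tx.transcript_id,
            gene_symbol=tx.gene_symbol,
            nomenclature=tx.nomenclature,
            location=location,
            effect=effect,
            cds_pos=cds_pos,
        )

    if end < tx.start:
        if tx.start - end > flank:
            return None
        return make("upstream" if tx.strand == "+" else "downstream")
    if start > tx.end:
        if start - tx.end > flank:
            return None
        return make("downstream" if tx.strand == "+" else "upstream")

    touches_exon = any(
        s <= end and start <= e for s, e in tx.exons
    )
    if touches_exon:
        if not tx.is_coding:
            return make("exonic", "noncoding")
        in_cds = start <= tx.cds_end and end >= tx.cds_start and any(
            s <= end and start <= e for s, e in tx.coding_segments()
        )
        if not in_cds:
            return make("utr")
        if variant.is_snv:
            effect, cpos = _snv_effect(tx, start, variant.ref, variant.alt)
            return make("exonic", effect, cpos)
        # indel (or MNV) touching the CDS
        delta = abs(len(variant.ref) - len(variant.alt))
        if delta == 0:
            return make("exonic", "unavailable")
        effect = "frameshift" if delta % 3 != 0 else "inframe"
        return make("exonic", effect, cds_coordinate(tx, start))

    # fully intronic: distance to the nearest exon boundary
    dist = None
    for s, e in tx.exons:
        if e < start:
            d = start - e
        elif s > end:
            d = s - end
        else:
            continue
        dist = d if dist is None else min(dist, d)
    if dist is not None and dist <= splice_window:
        return make("splicing", "splicing")
    return make("intronic")


def build_gene_model_source_values(
    annotations: Sequence[TranscriptAnnotation],
) -> Dict[str, str]:
    """Collapse per-transcript annotations into pipe-joined field values."""
    from .reporting import join_multi  # local import avoids a cycle

    if not annotations:
        return {"location": "intergenic"}
    fields = {
        "transcript_id": [a.transcript_id for a in annotations],
        "gene_symbol": [a.gene_symbol for a in annotations],
        "location": [a.location for a in annotations],
        "effect": [a.effect or "unavailable" for a in annotations],
    }
    return {k: join_multi(v) for k, v in fields.items()}


def validate_gene_models(transcripts: Sequence[Transcript]) -> None:
    """Raise if any transcript violates the gene-model invariants."""
    seen = set()
    for tx in transcripts:
        if tx.transcript_id in seen:
            raise ValidationError(f"duplicate transcript {tx.transcript_id}")
        seen.add(tx.transcript_id)
        if tx.is_coding and tx.cds_sequence is not None:
            span = sum(e - s + 1 for s, e in tx.coding_segments())
            if span != len(tx.cds_sequence):
                raise ValidationError(
                    f"{tx.transcript_id}: CDS sequence length "
                    f"{len(tx.cds_sequence)} != genomic CDS span {span}"
                )
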