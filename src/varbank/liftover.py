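"""Genome-build conversion through UCSC chain files.

A chain is a gapped alignment between a source and a target assembly:
``chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart
qEnd id`` followed by alignment lines ``size dt dq`` (the last line a bare
size).  Coordinates are kept 0-based half-open internally and converted at
the variant boundary.

Positions falling in a source gap are unmapped; variants whose reference
span crosses an alignment-segment boundary fail as ``split_across_blocks``;
chains aligning to the minus strand of the target would require
reverse-complementing the alleles and are rejected as
``strand_flip_unsupported``.  Failures are data, not exceptions: they are
queued for manual curation.  After conversion the source build is flagged
read-only with its final annotations frozen.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .errors import FormatError, NotFoundError, ValidationError
from .models import ConversionFailure, ConversionReport, GenotypeCall, Variant
from .store import VariantStore


@dataclass
class ChainBlock:
    """One chain: an alignment between a source and target interval."""

    score: float
    chain_id: Optional[str]
    s_chrom: str
    s_size: int
    s_strand: str
    s_start: int  # 0-based half-open
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    segments: List[Tuple[int, int, int]] = field(default_factory=list)
    # (aligned size, gap in source after segment, gap in target after)

    def validate(self) -> None:
        s_span = sum(size + ds for size, ds, _ in self.segments)
        t_span = sum(size + dt for size, _, dt in self.segments)
        if s_span != self.s_end - self.s_start:
            raise FormatError(
                f"chain {self.chain_id}: segment sizes sum to {s_span}, "
                f"source interval is {self.s_end - self.s_start}"
            )
        if t_span != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.chain_id}: segment sizes sum to {t_span}, "
                f"target interval is {self.t_end - self.t_start}"
            )


def parse_chain(source: Union[str, Path, io.IOBase]) -> List[ChainBlock]:
    """Parse a UCSC chain file (path, text, or stream)."""
    if isinstance(source, (str, Path)) and str(source) and (
        "\n" not in str(source)
    ):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    blocks: List[ChainBlock] = []
    current: Optional[ChainBlock] = None
    done = True
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            if current is not None and not done:
                raise FormatError(
                    f"line {lineno}: new chain before previous one ended"
                )
            parts = line.split()
            if len(parts) not in (12, 13):
                raise FormatError(
                    f"line {lineno}: malformed chain header "
                    f"({len(parts)} fields)"
                )
            try:
                current = ChainBlock(
                    score=float(parts[1]),
                    s_chrom=parts[2],
                    s_size=int(parts[3]),
                    s_strand=parts[4],
                    s_start=int(parts[5]),
                    s_end=int(parts[6]),
                    t_chrom=parts[7],
                    t_size=int(parts[8]),
                    t_strand=parts[9],
                    t_start=int(parts[10]),
                    t_end=int(parts[11]),
                    chain_id=parts[12] if len(parts) == 13 else None,
                )
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: malformed chain header: {exc}"
                ) from exc
            if current.s_strand != "+":
                raise FormatError(
                    f"line {lineno}: source strand must be '+'"
                )
            blocks.append(current)
            done = False
        else:
            if current is None:
                raise FormatError(
                    f"line {lineno}: alignment line outside a chain"
                )
            parts = line.split()
            try:
                nums = [int(p) for p in parts]
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: malformed alignment line"
                ) from exc
            if len(nums) == 1:
                current.segments.append((nums[0], 0, 0))
                done = True
            elif len(nums) == 3:
                current.segments.append((nums[0], nums[1], nums[2]))
            else:
                raise FormatError(
                    f"line {lineno}: alignment line needs 1 or 3 numbers"
                )
    for block in blocks:
        block.validate()
    return blocks


def _map_through_block(
    block: ChainBlock, pos0: int, span: int = 1
):
    """Map a 0-based source position (with a span) through one chain.

    Returns (t_chrom, t_pos0) or a failure-reason string, or None when the
    chain does not cover the position at all.
    """
    if not (block.s_start <= pos0 < block.s_end):
        return None
    if block.t_strand != "+":
        return "strand_flip_unsupported"
    cur_s, cur_t = block.s_start, block.t_start
    for size, ds, dt in block.segments:
        if cur_s <= pos0 < cur_s + size:
            if pos0 + span > cur_s + size:
                return "split_across_blocks"
            return (block.t_chrom, cur_t + (pos0 - cur_s))
        cur_s += size + ds
        cur_t += size + dt
        if pos0 < cur_s - ds:
            break
        if cur_s - ds <= pos0 < cur_s:
            return "unmapped"  # inside a source gap
    return "unmapped"


def convert_position(
    chrom: str,
    pos: int,
    chains: Sequence[ChainBlock],
    span: int = 1,
) -> Union[Tuple[str, int], str]:
    """Convert a 1-based position; returns (chrom', pos') or a failure
    reason (unmapped, split_across_blocks, strand_flip_unsupported)."""
    pos0 = pos - 1
    candidates = [b for b in chains if b.s_chrom == chrom]
    best_reason = "unmapped"
    for block in sorted(candidates, key=lambda b: -b.score):
        result = _map_through_block(block, pos0, span)
        if result is None:
            continue
        if isinstance(result, tuple):
            t_chrom, t_pos0 = result
            return (t_chrom, t_pos0 + 1)
        best_reason = result
    return best_reason


def convert_store(
    store: VariantStore,
    chains: Sequence[ChainBlock],
    new_build: str,
    sources: Sequence = (),
    target_sequences: Optional[Dict[str, str]] = None,
) -> ConversionReport:
    """Convert every variant of the current build to ``new_build``.

    Converted variants (and their genotype calls) are inserted under the new
    build; failures are queued for manual curation with their reason; the
    old build is then retired read-only and, when annotation ``sources`` are
    supplied, the new coordinates are re-annotated.  When
    ``target_sequences`` (chrom -> sequence) is given, the reference allele
    is verified on the new build and mismatches fail as ``ref_changed``.
    """
    from .annotation import annotate_missing

    if not chains:
        raise ValidationError("no chains supplied; conversion aborted")
    old_build = store.current_build
    if old_build is None:
        raise NotFoundError("store has no current build to convert from")
    if old_build == new_build:
        raise ValidationError("source and target build are identical")
    store.register_build(new_build)
    variants = store.variants(old_build)
    report = ConversionReport(n_converted=0)
    for variant in variants:
        result = convert_position(
            variant.chrom, variant.pos, chains, span=len(variant.ref)
        )
        if not isinstance(result, tuple):
            report.failures.append(ConversionFailure(variant, result))
            store.queue_curation(variant.variant_id, result)
            continue
        t_chrom, t_pos = result
        if target_sequences is not None:
            seq = target_sequences.get(t_chrom, "")
            found = seq[t_pos - 1: t_pos - 1 + len(variant.ref)].upper()
            if found != variant.ref:
                report.failures.append(
                    ConversionFailure(variant, "ref_changed")
                )
                store.queue_curation(variant.variant_id, "ref_changed")
                continue
        new_vid = store.upsert_variant(
            new_build, t_chrom, t_pos, variant.ref, variant.alt
        )
        for call in store.calls_for_variant(variant.variant_id):
            moved = GenotypeCall(
                **{
                    **call.__dict__,
                    "variant_id": new_vid,
                }
            )
            store.store_call(moved, overwrite=True)
        report.n_converted += 1
    store.retire_build(old_build)
    store.set_current_build(new_build)
    for source in sources:
        annotate_missing(store, source, build=new_build)
    return report
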