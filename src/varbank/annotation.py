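"""Versioned annotation engine.

Annotation sources are pluggable providers that map a batch of variants to
(field -> value) dictionaries.  The engine implements the
collect-missing / annotate / store cycle, release updates with archival of
superseded records, a change log, and flagging of putatively interesting
changes (gained high-impact coding effect, or a clinical class turning
pathogenic).

All providers here are offline and table-driven: tab-delimited tables keyed
on (chrom, pos, ref, alt) for frequencies, clinical assertions and
prediction scores, and a gene-model provider computing per-transcript
consequences.  Adapters that shell out to live annotation services would
implement the same ``lookup`` contract; none are shipped.

Variants for which a source has no data receive an explicit no-hit sentinel
record so the annotate-missing cycle is idempotent and never re-queries them.
"""
from __future__ import annotations

import datetime
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

from .errors import ConflictError, ValidationError
from .genemodel import (
    GeneModelIndex,
    build_gene_model_source_values,
    classify_variant,
)
from .models import ChangeLogEntry, Variant
from .store import VariantStore

NO_HIT_FIELD = "__no_hit__"

PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})
ACMG_CLASSES = (
    "benign", "likely_benign", "uncertain_significance",
    "likely_pathogenic", "pathogenic",
)
HIGH_IMPACT_TERMS = frozenset({"frameshift", "stopgain", "splicing"})
DEFAULT_EFFECT_FIELDS = frozenset({"effect"})
DEFAULT_CLINICAL_FIELDS = frozenset(
    {"clinical_significance", "pathogenic_class"}
)


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _to_text(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


@dataclass
class TableAnnotationSource:
    """Offline source backed by a tab-delimited table keyed on
    chrom/pos/ref/alt.  Column values equal to '' or '.' mean absent."""

    name: str
    version: str
    fields: Sequence[str]
    table: Mapping[tuple, Dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(
        cls,
        name: str,
        version: str,
        source: Union[str, Path, io.IOBase],
    ) -> "TableAnnotationSource":
        if isinstance(source, (str, Path)) and str(source) and (
            "\n" not in str(source)
        ):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValidationError(f"annotation table for {name!r} is empty")
        header = lines[0].lstrip("#").split("\t")
        required = ("chrom", "pos", "ref", "alt")
        if tuple(header[:4]) != required:
            raise ValidationError(
                f"annotation table for {name!r} must start with columns "
                f"{required}, got {header[:4]}"
            )
        fields = header[4:]
        if len(set(fields)) != len(fields):
            raise ValidationError(f"duplicate field names in source {name!r}")
        table: Dict[tuple, Dict[str, str]] = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            key = (parts[0], int(parts[1]), parts[2], parts[3])
            values = {
                f: v
                for f, v in zip(fields, parts[4:])
                if v not in ("", ".")
            }
            table[key] = values
        return cls(name=name, version=version, fields=fields, table=table)

    def lookup(self, variants: Sequence[Variant]) -> Dict[int, Dict[str, str]]:
        out = {}
        for v in variants:
            hit = self.table.get((v.chrom, v.pos, v.ref, v.alt))
            if hit:
                out[v.variant_id] = dict(hit)
        return out


@dataclass
class GeneModelAnnotationSource:
    """Gene-model source computing per-transcript location/effect values.

    Multi-transcript values are pipe-joined into the single active record
    per field; variants outside every transcript annotate as intergenic.
    """

    name: str
    version: str
    index: GeneModelIndex
    splice_window: int = 2
    fields: Sequence[str] = (
        "transcript_id", "gene_symbol", "location", "effect",
    )

    def lookup(self, variants: Sequence[Variant]) -> Dict[int, Dict[str, str]]:
        out = {}
        for v in variants:
            anns = classify_variant(v, self.index, self.splice_window)
            out[v.variant_id] = build_gene_model_source_values(anns)
        return out


def lookup_frequency(
    variant: Variant, source: TableAnnotationSource
) -> Dict[str, str]:
    """Exact-allele frequency lookup; empty dict when the allele is absent.

    A present ``rsid`` marks the variant as known for reporting.
    """
    hit = source.table.get(
        (variant.chrom, variant.pos, variant.ref, variant.alt)
    )
    return dict(hit) if hit else {}


def annotate_missing(
    store: VariantStore,
    source,
    build: Optional[str] = None,
    batch_size: int = 500,
) -> int:
    """Annotate every variant lacking an active record from ``source``.

    Returns the number of variants annotated (no-hit sentinels included).
    Re-running immediately annotates zero.
    """
    store.register_source_version(source.name, source.version)
    missing = store.variants_missing_annotation(source.name, build)
    count = 0
    for i in range(0, len(missing), batch_size):
        batch = missing[i: i + batch_size]
        results = source.lookup(batch)
        for v in batch:
            values = {
                f: _to_text(val)
                for f, val in (results.get(v.variant_id) or {}).items()
                if val is not None
            }
            if values:
                for fname, val in values.items():
                    store.insert_annotation(
                        v.variant_id, source.name, fname, val, source.version
                    )
            else:
                store.insert_annotation(
                    v.variant_id, source.name, NO_HIT_FIELD, "1",
                    source.version,
                )
            count += 1
    return count


def update_source(
    store: VariantStore,
    source,
    build: Optional[str] = None,
    batch_size: int = 500,
) -> List[ChangeLogEntry]:
    """Re-annotate every stored variant against a new source release.

    Unchanged values keep their record; changed values retire the old record
    (archived, never deleted) and insert a new one; every change is logged.
    The new version label must not have been registered before.
    """
    if source.version in store.source_versions(source.name):
        raise ConflictError(
            f"version {source.version!r} of source {source.name!r} is not "
            "newer than the registered releases"
        )
    build = build or store.current_build
    variants = store.variants(build)
    changes: List[ChangeLogEntry] = []
    now = _now()
    for i in range(0, len(variants), batch_size):
        batch = variants[i: i + batch_size]
        results = source.lookup(batch)
        for v in batch:
            new_values = {
                f: _to_text(val)
                for f, val in (results.get(v.variant_id) or {}).items()
                if val is not None
            }
            old_records = store.active_annotation_records(
                v.variant_id, source.name
            )
            nohit = old_records.pop(NO_HIT_FIELD, None)
            for fname in sorted(set(old_records) | set(new_values)):
                old_rec = old_records.get(fname)
                old_val = old_rec.value if old_rec else None
                new_val = new_values.get(fname)
                if old_val == new_val:
                    continue  # unchanged: keep the existing record
                if old_rec is not None:
                    store.retire_annotation(old_rec.record_id)
                if new_val is not None:
                    store.insert_annotation(
                        v.variant_id, source.name, fname, new_val,
                        source.version,
                    )
                entry = ChangeLogEntry(
                    variant_id=v.variant_id,
                    source_name=source.name,
                    field_name=fname,
                    old_value=old_val,
                    new_value=new_val,
                    old_version=old_rec.source_version if old_rec else None,
                    new_version=source.version,
                    timestamp=now,
                )
                entry.entry_id = store.log_change(entry)
                changes.append(entry)
            if new_values:
                if nohit is not None:
                    store.retire_annotation(nohit.record_id)
            elif nohit is None:
                # nothing known now and nothing before: park a sentinel so
                # the annotate-missing cycle stays idempotent
                store.insert_annotation(
                    v.variant_id, source.name, NO_HIT_FIELD, "1",
                    source.version,
                )
    store.register_source_version(source.name, source.version)
    return changes


def _split_values(value: Optional[str]) -> List[str]:
    from .reporting import split_multi

    if value is None:
        return []
    return [v.strip().lower() for v in split_multi(value)]


def flag_interesting(
    changes: Sequence[ChangeLogEntry],
    effect_fields: frozenset = DEFAULT_EFFECT_FIELDS,
    clinical_fields: frozenset = DEFAULT_CLINICAL_FIELDS,
    high_impact_terms: frozenset = HIGH_IMPACT_TERMS,
    pathogenic_classes: frozenset = PATHOGENIC_CLASSES,
    store: Optional[VariantStore] = None,
) -> List[ChangeLogEntry]:
    """Select putatively interesting changes.

    A change is flagged when a gene-effect field gained a high-impact term
    (frameshift, stopgain, splicing) it did not carry before, or a clinical
    significance field moved into a pathogenic class.  When ``store`` is
    given the flags are persisted on the change log.
    """
    flagged = []
    for entry in changes:
        hit = False
        new_vals = set(_split_values(entry.new_value))
        old_vals = set(_split_values(entry.old_value))
        norm_new = {v.replace(" ", "_") for v in new_vals}
        norm_old = {v.replace(" ", "_") for v in old_vals}
        if entry.field_name in effect_fields:
            gained = (norm_new & high_impact_terms) - norm_old
            hit = bool(gained)
        elif entry.field_name in clinical_fields:
            hit = bool(norm_new & pathogenic_classes) and not (
                norm_old & pathogenic_classes
            )
        if hit:
            entry.interesting = True
            flagged.append(entry)
    if store is not None and flagged:
        store.mark_interesting(
            [e.entry_id for e in flagged if e.entry_id is not None]
        )
    return flagged


def replay_changes(
    first_values: Mapping[tuple, Optional[str]],
    changes: Sequence[ChangeLogEntry],
) -> Dict[tuple, Optional[str]]:
    """Apply a change log over first stored values.

    Keys are (variant_id, source, field).  The result must equal the current
    active values; used to audit history completeness.
    """
    state = dict(first_values)
    for entry in sorted(
        changes, key=lambda e: (e.entry_id if e.entry_id is not None else 0)
    ):
        key = (entry.variant_id, entry.source_name, entry.field_name)
        if entry.new_value is None:
            state.pop(key, None)
        else:
            state[key] = entry.new_value
    return {k: v for k, v in state.items() if v is not None}
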