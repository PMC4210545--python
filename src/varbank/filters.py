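"""Composable AND/OR filter trees and family/cohort filters.

A filter scheme is a tree of atoms and AND/OR groups evaluated over one
sample's variants.  Atoms compare a named field — a genotype-call quality
field, a variant property, or any stored annotation field — against a value.
Transcript-level annotation fields hold pipe-joined per-transcript values
and an atom passes the variant when ANY transcript value satisfies it,
so e.g. a stopgain in a single transcript variant is enough to keep the
variant.

Missing values have no universal truth value in comparisons, so every atom
carries an explicit ``missing_policy``: ``exclude`` (default) makes a
missing field fail the atom, ``include`` makes it pass.

Beyond the tree, dedicated filters cover Mendelian inheritance (de novo,
dominant, recessive via father/mother/sibling links), cohort occurrence
bounds, per-gene mutation burden (distinct carrier samples), and in-silico
gene panels of transcript identifiers.
"""
from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .errors import (
    FamilyConfigError,
    SchemeValidationError,
    ValidationError,
)
from .genemodel import GeneModelIndex
from .models import Variant
from .reporting import position_order, split_multi
from .store import VariantStore

SCHEME_SCHEMA_VERSION = 1

OPERATORS = (
    "eq", "ne", "lt", "le", "gt", "ge",
    "contains", "in_set", "is_missing", "not_missing",
)
NUMERIC_OPERATORS = {"lt", "le", "gt", "ge"}
MISSING_POLICIES = ("exclude", "include")

CALL_FIELDS = (
    "genotype", "qual", "gq", "ad_ref", "ad_alt", "allelic_ratio",
    "qd", "mq", "fs", "base_q_rank_sum", "mq_rank_sum",
    "read_pos_rank_sum", "filter_status",
)
VARIANT_FIELDS = ("chrom", "pos", "ref", "alt", "variant_type")
BUILTIN_FIELDS = set(CALL_FIELDS) | set(VARIANT_FIELDS)


@dataclass
class FilterAtom:
    field_name: str
    operator: str
    value: object = None
    category: str = "annotation"
    missing_policy: str = "exclude"

    def validate(self, known_fields: Optional[Set[str]] = None) -> None:
        if self.operator not in OPERATORS:
            raise SchemeValidationError(
                f"unknown operator {self.operator!r}"
            )
        if self.missing_policy not in MISSING_POLICIES:
            raise SchemeValidationError(
                f"unknown missing policy {self.missing_policy!r}"
            )
        if self.operator in NUMERIC_OPERATORS:
            try:
                float(self.value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise SchemeValidationError(
                    f"operator {self.operator!r} needs a numeric value, "
                    f"got {self.value!r}"
                )
        if self.operator == "in_set" and not isinstance(
            self.value, (list, tuple, set)
        ):
            raise SchemeValidationError("in_set needs a list of values")
        if known_fields is not None and self.field_name not in known_fields:
            raise SchemeValidationError(
                f"unknown field {self.field_name!r}"
            )

    def to_dict(self) -> dict:
        value = self.value
        if isinstance(value, (set, tuple)):
            value = sorted(value)
        return {
            "kind": "atom",
            "category": self.category,
            "field": self.field_name,
            "op": self.operator,
            "value": value,
            "missing_policy": self.missing_policy,
        }


@dataclass
class FilterNode:
    """Atom leaf or AND/OR group; evaluation is independent of child order."""

    kind: str  # "atom" | "group"
    logic: Optional[str] = None  # AND | OR for groups
    children: List["FilterNode"] = dc_field(default_factory=list)
    atom: Optional[FilterAtom] = None

    @classmethod
    def make_atom(cls, *args, **kwargs) -> "FilterNode":
        return cls(kind="atom", atom=FilterAtom(*args, **kwargs))

    @classmethod
    def make_group(
        cls, logic: str, children: Sequence["FilterNode"]
    ) -> "FilterNode":
        return cls(kind="group", logic=logic, children=list(children))

    def validate(self, known_fields: Optional[Set[str]] = None) -> None:
        if self.kind == "atom":
            if self.atom is None:
                raise SchemeValidationError("atom node without an atom")
            self.atom.validate(known_fields)
        elif self.kind == "group":
            if self.logic not in ("AND", "OR"):
                raise SchemeValidationError(
                    f"group logic must be AND or OR, got {self.logic!r}"
                )
            if not self.children:
                raise SchemeValidationError("empty filter group")
            for child in self.children:
                child.validate(known_fields)
        else:
            raise SchemeValidationError(f"unknown node kind {self.kind!r}")

    def to_dict(self) -> dict:
        if self.kind == "atom":
            return self.atom.to_dict()
        return {
            "kind": "group",
            "logic": self.logic,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FilterNode":
        kind = doc.get("kind")
        if kind == "atom":
            return cls.make_atom(
                field_name=doc["field"],
                operator=doc["op"],
                value=doc.get("value"),
                category=doc.get("category", "annotation"),
                missing_policy=doc.get("missing_policy", "exclude"),
            )
        if kind == "group":
            return cls.make_group(
                doc["logic"],
                [cls.from_dict(c) for c in doc.get("children", [])],
            )
        raise SchemeValidationError(f"unknown node kind {kind!r}")


@dataclass
class FilterScheme:
    name: str
    owner: str
    root: FilterNode
    created_at: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEME_SCHEMA_VERSION,
            "name": self.name,
            "owner": self.owner,
            "created_at": self.created_at,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FilterScheme":
        version = doc.get("schema_version")
        if version != SCHEME_SCHEMA_VERSION:
            raise SchemeValidationError(
                f"unsupported scheme schema version {version!r}"
            )
        return cls(
            name=doc["name"],
            owner=doc.get("owner", ""),
            root=FilterNode.from_dict(doc["root"]),
            created_at=doc.get("created_at", ""),
        )


# -- evaluation contexts -------------------------------------------------


def build_contexts(
    store: VariantStore, sample_id: str, build: Optional[str] = None
) -> List[Tuple[Variant, Dict[str, list]]]:
    """Per-variant field->values mapping for one sample's variants.

    Builtin call/variant fields map to single-element lists; annotation
    fields are pipe-split into per-transcript value lists and exposed both
    bare and qualified as ``source.field``.
    """
    build = build or store.current_build
    contexts = []
    for call in store.calls_for_sample(sample_id, build):
        variant = store.get_variant(call.variant_id)
        ctx: Dict[str, list] = {}
        for f in CALL_FIELDS:
            value = getattr(call, f)
            ctx[f] = [] if value is None else [value]
        ctx["chrom"] = [variant.chrom]
        ctx["pos"] = [variant.pos]
        ctx["ref"] = [variant.ref]
        ctx["alt"] = [variant.alt]
        ctx["variant_type"] = ["snp" if variant.is_snv else "indel"]
        for (src, fname), value in store.active_annotations(
            variant.variant_id
        ).items():
            if fname.startswith("__") or value is None:
                continue
            values = split_multi(value)
            ctx[f"{src}.{fname}"] = values
            ctx.setdefault(fname, values)
        contexts.append((variant, ctx))
    return contexts


def _coerce_pair(a, b):
    try:
        return float(a), float(b)
    except (TypeError, ValueError):
        return str(a), str(b)


def _value_passes(op: str, value, target) -> bool:
    if op == "eq":
        a, b = _coerce_pair(value, target)
        return a == b
    if op == "ne":
        a, b = _coerce_pair(value, target)
        return a != b
    if op in NUMERIC_OPERATORS:
        try:
            a, b = float(value), float(target)
        except (TypeError, ValueError):
            return False
        return {
            "lt": a < b, "le": a <= b, "gt": a > b, "ge": a >= b,
        }[op]
    if op == "contains":
        return str(target) in str(value)
    if op == "in_set":
        targets = {str(t) for t in target}
        return str(value) in targets or (
            _is_number(value) and any(
                _is_number(t) and float(t) == float(value) for t in target
            )
        )
    raise SchemeValidationError(f"unknown operator {op!r}")


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def atom_passes(atom: FilterAtom, ctx: Dict[str, list]) -> bool:
    """ANY-value semantics over the (possibly per-transcript) value list."""
    values = ctx.get(atom.field_name) or []
    if atom.operator == "is_missing":
        return not values
    if atom.operator == "not_missing":
        return bool(values)
    if not values:
        return atom.missing_policy == "include"
    return any(_value_passes(atom.operator, v, atom.value) for v in values)


def node_passes(node: FilterNode, ctx: Dict[str, list]) -> bool:
    if node.kind == "atom":
        return atom_passes(node.atom, ctx)
    results = (node_passes(c, ctx) for c in node.children)
    return all(results) if node.logic == "AND" else any(results)


def _evaluate_node_sets(
    node: FilterNode,
    contexts: Sequence[Tuple[Variant, Dict[str, list]]],
) -> Set[int]:
    """Set-algebra evaluation: AND = intersection, OR = union, recursively."""
    if node.kind == "atom":
        return {
            v.variant_id for v, ctx in contexts if atom_passes(node.atom, ctx)
        }
    child_sets = [_evaluate_node_sets(c, contexts) for c in node.children]
    result = child_sets[0]
    for s in child_sets[1:]:
        result = result & s if node.logic == "AND" else result | s
    return result


def known_fields(store: VariantStore) -> Set[str]:
    return BUILTIN_FIELDS | store.annotation_field_names()


def evaluate(
    scheme: Union[FilterScheme, FilterNode],
    sample_id: str,
    store: VariantStore,
    contexts: Optional[Sequence[Tuple[Variant, Dict[str, list]]]] = None,
) -> List[Variant]:
    """Variants of one sample satisfying the tree, ordered by (chrom, pos).

    The scheme is validated against the store's resolvable fields before any
    evaluation; unknown fields raise :class:`SchemeValidationError`.
    """
    root = scheme.root if isinstance(scheme, FilterScheme) else scheme
    root.validate(known_fields(store))
    if contexts is None:
        contexts = build_contexts(store, sample_id)
    passing = _evaluate_node_sets(root, contexts)
    by_id = {v.variant_id: v for v, _ in contexts}
    return position_order(by_id[vid] for vid in passing)


# -- scheme persistence --------------------------------------------------


def save_scheme(
    store: VariantStore, scheme: FilterScheme, overwrite: bool = False
) -> None:
    """Persist a scheme; the tree must validate structurally (field names
    are bound late, at evaluation time)."""
    scheme.root.validate(None)
    if not scheme.created_at:
        scheme.created_at = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    store.save_scheme_document(
        scheme.name, scheme.owner, scheme.to_dict(), overwrite=overwrite
    )


def load_scheme(store: VariantStore, name: str) -> FilterScheme:
    return FilterScheme.from_dict(store.load_scheme_document(name))


def scheme_to_json(scheme: FilterScheme, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(scheme.to_dict(), indent=2))


def scheme_from_json(path: Union[str, Path]) -> FilterScheme:
    return FilterScheme.from_dict(json.loads(Path(path).read_text()))


# -- inheritance filters -------------------------------------------------


def _trio(store: VariantStore, child_id: str):
    child = store.get_sample(child_id)
    if not child.father_id or not child.mother_id:
        raise FamilyConfigError(
            f"sample {child_id!r} needs both father and mother links for "
            "inheritance filtering"
        )
    return child


def _genotype(store: VariantStore, sample_id: str, variant_id: int) -> str:
    """Genotype of a sample at a variant; 'absent' when no call is stored."""
    call = store.get_call(sample_id, variant_id)
    return call.genotype if call else "absent"


def filter_de_novo(
    store: VariantStore,
    child_id: str,
    require_called_parents: bool = True,
    build: Optional[str] = None,
) -> List[Variant]:
    """Variants carried by the child and ruled out in both parents.

    With ``require_called_parents`` both parents must have an explicit
    hom_ref call; without it an absent or missing parental genotype also
    counts as non-carrying.
    """
    child = _trio(store, child_id)
    build = build or store.current_build
    out = []
    for call in store.calls_for_sample(child_id, build):
        if not call.is_carrier:
            continue
        parental = [
            _genotype(store, pid, call.variant_id)
            for pid in (child.father_id, child.mother_id)
        ]
        if require_called_parents:
            ok = all(g == "hom_ref" for g in parental)
        else:
            ok = all(g in ("hom_ref", "missing", "absent") for g in parental)
        if ok:
            out.append(store.get_variant(call.variant_id))
    return position_order(out)


def filter_recessive(
    store: VariantStore, child_id: str, build: Optional[str] = None
) -> List[Variant]:
    """Homozygous in the child, heterozygous in both parents."""
    child = _trio(store, child_id)
    build = build or store.current_build
    out = []
    for call in store.calls_for_sample(child_id, build):
        if call.genotype != "hom_alt":
            continue
        if (
            _genotype(store, child.father_id, call.variant_id) == "het"
            and _genotype(store, child.mother_id, call.variant_id) == "het"
        ):
            out.append(store.get_variant(call.variant_id))
    return position_order(out)


def filter_dominant(
    store: VariantStore, child_id: str, build: Optional[str] = None
) -> List[Variant]:
    """Strict co-segregation with affected status across the family.

    The family is the child, its parents and registered siblings.  A variant
    passes when every affected member carries it (het or hom_alt) and every
    unaffected member is hom_ref or has no call.  A missing genotype in an
    affected member excludes the variant.
    """
    child = _trio(store, child_id)
    build = build or store.current_build
    family = [child_id, child.father_id, child.mother_id, *child.sibling_ids]
    members = [store.get_sample(sid) for sid in dict.fromkeys(family)]
    affected = [s.sample_id for s in members if s.affected]
    unaffected = [s.sample_id for s in members if not s.affected]
    if not affected:
        raise FamilyConfigError(
            "dominant filtering needs at least one affected family member"
        )
    candidate_ids: Set[int] = set()
    for call in store.calls_for_sample(affected[0], build):
        if call.is_carrier:
            candidate_ids.add(call.variant_id)
    out = []
    for vid in candidate_ids:
        if not all(
            _genotype(store, sid, vid) in ("het", "hom_alt")
            for sid in affected
        ):
            continue
        if not all(
            _genotype(store, sid, vid) in ("hom_ref", "absent")
            for sid in unaffected
        ):
            continue
        out.append(store.get_variant(vid))
    return position_order(out)


# -- cohort filters ------------------------------------------------------


def filter_occurrence(
    store: VariantStore,
    variants: Sequence[Variant],
    sample_set: Sequence[str],
    min_count: Optional[int] = None,
    max_count: Optional[int] = None,
) -> List[Variant]:
    """Keep variants whose carrier count within ``sample_set`` lies in
    [min_count, max_count]; carriers are counted as samples, not alleles."""
    if not sample_set:
        raise ValidationError("occurrence filtering needs a non-empty "
                              "sample selection")
    if (
        min_count is not None
        and max_count is not None
        and min_count > max_count
    ):
        raise ValidationError(
            f"min_count {min_count} exceeds max_count {max_count}"
        )
    out = []
    for v in variants:
        n = len(store.carrier_samples(v.variant_id, sample_set))
        if min_count is not None and n < min_count:
            continue
        if max_count is not None and n > max_count:
            continue
        out.append(v)
    return position_order(out)


def filter_burden(
    store: VariantStore,
    sample_set: Sequence[str],
    min_samples: Optional[int] = None,
    max_samples: Optional[int] = None,
    gene_field: str = "gene_symbol",
    build: Optional[str] = None,
) -> Dict[str, List[Variant]]:
    """Genes whose count of distinct carrier samples lies in the bounds.

    A sample with several qualifying variants in the same gene counts once.
    Returns gene -> position-ordered contributing variants (those carried by
    at least one sample of the selection).
    """
    if not sample_set:
        raise ValidationError("burden filtering needs a non-empty sample "
                              "selection")
    build = build or store.current_build
    gene_variants: Dict[str, List[Variant]] = {}
    for variant in store.variants(build):
        for (src, fname), value in store.active_annotations(
            variant.variant_id
        ).items():
            if fname != gene_field or value is None:
                continue
            for gene in sorted(set(split_multi(value))):
                if gene and gene != "intergenic":
                    gene_variants.setdefault(gene, []).append(variant)
            break
    out: Dict[str, List[Variant]] = {}
    for gene, variants in gene_variants.items():
        carriers: Set[str] = set()
        contributing = []
        for v in variants:
            vc = store.carrier_samples(v.variant_id, sample_set)
            if vc:
                contributing.append(v)
            carriers |= vc
        n = len(carriers)
        if min_samples is not None and n < min_samples:
            continue
        if max_samples is not None and n > max_samples:
            continue
        out[gene] = position_order(contributing)
    return out


# -- gene panels ---------------------------------------------------------


def _strip_version(tid: str) -> str:
    return tid.split(".")[0]


def filter_panel(
    store: VariantStore,
    variants: Sequence[Variant],
    panel: Union[str, Sequence[str]],
    index: Optional[GeneModelIndex] = None,
    user: Optional[str] = None,
) -> List[Variant]:
    """Restrict variants to those hitting a panel's transcripts.

    ``panel`` is a stored panel name or a raw list of transcript ids.
    Matching is on transcript id with the version suffix ignored, or on the
    gene symbol the panel transcripts resolve to through the gene model
    index (when supplied).  Intergenic variants never match.
    """
    if isinstance(panel, str):
        ids = store.get_panel(panel, user=user)["transcript_ids"]
    else:
        ids = list(panel)
    if not ids:
        raise ValidationError("gene panel is empty")
    panel_tids = {_strip_version(t) for t in ids}
    panel_genes: Set[str] = set()
    if index is not None:
        for tid in panel_tids:
            tx = index.by_id(tid)
            if tx is not None:
                panel_genes.add(tx.gene_symbol)
    out = []
    for v in variants:
        hit = False
        for (src, fname), value in store.active_annotations(
            v.variant_id
        ).items():
            if value is None:
                continue
            if fname == "transcript_id":
                if any(
                    _strip_version(t) in panel_tids
                    for t in split_multi(value)
                ):
                    hit = True
                    break
            if fname == "gene_symbol" and panel_genes:
                if any(g in panel_genes for g in split_multi(value)):
                    hit = True
                    break
        if hit:
            out.append(v)
    return position_order(out)
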