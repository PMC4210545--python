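"""Result presentation: summary statistics, tabular export, IGV loci,
pagination.

The multi-value delimiter for per-transcript annotations is ``|``; literal
pipes inside values are escaped as ``\\|`` so joining is reversible.
"""
from __future__ import annotations

import csv
import io
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import ValidationError
from .models import Variant, VariantSummarySet
from .store import VariantStore

MULTI_DELIMITER = "|"
DEFAULT_MAF_BIN_EDGES = (0.0, 0.001, 0.01, 0.05, 0.1, 0.5)
DEFAULT_PAGE_SIZE = 100
IGV_WINDOW = 25

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

FIXED_COLUMNS = ("chrom", "pos", "ref", "alt", "locus")


def join_multi(values: Sequence[str]) -> str:
    """Join per-transcript values with ``|``, escaping literal pipes."""
    return MULTI_DELIMITER.join(
        str(v).replace("\\", "\\\\").replace("|", "\\|") for v in values
    )


def split_multi(value: str) -> List[str]:
    """Inverse of :func:`join_multi`."""
    parts = re.split(r"(?<!\\)\|", value)
    return [p.replace("\\|", "|").replace("\\\\", "\\") for p in parts]


def chrom_sort_key(chrom: str) -> Tuple[int, Union[int, str]]:
    """Natural chromosome order: 1..22, X, Y, MT, then everything else."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c))
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (0, special[c.upper()])
    return (1, c)


def position_order(variants: Iterable[Variant]) -> List[Variant]:
    return sorted(
        variants,
        key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt),
    )


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine single-base change."""
    return (ref in PURINES and alt in PURINES) or (
        ref in PYRIMIDINES and alt in PYRIMIDINES
    )


def compute_summary(
    variants: Sequence[Variant],
    annotations: Optional[Dict[int, Dict[str, str]]] = None,
    rsid_field: str = "rsid",
    maf_field: str = "global_maf",
    maf_bin_edges: Sequence[float] = DEFAULT_MAF_BIN_EDGES,
) -> VariantSummarySet:
    """Transition/transversion, known/novel, SNP/indel and MAF histogram.

    ``annotations`` maps variant_id to a flat field->value dict; a variant
    with a value in ``rsid_field`` counts as known.  The Tr/Tv ratio is None
    (undefined) when there are no transversions.  Missing MAFs are counted
    in a separate bin, never imputed.
    """
    annotations = annotations or {}
    tr = tv = n_snp = n_indel = n_known = 0
    edges = tuple(maf_bin_edges)
    hist = [0] * (len(edges) - 1)
    n_maf_missing = 0
    for v in variants:
        if v.is_snv:
            n_snp += 1
            if is_transition(v.ref, v.alt):
                tr += 1
            else:
                tv += 1
        elif v.is_indel:
            n_indel += 1
        ann = annotations.get(v.variant_id, {})
        if ann.get(rsid_field):
            n_known += 1
        maf_raw = ann.get(maf_field)
        if maf_raw is None or maf_raw == "":
            n_maf_missing += 1
        else:
            maf = float(maf_raw)
            placed = False
            for i in range(len(edges) - 1):
                last = i == len(edges) - 2
                if edges[i] <= maf < edges[i + 1] or (
                    last and maf == edges[i + 1]
                ):
                    hist[i] += 1
                    placed = True
                    break
            if not placed:
                n_maf_missing += 1  # outside configured range
    ratio = (tr / tv) if tv else None
    total = len(variants)
    return VariantSummarySet(
        tr_count=tr,
        tv_count=tv,
        trtv_ratio=ratio,
        n_known=n_known,
        n_novel=total - n_known,
        n_snp=n_snp,
        n_indel=n_indel,
        maf_bin_edges=edges,
        maf_histogram=tuple(hist),
        n_maf_missing=n_maf_missing,
    )


def igv_locus(variant: Variant, window: int = IGV_WINDOW) -> str:
    """IGV locus string with a +/- ``window`` bp context, clamped at 1."""
    start = max(1, variant.pos - window)
    end = variant.end + window
    return f"{variant.chrom}:{start}-{end}"


def paginate(
    results: Sequence, page: int, page_size: int = DEFAULT_PAGE_SIZE
) -> Tuple[list, int]:
    """Deterministic page slice plus the total result count.

    Pages are 1-based; a page past the end returns an empty slice.
    """
    if page < 1:
        raise ValidationError(f"page must be >= 1, got {page}")
    if page_size < 1:
        raise ValidationError(f"page_size must be >= 1, got {page_size}")
    start = (page - 1) * page_size
    return list(results[start: start + page_size]), len(results)


def _annotation_table(
    store: VariantStore, variants: Sequence[Variant]
) -> Dict[int, Dict[str, str]]:
    out = {}
    for v in variants:
        flat: Dict[str, str] = {}
        for (src, fname), value in store.active_annotations(
            v.variant_id
        ).items():
            if fname.startswith("__"):
                continue
            flat[f"{src}.{fname}"] = value
            flat.setdefault(fname, value)
        out[v.variant_id] = flat
    return out


def export(
    store: VariantStore,
    variants: Sequence[Variant],
    selected_annotations: Sequence[str],
    layout: str = "wide",
    destination: Optional[Union[str, Path, io.IOBase]] = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Export variants plus selected annotation columns.

    ``wide``: one row per variant, one column per selected annotation,
    multi-transcript values pipe-joined in the cell.  ``compact``: one row
    per (variant, transcript slot) with annotation values unpacked, so a
    variant with two overlapping transcripts occupies two sub-rows.
    CSV output is RFC 4180 (quoted with the csv module's minimal quoting).
    """
    if layout not in ("wide", "compact"):
        raise ValidationError(f"unknown layout {layout!r}")
    ordered = position_order(variants)
    annotations = _annotation_table(store, ordered)
    known_fields = set()
    for flat in annotations.values():
        known_fields.update(flat)
    known_fields.update(store.annotation_field_names())
    for name in selected_annotations:
        if name not in known_fields:
            raise ValidationError(f"unknown annotation name {name!r}")

    rows = []
    for v in ordered:
        fixed = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "locus": igv_locus(v),
        }
        flat = annotations.get(v.variant_id, {})
        if layout == "wide":
            row = dict(fixed)
            for name in selected_annotations:
                row[name] = flat.get(name, "")
            rows.append(row)
        else:
            values = {
                name: split_multi(flat[name]) if name in flat else []
                for name in selected_annotations
            }
            depth = max([len(v_) for v_ in values.values()] + [1])
            for i in range(depth):
                row = dict(fixed) if i == 0 else {
                    k: "" for k in FIXED_COLUMNS
                }
                row["slot"] = i + 1
                for name in selected_annotations:
                    vals = values[name]
                    row[name] = vals[i] if i < len(vals) else ""
                rows.append(row)

    columns = list(FIXED_COLUMNS)
    if layout == "compact":
        columns.append("slot")
    columns.extend(selected_annotations)
    frame = pd.DataFrame(rows, columns=columns)
    if destination is not None:
        _write_csv(frame, destination, delimiter)
    return frame


def _write_csv(
    frame: pd.DataFrame,
    destination: Union[str, Path, io.IOBase],
    delimiter: str,
) -> None:
    frame.to_csv(
        destination,
        sep=delimiter,
        index=False,
        quoting=csv.QUOTE_MINIMAL,
        lineterminator="\r\n",
    )
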