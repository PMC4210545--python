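"""YAML configuration: database path, current build, registered annotation
sources, defaults.  Unknown keys are rejected at load time."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

from .errors import ValidationError

_TOP_KEYS = {"database", "build", "page_size", "missing_policy", "sources"}
_SOURCE_KEYS = {
    "name", "version", "kind", "path", "cds_fasta", "nomenclature",
    "splice_window",
}
_SOURCE_KINDS = {"table", "gene_model"}


@dataclass
class SourceConfig:
    name: str
    version: str
    kind: str
    path: str
    cds_fasta: Optional[str] = None
    nomenclature: str = "refseq"
    splice_window: int = 2


@dataclass
class Config:
    database: str = "varbank.db"
    build: Optional[str] = None
    page_size: int = 100
    missing_policy: str = "exclude"
    sources: List[SourceConfig] = field(default_factory=list)
    base_dir: Path = Path(".")

    def database_path(self) -> Path:
        p = Path(self.database)
        return p if p.is_absolute() else self.base_dir / p

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p


def load_config(path) -> Config:
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if doc.get("missing_policy", "exclude") not in ("exclude", "include"):
        raise ValidationError("missing_policy must be exclude or include")
    sources = []
    for i, raw in enumerate(doc.get("sources") or []):
        bad = set(raw) - _SOURCE_KEYS
        if bad:
            raise ValidationError(
                f"unknown keys in source #{i + 1}: {sorted(bad)}"
            )
        for req in ("name", "version", "kind", "path"):
            if req not in raw:
                raise ValidationError(f"source #{i + 1} misses {req!r}")
        if raw["kind"] not in _SOURCE_KINDS:
            raise ValidationError(
                f"source #{i + 1}: kind must be one of {sorted(_SOURCE_KINDS)}"
            )
        sources.append(SourceConfig(**raw))
    return Config(
        database=doc.get("database", "varbank.db"),
        build=doc.get("build"),
        page_size=int(doc.get("page_size", 100)),
        missing_policy=doc.get("missing_policy", "exclude"),
        sources=sources,
        base_dir=path.parent,
    )


def build_sources(config: Config) -> list:
    """Instantiate the configured annotation sources."""
    from .annotation import GeneModelAnnotationSource, TableAnnotationSource
    from .genemodel import (
        GeneModelIndex,
        attach_cds_sequences,
        load_bed12,
    )

    out = []
    for sc in config.sources:
        if sc.kind == "table":
            out.append(
                TableAnnotationSource.from_tsv(
                    sc.name, sc.version, config.resolve(sc.path)
                )
            )
        else:
            transcripts = load_bed12(
                str(config.resolve(sc.path)), nomenclature=sc.nomenclature
            )
            if sc.cds_fasta:
                attach_cds_sequences(
                    transcripts, str(config.resolve(sc.cds_fasta))
                )
            out.append(
                GeneModelAnnotationSource(
                    name=sc.name,
                    version=sc.version,
                    index=GeneModelIndex(transcripts),
                    splice_window=sc.splice_window,
                )
            )
    return out
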