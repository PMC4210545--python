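"""Embedded relational variant store.

Samples, variants, genotype calls, projects/roles, annotations with history,
filter schemes, gene panels, a liftover curation queue and an audit journal
all live in a single SQLite file (or in memory for tests).  The schema is
versioned through an explicit ``schema_migrations`` table.

Variants are unique on (build, chrom, pos, ref, alt); a link table holds one
genotype call per (sample, variant) with the GATK quality vector.  Retired
genome builds are flagged read-only and every write path checks the flag.
"""
from __future__ import annotations

import datetime
import json
import sqlite3
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .errors import (
    AuthorizationError,
    ConflictError,
    NotFoundError,
    ReadOnlyBuildError,
    ValidationError,
)
from .models import (
    GENDERS,
    ROLE_RANK,
    AnnotationRecord,
    ChangeLogEntry,
    GenotypeCall,
    Project,
    Sample,
    UserClassification,
    Variant,
    validate_alleles,
)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE schema_migrations (
    version INTEGER PRIMARY KEY,
    applied_at TEXT NOT NULL
);
CREATE TABLE meta (
    key TEXT PRIMARY KEY,
    value TEXT
);
CREATE TABLE builds (
    name TEXT PRIMARY KEY,
    read_only INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE projects (
    project_id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE role_grants (
    project_id INTEGER NOT NULL REFERENCES projects(project_id),
    user_id TEXT NOT NULL,
    role TEXT NOT NULL CHECK (role IN ('read_only','edit','admin')),
    PRIMARY KEY (project_id, user_id)
);
CREATE TABLE samples (
    sample_id TEXT PRIMARY KEY,
    project_id INTEGER NOT NULL REFERENCES projects(project_id),
    display_name TEXT,
    gender TEXT NOT NULL DEFAULT 'unknown',
    is_control INTEGER NOT NULL DEFAULT 0,
    affected INTEGER NOT NULL DEFAULT 0,
    father_id TEXT REFERENCES samples(sample_id),
    mother_id TEXT REFERENCES samples(sample_id),
    bam_path TEXT
);
CREATE TABLE sample_hpo (
    sample_id TEXT NOT NULL REFERENCES samples(sample_id),
    term TEXT NOT NULL,
    PRIMARY KEY (sample_id, term)
);
CREATE TABLE sample_siblings (
    sample_id TEXT NOT NULL REFERENCES samples(sample_id),
    sibling_id TEXT NOT NULL REFERENCES samples(sample_id),
    PRIMARY KEY (sample_id, sibling_id)
);
CREATE TABLE variants (
    variant_id INTEGER PRIMARY KEY AUTOINCREMENT,
    build TEXT NOT NULL REFERENCES builds(name),
    chrom TEXT NOT NULL,
    pos INTEGER NOT NULL,
    ref TEXT NOT NULL,
    alt TEXT NOT NULL,
    UNIQUE (build, chrom, pos, ref, alt)
);
CREATE INDEX idx_variants_locus ON variants (build, chrom, pos);
CREATE TABLE calls (
    sample_id TEXT NOT NULL REFERENCES samples(sample_id),
    variant_id INTEGER NOT NULL REFERENCES variants(variant_id),
    genotype TEXT NOT NULL,
    qual REAL, gq REAL, ad_ref INTEGER, ad_alt INTEGER,
    qd REAL, mq REAL, fs REAL,
    base_q_rank_sum REAL, mq_rank_sum REAL, read_pos_rank_sum REAL,
    filter_status TEXT,
    PRIMARY KEY (sample_id, variant_id)
);
CREATE INDEX idx_calls_variant ON calls (variant_id);
CREATE TABLE annotation_sources (
    source_name TEXT NOT NULL,
    version_label TEXT NOT NULL,
    registered_at TEXT NOT NULL,
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    UNIQUE (source_name, version_label)
);
CREATE TABLE annotations (
    record_id INTEGER PRIMARY KEY AUTOINCREMENT,
    variant_id INTEGER NOT NULL REFERENCES variants(variant_id),
    source_name TEXT NOT NULL,
    field_name TEXT NOT NULL,
    value TEXT,
    source_version TEXT NOT NULL,
    active INTEGER NOT NULL DEFAULT 1,
    created_at TEXT NOT NULL,
    retired_at TEXT
);
CREATE INDEX idx_ann_lookup ON annotations (variant_id, source_name, field_name, active);
CREATE INDEX idx_ann_field ON annotations (source_name, field_name, active);
CREATE UNIQUE INDEX idx_ann_one_active
    ON annotations (variant_id, source_name, field_name) WHERE active = 1;
CREATE TABLE change_log (
    entry_id INTEGER PRIMARY KEY AUTOINCREMENT,
    variant_id INTEGER NOT NULL,
    source_name TEXT NOT NULL,
    field_name TEXT NOT NULL,
    old_value TEXT, new_value TEXT,
    old_version TEXT, new_version TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    interesting INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE classifications (
    variant_id INTEGER NOT NULL REFERENCES variants(variant_id),
    sample_id TEXT NOT NULL REFERENCES samples(sample_id),
    inheritance_note TEXT, validation_status TEXT,
    diagnostic_class TEXT, free_text TEXT,
    PRIMARY KEY (variant_id, sample_id)
);
CREATE TABLE filter_schemes (
    name TEXT PRIMARY KEY,
    owner TEXT NOT NULL,
    document TEXT NOT NULL,
    created_at TEXT NOT NULL
);
CREATE TABLE gene_panels (
    name TEXT PRIMARY KEY,
    owner TEXT NOT NULL,
    public INTEGER NOT NULL DEFAULT 0,
    comment TEXT
);
CREATE TABLE gene_panel_members (
    panel_name TEXT NOT NULL REFERENCES gene_panels(name),
    transcript_id TEXT NOT NULL,
    PRIMARY KEY (panel_name, transcript_id)
);
CREATE TABLE curation_queue (
    item_id INTEGER PRIMARY KEY AUTOINCREMENT,
    variant_id INTEGER NOT NULL,
    reason TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'pending',
    created_at TEXT NOT NULL
);
CREATE TABLE audit_log (
    entry_id INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL,
    command TEXT NOT NULL
);
"""


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _clean(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    return str(value)


_CALL_FIELDS = (
    "qual", "gq", "ad_ref", "ad_alt", "qd", "mq", "fs",
    "base_q_rank_sum", "mq_rank_sum", "read_pos_rank_sum", "filter_status",
)


class VariantStore:
    """One open connection to a variant database file."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._migrate()

    # -- lifecycle -------------------------------------------------------

    def _migrate(self) -> None:
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name='schema_migrations'"
        )
        if cur.fetchone() is None:
            with self._conn:
                self._conn.executescript(_SCHEMA)
                self._conn.execute(
                    "INSERT INTO schema_migrations (version, applied_at) "
                    "VALUES (?, ?)",
                    (SCHEMA_VERSION, _now()),
                )

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "VariantStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def connection(self) -> sqlite3.Connection:
        return self._conn

    # -- builds ----------------------------------------------------------

    @property
    def current_build(self) -> Optional[str]:
        row = self._conn.execute(
            "SELECT value FROM meta WHERE key='current_build'"
        ).fetchone()
        return row["value"] if row else None

    def set_current_build(self, build: str) -> None:
        with self._conn:
            self._conn.execute(
                "INSERT OR IGNORE INTO builds (name) VALUES (?)", (build,)
            )
            self._conn.execute(
                "INSERT INTO meta (key, value) VALUES ('current_build', ?) "
                "ON CONFLICT(key) DO UPDATE SET value=excluded.value",
                (build,),
            )

    def register_build(self, build: str) -> None:
        with self._conn:
            self._conn.execute(
                "INSERT OR IGNORE INTO builds (name) VALUES (?)", (build,)
            )

    def retire_build(self, build: str) -> None:
        """Flag a build read-only; subsequent writes against it are rejected."""
        with self._conn:
            self._conn.execute(
                "UPDATE builds SET read_only=1 WHERE name=?", (build,)
            )

    def build_is_read_only(self, build: str) -> bool:
        row = self._conn.execute(
            "SELECT read_only FROM builds WHERE name=?", (build,)
        ).fetchone()
        return bool(row and row["read_only"])

    def _check_writable_build(self, build: str) -> None:
        if self.build_is_read_only(build):
            raise ReadOnlyBuildError(f"build {build!r} is retired (read-only)")

    # -- projects and roles ---------------------------------------------

    def create_project(self, name: str) -> int:
        try:
            with self._conn:
                cur = self._conn.execute(
                    "INSERT INTO projects (name) VALUES (?)", (name,)
                )
        except sqlite3.IntegrityError as exc:
            raise ConflictError(f"project {name!r} already exists") from exc
        return cur.lastrowid

    def get_project(self, project_id: int) -> Project:
        row = self._conn.execute(
            "SELECT * FROM projects WHERE project_id=?", (project_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no project with id {project_id}")
        grants = {
            r["user_id"]: r["role"]
            for r in self._conn.execute(
                "SELECT user_id, role FROM role_grants WHERE project_id=?",
                (project_id,),
            )
        }
        return Project(row["project_id"], row["name"], grants)

    def grant_role(self, project_id: int, user_id: str, role: str) -> None:
        if role not in ROLE_RANK:
            raise ValidationError(f"unknown role {role!r}")
        self.get_project(project_id)
        with self._conn:
            self._conn.execute(
                "INSERT INTO role_grants (project_id, user_id, role) "
                "VALUES (?, ?, ?) "
                "ON CONFLICT(project_id, user_id) DO UPDATE SET role=excluded.role",
                (project_id, user_id, role),
            )

    def check_permission(
        self, user_id: str, project_id: int, required_role: str
    ) -> bool:
        """True iff the user holds a role >= required under
        read_only < edit < admin."""
        if required_role not in ROLE_RANK:
            raise ValidationError(f"unknown role {required_role!r}")
        self.get_project(project_id)
        row = self._conn.execute(
            "SELECT role FROM role_grants WHERE project_id=? AND user_id=?",
            (project_id, user_id),
        ).fetchone()
        if row is None:
            return False
        return ROLE_RANK[row["role"]] >= ROLE_RANK[required_role]

    def delete_project(self, project_id: int, cascade: bool = False) -> None:
        """Delete a project; without ``cascade`` refuse if samples exist
        (never silently orphan)."""
        self.get_project(project_id)
        sample_ids = [
            r["sample_id"]
            for r in self._conn.execute(
                "SELECT sample_id FROM samples WHERE project_id=?", (project_id,)
            )
        ]
        if sample_ids and not cascade:
            raise ConflictError(
                f"project {project_id} still owns {len(sample_ids)} samples; "
                "pass cascade=True to delete them too"
            )
        with self._conn:
            for sid in sample_ids:
                self._conn.execute(
                    "DELETE FROM classifications WHERE sample_id=?", (sid,)
                )
                self._conn.execute("DELETE FROM calls WHERE sample_id=?", (sid,))
                self._conn.execute(
                    "DELETE FROM sample_hpo WHERE sample_id=?", (sid,)
                )
                self._conn.execute(
                    "DELETE FROM sample_siblings WHERE sample_id=? "
                    "OR sibling_id=?",
                    (sid, sid),
                )
            if sample_ids:
                self._conn.execute(
                    "UPDATE samples SET father_id=NULL WHERE father_id IN "
                    "(SELECT sample_id FROM samples WHERE project_id=?)",
                    (project_id,),
                )
                self._conn.execute(
                    "UPDATE samples SET mother_id=NULL WHERE mother_id IN "
                    "(SELECT sample_id FROM samples WHERE project_id=?)",
                    (project_id,),
                )
                self._conn.execute(
                    "DELETE FROM samples WHERE project_id=?", (project_id,)
                )
            self._conn.execute(
                "DELETE FROM role_grants WHERE project_id=?", (project_id,)
            )
            self._conn.execute(
                "DELETE FROM projects WHERE project_id=?", (project_id,)
            )

    # -- samples ---------------------------------------------------------

    def add_sample(
        self,
        sample_id: str,
        project_id: int,
        display_name: Optional[str] = None,
        gender: str = "unknown",
        hpo_terms: Iterable[str] = (),
        is_control: bool = False,
        affected: bool = False,
        father_id: Optional[str] = None,
        mother_id: Optional[str] = None,
        bam_path: Optional[str] = None,
    ) -> None:
        if gender not in GENDERS:
            raise ValidationError(f"unknown gender {gender!r}")
        self.get_project(project_id)
        if self._conn.execute(
            "SELECT 1 FROM samples WHERE sample_id=?", (sample_id,)
        ).fetchone():
            raise ConflictError(f"sample {sample_id!r} already registered")
        with self._conn:
            self._conn.execute(
                "INSERT INTO samples (sample_id, project_id, display_name, "
                "gender, is_control, affected, bam_path) "
                "VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    sample_id, project_id, display_name or sample_id,
                    gender, int(is_control), int(affected), bam_path,
                ),
            )
            for term in hpo_terms:
                self._conn.execute(
                    "INSERT OR IGNORE INTO sample_hpo (sample_id, term) "
                    "VALUES (?, ?)",
                    (sample_id, term),
                )
        if father_id or mother_id:
            self.set_parents(sample_id, father_id, mother_id)

    def _require_sample(self, sample_id: str) -> sqlite3.Row:
        row = self._conn.execute(
            "SELECT * FROM samples WHERE sample_id=?", (sample_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no sample {sample_id!r}")
        return row

    def _ancestors(self, sample_id: str) -> Iterator[str]:
        seen = set()
        stack = [sample_id]
        while stack:
            sid = stack.pop()
            row = self._conn.execute(
                "SELECT father_id, mother_id FROM samples WHERE sample_id=?",
                (sid,),
            ).fetchone()
            if row is None:
                continue
            for parent in (row["father_id"], row["mother_id"]):
                if parent and parent not in seen:
                    seen.add(parent)
                    yield parent
                    stack.append(parent)

    def set_parents(
        self,
        sample_id: str,
        father_id: Optional[str],
        mother_id: Optional[str],
    ) -> None:
        self._require_sample(sample_id)
        for parent in (father_id, mother_id):
            if parent is not None:
                self._require_sample(parent)
                if parent == sample_id or sample_id in set(
                    self._ancestors(parent)
                ):
                    raise ValidationError(
                        f"parent link {sample_id} -> {parent} creates a cycle"
                    )
        with self._conn:
            self._conn.execute(
                "UPDATE samples SET father_id=?, mother_id=? WHERE sample_id=?",
                (father_id, mother_id, sample_id),
            )

    def add_sibling(self, a: str, b: str) -> None:
        """Register a sibling relation; stored symmetrically."""
        if a == b:
            raise ValidationError("a sample cannot be its own sibling")
        self._require_sample(a)
        self._require_sample(b)
        with self._conn:
            for x, y in ((a, b), (b, a)):
                self._conn.execute(
                    "INSERT OR IGNORE INTO sample_siblings (sample_id, "
                    "sibling_id) VALUES (?, ?)",
                    (x, y),
                )

    def set_sample_flags(
        self,
        sample_id: str,
        is_control: Optional[bool] = None,
        affected: Optional[bool] = None,
    ) -> None:
        self._require_sample(sample_id)
        with self._conn:
            if is_control is not None:
                self._conn.execute(
                    "UPDATE samples SET is_control=? WHERE sample_id=?",
                    (int(is_control), sample_id),
                )
            if affected is not None:
                self._conn.execute(
                    "UPDATE samples SET affected=? WHERE sample_id=?",
                    (int(affected), sample_id),
                )

    def get_sample(self, sample_id: str) -> Sample:
        row = self._require_sample(sample_id)
        hpo = tuple(
            r["term"]
            for r in self._conn.execute(
                "SELECT term FROM sample_hpo WHERE sample_id=? ORDER BY term",
                (sample_id,),
            )
        )
        sibs = tuple(
            r["sibling_id"]
            for r in self._conn.execute(
                "SELECT sibling_id FROM sample_siblings WHERE sample_id=? "
                "ORDER BY sibling_id",
                (sample_id,),
            )
        )
        return Sample(
            sample_id=row["sample_id"],
            project_id=row["project_id"],
            display_name=row["display_name"],
            gender=row["gender"],
            hpo_terms=hpo,
            is_control=bool(row["is_control"]),
            affected=bool(row["affected"]),
            father_id=row["father_id"],
            mother_id=row["mother_id"],
            sibling_ids=sibs,
            bam_path=row["bam_path"],
        )

    def sample_ids(self, project_id: Optional[int] = None) -> list:
        if project_id is None:
            rows = self._conn.execute(
                "SELECT sample_id FROM samples ORDER BY sample_id"
            )
        else:
            rows = self._conn.execute(
                "SELECT sample_id FROM samples WHERE project_id=? "
                "ORDER BY sample_id",
                (project_id,),
            )
        return [r["sample_id"] for r in rows]

    # -- variants --------------------------------------------------------

    def upsert_variant(
        self, build: str, chrom: str, pos: int, ref: str, alt: str
    ) -> int:
        """Insert or fetch the variant row for an already-normalized change."""
        validate_alleles(ref, alt)
        if pos < 1:
            raise ValidationError(f"position must be >= 1, got {pos}")
        existing = self.find_variant(build, chrom, pos, ref, alt)
        if existing is not None:
            return existing
        self._check_writable_build(build)
        with self._conn:
            self._conn.execute(
                "INSERT OR IGNORE INTO builds (name) VALUES (?)", (build,)
            )
            cur = self._conn.execute(
                "INSERT INTO variants (build, chrom, pos, ref, alt) "
                "VALUES (?, ?, ?, ?, ?)",
                (build, chrom, pos, ref, alt),
            )
        return cur.lastrowid

    def find_variant(
        self, build: str, chrom: str, pos: int, ref: str, alt: str
    ) -> Optional[int]:
        row = self._conn.execute(
            "SELECT variant_id FROM variants WHERE build=? AND chrom=? "
            "AND pos=? AND ref=? AND alt=?",
            (build, chrom, pos, ref, alt),
        ).fetchone()
        return row["variant_id"] if row else None

    def get_variant(self, variant_id: int) -> Variant:
        row = self._conn.execute(
            "SELECT * FROM variants WHERE variant_id=?", (variant_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no variant with id {variant_id}")
        return Variant(
            build=row["build"], chrom=row["chrom"], pos=row["pos"],
            ref=row["ref"], alt=row["alt"], variant_id=row["variant_id"],
        )

    def variants(self, build: Optional[str] = None) -> list:
        if build is None:
            rows = self._conn.execute("SELECT * FROM variants ORDER BY variant_id")
        else:
            rows = self._conn.execute(
                "SELECT * FROM variants WHERE build=? ORDER BY variant_id",
                (build,),
            )
        return [
            Variant(
                build=r["build"], chrom=r["chrom"], pos=r["pos"],
                ref=r["ref"], alt=r["alt"], variant_id=r["variant_id"],
            )
            for r in rows
        ]

    def count_variants(self, build: Optional[str] = None) -> int:
        if build is None:
            row = self._conn.execute("SELECT COUNT(*) AS n FROM variants")
        else:
            row = self._conn.execute(
                "SELECT COUNT(*) AS n FROM variants WHERE build=?", (build,)
            )
        return row.fetchone()["n"]

    # -- genotype calls --------------------------------------------------

    def store_call(self, call: GenotypeCall, overwrite: bool = False) -> None:
        self._require_sample(call.sample_id)
        variant = self.get_variant(call.variant_id)
        self._check_writable_build(variant.build)
        exists = self._conn.execute(
            "SELECT 1 FROM calls WHERE sample_id=? AND variant_id=?",
            (call.sample_id, call.variant_id),
        ).fetchone()
        if exists and not overwrite:
            raise ConflictError(
                f"call for ({call.sample_id}, variant {call.variant_id}) "
                "already stored; pass overwrite=True to replace"
            )
        cols = ", ".join(_CALL_FIELDS)
        placeholders = ", ".join("?" for _ in _CALL_FIELDS)
        values = [getattr(call, f) for f in _CALL_FIELDS]
        with self._conn:
            self._conn.execute(
                f"INSERT INTO calls (sample_id, variant_id, genotype, {cols}) "
                f"VALUES (?, ?, ?, {placeholders}) "
                "ON CONFLICT(sample_id, variant_id) DO UPDATE SET "
                "genotype=excluded.genotype, "
                + ", ".join(f"{f}=excluded.{f}" for f in _CALL_FIELDS),
                [call.sample_id, call.variant_id, call.genotype] + values,
            )

    def _row_to_call(self, row: sqlite3.Row) -> GenotypeCall:
        return GenotypeCall(
            sample_id=row["sample_id"],
            variant_id=row["variant_id"],
            genotype=row["genotype"],
            **{f: row[f] for f in _CALL_FIELDS},
        )

    def get_call(
        self, sample_id: str, variant_id: int
    ) -> Optional[GenotypeCall]:
        row = self._conn.execute(
            "SELECT * FROM calls WHERE sample_id=? AND variant_id=?",
            (sample_id, variant_id),
        ).fetchone()
        return self._row_to_call(row) if row else None

    def calls_for_sample(
        self, sample_id: str, build: Optional[str] = None
    ) -> list:
        self._require_sample(sample_id)
        if build is None:
            rows = self._conn.execute(
                "SELECT c.* FROM calls c WHERE c.sample_id=?", (sample_id,)
            )
        else:
            rows = self._conn.execute(
                "SELECT c.* FROM calls c JOIN variants v USING (variant_id) "
                "WHERE c.sample_id=? AND v.build=?",
                (sample_id, build),
            )
        return [self._row_to_call(r) for r in rows]

    def calls_for_variant(self, variant_id: int) -> list:
        rows = self._conn.execute(
            "SELECT * FROM calls WHERE variant_id=?", (variant_id,)
        )
        return [self._row_to_call(r) for r in rows]

    def carrier_samples(
        self, variant_id: int, sample_set: Sequence[str]
    ) -> set:
        """Samples in ``sample_set`` carrying the variant (het or hom_alt)."""
        if not sample_set:
            return set()
        qs = ",".join("?" for _ in sample_set)
        rows = self._conn.execute(
            f"SELECT sample_id FROM calls WHERE variant_id=? "
            f"AND genotype IN ('het','hom_alt') AND sample_id IN ({qs})",
            [variant_id, *sample_set],
        )
        return {r["sample_id"] for r in rows}

    # -- user classifications -------------------------------------------

    def set_classification(
        self, user_id: str, classification: UserClassification
    ) -> None:
        """Requires the edit role on the project owning the sample."""
        sample = self._require_sample(classification.sample_id)
        self.get_variant(classification.variant_id)
        if not self.check_permission(user_id, sample["project_id"], "edit"):
            raise AuthorizationError(
                f"user {user_id!r} lacks edit rights on project "
                f"{sample['project_id']}"
            )
        c = classification
        with self._conn:
            self._conn.execute(
                "INSERT INTO classifications (variant_id, sample_id, "
                "inheritance_note, validation_status, diagnostic_class, "
                "free_text) VALUES (?, ?, ?, ?, ?, ?) "
                "ON CONFLICT(variant_id, sample_id) DO UPDATE SET "
                "inheritance_note=excluded.inheritance_note, "
                "validation_status=excluded.validation_status, "
                "diagnostic_class=excluded.diagnostic_class, "
                "free_text=excluded.free_text",
                (
                    c.variant_id, c.sample_id, c.inheritance_note,
                    c.validation_status, c.diagnostic_class, c.free_text,
                ),
            )

    def get_classification(
        self, variant_id: int, sample_id: str
    ) -> Optional[UserClassification]:
        row = self._conn.execute(
            "SELECT * FROM classifications WHERE variant_id=? AND sample_id=?",
            (variant_id, sample_id),
        ).fetchone()
        if row is None:
            return None
        return UserClassification(
            variant_id=row["variant_id"], sample_id=row["sample_id"],
            inheritance_note=row["inheritance_note"],
            validation_status=row["validation_status"],
            diagnostic_class=row["diagnostic_class"],
            free_text=row["free_text"],
        )

    # -- annotation records ---------------------------------------------

    def register_source_version(self, source_name: str, version: str) -> None:
        """Record a source release; versions are ordered by registration."""
        exists = self._conn.execute(
            "SELECT 1 FROM annotation_sources WHERE source_name=? "
            "AND version_label=?",
            (source_name, version),
        ).fetchone()
        if exists:
            return
        with self._conn:
            self._conn.execute(
                "INSERT INTO annotation_sources (source_name, version_label, "
                "registered_at) VALUES (?, ?, ?)",
                (source_name, version, _now()),
            )

    def source_versions(self, source_name: str) -> list:
        rows = self._conn.execute(
            "SELECT version_label FROM annotation_sources WHERE source_name=? "
            "ORDER BY seq",
            (source_name,),
        )
        return [r["version_label"] for r in rows]

    def variants_missing_annotation(
        self, source_name: str, build: Optional[str] = None
    ) -> list:
        """Variants with no active record (not even a no-hit) from a source."""
        build = build or self.current_build
        rows = self._conn.execute(
            "SELECT v.* FROM variants v WHERE v.build=? AND NOT EXISTS "
            "(SELECT 1 FROM annotations a WHERE a.variant_id=v.variant_id "
            " AND a.source_name=? AND a.active=1) ORDER BY v.variant_id",
            (build, source_name),
        )
        return [
            Variant(
                build=r["build"], chrom=r["chrom"], pos=r["pos"],
                ref=r["ref"], alt=r["alt"], variant_id=r["variant_id"],
            )
            for r in rows
        ]

    def insert_annotation(
        self,
        variant_id: int,
        source_name: str,
        field_name: str,
        value: Optional[str],
        source_version: str,
    ) -> int:
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO annotations (variant_id, source_name, field_name, "
                "value, source_version, active, created_at) "
                "VALUES (?, ?, ?, ?, ?, 1, ?)",
                (
                    variant_id, source_name, field_name, _clean(value),
                    source_version, _now(),
                ),
            )
        return cur.lastrowid

    def retire_annotation(self, record_id: int) -> None:
        with self._conn:
            self._conn.execute(
                "UPDATE annotations SET active=0, retired_at=? "
                "WHERE record_id=?",
                (_now(), record_id),
            )

    def active_annotations(
        self, variant_id: int, source_name: Optional[str] = None
    ) -> dict:
        """Active (source, field) -> value mapping for one variant."""
        if source_name is None:
            rows = self._conn.execute(
                "SELECT source_name, field_name, value FROM annotations "
                "WHERE variant_id=? AND active=1",
                (variant_id,),
            )
        else:
            rows = self._conn.execute(
                "SELECT source_name, field_name, value FROM annotations "
                "WHERE variant_id=? AND source_name=? AND active=1",
                (variant_id, source_name),
            )
        return {(r["source_name"], r["field_name"]): r["value"] for r in rows}

    def active_annotation_records(
        self, variant_id: int, source_name: str
    ) -> dict:
        """field -> AnnotationRecord for the active records of one source."""
        rows = self._conn.execute(
            "SELECT * FROM annotations WHERE variant_id=? AND source_name=? "
            "AND active=1",
            (variant_id, source_name),
        )
        return {r["field_name"]: self._row_to_annotation(r) for r in rows}

    def _row_to_annotation(self, r: sqlite3.Row) -> AnnotationRecord:
        return AnnotationRecord(
            variant_id=r["variant_id"], source_name=r["source_name"],
            field_name=r["field_name"], value=r["value"],
            source_version=r["source_version"], active=bool(r["active"]),
            created_at=r["created_at"], retired_at=r["retired_at"],
            record_id=r["record_id"],
        )

    def annotation_history(
        self, variant_id: int, source_name: str, field_name: str
    ) -> list:
        """All records ever stored for one (variant, source, field), oldest
        first.  Retired records are never deleted."""
        rows = self._conn.execute(
            "SELECT * FROM annotations WHERE variant_id=? AND source_name=? "
            "AND field_name=? ORDER BY record_id",
            (variant_id, source_name, field_name),
        )
        return [self._row_to_annotation(r) for r in rows]

    def annotation_field_names(self) -> set:
        rows = self._conn.execute(
            "SELECT DISTINCT source_name, field_name FROM annotations"
        )
        names = set()
        for r in rows:
            names.add(r["field_name"])
            names.add(f"{r['source_name']}.{r['field_name']}")
        return names

    # -- change log ------------------------------------------------------

    def log_change(self, entry: ChangeLogEntry) -> int:
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO change_log (variant_id, source_name, field_name, "
                "old_value, new_value, old_version, new_version, timestamp, "
                "interesting) VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    entry.variant_id, entry.source_name, entry.field_name,
                    entry.old_value, entry.new_value, entry.old_version,
                    entry.new_version, entry.timestamp, int(entry.interesting),
                ),
            )
        return cur.lastrowid

    def mark_interesting(self, entry_ids: Iterable[int]) -> None:
        with self._conn:
            for eid in entry_ids:
                self._conn.execute(
                    "UPDATE change_log SET interesting=1 WHERE entry_id=?",
                    (eid,),
                )

    def change_log(
        self,
        source_name: Optional[str] = None,
        interesting_only: bool = False,
    ) -> list:
        sql = "SELECT * FROM change_log WHERE 1=1"
        params: list = []
        if source_name is not None:
            sql += " AND source_name=?"
            params.append(source_name)
        if interesting_only:
            sql += " AND interesting=1"
        sql += " ORDER BY entry_id"
        return [
            ChangeLogEntry(
                variant_id=r["variant_id"], source_name=r["source_name"],
                field_name=r["field_name"], old_value=r["old_value"],
                new_value=r["new_value"], old_version=r["old_version"],
                new_version=r["new_version"], timestamp=r["timestamp"],
                interesting=bool(r["interesting"]), entry_id=r["entry_id"],
            )
            for r in self._conn.execute(sql, params)
        ]

    # -- filter schemes --------------------------------------------------

    def save_scheme_document(
        self, name: str, owner: str, document: dict, overwrite: bool = False
    ) -> None:
        exists = self._conn.execute(
            "SELECT 1 FROM filter_schemes WHERE name=?", (name,)
        ).fetchone()
        if exists and not overwrite:
            raise ConflictError(f"filter scheme {name!r} already exists")
        with self._conn:
            self._conn.execute(
                "INSERT INTO filter_schemes (name, owner, document, created_at) "
                "VALUES (?, ?, ?, ?) ON CONFLICT(name) DO UPDATE SET "
                "owner=excluded.owner, document=excluded.document",
                (name, owner, json.dumps(document), _now()),
            )

    def load_scheme_document(self, name: str) -> dict:
        row = self._conn.execute(
            "SELECT document FROM filter_schemes WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no filter scheme named {name!r}")
        return json.loads(row["document"])

    # -- gene panels -----------------------------------------------------

    def create_panel(
        self,
        name: str,
        owner: str,
        transcript_ids: Iterable[str],
        public: bool = False,
        comment: Optional[str] = None,
    ) -> None:
        ids = list(transcript_ids)
        if not ids:
            raise ValidationError("a gene panel needs at least one identifier")
        if self._conn.execute(
            "SELECT 1 FROM gene_panels WHERE name=?", (name,)
        ).fetchone():
            raise ConflictError(f"panel {name!r} already exists")
        with self._conn:
            self._conn.execute(
                "INSERT INTO gene_panels (name, owner, public, comment) "
                "VALUES (?, ?, ?, ?)",
                (name, owner, int(public), comment),
            )
            for tid in ids:
                self._conn.execute(
                    "INSERT OR IGNORE INTO gene_panel_members "
                    "(panel_name, transcript_id) VALUES (?, ?)",
                    (name, tid),
                )

    def get_panel(self, name: str, user: Optional[str] = None) -> dict:
        row = self._conn.execute(
            "SELECT * FROM gene_panels WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no panel named {name!r}")
        if user is not None and not row["public"] and row["owner"] != user:
            raise AuthorizationError(
                f"panel {name!r} is private to {row['owner']!r}"
            )
        members = [
            r["transcript_id"]
            for r in self._conn.execute(
                "SELECT transcript_id FROM gene_panel_members "
                "WHERE panel_name=? ORDER BY transcript_id",
                (name,),
            )
        ]
        return {
            "name": row["name"], "owner": row["owner"],
            "public": bool(row["public"]), "comment": row["comment"],
            "transcript_ids": members,
        }

    def list_panels(self, user: Optional[str] = None) -> list:
        rows = self._conn.execute(
            "SELECT name, owner, public FROM gene_panels ORDER BY name"
        )
        out = []
        for r in rows:
            if user is None or r["public"] or r["owner"] == user:
                out.append(r["name"])
        return out

    def share_panel(self, name: str, user: str) -> None:
        panel = self.get_panel(name)
        if panel["owner"] != user:
            raise AuthorizationError(
                f"only the owner may publish panel {name!r}"
            )
        with self._conn:
            self._conn.execute(
                "UPDATE gene_panels SET public=1 WHERE name=?", (name,)
            )

    # -- curation queue --------------------------------------------------

    def queue_curation(self, variant_id: int, reason: str) -> int:
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO curation_queue (variant_id, reason, created_at) "
                "VALUES (?, ?, ?)",
                (variant_id, reason, _now()),
            )
        return cur.lastrowid

    def pending_curation(self) -> list:
        rows = self._conn.execute(
            "SELECT * FROM curation_queue WHERE status='pending' "
            "ORDER BY item_id"
        )
        return [dict(r) for r in rows]

    def resolve_curation(self, item_id: int, action: str = "resolved") -> None:
        if action not in ("resolved", "skipped"):
            raise ValidationError("curation action must be resolved or skipped")
        with self._conn:
            self._conn.execute(
                "UPDATE curation_queue SET status=? WHERE item_id=?",
                (action, item_id),
            )

    # -- audit journal ---------------------------------------------------

    def append_audit(self, argv: Sequence[str]) -> None:
        with self._conn:
            self._conn.execute(
                "INSERT INTO audit_log (timestamp, command) VALUES (?, ?)",
                (_now(), json.dumps(list(argv))),
            )

    def audit_entries(self) -> list:
        rows = self._conn.execute(
            "SELECT command FROM audit_log ORDER BY entry_id"
        )
        return [json.loads(r["command"]) for r in rows]


def load_pedigree(
    store: VariantStore,
    ped_source,
    project_id: int,
    sidecar_source=None,
) -> list:
    """Register samples from a PED-like tab-delimited file.

    Columns: family_id, sample_id, father_id, mother_id, sex (1 male,
    2 female), phenotype (2 affected, 1 unaffected); '0' means unknown.
    Samples are registered first, then parent links are set (so the file
    order does not matter) and full siblings (same family, same parents)
    are linked symmetrically.  An optional sidecar table with header
    ``sample_id, hpo_terms, is_control`` adds HPO terms (comma separated)
    and the control flag.

    Returns the registered sample ids.
    """
    if hasattr(ped_source, "read"):
        text = ped_source.read()
    elif "\n" in str(ped_source):
        text = str(ped_source)
    else:
        text = Path(ped_source).read_text()

    hpo: dict = {}
    control: dict = {}
    if sidecar_source is not None:
        if hasattr(sidecar_source, "read"):
            side_text = sidecar_source.read()
        elif "\n" in str(sidecar_source):
            side_text = str(sidecar_source)
        else:
            side_text = Path(sidecar_source).read_text()
        lines = [ln for ln in side_text.splitlines() if ln.strip()]
        for ln in lines[1:]:
            parts = ln.split("\t")
            sid = parts[0]
            if len(parts) > 1 and parts[1]:
                hpo[sid] = tuple(t for t in parts[1].split(",") if t)
            if len(parts) > 2:
                control[sid] = parts[2] in ("1", "true", "True")

    rows = []
    for lineno, ln in enumerate(text.splitlines(), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 6:
            raise ValidationError(
                f"pedigree line {lineno}: expected 6 columns, got {len(parts)}"
            )
        rows.append(parts[:6])

    sex_map = {"1": "male", "2": "female"}
    for family, sid, father, mother, sex, phenotype in rows:
        store.add_sample(
            sid,
            project_id,
            gender=sex_map.get(sex, "unknown"),
            hpo_terms=hpo.get(sid, ()),
            is_control=control.get(sid, False),
            affected=(phenotype == "2"),
        )
    for family, sid, father, mother, sex, phenotype in rows:
        store.set_parents(
            sid,
            father if father != "0" else None,
            mother if mother != "0" else None,
        )
    # symmetric sibling links: same family and same (known) parents
    by_parents: dict = {}
    for family, sid, father, mother, sex, phenotype in rows:
        if father != "0" or mother != "0":
            by_parents.setdefault((family, father, mother), []).append(sid)
    for sibs in by_parents.values():
        for i, a in enumerate(sibs):
            for b in sibs[i + 1:]:
                store.add_sibling(a, b)
    return [r[1] for r in rows]
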