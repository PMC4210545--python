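"""Annotate-missing cycle, release updates, archival, change log, flagging."""
import pytest

from varbank import VariantStore
from varbank import fixtures as fx
from varbank.annotation import (
    NO_HIT_FIELD,
    TableAnnotationSource,
    annotate_missing,
    flag_interesting,
    lookup_frequency,
    replay_changes,
    update_source,
)
from varbank.errors import ConflictError
from varbank.models import ChangeLogEntry


def _seeded_store(keys):
    store = VariantStore()
    store.set_current_build("hg19")
    ids = {k: store.upsert_variant("hg19", *k) for k in keys}
    return store, ids


KEYS = [("chrT", 1_000 + 10 * i, "A", "G") for i in range(12)]


def _table(version, rows):
    header = "chrom\tpos\tref\talt\tscore\n"
    body = "".join(
        f"{c}\t{p}\t{r}\t{a}\t{v}\n" for (c, p, r, a), v in rows.items()
    )
    return TableAnnotationSource.from_tsv("toy", version, header + body)


class TestAnnotateMissing:
    def test_only_unannotated_variants_are_queried(self):
        store, ids = _seeded_store(KEYS[:5])
        src = _table("v1", {k: "1" for k in KEYS[:5]})
        queried = []
        original = src.lookup

        def spy(variants):
            queried.extend(v.variant_id for v in variants)
            return original(variants)

        src.lookup = spy
        # pre-annotate two variants
        for k in KEYS[:2]:
            store.insert_annotation(ids[k], "toy", "score", "0", "v0")
        store.register_source_version("toy", "v0")
        annotate_missing(store, src)
        assert sorted(queried) == sorted(ids[k] for k in KEYS[2:5])

    def test_rerun_annotates_zero(self):
        store, ids = _seeded_store(KEYS[:5])
        src = _table("v1", {k: "1" for k in KEYS[:3]})
        assert annotate_missing(store, src) == 5
        assert annotate_missing(store, src) == 0

    def test_no_hit_variants_get_sentinel(self):
        store, ids = _seeded_store(KEYS[:2])
        src = _table("v1", {KEYS[0]: "1"})  # KEYS[1] missing from the table
        annotate_missing(store, src)
        records = store.active_annotation_records(ids[KEYS[1]], "toy")
        assert set(records) == {NO_HIT_FIELD}


class TestUpdateSource:
    def test_changed_value_is_archived_not_deleted(self):
        store, ids = _seeded_store(KEYS[:1])
        annotate_missing(store, _table("v1", {KEYS[0]: "0.01"}))
        changes = update_source(store, _table("v2", {KEYS[0]: "0.02"}))
        assert len(changes) == 1
        history = store.annotation_history(ids[KEYS[0]], "toy", "score")
        assert [(r.value, r.active) for r in history] == [
            ("0.01", False), ("0.02", True)
        ]
        assert history[0].retired_at is not None

    def test_identical_release_logs_nothing(self):
        store, ids = _seeded_store(KEYS[:3])
        rows = {k: "7" for k in KEYS[:3]}
        annotate_missing(store, _table("v1", rows))
        assert update_source(store, _table("v2", rows)) == []

    def test_dropped_field_retired_and_logged_absent(self):
        store, ids = _seeded_store(KEYS[:1])
        annotate_missing(store, _table("v1", {KEYS[0]: "5"}))
        changes = update_source(store, _table("v2", {}))
        assert len(changes) == 1 and changes[0].new_value is None
        history = store.annotation_history(ids[KEYS[0]], "toy", "score")
        assert [r.active for r in history] == [False]

    def test_version_must_be_new(self):
        store, _ = _seeded_store(KEYS[:1])
        annotate_missing(store, _table("v1", {KEYS[0]: "5"}))
        with pytest.raises(ConflictError):
            update_source(store, _table("v1", {KEYS[0]: "6"}))

    def test_single_active_record_under_repeated_updates(self):
        store, ids = _seeded_store(KEYS[:4])
        annotate_missing(store, _table("v1", {k: "1" for k in KEYS[:4]}))
        for i, value in enumerate(["2", "3", "2"], start=2):
            update_source(
                store, _table(f"v{i}", {k: value for k in KEYS[:4]})
            )
        for k in KEYS[:4]:
            active = [
                r
                for r in store.annotation_history(ids[k], "toy", "score")
                if r.active
            ]
            assert len(active) == 1 and active[0].value == "2"

    def test_changelog_replay_reconstructs_state(self):
        store, ids = _seeded_store(KEYS)
        upd = fx.generate_annotation_update(3, KEYS)
        annotate_missing(
            store, TableAnnotationSource.from_tsv("knowledge", "v1", upd.v1)
        )
        update_source(
            store, TableAnnotationSource.from_tsv("knowledge", "v2", upd.v2)
        )
        first = {}
        current = {}
        for k, vid in ids.items():
            for field in ("effect", "clinical_significance", "global_maf",
                          "rsid"):
                hist = store.annotation_history(vid, "knowledge", field)
                if hist:
                    first[(vid, "knowledge", field)] = hist[0].value
                active = [r for r in hist if r.active]
                if active:
                    current[(vid, "knowledge", field)] = active[0].value
        replayed = replay_changes(first, store.change_log("knowledge"))
        assert replayed == current


class TestFlagging:
    def _entry(self, field, old, new):
        return ChangeLogEntry(
            variant_id=1, source_name="s", field_name=field,
            old_value=old, new_value=new, old_version="v1",
            new_version="v2", timestamp="t",
        )

    @pytest.mark.parametrize(
        "field,old,new,expected",
        [
            ("effect", "synonymous", "stopgain", True),
            ("effect", "missense", "frameshift", True),
            ("effect", "intronic", "splicing", True),
            ("effect", "stopgain", "synonymous", False),
            ("effect", "synonymous", "missense", False),
            ("global_maf", "0.010", "0.011", False),
            ("clinical_significance", "uncertain_significance",
             "pathogenic", True),
            ("clinical_significance", "benign", "likely_pathogenic", True),
            ("clinical_significance", "pathogenic", "benign", False),
        ],
    )
    def test_flag_rules(self, field, old, new, expected):
        flagged = flag_interesting([self._entry(field, old, new)])
        assert bool(flagged) is expected

    def test_any_transcript_effect_triggers_flag(self):
        entry = self._entry(
            "effect", "synonymous|missense", "synonymous|stopgain"
        )
        assert flag_interesting([entry]) == [entry]

    def test_fixture_planted_flags_recovered_exactly(self):
        store, ids = _seeded_store(KEYS)
        upd = fx.generate_annotation_update(9, KEYS)
        annotate_missing(
            store, TableAnnotationSource.from_tsv("knowledge", "v1", upd.v1)
        )
        changes = update_source(
            store, TableAnnotationSource.from_tsv("knowledge", "v2", upd.v2)
        )
        flagged = flag_interesting(changes, store=store)
        got = {
            (*store.get_variant(c.variant_id).key()[1:], c.field_name)
            for c in flagged
        }
        assert got == upd.interesting
        persisted = store.change_log(interesting_only=True)
        assert len(persisted) == len(flagged)


class TestFrequencyLookup:
    def test_exact_allele_match_only(self):
        text = (
            "chrom\tpos\tref\talt\trsid\tglobal_maf\n"
            "chrT\t100\tA\tG\trs42\t0.05\n"
        )
        src = TableAnnotationSource.from_tsv("freq", "v1", text)
        from varbank.models import Variant

        hit = lookup_frequency(Variant("hg19", "chrT", 100, "A", "G"), src)
        assert hit == {"rsid": "rs42", "global_maf": "0.05"}
        miss = lookup_frequency(Variant("hg19", "chrT", 100, "A", "T"), src)
        assert miss == {}
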