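"""Relational store: identity, round trips, permissions, integrity."""
import pytest

from varbank import (
    AuthorizationError,
    ConflictError,
    GenotypeCall,
    NotFoundError,
    ValidationError,
    VariantStore,
)
from varbank.models import UserClassification
from varbank.store import load_pedigree


@pytest.fixture()
def project(store):
    pid = store.create_project("demo")
    store.add_sample("S1", pid)
    return pid


class TestVariantIdentity:
    def test_upsert_is_idempotent(self, store):
        a = store.upsert_variant("hg19", "1", 100, "A", "G")
        b = store.upsert_variant("hg19", "1", 100, "A", "G")
        assert a == b

    def test_distinct_alt_gets_distinct_id(self, store):
        a = store.upsert_variant("hg19", "1", 100, "A", "G")
        b = store.upsert_variant("hg19", "1", 100, "A", "T")
        assert a != b

    @pytest.mark.parametrize(
        "ref,alt",
        [("A", "A"), ("", "G"), ("A", ""), ("N", "G"), ("A", "<DEL>"),
         ("a", "g")],
    )
    def test_malformed_alleles_rejected(self, store, ref, alt):
        with pytest.raises(ValidationError):
            store.upsert_variant("hg19", "1", 100, ref, alt)

    def test_variant_round_trip(self, store):
        vid = store.upsert_variant("hg19", "chr2", 5_000, "AT", "A")
        v = store.get_variant(vid)
        assert (v.build, v.chrom, v.pos, v.ref, v.alt) == (
            "hg19", "chr2", 5_000, "AT", "A"
        )


class TestCalls:
    def test_allelic_ratio_from_depths(self, store, project):
        vid = store.upsert_variant("hg19", "1", 100, "A", "G")
        store.store_call(
            GenotypeCall("S1", vid, "het", ad_ref=10, ad_alt=10)
        )
        call = store.get_call("S1", vid)
        assert call.allelic_ratio == pytest.approx(0.5)

    def test_missing_depths_propagate_as_none(self, store, project):
        vid = store.upsert_variant("hg19", "1", 100, "A", "G")
        store.store_call(GenotypeCall("S1", vid, "het"))
        call = store.get_call("S1", vid)
        assert call.allelic_ratio is None
        assert call.gq is None and call.qd is None

    def test_duplicate_call_needs_overwrite(self, store, project):
        vid = store.upsert_variant("hg19", "1", 100, "A", "G")
        store.store_call(GenotypeCall("S1", vid, "het"))
        with pytest.raises(ConflictError):
            store.store_call(GenotypeCall("S1", vid, "hom_alt"))
        store.store_call(GenotypeCall("S1", vid, "hom_alt"), overwrite=True)
        assert store.get_call("S1", vid).genotype == "hom_alt"

    def test_call_quality_vector_round_trip(self, store, project):
        vid = store.upsert_variant("hg19", "1", 100, "A", "G")
        call = GenotypeCall(
            "S1", vid, "het", qual=812.5, gq=99, ad_ref=12, ad_alt=6,
            qd=14.2, mq=58.1, fs=1.2, base_q_rank_sum=-0.3,
            mq_rank_sum=0.1, read_pos_rank_sum=2.0,
            filter_status="VQSRTrancheSNP99.90to100.00",
        )
        store.store_call(call)
        back = store.get_call("S1", vid)
        assert back == call

    def test_one_variant_row_many_calls(self, store, project):
        store.add_sample("S2", project)
        store.add_sample("S3", project)
        for s in ("S1", "S2", "S3"):
            vid = store.upsert_variant("hg19", "1", 100, "A", "G")
            store.store_call(GenotypeCall(s, vid, "het"))
        assert store.count_variants() == 1
        assert len(store.calls_for_variant(vid)) == 3


class TestPermissions:
    def test_role_ordering(self, store):
        pid = store.create_project("p")
        store.grant_role(pid, "alice", "edit")
        assert store.check_permission("alice", pid, "read_only")
        assert store.check_permission("alice", pid, "edit")
        assert not store.check_permission("alice", pid, "admin")

    def test_read_only_cannot_edit(self, store):
        pid = store.create_project("p")
        store.grant_role(pid, "bob", "read_only")
        assert not store.check_permission("bob", pid, "edit")

    def test_absent_user_has_no_access(self, store):
        pid = store.create_project("p")
        assert not store.check_permission("eve", pid, "read_only")

    def test_unknown_project_is_an_error(self, store):
        with pytest.raises(NotFoundError):
            store.check_permission("alice", 999, "read_only")

    def test_classification_requires_edit_role(self, store, project):
        vid = store.upsert_variant("hg19", "1", 100, "A", "G")
        store.grant_role(project, "viewer", "read_only")
        store.grant_role(project, "editor", "edit")
        c = UserClassification(vid, "S1", diagnostic_class="pathogenic")
        with pytest.raises(AuthorizationError):
            store.set_classification("viewer", c)
        store.set_classification("editor", c)
        assert store.get_classification(vid, "S1").diagnostic_class == (
            "pathogenic"
        )


class TestProjectIntegrity:
    def test_delete_refuses_to_orphan(self, store, project):
        with pytest.raises(ConflictError):
            store.delete_project(project)

    def test_cascade_delete_removes_samples_and_calls(self, store, project):
        vid = store.upsert_variant("hg19", "1", 100, "A", "G")
        store.store_call(GenotypeCall("S1", vid, "het"))
        store.delete_project(project, cascade=True)
        with pytest.raises(NotFoundError):
            store.get_sample("S1")
        assert store.calls_for_variant(vid) == []

    def test_duplicate_sample_rejected(self, store, project):
        with pytest.raises(ConflictError):
            store.add_sample("S1", project)


class TestPedigree:
    def test_parent_cycles_rejected(self, store, project):
        store.add_sample("S2", project)
        store.set_parents("S1", "S2", None)
        with pytest.raises(ValidationError):
            store.set_parents("S2", "S1", None)

    def test_siblings_are_symmetric(self, store, project):
        store.add_sample("S2", project)
        store.add_sibling("S1", "S2")
        assert store.get_sample("S2").sibling_ids == ("S1",)
        assert store.get_sample("S1").sibling_ids == ("S2",)

    def test_ped_file_round_trip(self, store):
        pid = store.create_project("fam")
        ped = (
            "FAM1\tKID\tDAD\tMUM\t1\t2\n"
            "FAM1\tSIB\tDAD\tMUM\t2\t1\n"
            "FAM1\tDAD\t0\t0\t1\t1\n"
            "FAM1\tMUM\t0\t0\t2\t1\n"
        )
        sidecar = (
            "sample_id\thpo_terms\tis_control\n"
            "KID\tHP:0000001,HP:0000002\t0\n"
            "MUM\t\t1\n"
        )
        load_pedigree(store, ped, pid, sidecar)
        kid = store.get_sample("KID")
        assert kid.father_id == "DAD" and kid.mother_id == "MUM"
        assert kid.affected and kid.hpo_terms == ("HP:0000001", "HP:0000002")
        assert kid.sibling_ids == ("SIB",)
        assert store.get_sample("MUM").is_control

    def test_sample_round_trip(self, store, project):
        store.add_sample(
            "P1", project, gender="female", hpo_terms=("HP:1",),
            is_control=True, affected=True,
        )
        s = store.get_sample("P1")
        assert (s.gender, s.is_control, s.affected, s.hpo_terms) == (
            "female", True, True, ("HP:1",)
        )


class TestBuilds:
    def test_retired_build_rejects_writes(self, store, project):
        store.upsert_variant("hg18", "1", 100, "A", "G")
        store.retire_build("hg18")
        from varbank import ReadOnlyBuildError

        with pytest.raises(ReadOnlyBuildError):
            store.upsert_variant("hg18", "1", 200, "A", "G")


class TestPanels:
    def test_private_panel_is_owner_only(self, store):
        store.create_panel("cardio", "alice", ["NM_1", "NM_2"])
        with pytest.raises(AuthorizationError):
            store.get_panel("cardio", user="bob")
        store.share_panel("cardio", "alice")
        assert store.get_panel("cardio", user="bob")["transcript_ids"] == [
            "NM_1", "NM_2"
        ]

    def test_empty_panel_rejected(self, store):
        with pytest.raises(ValidationError):
            store.create_panel("empty", "alice", [])
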