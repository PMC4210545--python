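"""Filter trees vs brute force, inheritance truth tables, occurrence,
burden, panels, scheme persistence."""
import random

import pytest

from helpers import variant_keys, write_trio_store
from varbank import GenotypeCall, VariantStore
from varbank import fixtures as fx
from varbank.errors import (
    ConflictError,
    FamilyConfigError,
    NotFoundError,
    SchemeValidationError,
    ValidationError,
)
from varbank.filters import (
    FilterNode,
    FilterScheme,
    build_contexts,
    evaluate,
    filter_burden,
    filter_de_novo,
    filter_dominant,
    filter_occurrence,
    filter_panel,
    filter_recessive,
    load_scheme,
    node_passes,
    save_scheme,
)
from varbank.genemodel import GeneModelIndex
from varbank.vcf_import import import_vcf

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing", "absent")


def atom(field, op, value, policy="exclude"):
    return FilterNode.make_atom(
        field_name=field, operator=op, value=value, missing_policy=policy
    )


class TestTreeEvaluation:
    def test_and_of_quality_and_location(self, corpus_store):
        tree = FilterNode.make_group(
            "AND", [atom("gq", "ge", 60), atom("location", "eq", "exonic")]
        )
        got = evaluate(tree, "S1", corpus_store)
        contexts = build_contexts(corpus_store, "S1")
        expected = [
            v for v, ctx in contexts
            if ctx.get("gq") and ctx["gq"][0] >= 60
            and ctx.get("location") == ["exonic"]
        ]
        assert variant_keys(got) == variant_keys(expected)
        assert len(got) > 0
        positions = [(v.chrom, v.pos) for v in got]
        assert positions == sorted(positions)

    def test_or_is_union_and_and_is_intersection(self, corpus_store):
        a = atom("genotype", "eq", "hom_alt")
        b = atom("global_maf", "lt", 0.01)
        sa = {v.variant_id for v in evaluate(a, "S1", corpus_store)}
        sb = {v.variant_id for v in evaluate(b, "S1", corpus_store)}
        s_or = {
            v.variant_id
            for v in evaluate(
                FilterNode.make_group("OR", [a, b]), "S1", corpus_store
            )
        }
        s_and = {
            v.variant_id
            for v in evaluate(
                FilterNode.make_group("AND", [a, b]), "S1", corpus_store
            )
        }
        assert s_or == sa | sb
        assert s_and == sa & sb

    def test_random_trees_match_per_variant_oracle(self, corpus_store):
        rng = random.Random(2024)
        contexts = build_contexts(corpus_store, "S1")
        for _ in range(50):
            tree = fx.random_filter_tree(rng)
            got = {
                v.variant_id
                for v in evaluate(tree, "S1", corpus_store,
                                  contexts=contexts)
            }
            expected = {
                v.variant_id
                for v, ctx in contexts
                if node_passes(tree, ctx)
            }
            assert got == expected

    def test_empty_group_is_a_validation_error(self, corpus_store):
        with pytest.raises(SchemeValidationError):
            evaluate(
                FilterNode.make_group("AND", []), "S1", corpus_store
            )

    def test_unknown_field_rejected_before_evaluation(self, corpus_store):
        with pytest.raises(SchemeValidationError) as err:
            evaluate(atom("no_such_field", "eq", 1), "S1", corpus_store)
        assert "no_such_field" in str(err.value)

    def test_missing_policy_include_vs_exclude(self, corpus_store):
        contexts = build_contexts(corpus_store, "S1")
        n_missing = sum(1 for _, ctx in contexts if not ctx.get("global_maf"))
        assert n_missing > 0  # the corpus plants annotation gaps
        excl = evaluate(
            atom("global_maf", "le", 1.0, "exclude"), "S1", corpus_store
        )
        incl = evaluate(
            atom("global_maf", "le", 1.0, "include"), "S1", corpus_store
        )
        assert len(incl) - len(excl) == n_missing

    def test_is_missing_operator(self, corpus_store):
        contexts = build_contexts(corpus_store, "S1")
        missing = evaluate(
            atom("global_maf", "is_missing", None), "S1", corpus_store
        )
        assert len(missing) == sum(
            1 for _, ctx in contexts if not ctx.get("global_maf")
        )

    def test_any_transcript_semantics(self, store):
        """A pipe-joined multi-transcript value passes when any component
        matches the atom."""
        pid = store.create_project("p")
        store.add_sample("S1", pid)
        store.set_current_build("hg19")
        v1 = store.upsert_variant("hg19", "chrT", 100, "A", "G")
        v2 = store.upsert_variant("hg19", "chrT", 200, "A", "G")
        for vid in (v1, v2):
            store.store_call(GenotypeCall("S1", vid, "het"))
        store.insert_annotation(v1, "genes", "effect",
                                "synonymous|stopgain", "v1")
        store.insert_annotation(v2, "genes", "effect", "synonymous", "v1")
        got = evaluate(atom("effect", "eq", "stopgain"), "S1", store)
        assert [v.variant_id for v in got] == [v1]


class TestInheritanceModels:
    def test_trio_truth_classes_recovered(self, trio):
        store, truth = trio
        assert variant_keys(filter_de_novo(store, "CHILD")) == sorted(
            truth.classes["de_novo"]
        )
        assert variant_keys(filter_recessive(store, "CHILD")) == sorted(
            truth.classes["recessive"]
        )
        assert variant_keys(filter_dominant(store, "CHILD")) == sorted(
            truth.classes["dominant"]
        )

    def test_de_novo_and_recessive_are_disjoint(self, trio):
        store, _ = trio
        dn = {v.variant_id for v in filter_de_novo(store, "CHILD")}
        rec = {v.variant_id for v in filter_recessive(store, "CHILD")}
        assert dn & rec == set()

    def test_missing_parent_links_raise(self, trio):
        store, _ = trio
        with pytest.raises(FamilyConfigError):
            filter_de_novo(store, "FATHER")

    @pytest.mark.parametrize("father_g", GENOTYPES)
    @pytest.mark.parametrize("mother_g", GENOTYPES)
    def test_de_novo_truth_table(self, store, father_g, mother_g):
        """Both parental-call policies over all 25 genotype combinations."""
        pid = store.create_project("p")
        for s in ("F", "M"):
            store.add_sample(s, pid)
        store.add_sample("C", pid, father_id="F", mother_id="M")
        vid = store.upsert_variant("hg19", "chrT", 100, "A", "G")
        store.set_current_build("hg19")
        store.store_call(GenotypeCall("C", vid, "het"))
        for s, g in (("F", father_g), ("M", mother_g)):
            if g != "absent":
                store.store_call(GenotypeCall(s, vid, g))
        strict = bool(filter_de_novo(store, "C",
                                     require_called_parents=True))
        lenient = bool(filter_de_novo(store, "C",
                                      require_called_parents=False))
        assert strict == (father_g == "hom_ref" and mother_g == "hom_ref")
        non_carrier = ("hom_ref", "missing", "absent")
        assert lenient == (
            father_g in non_carrier and mother_g in non_carrier
        )

    def test_recessive_requires_het_parents(self, store):
        pid = store.create_project("p")
        for s in ("F", "M"):
            store.add_sample(s, pid)
        store.add_sample("C", pid, father_id="F", mother_id="M")
        store.set_current_build("hg19")

        def plant(pos, c, f, m):
            vid = store.upsert_variant("hg19", "chrT", pos, "A", "G")
            for s, g in (("C", c), ("F", f), ("M", m)):
                store.store_call(GenotypeCall(s, vid, g))
            return vid

        keep = plant(100, "hom_alt", "het", "het")
        plant(200, "hom_alt", "het", "hom_alt")  # mother hom -> excluded
        plant(300, "het", "het", "het")          # child het -> excluded
        got = filter_recessive(store, "C")
        assert [v.variant_id for v in got] == [keep]

    def test_dominant_cosegregation_truth_table(self, store):
        """Affected must carry; a missing call in an affected member
        excludes; unaffected carriers exclude."""
        pid = store.create_project("p")
        store.add_sample("F", pid, affected=True)
        store.add_sample("M", pid)
        store.add_sample("C", pid, father_id="F", mother_id="M",
                         affected=True)
        store.set_current_build("hg19")

        def plant(pos, c, f, m):
            vid = store.upsert_variant("hg19", "chrT", pos, "A", "G")
            for s, g in (("C", c), ("F", f), ("M", m)):
                if g != "absent":
                    store.store_call(GenotypeCall(s, vid, g))
            return vid

        keep1 = plant(100, "het", "het", "hom_ref")
        keep2 = plant(150, "hom_alt", "het", "absent")
        plant(200, "het", "hom_ref", "hom_ref")   # affected father lacks it
        plant(300, "het", "het", "het")           # unaffected mother carries
        plant(400, "het", "missing", "hom_ref")   # affected call missing
        got = filter_dominant(store, "C")
        assert sorted(v.variant_id for v in got) == sorted([keep1, keep2])

    def test_dominant_requires_an_affected_member(self, store):
        pid = store.create_project("p")
        for s in ("F", "M"):
            store.add_sample(s, pid)
        store.add_sample("C", pid, father_id="F", mother_id="M")
        with pytest.raises(FamilyConfigError):
            filter_dominant(store, "C")


@pytest.fixture()
def cohort(tmp_path):
    """6-sample cohort with 3 planted carriers in GENE1 (first carrier has
    two variants there), annotated with the fixture gene models."""
    from varbank.annotation import GeneModelAnnotationSource, annotate_missing

    gm = fx.generate_gene_model(1)
    vcfs, truth = fx.generate_cohort(5, 6, "GENE1", 3, gene_model=gm)
    store = VariantStore()
    pid = store.create_project("cohort")
    for sample, text in vcfs.items():
        store.add_sample(sample, pid)
        p = tmp_path / f"{sample}.vcf"
        p.write_text(text)
        import_vcf(store, sample, p, "hg19")
    index = GeneModelIndex(gm.transcripts)
    annotate_missing(
        store,
        GeneModelAnnotationSource(name="genes", version="v1", index=index),
    )
    yield store, truth, index
    store.close()


class TestOccurrence:
    def test_bounds(self, cohort):
        store, truth, _ = cohort
        samples = store.sample_ids()
        variants = store.variants("hg19")
        shared = [
            v for v in variants
            if len(store.carrier_samples(v.variant_id, samples)) >= 1
        ]
        # every planted variant is sample-private, so max_count 0 drops all
        assert filter_occurrence(store, variants, samples, None, 0) == []
        assert variant_keys(
            filter_occurrence(store, variants, samples, 1, None)
        ) == variant_keys(shared)

    def test_no_op_bounds_are_identity(self, cohort):
        store, _, _ = cohort
        variants = store.variants("hg19")
        got = filter_occurrence(
            store, variants, store.sample_ids(), 0, None
        )
        assert variant_keys(got) == variant_keys(variants)

    def test_empty_sample_set_rejected(self, cohort):
        store, _, _ = cohort
        with pytest.raises(ValidationError):
            filter_occurrence(store, store.variants("hg19"), [], 1, None)

    def test_monotone_in_min_count(self, corpus_store):
        variants = corpus_store.variants("hg19")
        sizes = [
            len(filter_occurrence(corpus_store, variants, ["S1"], m, None))
            for m in (0, 1, 2)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_carrier_count_against_call_table(self, trio):
        store, truth = trio
        samples = list(fx.TRIO_SAMPLES)
        for v in store.variants("hg19"):
            expected = sum(
                1
                for s in samples
                if (c := store.get_call(s, v.variant_id)) is not None
                and c.genotype in ("het", "hom_alt")
            )
            assert len(
                store.carrier_samples(v.variant_id, samples)
            ) == expected


class TestBurden:
    def test_distinct_sample_counting(self, cohort):
        store, truth, _ = cohort
        samples = store.sample_ids()
        genes = filter_burden(store, samples, min_samples=3)
        assert "GENE1" in genes
        # the double-variant carrier counts once: min 4 excludes the gene
        assert "GENE1" not in filter_burden(store, samples, min_samples=4)
        assert "GENE1" not in filter_burden(store, samples, max_samples=2)

    def test_contributing_variants_returned(self, cohort):
        store, truth, _ = cohort
        genes = filter_burden(store, store.sample_ids(), min_samples=3)
        planted = sorted(
            k
            for sample_vs in truth.gene_variants.values()
            for k in sample_vs
        )
        assert variant_keys(genes["GENE1"]) == planted


class TestPanels:
    def test_version_suffix_ignored(self, cohort):
        store, truth, index = cohort
        variants = store.variants("hg19")
        kept = filter_panel(store, variants, ["NM_0001.3"], index=index)
        planted = sorted(
            k
            for sample_vs in truth.gene_variants.values()
            for k in sample_vs
        )
        assert variant_keys(kept) == planted

    def test_non_panel_gene_excluded(self, cohort):
        store, _, index = cohort
        variants = store.variants("hg19")
        assert filter_panel(store, variants, ["NM_9999"], index=index) == []

    def test_empty_panel_rejected(self, cohort):
        store, _, _ = cohort
        with pytest.raises(ValidationError):
            filter_panel(store, store.variants("hg19"), [])

    def test_stored_panel_lookup(self, cohort):
        store, truth, index = cohort
        store.create_panel("p1", "alice", ["NM_0001"], public=True)
        kept = filter_panel(
            store, store.variants("hg19"), "p1", index=index, user="bob"
        )
        assert len(kept) == 4  # 3 carriers, first one with two variants


class TestSchemePersistence:
    def _scheme(self):
        root = FilterNode.make_group(
            "AND",
            [
                atom("gq", "ge", 30),
                FilterNode.make_group(
                    "OR",
                    [
                        atom("effect", "eq", "stopgain"),
                        FilterNode.make_group(
                            "AND", [atom("global_maf", "lt", 0.01)]
                        ),
                    ],
                ),
            ],
        )
        return FilterScheme(name="rare_lof", owner="alice", root=root)

    def test_save_load_round_trip_evaluates_identically(self, corpus_store):
        scheme = self._scheme()
        save_scheme(corpus_store, scheme)
        loaded = load_scheme(corpus_store, "rare_lof")
        assert loaded.root.to_dict() == scheme.root.to_dict()
        assert variant_keys(
            evaluate(loaded, "S1", corpus_store)
        ) == variant_keys(evaluate(scheme, "S1", corpus_store))

    def test_name_collision_needs_overwrite(self, corpus_store):
        scheme = self._scheme()
        save_scheme(corpus_store, scheme, overwrite=True)
        with pytest.raises(ConflictError):
            save_scheme(corpus_store, scheme)

    def test_unknown_scheme_not_found(self, corpus_store):
        with pytest.raises(NotFoundError):
            load_scheme(corpus_store, "nope")

    def test_late_binding_of_fields(self, store):
        """A scheme referencing an unknown annotation loads fine but fails
        validation at evaluation time, naming the field."""
        pid = store.create_project("p")
        store.add_sample("S1", pid)
        store.set_current_build("hg19")
        scheme = FilterScheme(
            name="stale", owner="alice",
            root=atom("retired_field", "eq", "x"),
        )
        save_scheme(store, scheme)
        loaded = load_scheme(store, "stale")
        with pytest.raises(SchemeValidationError) as err:
            evaluate(loaded, "S1", store)
        assert "retired_field" in str(err.value)
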