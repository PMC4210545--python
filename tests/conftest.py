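import pytest

from varbank import VariantStore
from varbank import fixtures as fx
from varbank.annotation import TableAnnotationSource, annotate_missing
from varbank.vcf_import import import_vcf


@pytest.fixture()
def store():
    with VariantStore() as s:
        yield s


@pytest.fixture()
def trio(tmp_path):
    """In-memory store loaded with the seed-1 trio plus its truth table."""
    from helpers import write_trio_store

    vcf, truth = fx.generate_trio(1, 5)
    s = VariantStore()
    write_trio_store(s, vcf, tmp_path)
    yield s, truth
    s.close()


@pytest.fixture(scope="session")
def gene_model():
    return fx.generate_gene_model(1)


@pytest.fixture(scope="session")
def corpus_store(tmp_path_factory):
    """500-variant single-sample store with the 'knowledge' annotations."""
    tmp = tmp_path_factory.mktemp("corpus")
    vcf_text, table_text = fx.generate_filter_corpus(11, 500)
    vcf_path = tmp / "corpus.vcf"
    vcf_path.write_text(vcf_text)
    s = VariantStore(tmp / "corpus.db")
    pid = s.create_project("corpus")
    s.add_sample("S1", pid)
    import_vcf(s, "S1", vcf_path, "hg19")
    source = TableAnnotationSource.from_tsv("knowledge", "v1", table_text)
    annotate_missing(s, source)
    yield s
    s.close()
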