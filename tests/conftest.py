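import pytest

from chdprio import synthetic_data as syn
from chdprio.annotation import read_annotation_table
from chdprio.genomic_io import read_pedigree, read_vcf


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """Worked-example quintet fixture, study-initiation frequency mode."""
    d = tmp_path_factory.mktemp("fixture_study")
    return syn.make_quintet_fixture(syn.QuintetFixtureSpec(seed=1), d)


@pytest.fixture(scope="session")
def current_fixture(tmp_path_factory):
    """Same fixture annotated with current gnomAD frequencies."""
    d = tmp_path_factory.mktemp("fixture_current")
    return syn.make_quintet_fixture(
        syn.QuintetFixtureSpec(seed=1, frequency_mode="current"), d)


@pytest.fixture(scope="session")
def study_inputs(study_fixture):
    """(variants, annotations, pedigree) loaded from the study fixture."""
    variants = list(read_vcf(study_fixture.vcf))
    annotations = read_annotation_table(study_fixture.annotations)
    pedigree = read_pedigree(study_fixture.ped)
    return variants, annotations, pedigree


@pytest.fixture()
def quintet():
    return syn.quintet_pedigree()
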