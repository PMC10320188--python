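import pytest

from drugrank import (
    build_profile, generate_fixture_kb, parse_cnv_tsv, parse_rnk, parse_vcf,
    write_breast_patient, write_melanoma_patient,
)
from drugrank.inputs import Origin, QueryMode


@pytest.fixture(scope="session")
def curated_kb():
    """Randomized 50-gene / 30-drug knowledge base plus the curated
    melanoma/breast scenario rows."""
    return generate_fixture_kb(seed=1, n_genes=50, n_drugs=30, curated=True)


@pytest.fixture(scope="session")
def melanoma_files(tmp_path_factory):
    return write_melanoma_patient(tmp_path_factory.mktemp("melanoma"))


@pytest.fixture(scope="session")
def breast_files(tmp_path_factory):
    return write_breast_patient(tmp_path_factory.mktemp("breast"))


@pytest.fixture(scope="session")
def melanoma_profile(melanoma_files):
    return build_profile(
        somatic=parse_vcf(melanoma_files["somatic"], Origin.SOMATIC),
        cnvs=parse_cnv_tsv(melanoma_files["cnv"]),
        expr=parse_rnk(melanoma_files["rnk"]),
        cancer_type="SKIN",
        mode=QueryMode.CLINICAL,
    )


@pytest.fixture(scope="session")
def breast_profile(breast_files):
    return build_profile(
        somatic=parse_vcf(breast_files["somatic"], Origin.SOMATIC),
        germline=parse_vcf(breast_files["germline"], Origin.GERMLINE),
        cancer_type="BREAST",
        mode=QueryMode.CLINICAL,
    )
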