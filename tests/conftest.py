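import pytest

from pgxkit.classify import classify_records
from pgxkit.panel import PhenotypeRules, Recommendations, load_panel
from pgxkit.synthetic import CohortSpec, generate_cohort
from pgxkit.variant_io import (
    apply_site_filters,
    attach_annotations,
    read_annotations,
    read_vcf,
)

BUILD = "GRCh37"


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def rules():
    return PhenotypeRules.load()


@pytest.fixture(scope="session")
def recommendations():
    return Recommendations.load()


@pytest.fixture(scope="session")
def cohort500(tmp_path_factory, panel):
    """Synthetic 500-genome cohort written to disk and read back through VCF."""
    out = tmp_path_factory.mktemp("cohort500")
    spec = CohortSpec(seed=123, n_samples=500)
    cohort = generate_cohort(spec, panel, out_dir=out)
    return spec, cohort, out


@pytest.fixture(scope="session")
def retained500(cohort500, panel):
    """Filter-cascade output of the 500-genome cohort, from the written files."""
    _, _, out = cohort500
    records = read_vcf(out / "cohort.vcf", mode="cohort", build=BUILD)
    attach_annotations(records, read_annotations(out / "annotations.tsv"))
    retained, excluded = apply_site_filters(records)
    assert not excluded  # the generator emits clean sites by default
    return retained


@pytest.fixture(scope="session")
def classified500(retained500, panel):
    return classify_records(retained500, panel, BUILD)


@pytest.fixture(scope="session")
def cohort547(panel):
    """Default-size cohort (547 genomes), in memory."""
    spec = CohortSpec(seed=11)
    return spec, generate_cohort(spec, panel)
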