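import pytest

from ohnoretain import build_summary_report
from ohnoretain.datasets import BASELINES, SS4R_OVERALL_REPORTED, curated_dataset


@pytest.fixture(scope="session")
def curated():
    """Gene and event tables reproducing the curated-dataset stratum counts."""
    return curated_dataset()


@pytest.fixture(scope="session")
def curated_report(curated):
    genes, events = curated
    return build_summary_report(
        genes,
        events,
        BASELINES,
        reported_totals={"SSGD.overall_pg": SS4R_OVERALL_REPORTED},
    )
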