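import warnings
from pathlib import Path

import pytest

from bmzone.registry import GeneRecord

FIXTURES = Path(__file__).parent / "data"


@pytest.fixture
def toy_cohort_dir() -> Path:
    """Shipped desk-size cohort fixture (regenerable from seed 17)."""
    return FIXTURES / "toy_cohort"


def make_record(symbol="HSPG2", role="BM_matrix", mclass="proteoglycan", **flags):
    return GeneRecord(
        symbol=symbol,
        network_role=role,
        matrisome_class=mclass,
        evidence_flags=dict(flags),
    )


@pytest.fixture
def small_registry_records():
    """Five curated candidates: 3 confirmed, 1 predicted, 1 insufficient."""
    return [
        make_record("HSPG2", vertebrate_immunolocalization=True),
        make_record("LAMA5", "BM_matrix", "glycoprotein",
                    vertebrate_immunolocalization=True),
        make_record("COL4A1", "BM_matrix", "collagen",
                    vertebrate_immunolocalization=True),
        make_record("MATN1", "BM_matrix", "glycoprotein",
                    ortholog_tag_localized=True),
        make_record("NOEV1", "BM_matrix", "secreted_factor"),
    ]


@pytest.fixture(autouse=True)
def _silence_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
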