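import io

import pytest

from aedisparity import CountCube, read_reports
from aedisparity.datasets import analgesics_sex

TOY_TSV = """\
report_id\tdrug\trole\tpt\tsex
r1\tDrugA\tPS\tHepatitis\tmale
r2\tDrugA\tPS\tHepatic failure\tfemale
r3\tDrugB\tC\tHepatitis\tmale
r4\tDrugA\tPS\tHepatitis\tUNK
r5\tDrugB\tPS\tRash\tfemale
"""


@pytest.fixture
def toy_records():
    return read_reports(
        io.StringIO(TOY_TSV),
        columns={"event_term": "pt", "group": "sex"},
        group_labels=("male", "female"),
    )


@pytest.fixture
def two_drug_cube():
    """One AE, two drugs: d1 counts (10, 20), d2 counts (5, 5)."""
    entries = {
        ("ae", "d1", "male"): 10, ("ae", "d1", "female"): 20,
        ("ae", "d2", "male"): 5, ("ae", "d2", "female"): 5,
    }
    return CountCube(entries=entries, group_labels=("male", "female"))


@pytest.fixture(scope="session")
def analgesics():
    return analgesics_sex()
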