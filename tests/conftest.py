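import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from aldh_curator import catalog


@pytest.fixture(scope="session")
def table_records():
    """The packaged chickpea ALDH superfamily catalog."""
    return catalog.load_packaged_catalog()


@pytest.fixture(scope="session")
def table_by_locus(table_records):
    return {r.locus_id: r for r in table_records}
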