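import csv

import pytest

from mthia.pipeline import load_packaged_variant_table
from mthia.hia import load_packaged_evidence
from mthia.structure import StructureMap


@pytest.fixture(scope="session")
def variant_table():
    """Packaged per-variant rows (category, equivalent, CRW letter, Cis)."""
    return load_packaged_variant_table()


@pytest.fixture(scope="session")
def evidence_records():
    return load_packaged_evidence()


def make_map(organism, spec):
    """Build a StructureMap from (pos, base, partner_or_None, helix) tuples."""
    return StructureMap(
        organism=organism,
        bases={p: b for p, b, _, _ in spec},
        partners={p: q for p, b, q, _ in spec},
        helices={p: h for p, b, _, h in spec},
    )
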