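"""Shared fixtures: one simulated gene family reused across the suite.

The family is the standard study condition of the synthetic generator
(12 in-group + 5 out-group taxa, 1800 nt gene, two planted 21-nt windows,
16S-like marker at a tenth of the gene rate); expensive derived objects
(the in-group alignment, the window scan) are session-scoped.
"""

import pytest

from cladeamp import alignment, fixtures, primer_design
from cladeamp.io import Taxonomy


@pytest.fixture(scope="session")
def family():
    return fixtures.simulate_gene_family(fixtures.SimulationParams(seed=3))


@pytest.fixture(scope="session")
def ingroup_records(family):
    return [r for r in family.gene_records if r[0].startswith("IN")]


@pytest.fixture(scope="session")
def ingroup_msa(family, ingroup_records):
    return alignment.progressive_align(ingroup_records)


@pytest.fixture(scope="session")
def candidates(ingroup_msa):
    return primer_design.scan_windows(
        ingroup_msa, primer_design.DesignParams(), "IN01"
    )


@pytest.fixture(scope="session")
def taxonomy(family):
    return Taxonomy(family.taxonomy)
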