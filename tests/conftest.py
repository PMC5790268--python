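"""Shared fixtures: example templates and the canonical simulated data set.

All synthetic data is generated at test time; nothing is loaded from
disk except the packaged example templates.
"""

import pytest

from mitorrna import annotate_sequence, load_example_template
from mitorrna.simulate import default_config, evolve

CANONICAL_SEED = 11
CANONICAL_DEPTH = 0.05


@pytest.fixture(scope="session")
def rrns_template():
    return load_example_template("rrnS")


@pytest.fixture(scope="session")
def rrnl_template():
    return load_example_template("rrnL")


@pytest.fixture(scope="session")
def sim(rrns_template):
    """Canonical 11-taxon simulation (depth 0.05, divergent T01 at H47)."""
    return evolve(
        default_config(rrns_template, depth=CANONICAL_DEPTH, seed=CANONICAL_SEED)
    )


@pytest.fixture(scope="session")
def sim_structures(sim, rrns_template):
    """Annotated structures of the canonical simulated leaves."""
    return {
        r.id: annotate_sequence(r, rrns_template) for r in sim.leaf_records
    }
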