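import logging

import pytest

from eqowl import (
    PhenotypeProfile,
    RoleAssignment,
    make_relational_statement,
    make_simple_statement,
)
from eqowl.fixtures import make_reference_bundle

# classic-EQ relational compilations warn about slot-map ambiguity by design;
# keep test output readable.
logging.getLogger("eqowl.compile").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    return make_reference_bundle()


@pytest.fixture(scope="session")
def tax(bundle):
    return bundle.taxonomy


@pytest.fixture(scope="session")
def red_eye(bundle):
    return make_simple_statement(bundle.term("red"), bundle.term("eye"))


@pytest.fixture(scope="session")
def short_tail(bundle):
    return make_simple_statement(bundle.term("short"), bundle.term("tail"))


@pytest.fixture(scope="session")
def red_short_profile(red_eye, short_tail):
    return PhenotypeProfile("red-eye-short-tail", (red_eye, short_tail))


@pytest.fixture(scope="session")
def iron_spleen(bundle):
    """Relational statement: concentration of iron in the spleen."""
    return make_relational_statement(
        bundle.term("concentration of"),
        [
            RoleAssignment("concentrated", bundle.term("iron")),
            RoleAssignment("concentrator", bundle.term("spleen")),
        ],
        relation=bundle.term("is concentrated in"),
    )


@pytest.fixture(scope="session")
def eye_distance(bundle):
    """Symmetric relational statement: distance between the two eyes."""
    return make_relational_statement(
        bundle.term("distance"),
        [
            RoleAssignment("relatum", bundle.term("left eye")),
            RoleAssignment("relatum", bundle.term("right eye")),
        ],
        relation=bundle.term("is distant from"),
        spec=bundle.relation_specs[1],
    )
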