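import pytest

from grnmc.fixtures import (
    TABLE2_PROFILES,
    profile_index,
    root_scn,
    root_scn_fas0,
    root_scn_scr_star,
)

# Formula battery used by the differential (engine vs oracle) suites.
# Covers every operator, state literals and binder nesting to depth 2;
# gene names follow the random-network generator (g0, g1, ...).
FORMULA_BATTERY = [
    "true",
    "false",
    "g0",
    "not g0",
    "g0 and g1",
    "g0 or not g1",
    "g0 implies g1",
    "EX g0",
    "AX (g0 or g1)",
    "EF (g0 and not g1)",
    "AF g0",
    "EG g0",
    "AG (g0 implies EF g1)",
    "E[g0 U g1]",
    "A[(not g0) U g1]",
    "EY g0",
    "EF #3",
    "E[(not #0) U #3]",
    "down s . EX s",
    "down s . AX s",
    "down s . EX EF s",
    "down s . EX ((not s) and EX s)",
    "down s . EX down t . EY (s and EX not t)",
    "down s . EF s",
    "down s . EX EX s",
    "not EF (down s . EX EX s)",
    "down s . (g0 and EX (down t . EY (s and t)))",
    "down s . AX EF s",
]

# the five special-cased binder patterns, in canonical spelling
OPTIMIZED_PATTERNS = [
    "down s . EX s",
    "down s . AX s",
    "down s . EX EF s",
    "down s . EX ((not s) and EX s)",
    "down s . EX down t . EY (s and EX not t)",
]


@pytest.fixture(scope="session")
def root_grn():
    return root_scn()


@pytest.fixture(scope="session")
def root_grn_star():
    return root_scn_scr_star()


@pytest.fixture(scope="session")
def root_grn_fas0():
    return root_scn_fas0()


@pytest.fixture(scope="session")
def table2_indices(root_grn):
    """Cell type -> state index of its expected expression profile."""
    return {
        name: profile_index(root_grn, profile)
        for name, profile in TABLE2_PROFILES.items()
    }
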