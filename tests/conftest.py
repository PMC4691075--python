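import io

import pytest

from hopperpath.de_input import Contrast
from hopperpath.pathway_calls import PathwayDirection, RegulationPattern
from hopperpath.pathway_db import PathwayDatabase, PathwayRecord

#: Shorthand direction states used across tests: None = no call.
U, D, M = PathwayDirection.UP, PathwayDirection.DOWN, PathwayDirection.MIXED
STATES = (None, U, D, M)


def make_pattern(pathway_id="P", s=None, r=None, g0=None, g6=None):
    """Build a RegulationPattern from per-contrast states (None = absent)."""
    calls = {}
    for contrast, state in (
        (Contrast.S6_S0, s),
        (Contrast.R6_R0, r),
        (Contrast.R0_S0, g0),
        (Contrast.R6_S6, g6),
    ):
        if state is not None:
            calls[contrast] = state
    return RegulationPattern(pathway_id=pathway_id, calls=calls)


@pytest.fixture
def toy_db():
    """Three pathways over five loci, with one shared locus and one empty."""
    return PathwayDatabase(
        [
            PathwayRecord(
                "PWY1",
                "alpha biosynthesis",
                ("Biosynthesis", "Amino acids biosynthesis"),
                frozenset({"L1", "L2"}),
            ),
            PathwayRecord(
                "PWY2",
                "beta degradation",
                ("Degradation", "Amino acids degradation"),
                frozenset({"L2", "L3", "L4"}),
            ),
            PathwayRecord(
                "PWY3",
                "gamma fermentation",
                ("Energy",),
                frozenset(),
            ),
        ]
    )


def tsv(text):
    """An in-memory TSV stream from a triple-quoted template."""
    lines = [line for line in text.strip("\n").splitlines()]
    return io.StringIO("\n".join(lines) + "\n")
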