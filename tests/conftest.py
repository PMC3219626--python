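"""Shared fixtures. Expensive surface maps are session-scoped so the
pocket/groove/background pipelines run once and are reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from anchorprobe.fixtures import (make_background_decoys,
                                  make_groove_fixture, make_pocket_fixture,
                                  negate_charges, pocket_with_carboxylates)
from anchorprobe.groove import background_distribution
from anchorprobe.surface import MapConfig, map_surface


@pytest.fixture(scope="session")
def pocket2():
    """Hemispherical pocket, two carboxylates, plus its ground truth."""
    return make_pocket_fixture(pocket_with_carboxylates(2))


@pytest.fixture(scope="session")
def pocket1():
    return make_pocket_fixture(pocket_with_carboxylates(1))


@pytest.fixture(scope="session")
def pocket0():
    return make_pocket_fixture(pocket_with_carboxylates(0))


@pytest.fixture(scope="session")
def arg_map2(pocket2):
    structure, _ = pocket2
    return map_surface(structure, "ARG", config=MapConfig())


@pytest.fixture(scope="session")
def arg_map1(pocket1):
    structure, _ = pocket1
    return map_surface(structure, "ARG", config=MapConfig())


@pytest.fixture(scope="session")
def arg_map0(pocket0):
    structure, _ = pocket0
    return map_surface(structure, "ARG", config=MapConfig())


@pytest.fixture(scope="session")
def glu_map2(pocket2):
    structure, _ = pocket2
    return map_surface(structure, "GLU", config=MapConfig())


@pytest.fixture(scope="session")
def acidic_groove():
    return make_groove_fixture("carboxylate")


@pytest.fixture(scope="session")
def groove_maps(acidic_groove):
    """Arg and Glu maps of the acid-lined groove and its charge-negated
    mirror, keyed (structure_kind, probe)."""
    structure, path = acidic_groove
    negated = negate_charges(structure)
    out = {}
    for kind, st in (("acidic", structure), ("negated", negated)):
        for probe in ("ARG", "GLU"):
            out[(kind, probe)] = map_surface(st, probe, config=MapConfig())
    return out


@pytest.fixture(scope="session")
def decoy_set():
    return make_background_decoys(4, seed=7)


@pytest.fixture(scope="session")
def background(decoy_set):
    return background_distribution(decoy_set, probe="ARG")
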