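"""Shared fixtures: reference meshes, the canonical design, toy duplexes."""

from collections import OrderedDict

import pytest

from endobox import canonical_config, run_pipeline
from endobox.assembly import Assembly, Label
from endobox.lid import LidSpec
from endobox.mesh import PolyhedralMesh, build_cube_mesh
from endobox.seqplan import reverse_complement


def make_cube():
    return build_cube_mesh(50.7)


def make_tetra():
    vertices = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    faces = [(0, 1, 2), (0, 2, 3), (0, 3, 1), (1, 3, 2)]
    return PolyhedralMesh.from_data(vertices, faces)


def make_octa():
    vertices = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    faces = [
        (0, 2, 4), (2, 1, 4), (1, 3, 4), (3, 0, 4),
        (2, 0, 5), (1, 2, 5), (3, 1, 5), (0, 3, 5),
    ]
    return PolyhedralMesh.from_data(vertices, faces)


@pytest.fixture(scope="session")
def cube_mesh():
    return make_cube()


@pytest.fixture(scope="session")
def tetra_mesh():
    return make_tetra()


@pytest.fixture(scope="session")
def octa_mesh():
    return make_octa()


@pytest.fixture(scope="session")
def canonical_bundle():
    """The canonical gene-box design built once per test session."""
    return run_pipeline(canonical_config(seed=7))


@pytest.fixture(scope="session")
def canonical_design(canonical_bundle):
    return canonical_bundle.design


def make_toy_duplex(with_labels: bool = True):
    """A 42-bp linear duplex with one central BamHI site.

    The top strand is one continuous 42-nt strand; the bottom is two
    staples whose nick falls inside the recognition site, exactly at the
    enzyme's bottom-strand cut position.  The Cy3 label sits on the left
    staple, the BHQ2 quencher on the right one, 9 bp apart across the
    future cut -- digestion separates them into two fragments.
    """
    top = "ACGTTACCAGTCAGTGAC" + "GGATCC" + "TATTGGACAACCGTTCAT"
    assert len(top) == 42 and top.count("GGATCC") == 1
    left = reverse_complement(top[:23])    # covers through the overhang
    right = reverse_complement(top[23:])
    strands = OrderedDict([("top", top), ("bottom-L", left), ("bottom-R", right)])
    pairs = []
    for i in range(23):
        pairs.append((("top", i), ("bottom-L", 22 - i)))
    for j in range(19):
        pairs.append((("top", 23 + j), ("bottom-R", 18 - j)))
    labels = ()
    if with_labels:
        labels = (
            Label(strand="bottom-L", index=6, dye="Cy3",
                  role="fluorophore", pair_id=1),     # faces top[16]
            Label(strand="bottom-R", index=16, dye="BHQ2",
                  role="quencher", pair_id=1),        # faces top[25]
        )
    lid = LidSpec(site_anchors=((19, 24),))
    return Assembly(strands=strands, pairs=tuple(pairs), labels=labels), lid


@pytest.fixture()
def toy_duplex():
    return make_toy_duplex()
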