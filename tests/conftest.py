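import gemmi
import numpy as np
import pytest

import rotascape as rs

CLASS_MAP = {"class": "rotClassLabel"}


@pytest.fixture(scope="session")
def small_scene_tables():
    """A small labelled, C2-expanded scene as in-memory half-tables."""
    truth = rs.default_scene(n=400, seed=5)
    return rs.scene_tables(truth), truth


@pytest.fixture(scope="session")
def paired_small(small_scene_tables):
    (mod, cond), truth = small_scene_tables
    return rs.pair_refinements(mod, cond), truth


@pytest.fixture(scope="session")
def three_component_truth():
    """The well-separated three-mode scene used for recovery checks."""
    return rs.SceneTruth(
        components=[
            rs.MixtureComponent(center=(13.0, 0.0, 14.0), sigma=5.0, weight=0.5),
            rs.MixtureComponent(center=(-3.0, -8.0, -8.0), sigma=5.0, weight=0.3),
            rs.MixtureComponent(center=(-40.0, 0.0, 12.0), sigma=5.0, weight=0.2),
        ],
        n=50_000, noise_sigma=1.0, seed=11,
    )


def _toy_structure() -> gemmi.Structure:
    """Three atoms in the swivel plane: anchor plus two catalytic sites.

    Anchor radius 30 A, site radii 40 and 35 A about the z pivot axis, with
    out-of-plane offsets, so anchor-to-site distances follow the law of
    cosines in the swivel angle.
    """
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")

    def add(resnum, resname, atomname, pos, element):
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resnum, " ")
        atom = gemmi.Atom()
        atom.name = atomname
        atom.pos = gemmi.Position(*pos)
        atom.element = gemmi.Element(element)
        res.add_atom(atom)
        chain.add_residue(res)

    add(2112, "ALA", "CA", (30.0, 0.0, 10.0), "C")
    add(161, "CYS", "SG", (40.0, 0.0, -5.0), "S")
    add(581, "SER", "OG", (-35.0, 0.0, -5.0), "O")
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


@pytest.fixture(scope="session")
def toy_structure_files(tmp_path_factory):
    base = tmp_path_factory.mktemp("structure")
    st = _toy_structure()
    pdb = base / "toy.pdb"
    cif = base / "toy.cif"
    st.write_pdb(str(pdb))
    st.make_mmcif_document().write_file(str(cif))
    return pdb, cif


@pytest.fixture()
def toy_tether_model():
    """Analytic toy geometry (no file I/O): anchor r=30, sites r=40 and 35."""
    return rs.TetherModel(
        anchor=np.array([30.0, 0.0, 10.0]),
        sites={"KS": np.array([40.0, 0.0, -5.0]),
               "MAT": np.array([-35.0, 0.0, -5.0])},
        pivot_point=np.zeros(3),
        pivot_axis=np.array([0.0, 0.0, 1.0]),
        max_reach=60.0,
    )
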