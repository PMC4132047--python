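import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.spatial import cKDTree

from silkfric import structures as st
from silkfric.constants import RISE_PER_RESIDUE


@pytest.mark.parametrize("strands,sheets,length,chains,residues", [
    (5, 5, 8, 25, 200),     # published unit composition
    (1, 1, 1, 1, 1),
    (2, 3, 4, 6, 24),
])
def test_crystal_unit_counts(strands, sheets, length, chains, residues):
    spec = st.BuilderSpec(strands_per_sheet=strands, sheets_per_unit=sheets,
                          polyala_length=length)
    unit = st.build_crystal_unit(spec)
    assert unit.n_chains == chains
    assert unit.n_residues == residues
    assert set(unit.phase) == {"crystalline"}


@pytest.mark.parametrize("chains", [8, 1])
def test_amorphous_bundle_counts(chains):
    spec = st.BuilderSpec(chains_per_bundle=chains)
    bundle = st.build_amorphous_bundle(spec, anchor=(0, 0, 0))
    assert bundle.n_chains == chains
    assert bundle.n_residues == chains * 24
    assert set(bundle.phase) == {"amorphous"}


def test_extended_chain_end_to_end_length():
    spec = st.BuilderSpec(chains_per_bundle=1)
    bundle = st.build_amorphous_bundle(spec, anchor=(0, 0, 0))
    ca = bundle.coords[bundle.atom_names == "CA"]
    length = ca[:, 2].max() - ca[:, 2].min()
    assert length == pytest.approx(23 * RISE_PER_RESIDUE, abs=1e-9)


def test_composite_published_composition():
    comp = st.assemble_composite(st.BuilderSpec())
    assert comp.select_phase("crystalline").n_chains == 50
    assert comp.select_phase("amorphous").n_chains == 56


def test_composite_crystal_only():
    comp = st.assemble_composite(st.BuilderSpec(n_units=1, n_bundles=0))
    assert comp.select_phase("amorphous").n_atoms == 0
    assert comp.n_chains == 25


def test_inter_unit_gap_is_three_nm():
    comp = st.assemble_composite(st.BuilderSpec(n_bundles=0))
    labels = comp.chains
    unit_a = comp.select_chains(labels[:25])
    unit_b = comp.select_chains(labels[25:])
    d, _ = cKDTree(unit_a.coords).query(unit_b.coords, k=1)
    assert d.min() == pytest.approx(3.0, abs=0.1)


def test_phase_partition_and_determinism(small_spec):
    a = st.assemble_composite(small_spec)
    b = st.assemble_composite(small_spec)
    assert np.array_equal(a.coords, b.coords)           # bit-identical
    cry = a.select_phase("crystalline")
    amo = a.select_phase("amorphous")
    assert cry.n_atoms + amo.n_atoms == a.n_atoms       # disjoint + exhaustive


@settings(max_examples=25, deadline=None)
@given(units=st_.integers(1, 2), strands=st_.integers(1, 4),
       sheets=st_.integers(1, 3), bundles=st_.integers(0, 4),
       chains=st_.integers(1, 4))
def test_chain_count_conservation(units, strands, sheets, bundles, chains):
    spec = st.BuilderSpec(n_units=units, strands_per_sheet=strands,
                          sheets_per_unit=sheets, n_bundles=bundles,
                          chains_per_bundle=chains,
                          amorphous_sequence="GPGGYG")
    comp = st.assemble_composite(spec)
    assert comp.select_phase("crystalline").n_chains == units * strands * sheets
    assert comp.select_phase("amorphous").n_chains == bundles * chains


def test_invalid_specs_rejected():
    with pytest.raises(st.ValidationError):
        st.BuilderSpec(strands_per_sheet=0).validate()
    with pytest.raises(st.ValidationError):
        st.BuilderSpec(unit_gap=-1.0).validate()
    with pytest.raises(st.ValidationError):
        st.BuilderSpec(amorphous_sequence="GPZ").validate()


def test_placement_clash_raises():
    with pytest.raises(st.PlacementError):
        st.assemble_composite(st.BuilderSpec(standoff=-0.15))


def test_pdb_round_trip(small_composite, tmp_path):
    path = tmp_path / "comp.pdb"
    st.write_pdb(small_composite, path)
    back = st.read_pdb(path)
    assert back.n_atoms == small_composite.n_atoms
    assert np.abs(back.coords - small_composite.coords).max() < 1e-3  # nm
    assert back.chains == small_composite.chains
    assert np.array_equal(back.phase, small_composite.phase)


def test_pdb_biotite_cross_read(small_composite, tmp_path):
    biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
    path = tmp_path / "comp.pdb"
    st.write_pdb(small_composite, path)
    arr = biotite_pdb.PDBFile.read(str(path)).get_structure(model=1)
    assert arr.array_length() == small_composite.n_atoms
    assert np.allclose(arr.coord / 10.0, small_composite.coords, atol=1e-3)


def test_pdb_errors(tmp_path):
    empty = st.Structure(np.zeros((0, 3)), np.zeros(0), np.array([]),
                         np.array([]), np.array([], dtype=int),
                         np.array([]), np.array([]))
    with pytest.raises(st.ValidationError):
        st.write_pdb(empty, tmp_path / "x.pdb")
    bad = tmp_path / "bad.pdb"
    bad.write_text("ATOM      1  CA  ALA A   1    garbage\n")
    with pytest.raises(st.PDBParseError, match="line 1"):
        st.read_pdb(bad)
    (tmp_path / "none.pdb").write_text("REMARK nothing\n")
    with pytest.raises(st.PDBParseError):
        st.read_pdb(tmp_path / "none.pdb")
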