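"""Shared fixtures: hand-written PDB snippets and synthetic proteins."""

from __future__ import annotations

import pytest

from casurf.structure_io import Atom, ProteinStructure, Residue
from casurf.synthetic import FixtureSpec, make_alignment, make_structure


def pdb_line(serial, name, res, chain, num, x, y, z, b=0.0, element=None,
             record="ATOM", altloc=" ", occ=1.0):
    element = element or name[0]
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (f"{record:<6}{serial:>5} {name_field}{altloc}{res:<3} {chain}"
            f"{num:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2}")


@pytest.fixture
def ala_pdb(tmp_path):
    """Single alanine: 5 heavy atoms plus one hydrogen to be dropped."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0),
        pdb_line(3, "C", "ALA", "A", 1, 2.01, 1.42, 0.0),
        pdb_line(4, "O", "ALA", "A", 1, 3.2, 1.6, 0.0),
        pdb_line(5, "CB", "ALA", "A", 1, 1.95, -0.78, -1.21),
        pdb_line(6, "H", "ALA", "A", 1, -0.5, 0.8, 0.0, element="H"),
        "END",
    ]
    path = tmp_path / "ala.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def af_model_pdb(tmp_path):
    """Two-residue AlphaFold-style model: pLDDT 91.3 and 68.2 in B-factors."""
    lines = []
    serial = 1
    for num, b, x0 in [(1, 91.3, 0.0), (2, 68.2, 3.8)]:
        for name, dx in [("N", 0.0), ("CA", 1.0), ("C", 2.0), ("O", 2.5),
                         ("CB", 1.2)]:
            lines.append(pdb_line(serial, name, "ALA", "A", num,
                                  x0 + dx, 0.3 * serial, 0.1 * num, b=b))
            serial += 1
    lines.append("END")
    path = tmp_path / "af.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def water_only_pdb(tmp_path):
    lines = [
        pdb_line(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, record="HETATM"),
        pdb_line(2, "O", "HOH", "A", 2, 3.0, 0.0, 0.0, record="HETATM"),
        "END",
    ]
    path = tmp_path / "water.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """CA with two conformers: B has the higher occupancy and must win."""
    lines = [
        pdb_line(1, "N", "SER", "A", 1, 0.0, 0.0, 0.0, b=20.0),
        pdb_line(2, "CA", "SER", "A", 1, 1.0, 0.0, 0.0, b=21.0,
                 altloc="A", occ=0.4),
        pdb_line(3, "CA", "SER", "A", 1, 9.0, 9.0, 9.0, b=22.0,
                 altloc="B", occ=0.6),
        pdb_line(4, "C", "SER", "A", 1, 2.0, 1.0, 0.0, b=23.0),
        pdb_line(5, "O", "SER", "A", 1, 3.0, 1.2, 0.0, b=24.0),
        pdb_line(6, "OG", "SER", "A", 1, 1.2, -1.0, 0.5, b=25.0),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def complex_pdb(tmp_path):
    """Two chains with controlled inter-chain distances (5, >6, exactly 6 A)."""
    lines = []
    serial = 1
    for chain, coords in [
        ("A", [(1, 0.0, 0.0), (2, 0.0, 20.0), (3, 0.0, 40.0)]),
        ("B", [(1, 5.0, 0.0), (2, 6.0, 40.0)]),
    ]:
        for num, x, y in coords:
            lines.append(pdb_line(serial, "N", "ALA", chain, num, x, y, 3.0,
                                  b=15.0 + serial))
            serial += 1
            lines.append(pdb_line(serial, "CA", "ALA", chain, num, x, y, 0.0,
                                  b=30.0 + serial))
            serial += 1
    lines.append("END")
    path = tmp_path / "complex.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_test_structure(atom_spec: list[tuple[int, str, str, bool, tuple]],
                        names: dict[int, str] | None = None
                        ) -> ProteinStructure:
    """Assemble a ProteinStructure from (residue idx, atom, element,
    backbone?, xyz) tuples for geometry unit tests."""
    by_res: dict[int, list[Atom]] = {}
    for idx, aname, element, backbone, xyz in atom_spec:
        by_res.setdefault(idx, []).append(
            Atom(aname, element, tuple(float(c) for c in xyz), backbone))
    residues = [
        Residue(chain="A", author_number=i, icode="",
                name=(names or {}).get(i, "ALA"), index=i,
                atoms=tuple(atoms))
        for i, atoms in sorted(by_res.items())
    ]
    return ProteinStructure(residues=residues, source_kind="experimental")


@pytest.fixture(scope="session")
def default_protein():
    """One synthetic module with the default study conditions."""
    spec = FixtureSpec(seed=11)
    return make_structure(spec)


@pytest.fixture(scope="session")
def default_alignment(default_protein):
    return make_alignment(default_protein.spec, default_protein)


@pytest.fixture(scope="session")
def two_module_files(tmp_path_factory):
    """Fixture files (model/PAE/alignment/tree) for a two-module protein."""
    from casurf.synthetic import write_fixture_files

    out = tmp_path_factory.mktemp("twomod")
    spec = FixtureSpec(seed=7, n_modules=2)
    return write_fixture_files(spec, out)
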