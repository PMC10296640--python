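"""Delaunay-tessellation surface geometry of a structural module.

The heavy atoms of a module are tessellated into tetrahedra; faces that
belong to exactly one tetrahedron form the boundary, and their vertices are
the surface atoms. A residue is *accessible* when at least one of its
side-chain heavy atoms is a surface atom — backbone exposure alone does not
count, which discriminates residues whose side chain points into the
hydrophobic core from those presenting it to solvent. Two accessible
residues are *adjacent* when a tetrahedron contains a surface atom of each.

Tessellation is computed per structural module, on that module's atoms
only, so interfaces between modules of the same protein register as
surface rather than core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import CasurfError, DegenerateGeometryError
from .structure_io import ProteinStructure, Residue

logger = logging.getLogger(__name__)

INTERFACE_CUTOFF_DEFAULT = 6.0  # A, strict less-than


@dataclass
class SurfaceModel:
    """Geometry of one structural module.

    Atom indices refer to the flattened atom list of the module
    (``atom_residue[i]`` gives the owning residue's sequence index).
    """

    atom_coords: np.ndarray            # (n_atoms, 3)
    atom_residue: np.ndarray           # (n_atoms,) residue sequence indices
    atom_is_side_chain: np.ndarray     # (n_atoms,) bool
    tetrahedra: np.ndarray             # (n_tet, 4) atom indices
    surface_atoms: frozenset[int]
    accessible_residues: frozenset[int]
    adjacency: frozenset[frozenset[int]]   # unordered accessible-residue pairs

    def neighbours(self, residue: int) -> set[int]:
        return {next(iter(p - {residue})) for p in self.adjacency if residue in p}


def triangulate(coords: np.ndarray) -> np.ndarray:
    """3-D Delaunay tessellation; returns (n_tet, 4) vertex-index array.

    Raises :class:`DegenerateGeometryError` for fewer than four points or
    coplanar/collinear input.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array")
    if coords.shape[0] < 4:
        raise DegenerateGeometryError(
            f"tessellation needs >= 4 points, got {coords.shape[0]}")
    try:
        tess = Delaunay(coords)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    if tess.simplices.shape[1] != 4:
        raise DegenerateGeometryError("input points are coplanar")
    return tess.simplices.copy()


def _face_counts(tetrahedra: np.ndarray) -> dict[tuple[int, int, int], int]:
    counts: dict[tuple[int, int, int], int] = {}
    for tet in tetrahedra:
        for face in combinations(sorted(int(v) for v in tet), 3):
            counts[face] = counts.get(face, 0) + 1
    return counts


def surface_atoms(tetrahedra: np.ndarray) -> frozenset[int]:
    """Vertices of boundary faces — faces present in exactly one tetrahedron."""
    out: set[int] = set()
    for face, count in _face_counts(tetrahedra).items():
        if count == 1:
            out.update(face)
    return frozenset(out)


def accessible_residues(residues: list[Residue],
                        atom_residue: np.ndarray,
                        atom_is_side_chain: np.ndarray,
                        surface: frozenset[int],
                        glycine_ca_proxy: bool = False) -> frozenset[int]:
    """Residues with at least one side-chain heavy atom on the surface.

    Under the strict default, glycine (no side-chain heavy atoms) is never
    accessible; ``glycine_ca_proxy`` instead treats CA as the side chain of
    residues that have none.
    """
    side_chain = atom_is_side_chain.copy()
    if glycine_ca_proxy:
        has_sc = {r.index: bool(r.side_chain_atoms) for r in residues}
        names = np.array([a.name for r in residues for a in r.atoms])
        for i in range(len(side_chain)):
            if not has_sc[int(atom_residue[i])] and names[i] == "CA":
                side_chain[i] = True
    accessible = {int(atom_residue[i]) for i in surface if side_chain[i]}
    return frozenset(accessible)


def residue_adjacency(atom_residue: np.ndarray,
                      tetrahedra: np.ndarray,
                      surface: frozenset[int],
                      accessible: frozenset[int]) -> frozenset[frozenset[int]]:
    """Accessible-residue pairs whose *surface* atoms share a tetrahedron."""
    pairs: set[frozenset[int]] = set()
    for tet in tetrahedra:
        res_here = {int(atom_residue[int(v)]) for v in tet
                    if int(v) in surface and int(atom_residue[int(v)]) in accessible}
        for a, b in combinations(sorted(res_here), 2):
            pairs.add(frozenset((a, b)))
    return frozenset(pairs)


def build_surface_model(structure: ProteinStructure,
                        residue_indices: set[int] | None = None,
                        chain: str | None = None,
                        glycine_ca_proxy: bool = False) -> SurfaceModel:
    """Compute the full surface geometry of one structural module.

    ``residue_indices`` restricts the module to a residue subset (sequence
    indices); by default the whole chain is one module.
    """
    if chain is None:
        if len(structure.chains) != 1:
            raise CasurfError("ambiguous chain: structure has several")
        chain = structure.chains[0]
    residues = [r for r in structure.chain_residues(chain)
                if residue_indices is None or r.index in residue_indices]
    if not residues:
        raise CasurfError("module contains no residues")

    coords = np.array([a.coord for r in residues for a in r.atoms])
    atom_residue = np.array([r.index for r in residues for _ in r.atoms])
    atom_sc = np.array([not a.is_backbone for r in residues for a in r.atoms])

    tets = triangulate(coords)
    surf = surface_atoms(tets)
    acc = accessible_residues(residues, atom_residue, atom_sc, surf,
                              glycine_ca_proxy=glycine_ca_proxy)
    adj = residue_adjacency(atom_residue, tets, surf, acc)

    _check_connected(acc, adj)
    return SurfaceModel(
        atom_coords=coords,
        atom_residue=atom_residue,
        atom_is_side_chain=atom_sc,
        tetrahedra=tets,
        surface_atoms=surf,
        accessible_residues=acc,
        adjacency=adj,
    )


def _check_connected(accessible: frozenset[int],
                     adjacency: frozenset[frozenset[int]]) -> None:
    # Accessible residues of a well-formed module form one adjacency
    # component; pathological geometry can break this, which is worth a
    # warning but not an error.
    if not accessible:
        return
    nbrs: dict[int, set[int]] = {r: set() for r in accessible}
    for pair in adjacency:
        a, b = tuple(pair)
        nbrs[a].add(b)
        nbrs[b].add(a)
    seen = set()
    stack = [next(iter(accessible))]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(nbrs[node] - seen)
    if seen != set(accessible):
        logger.warning(
            "accessible surface is not a single connected component "
            "(%d of %d residues reachable)", len(seen), len(accessible))


def interface_residues(structure: ProteinStructure, chain_a: str,
                       chain_b: str,
                       cutoff: float = INTERFACE_CUTOFF_DEFAULT) -> frozenset[int]:
    """Residues of ``chain_a`` with a heavy atom strictly within ``cutoff``
    A of any heavy atom of ``chain_b``."""
    chains = structure.chains
    for ch in (chain_a, chain_b):
        if ch not in chains:
            raise CasurfError(f"chain {ch!r} not in structure (has {chains})")
    res_a = structure.chain_residues(chain_a)
    coords_b = np.array([a.coord for r in structure.chain_residues(chain_b)
                         for a in r.atoms])
    tree = cKDTree(coords_b)
    out = set()
    for res in res_a:
        coords = np.array([a.coord for a in res.atoms])
        dmin = tree.query(coords, k=1)[0].min()
        if dmin < cutoff:
            out.add(res.index)
    return frozenset(out)
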