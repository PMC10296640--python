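"""Deterministic synthetic inputs for every pipeline stage.

The generator builds stylised pseudo-proteins. Each structural module is a
spherical shell of residues: surface residues sit on a Fibonacci sphere
(about 5 A apart) with a four-atom pseudo-backbone and one to three
side-chain pseudo-atoms pointing radially outward, the outermost always
reaching a common outer radius. Because the Delaunay boundary coincides
with the convex hull, placing every side-chain tip on a strictly convex
shell guarantees each surface residue is accessible, while an inner shell
of core residues stays buried — enough geometry for tessellation, burial
and adjacency, with no pretence of chemistry.

A conserved patch is planted as a compact spherical cap of surface
residues around a seed direction, and an orthologue alignment is sampled
so that patch columns match the query at ``patch_conservation_mean`` and
the rest at ``background_conservation_mean``. The accompanying PAE matrix
is block-structured: low error within modules, high between them. All
randomness flows through the single seed in :class:`FixtureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import Alignment
from .structure_io import Atom, PAEMatrix, ProteinStructure, Residue, write_pdb

LATTICE_SPACING = 5.0  # A between residue centres
SIDE_CHAIN_STEP = 1.4  # A between successive side-chain pseudo-atoms

# residues with at least one side-chain heavy atom (glycine excluded: under
# the strict accessibility rule it can never be accessible)
_AA3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
        "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]
_AA1 = "ARNDCQEHILKMFPSTWYV"
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic protein."""

    seed: int = 0
    n_modules: int = 1
    residues_per_module: int = 60
    patch_size: int = 12
    patch_conservation_mean: float = 0.9
    background_conservation_mean: float = 0.4
    conservation_noise_sd: float = 0.05
    n_orthologues: int = 50
    intra_module_pae: float = 2.0    # A
    inter_module_pae: float = 15.0   # A
    plddt_mean: float = 90.0

    def __post_init__(self):
        if not 0 < self.patch_size < self.residues_per_module:
            raise ValueError("patch_size must lie in (0, residues_per_module)")
        for mean in (self.patch_conservation_mean,
                     self.background_conservation_mean):
            if not 0.0 <= mean <= 1.0:
                raise ValueError("conservation means must lie in [0, 1]")


@dataclass
class SyntheticProtein:
    structure: ProteinStructure
    pae: PAEMatrix
    module_residues: list[frozenset[int]]    # per module, sequence indices
    planted_patches: list[frozenset[int]]    # per module, boundary patch
    spec: FixtureSpec = field(repr=False, default=None)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors (golden-spiral layout)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_structure(spec: FixtureSpec) -> SyntheticProtein:
    """Generate the pseudo-protein, its PAE matrix, and planted patches."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_modules * spec.residues_per_module

    residues: list[Residue] = []
    plddt: dict[tuple[str, int], float] = {}
    module_residues: list[frozenset[int]] = []
    planted: list[frozenset[int]] = []
    index = 0
    for mod in range(spec.n_modules):
        n = spec.residues_per_module
        n_core = max(4, n // 8)
        n_surface = n - n_core
        # outer shell spaced ~LATTICE_SPACING apart on the sphere
        radius = np.sqrt(LATTICE_SPACING ** 2 * n_surface / (4.0 * np.pi))
        offset = np.array([mod * 120.0, 0.0, 0.0])

        dirs_surface = _fibonacci_sphere(n_surface)
        dirs_core = _fibonacci_sphere(n_core)
        centres = np.vstack([
            dirs_surface * radius,
            dirs_core * max(radius - 5.5, 1.5),
        ]) + offset
        directions = np.vstack([dirs_surface, dirs_core])
        is_surface = np.arange(n) < n_surface

        # plant a compact spherical cap of surface residues around +x
        angles = np.arccos(np.clip(dirs_surface @ np.array([1.0, 0, 0]),
                                   -1, 1))
        order = np.argsort(angles, kind="stable")
        patch_local = set(int(i) for i in order[:spec.patch_size])

        mod_indices = []
        patch_indices = set()
        for local in range(n):
            index += 1
            centre = centres[local] + rng.uniform(-0.1, 0.1, size=3)
            direction = directions[local]
            name = _AA3[rng.integers(len(_AA3))]
            atoms = [
                Atom("N", "N", tuple(centre + [-0.8, -0.5, 0.1]), True),
                Atom("CA", "C", tuple(centre), True),
                Atom("C", "C", tuple(centre + [0.8, -0.5, -0.1]), True),
                Atom("O", "O", tuple(centre + [1.0, -1.4, -0.1]), True),
            ]
            # side chain built inward from a common outer tip radius so the
            # tip of every surface residue lies on one strictly convex shell
            n_sc = int(rng.integers(1, 4))
            tip = centre + direction * (4.2 + rng.uniform(-0.05, 0.05))
            for k in range(n_sc):
                pos = tip - direction * (SIDE_CHAIN_STEP * k)
                if k > 0:
                    pos = pos + rng.uniform(-0.1, 0.1, size=3)
                atoms.append(Atom(f"C{k + 1}X", "C", tuple(pos), False))
            residues.append(Residue(
                chain="A", author_number=index, icode="", name=name,
                index=index, atoms=tuple(atoms)))
            plddt[("A", index)] = float(np.clip(
                rng.normal(spec.plddt_mean, 3.0), 72.0, 99.9))
            mod_indices.append(index)
            if is_surface[local] and local in patch_local:
                patch_indices.add(index)
        module_residues.append(frozenset(mod_indices))
        planted.append(frozenset(patch_indices))

    structure = ProteinStructure(
        residues=residues, source_kind="alphafold-model", plddt=plddt,
        name=f"synthetic-seed{spec.seed}")

    pae = np.empty((n_total, n_total))
    for i, mod_i in enumerate(module_residues):
        for j, mod_j in enumerate(module_residues):
            ii = np.array(sorted(mod_i)) - 1
            jj = np.array(sorted(mod_j)) - 1
            if i == j:
                block = np.clip(
                    rng.normal(spec.intra_module_pae, 0.5,
                               (len(ii), len(jj))), 0.5, 4.5)
            else:
                block = np.clip(
                    rng.normal(spec.inter_module_pae, 1.0,
                               (len(ii), len(jj))), 6.0, None)
            pae[np.ix_(ii, jj)] = block
    np.fill_diagonal(pae, 0.2)

    return SyntheticProtein(structure=structure, pae=PAEMatrix(pae),
                            module_residues=module_residues,
                            planted_patches=planted, spec=spec)


def make_alignment(spec: FixtureSpec, protein: SyntheticProtein,
                   query_id: str = "query") -> tuple[Alignment, str]:
    """Sample an orthologue alignment with planted column conservation.

    Patch columns match the query with probability
    ``patch_conservation_mean``, other columns with
    ``background_conservation_mean`` (both perturbed by truncated Gaussian
    noise per column). Returns the alignment and a star-like Newick guide
    tree with randomised branch lengths.
    """
    rng = np.random.default_rng(spec.seed + 1)
    query = protein.structure.sequence("A")
    patch_cols = set()
    for patch in protein.planted_patches:
        patch_cols |= {i - 1 for i in patch}

    col_p = np.empty(len(query))
    for col in range(len(query)):
        target = (spec.patch_conservation_mean if col in patch_cols
                  else spec.background_conservation_mean)
        col_p[col] = np.clip(
            rng.normal(target, spec.conservation_noise_sd), 0.01, 0.999)

    sequences = [(query_id, query)]
    for o in range(spec.n_orthologues):
        chars = []
        for col, q_aa in enumerate(query):
            if rng.random() < col_p[col]:
                chars.append(q_aa)
            else:
                others = [a for a in _ALPHABET if a != q_aa]
                chars.append(others[rng.integers(len(others))])
        sequences.append((f"ortho{o + 1:03d}", "".join(chars)))
    alignment = Alignment(sequences=sequences, query_id=query_id)

    branches = rng.uniform(0.5, 1.5, size=spec.n_orthologues)
    leaves = [f"{query_id}:0.10"] + [
        f"ortho{o + 1:03d}:{branches[o]:.4f}" for o in range(spec.n_orthologues)]
    newick = "(" + ",".join(leaves) + ");"
    return alignment, newick


def write_fixture_files(spec: FixtureSpec, out_dir: str | Path,
                        query_id: str = "query") -> dict[str, Path]:
    """Materialise one synthetic protein as standard-format files.

    Writes a PDB model (pLDDT in B-factors), a PAE JSON in the nested-list
    dialect, an aligned FASTA, and a Newick guide tree, so that fixtures
    exercise the real readers. Returns the path of each file.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protein = make_structure(spec)
    alignment, newick = make_alignment(spec, protein, query_id=query_id)

    paths = {
        "model": out_dir / "model.pdb",
        "pae": out_dir / "pae.json",
        "alignment": out_dir / "alignment.fasta",
        "tree": out_dir / "tree.nwk",
    }
    write_pdb(protein.structure, paths["model"])
    with open(paths["pae"], "w") as fh:
        json.dump({"predicted_aligned_error":
                   protein.pae.values.round(3).tolist()}, fh)
    with open(paths["alignment"], "w") as fh:
        for ident, seq in alignment.sequences:
            fh.write(f">{ident}\n{seq}\n")
    paths["tree"].write_text(newick + "\n")
    return paths
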