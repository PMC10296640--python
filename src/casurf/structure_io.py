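"""Reading structural models and predicted-aligned-error matrices.

Structural models come as PDB or mmCIF files. AlphaFold-style models carry
the per-residue confidence score (pLDDT, 0-100) in the B-factor column;
experimental structures do not. Predicted aligned error (PAE) matrices are
read from the AlphaFold-DB JSON dialects.

Only heavy atoms of amino-acid residues survive parsing: hydrogens, waters
and ligands are dropped, and alternate conformations are collapsed to the
highest-occupancy conformer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError, MappingError, ParseError

logger = logging.getLogger(__name__)

#: Atom names treated as backbone; every other heavy atom is side-chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    is_backbone: bool


@dataclass(frozen=True)
class Residue:
    chain: str
    author_number: int
    icode: str
    name: str          # 3-letter amino-acid code
    index: int         # 1-based sequence index, contiguous per chain
    atoms: tuple[Atom, ...]

    @property
    def side_chain_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_backbone)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.index)


@dataclass
class ProteinStructure:
    """Heavy-atom protein model with optional per-residue confidence.

    ``plddt`` is present iff ``source_kind == "alphafold-model"`` and maps
    residue keys ``(chain, index)`` to confidence scores in [0, 100].
    """

    residues: list[Residue]
    source_kind: str  # "alphafold-model" | "experimental"
    plddt: dict[tuple[str, int], float] | None = None
    name: str = ""

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]

    def residue_by_key(self, key: tuple[str, int]) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def sequence(self, chain: str) -> str:
        return "".join(_three_to_one(r.name) for r in self.chain_residues(chain))


_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _three_to_one(name: str) -> str:
    if name in _3TO1:
        return _3TO1[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy; ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def _looks_like_alphafold(per_residue_b: list[list[float]]) -> bool:
    """Heuristic: every atom of a residue shares one B value, all in [0, 100]."""
    for bs in per_residue_b:
        if not bs:
            return False
        if max(bs) - min(bs) > 1e-3:
            return False
        if not (0.0 <= bs[0] <= 100.0):
            return False
    return True


def read_structure(path: str | Path, format: str = "auto",
                   source: str = "auto") -> ProteinStructure:
    """Parse a PDB or mmCIF file into a heavy-atom :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from contents/extension).
    source:
        ``"alphafold"``, ``"experimental"`` or ``"auto"``. In auto mode the
        file is classified as an AlphaFold-style model when B-factors are
        constant within each residue and bounded by 100, in which case they
        are interpreted as pLDDT.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    residues: list[Residue] = []
    per_residue_b: list[list[float]] = []
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        idx = 0
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue  # waters, ligands, nucleotides
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            bvals = []
            for aname in by_name:
                a = _pick_altloc(by_name[aname])
                atoms.append(Atom(
                    name=aname,
                    element=a.element.name,
                    coord=(a.pos.x, a.pos.y, a.pos.z),
                    is_backbone=aname in BACKBONE_ATOMS,
                ))
                bvals.append(a.b_iso)
            if not atoms:
                continue
            idx += 1
            residues.append(Residue(
                chain=chain.name,
                author_number=res.seqid.num,
                icode=res.seqid.icode.strip() or "",
                name=res.name,
                index=idx,
                atoms=tuple(atoms),
            ))
            per_residue_b.append(bvals)

    if not residues:
        raise EmptyStructureError(f"{path}: no protein residues found")

    if source == "auto":
        is_af = _looks_like_alphafold(per_residue_b)
    elif source == "alphafold":
        is_af = True
    elif source == "experimental":
        is_af = False
    else:
        raise ValueError(f"unknown source {source!r}")

    plddt = None
    if is_af:
        plddt = {r.key: float(np.mean(bs))
                 for r, bs in zip(residues, per_residue_b)}
    return ProteinStructure(
        residues=residues,
        source_kind="alphafold-model" if is_af else "experimental",
        plddt=plddt,
        name=path.stem,
    )


def write_pdb(structure: ProteinStructure, path: str | Path,
              bfactors: dict[tuple[str, int], float] | None = None) -> None:
    """Serialise a :class:`ProteinStructure` back to PDB format.

    ``bfactors`` overrides the B-factor column per residue (defaults to the
    stored pLDDT for model structures, 0 otherwise).
    """
    st = gemmi.Structure()
    st.name = structure.name or "casurf"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.author_number, res.icode or " ")
        b = 0.0
        if bfactors is not None and res.key in bfactors:
            b = bfactors[res.key]
        elif structure.plddt is not None:
            b = structure.plddt.get(res.key, 0.0)
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coord)
            ga.occ = 1.0
            ga.b_iso = b
            gres.add_atom(ga)
        chains[res.chain].add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


class PAEMatrix:
    """Dense n-by-n predicted-aligned-error matrix in Angstrom.

    Indexed by 1-based residue sequence index; generally asymmetric:
    ``pae(i, j)`` is the expected positional error of residue i when the
    prediction is aligned on residue j.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise FormatError(f"PAE matrix must be square, got {values.shape}")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise FormatError("PAE entries must be finite and non-negative")
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def pae(self, i: int, j: int) -> float:
        """PAE between 1-based residue indices."""
        return float(self.values[i - 1, j - 1])

    def symmetrised(self) -> np.ndarray:
        """Arithmetic-mean symmetrisation of the raw matrix."""
        return 0.5 * (self.values + self.values.T)

    def __eq__(self, other) -> bool:
        return isinstance(other, PAEMatrix) and np.array_equal(self.values, other.values)


def read_pae(path: str | Path) -> PAEMatrix:
    """Read a PAE matrix from either AlphaFold-DB JSON dialect.

    The nested-list dialect stores ``"predicted_aligned_error"`` as a list of
    rows. The flat dialect stores parallel ``"residue1"``/``"residue2"``/
    ``"distance"`` arrays. Both yield identical dense matrices.
    """
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot read PAE JSON {path}: {exc}") from exc
    if isinstance(payload, list):
        if not payload:
            raise FormatError(f"{path}: empty PAE payload")
        payload = payload[0]
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: unrecognised PAE payload structure")

    if "predicted_aligned_error" in payload:
        rows = payload["predicted_aligned_error"]
        n = len(rows)
        if any(len(row) != n for row in rows):
            raise FormatError(f"{path}: PAE rows are not all of length {n}")
        return PAEMatrix(np.asarray(rows, dtype=float))

    if {"residue1", "residue2", "distance"} <= payload.keys():
        r1 = np.asarray(payload["residue1"], dtype=int)
        r2 = np.asarray(payload["residue2"], dtype=int)
        d = np.asarray(payload["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(d)):
            raise FormatError(f"{path}: residue1/residue2/distance lengths differ")
        n = int(max(r1.max(), r2.max()))
        if len(d) != n * n:
            raise FormatError(
                f"{path}: {len(d)} entries cannot fill a {n}x{n} matrix")
        values = np.full((n, n), np.nan)
        values[r1 - 1, r2 - 1] = d
        if np.isnan(values).any():
            raise FormatError(f"{path}: flat PAE payload leaves matrix cells unset")
        return PAEMatrix(values)

    raise FormatError(f"{path}: neither PAE JSON dialect recognised")


def read_offset_map(path: str | Path) -> list[tuple[int, int]]:
    """Read a two-column TSV of (author residue number, target position)."""
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            pairs.append((int(fields[0]), int(fields[1])))
    return pairs


def map_positions(structure: ProteinStructure,
                  offset_map: list[tuple[int, int]]) -> ProteinStructure:
    """Renumber residue sequence indices through an author-number map.

    Residues whose author number is absent from the map are dropped with a
    warning. Duplicate target positions are a mapping error, and the mapping
    must preserve residue order (monotone increasing targets).
    """
    mapping = dict(offset_map)
    if len(mapping) != len(offset_map):
        raise MappingError("duplicate author numbers in offset map")
    targets = [t for _, t in offset_map]
    if len(set(targets)) != len(targets):
        raise MappingError("duplicate target positions in offset map")

    new_residues = []
    new_plddt = {} if structure.plddt is not None else None
    dropped = 0
    last_target: dict[str, int] = {}
    for res in structure.residues:
        if res.author_number not in mapping:
            dropped += 1
            continue
        target = mapping[res.author_number]
        if res.chain in last_target and target <= last_target[res.chain]:
            raise MappingError(
                f"offset map breaks monotonicity at residue {res.author_number}")
        last_target[res.chain] = target
        renum = replace(res, index=target)
        new_residues.append(renum)
        if new_plddt is not None and structure.plddt is not None:
            new_plddt[renum.key] = structure.plddt[res.key]
    if dropped:
        logger.warning("map_positions: dropped %d unmapped residues", dropped)
    if not new_residues:
        raise MappingError("offset map covers no residues of the structure")
    return ProteinStructure(
        residues=new_residues,
        source_kind=structure.source_kind,
        plddt=new_plddt,
        name=structure.name,
    )
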