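"""End-to-end orchestration of the conserved-surface workflow.

Two entry points cover the two input regimes. ``run_alphafold_mode``
consumes a predicted model plus its PAE matrix, segments it into
autonomous structural modules, and analyses each module independently.
``run_pdb_mode`` skips segmentation — PAE is not defined for experimental
structures — and treats one selected chain as a single module.

Both return an :class:`AnalysisResult` whose ``to_json`` form is
deterministic for fixed inputs and parameters (the provenance timestamp is
the only run-dependent field).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .conservation import (ConservationProfile, compute_wcs, map_profile,
                           read_alignment, sequence_weights)
from .errors import CasurfError, DegenerateGeometryError, ParseError
from .patches import MAX_PATCHES_DEFAULT, P_CUTOFF_DEFAULT, iterate_patches
from .segmentation import (MIN_MODULE_SIZE_DEFAULT, PAE_MAX_DEFAULT,
                           PLDDT_MIN_DEFAULT, RESOLUTION_DEFAULT,
                           StructuralModule, build_pae_graph,
                           detect_communities, filter_modules)
from .structure_io import (ProteinStructure, map_positions, read_offset_map,
                           read_pae, read_structure)
from .surface import build_surface_model
from .tac import build_tac_graph, eigenvector_centrality

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    plddt_min: float = PLDDT_MIN_DEFAULT
    pae_max: float = PAE_MAX_DEFAULT
    min_module_size: int = MIN_MODULE_SIZE_DEFAULT
    resolution: float = RESOLUTION_DEFAULT
    max_patches: int = MAX_PATCHES_DEFAULT
    p_cutoff: float = P_CUTOFF_DEFAULT
    glycine_ca_proxy: bool = False
    centrality_tol: float = 1e-8
    centrality_max_iter: int = 1000
    seed: int | None = None  # echoed for provenance; the pipeline is deterministic


@dataclass
class AnalysisResult:
    mode: str
    status: str
    modules: list[dict[str, Any]]
    parameters: dict[str, Any]
    inputs: dict[str, str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "tool": "casurf",
            "version": __version__,
            "mode": self.mode,
            "status": self.status,
            "parameters": self.parameters,
            "inputs": self.inputs,
            "modules": self.modules,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None,
                timestamp: bool = True) -> str:
        payload = self.to_dict()
        if timestamp:
            payload["provenance"] = dict(payload["provenance"])
            payload["provenance"]["timestamp"] = (
                datetime.datetime.now(datetime.timezone.utc).isoformat())
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _module_conservation(profile: ConservationProfile,
                         structure: ProteinStructure,
                         chain: str) -> dict[int, float]:
    return map_profile(profile, structure, chain=chain)


def _analyse_module(structure: ProteinStructure, chain: str,
                    module: StructuralModule | None,
                    residue_indices: frozenset[int] | None,
                    conservation_map: dict[int, float],
                    params: PipelineParams,
                    module_id: int) -> dict[str, Any]:
    surf = build_surface_model(structure, residue_indices=residue_indices,
                               chain=chain,
                               glycine_ca_proxy=params.glycine_ca_proxy)
    patches = iterate_patches(
        surf.accessible_residues, surf.adjacency,
        {i: conservation_map[i] for i in surf.accessible_residues},
        max_patches=params.max_patches, p_cutoff=params.p_cutoff,
        tol=params.centrality_tol, max_iter=params.centrality_max_iter)

    # per-residue table: first-round centrality for accessible residues
    centrality: dict[int, float] = {}
    if surf.adjacency:
        graph = build_tac_graph(
            surf.accessible_residues, surf.adjacency,
            {i: conservation_map[i] for i in surf.accessible_residues})
        centrality = eigenvector_centrality(
            graph, tol=params.centrality_tol,
            max_iter=params.centrality_max_iter)

    residues = sorted(residue_indices) if residue_indices is not None else \
        sorted(r.index for r in structure.chain_residues(chain))
    by_index = {r.index: r for r in structure.chain_residues(chain)}
    table = []
    for i in residues:
        table.append({
            "residue": i,
            "aa": by_index[i].name,
            "accessible": i in surf.accessible_residues,
            "wcs": round(conservation_map[i], 6),
            "centrality": round(centrality[i], 6) if i in centrality else None,
            "plddt": round(structure.plddt[(chain, i)], 2)
            if structure.plddt else None,
        })

    return {
        "id": module_id,
        "chain": chain,
        "residues": residues,
        "n_residues": len(residues),
        "n_accessible": len(surf.accessible_residues),
        "mean_plddt": round(module.mean_plddt, 3) if module else None,
        "mean_pae": round(module.mean_pae, 3) if module else None,
        "residue_table": table,
        "patches": [{
            "iteration": p.iteration,
            "residues": sorted(p.residues),
            "seed_residue": p.seed,
            "absolute_conservation": round(p.absolute_conservation, 6),
            "relative_conservation": round(p.relative_conservation, 6),
            "p_value": float(f"{p.p_value:.6g}"),
            "significant": p.significant,
        } for p in patches],
    }


def run_alphafold_mode(model_path: str | Path, pae_path: str | Path,
                       alignment_path: str | Path,
                       tree_path: str | Path | None = None,
                       query_id: str | None = None,
                       params: PipelineParams | None = None) -> AnalysisResult:
    """Full workflow on a predicted model: segment, then analyse each module."""
    params = params or PipelineParams()
    if not Path(pae_path).exists():
        raise ParseError(
            f"PAE file not found: {pae_path}. For experimental structures "
            "without a PAE matrix use the PDB mode instead.")
    structure = read_structure(model_path, source="alphafold")
    chain = structure.chains[0]
    pae = read_pae(pae_path)

    graph = build_pae_graph(structure, pae, plddt_min=params.plddt_min,
                            pae_max=params.pae_max)
    partition = detect_communities(graph, resolution=params.resolution)
    modules = filter_modules(partition, structure, pae,
                             min_size=params.min_module_size)

    if query_id is None:
        query_id = _default_query_id(alignment_path)
    alignment = read_alignment(alignment_path, query_id=query_id)
    weights = sequence_weights(tree_path, alignment)
    profile = compute_wcs(alignment, weights)
    conservation_map = _module_conservation(profile, structure, chain)

    reported = []
    for module in modules:
        try:
            reported.append(_analyse_module(
                structure, chain, module, module.residues,
                conservation_map, params, module_id=module.rank))
        except (DegenerateGeometryError, CasurfError) as exc:
            logger.warning("module %d skipped: %s", module.rank, exc)

    status = "ok" if reported else \
        "no structural module passed the size filter"
    return AnalysisResult(
        mode="alphafold", status=status, modules=reported,
        parameters=asdict(params),
        inputs={"model": str(model_path), "pae": str(pae_path),
                "alignment": str(alignment_path),
                "tree": str(tree_path) if tree_path else "",
                "query_id": query_id},
    )


def run_pdb_mode(structure_path: str | Path, chain: str,
                 alignment_path: str | Path,
                 tree_path: str | Path | None = None,
                 offset_map_path: str | Path | None = None,
                 query_id: str | None = None,
                 params: PipelineParams | None = None) -> AnalysisResult:
    """Workflow on an experimental structure: one chain, one module."""
    params = params or PipelineParams()
    structure = read_structure(structure_path)
    if chain not in structure.chains:
        raise CasurfError(
            f"chain {chain!r} not found; available chains: {structure.chains}")
    if offset_map_path is not None:
        structure = map_positions(structure, read_offset_map(offset_map_path))

    if query_id is None:
        query_id = _default_query_id(alignment_path)
    alignment = read_alignment(alignment_path, query_id=query_id)
    weights = sequence_weights(tree_path, alignment)
    profile = compute_wcs(alignment, weights)
    conservation_map = _module_conservation(profile, structure, chain)

    reported = []
    status = "ok"
    try:
        reported.append(_analyse_module(
            structure, chain, None, None, conservation_map, params,
            module_id=1))
    except (DegenerateGeometryError, CasurfError) as exc:
        logger.warning("chain %s skipped: %s", chain, exc)
        status = f"chain failed geometry: {exc}"

    return AnalysisResult(
        mode="pdb", status=status, modules=reported,
        parameters=asdict(params),
        inputs={"structure": str(structure_path), "chain": chain,
                "alignment": str(alignment_path),
                "tree": str(tree_path) if tree_path else "",
                "offset_map": str(offset_map_path) if offset_map_path else "",
                "query_id": query_id},
    )


def _default_query_id(alignment_path: str | Path) -> str:
    """First sequence identifier in the alignment file."""
    with open(alignment_path) as fh:
        for line in fh:
            if line.startswith(">"):
                return line[1:].split()[0]
            if line.strip() and not line.upper().startswith("CLUSTAL"):
                return line.split()[0]
    raise ParseError(f"no sequences found in {alignment_path}")


def write_module_tsvs(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    """TSV side-products: module definitions, per-residue tables, patches."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    mod_rows = [{"module": m["id"], "chain": m["chain"],
                 "n_residues": m["n_residues"],
                 "residues": _runs(m["residues"])} for m in result.modules]
    path = out_dir / "modules.tsv"
    pd.DataFrame(mod_rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    for m in result.modules:
        path = out_dir / f"module{m['id']}_residues.tsv"
        pd.DataFrame(m["residue_table"]).to_csv(path, sep="\t", index=False)
        written.append(path)
        patch_rows = [{"iteration": p["iteration"],
                       "residues": ",".join(map(str, p["residues"])),
                       "absolute": p["absolute_conservation"],
                       "relative": p["relative_conservation"],
                       "p_value": p["p_value"]} for p in m["patches"]]
        path = out_dir / f"module{m['id']}_patches.tsv"
        pd.DataFrame(patch_rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def _runs(indices: list[int]) -> str:
    """Comma-joined runs, e.g. [1,2,3,7,8] -> '1-3,7-8'."""
    if not indices:
        return ""
    runs = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append(f"{start}-{prev}" if prev > start else str(start))
        start = prev = i
    runs.append(f"{start}-{prev}" if prev > start else str(start))
    return ",".join(runs)
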