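"""Autonomous structural modules from the inverse-PAE residue graph.

An AlphaFold model of a multi-domain protein is split into autonomous
structural modules — groups of residues predicted to fold as a unit — by
community detection on a graph whose nodes are confident residues
(pLDDT > 70) and whose edges connect residue pairs with predicted aligned
error below 5 A, weighted by the inverse PAE. Greedy agglomerative
modularity maximisation with a tunable resolution partitions this graph;
communities below 30 residues are discarded as too small to fold stably.

PAE matrices are generally asymmetric; both the edge threshold and the
weight use the arithmetic-mean symmetrised value, floored at 0.2 A before
inversion so near-zero errors cannot produce unbounded weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import EmptyGraphError, FormatError
from .structure_io import PAEMatrix, ProteinStructure

logger = logging.getLogger(__name__)

PLDDT_MIN_DEFAULT = 70.0
PAE_MAX_DEFAULT = 5.0
MIN_MODULE_SIZE_DEFAULT = 30
PAE_FLOOR = 0.2  # A; lower bound applied before inversion
RESOLUTION_DEFAULT = 0.8


@dataclass(frozen=True)
class StructuralModule:
    """A community of residues predicted to fold as one unit."""

    residues: frozenset[int]     # 1-based sequence indices
    mean_pae: float              # mean symmetrised intra-module PAE, A
    mean_plddt: float
    rank: int                    # 1 = largest module

    @property
    def size(self) -> int:
        return len(self.residues)


def build_pae_graph(structure: ProteinStructure, pae: PAEMatrix,
                    plddt_min: float = PLDDT_MIN_DEFAULT,
                    pae_max: float = PAE_MAX_DEFAULT) -> nx.Graph:
    """Build the weighted residue graph used for module detection.

    Nodes are residue sequence indices with pLDDT strictly above
    ``plddt_min``; an edge joins i and j when the symmetrised PAE is
    strictly below ``pae_max``, weighted by 1 / max(PAE, 0.2 A).
    """
    if len(structure.chains) != 1:
        raise FormatError("PAE graphs are defined for single-chain models")
    residues = structure.residues
    if pae.n != len(residues):
        raise FormatError(
            f"PAE dimension {pae.n} != residue count {len(residues)}")
    if structure.plddt is None:
        raise FormatError("module segmentation requires per-residue pLDDT")

    sym = pae.symmetrised()
    graph = nx.Graph()
    kept = [r.index for r in residues if structure.plddt[r.key] > plddt_min]
    graph.add_nodes_from(kept)
    kept_arr = np.array(kept, dtype=int)
    for a_pos, i in enumerate(kept_arr):
        for j in kept_arr[a_pos + 1:]:
            value = sym[i - 1, j - 1]
            if value < pae_max:
                graph.add_edge(int(i), int(j),
                               weight=1.0 / max(value, PAE_FLOOR))
    return graph


def detect_communities(graph: nx.Graph, resolution: float = RESOLUTION_DEFAULT
                       ) -> list[frozenset[int]]:
    """Partition the PAE graph by greedy modularity maximisation.

    The resolution parameter scales the null-model term of modularity:
    zero collapses everything reachable into one community, larger values
    favour smaller communities. Singleton nodes form singleton communities.
    """
    if graph.number_of_nodes() == 0:
        raise EmptyGraphError("cannot detect communities on an empty graph")
    if graph.number_of_edges() == 0:
        return [frozenset([n]) for n in sorted(graph.nodes)]
    comms = nx.community.greedy_modularity_communities(
        graph, weight="weight", resolution=resolution)
    return sorted((frozenset(c) for c in comms),
                  key=lambda c: (-len(c), min(c)))


def filter_modules(partition: list[frozenset[int]],
                   structure: ProteinStructure, pae: PAEMatrix,
                   min_size: int = MIN_MODULE_SIZE_DEFAULT
                   ) -> list[StructuralModule]:
    """Drop communities below ``min_size`` residues and annotate survivors.

    Survivors carry their mean intra-module symmetrised PAE and mean pLDDT
    and are ranked by size, largest first.
    """
    sym = pae.symmetrised()
    by_index = {r.index: r for r in structure.residues}
    modules = []
    for comm in partition:
        if len(comm) < min_size:
            continue
        idx = np.array(sorted(comm), dtype=int) - 1
        block = sym[np.ix_(idx, idx)]
        off_diag = block[~np.eye(len(idx), dtype=bool)]
        mean_pae = float(off_diag.mean()) if off_diag.size else 0.0
        plddts = [structure.plddt[by_index[i].key] for i in sorted(comm)] \
            if structure.plddt else []
        modules.append((comm, mean_pae,
                        float(np.mean(plddts)) if plddts else float("nan")))
    modules.sort(key=lambda m: (-len(m[0]), min(m[0])))
    result = [StructuralModule(residues=c, mean_pae=p, mean_plddt=pl, rank=k + 1)
              for k, (c, p, pl) in enumerate(modules)]
    if not result:
        logger.info("all %d communities below min_size=%d", len(partition), min_size)
    return result


def optimize_resolution(
    cases: list[tuple[ProteinStructure, PAEMatrix, list[range]]],
    plddt_min: float = PLDDT_MIN_DEFAULT,
    pae_max: float = PAE_MAX_DEFAULT,
    step: float = 0.01,
) -> float:
    """Find the largest resolution that never splits a reference domain.

    Each case supplies a structure, its PAE matrix, and reference domains as
    residue-index ranges. Scanning the resolution downward from 1.0 in
    ``step`` decrements, the first value at which no reference domain is
    divided between two communities is returned: the smallest modules
    compatible with the annotation. Returns 0.0 with a warning when even
    that fails.
    """
    if not cases:
        raise ValueError("optimize_resolution needs at least one annotated case")
    graphs = [(build_pae_graph(s, p, plddt_min, pae_max), domains)
              for s, p, domains in cases]
    n_steps = int(round(1.0 / step))
    for k in range(n_steps + 1):
        resolution = round(1.0 - k * step, 10)
        ok = True
        for graph, domains in graphs:
            partition = detect_communities(graph, resolution=resolution)
            membership = {n: ci for ci, comm in enumerate(partition) for n in comm}
            for domain in domains:
                owners = {membership[i] for i in domain if i in membership}
                if len(owners) > 1:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return resolution
    logger.warning("no resolution avoids splitting reference domains; using 0.0")
    return 0.0
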