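"""Extracting, scoring, and iterating conserved accessible surface patches.

Centrality scores are split into a high and a low cluster by the exact
minimum-variance two-cluster partition (optimal one-dimensional clusters
are contiguous in score order, so the split reduces to the threshold
minimising total within-cluster sum of squares — the partition Ward-style
agglomeration targets). The patch is the connected component of the
high cluster, in the undirected view of the TAC graph, that contains the
top-centrality residue.

A patch is scored three ways: absolute conservation (mean patch WCS),
relative conservation (mean patch WCS minus mean WCS of the remaining
surface), and a one-sided Mann-Whitney U p-value for patch conservation
being stochastically greater than non-patch surface conservation.

Multiple patches are found iteratively: after each extraction the patch
residues are removed, edge weights (which depend on in-degree) and
centrality are fully recomputed on the reduced graph, and the next patch
is extracted until an iteration cap, a non-significant patch, or graph
exhaustion stops the loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu, norm, rankdata, tiecorrect

from .errors import DegenerateSplitError, ScoringError
from .tac import build_tac_graph, eigenvector_centrality

logger = logging.getLogger(__name__)

P_CUTOFF_DEFAULT = 1e-10
MAX_PATCHES_DEFAULT = 3
EXACT_MIN_N = 8      # exact Mann-Whitney when min(n, m) <= this ...
EXACT_MAX_N = 25     # ... and both samples at most this large
EXACT_ENUM_LIMIT = 2_000_000  # tie-handling enumeration budget (combinations)


@dataclass(frozen=True)
class ConservedPatch:
    residues: frozenset[int]
    iteration: int                  # 1 = most conserved patch
    seed: int                       # top-centrality residue
    absolute_conservation: float    # mean patch WCS
    relative_conservation: float    # minus mean non-patch surface WCS
    p_value: float
    significant: bool


def split_clusters(scores: dict[int, float]) -> tuple[set[int], set[int]]:
    """Exact minimum-variance split of 1-D scores into high and low clusters.

    Returns ``(high, low)`` where *high* contains the maximum score. All
    scores identical is a degenerate split (no patch is defined).
    """
    if len(scores) < 2:
        raise DegenerateSplitError("need at least two scored residues to split")
    nodes = sorted(scores, key=lambda n: (scores[n], n))
    values = np.array([scores[n] for n in nodes])
    if values.max() - values.min() == 0:
        raise DegenerateSplitError("all centrality scores identical")

    # prefix sums give within-cluster SS of every contiguous split in O(n)
    csum = np.cumsum(values)
    csq = np.cumsum(values ** 2)
    n = len(values)
    best_k, best_ss = None, np.inf
    for k in range(1, n):  # low cluster = first k sorted values
        ss_low = csq[k - 1] - csum[k - 1] ** 2 / k
        hi_sum = csum[-1] - csum[k - 1]
        hi_sq = csq[-1] - csq[k - 1]
        ss_high = hi_sq - hi_sum ** 2 / (n - k)
        ss = ss_low + ss_high
        if ss < best_ss - 1e-12:
            best_ss, best_k = ss, k
    low = set(nodes[:best_k])
    high = set(nodes[best_k:])
    return high, low


def extract_patch(graph: nx.DiGraph, centrality: dict[int, float],
                  high: set[int]) -> frozenset[int]:
    """Connected component of the high cluster containing the top residue.

    Connectivity is taken in the undirected view of the TAC graph; the top
    residue is the maximum-centrality node, ties broken by lowest index.
    """
    if not high:
        raise ValueError("high cluster is empty")
    seed = min(high, key=lambda n: (-centrality[n], n))
    undirected = graph.to_undirected(as_view=True)
    sub = undirected.subgraph(high)
    return frozenset(nx.node_connected_component(sub, seed))


def _exact_p_with_ties(patch: np.ndarray, rest: np.ndarray) -> float:
    """One-sided exact Mann-Whitney by enumerating group assignments.

    Midranks handle ties; the p-value is the fraction of assignments with a
    U statistic at least as large as observed.
    """
    pooled = np.concatenate([patch, rest])
    ranks = rankdata(pooled)
    n = len(patch)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    total = 0
    at_least = 0
    for idx in combinations(range(len(pooled)), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        total += 1
        if u >= u_obs - 1e-9:
            at_least += 1
    return at_least / total


def mann_whitney_greater(patch_values: np.ndarray,
                         rest_values: np.ndarray) -> float:
    """One-sided (greater) Mann-Whitney U p-value, exact for small samples.

    Tiny tie-free samples use the exact null distribution; tiny samples with
    ties use full enumeration over group assignments with midranks; larger
    samples use the normal approximation with tie and continuity
    corrections. Identical constant samples carry no evidence and score 1.
    """
    patch_values = np.asarray(patch_values, dtype=float)
    rest_values = np.asarray(rest_values, dtype=float)
    n, m = len(patch_values), len(rest_values)
    if n == 0 or m == 0:
        raise ScoringError("both patch and non-patch samples must be nonempty")

    pooled = np.concatenate([patch_values, rest_values])
    if pooled.max() - pooled.min() == 0:
        return 1.0

    has_ties = len(np.unique(pooled)) < n + m
    small = min(n, m) <= EXACT_MIN_N and max(n, m) <= EXACT_MAX_N
    if small and not has_ties:
        return float(mannwhitneyu(patch_values, rest_values,
                                  alternative="greater", method="exact").pvalue)
    if small and has_ties and comb(n + m, min(n, m)) <= EXACT_ENUM_LIMIT:
        return _exact_p_with_ties(patch_values, rest_values)

    # normal approximation, tie-corrected variance, continuity correction
    ranks = rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2
    mean_u = n * m / 2
    tie_factor = tiecorrect(ranks)
    if tie_factor == 0:
        return 1.0
    sd = np.sqrt(tie_factor * n * m * (n + m + 1) / 12)
    z = (u - mean_u - 0.5) / sd
    return float(norm.sf(z))


def score_patch(patch: frozenset[int], surface_conservation: dict[int, float]
                ) -> tuple[float, float, float]:
    """(absolute, relative, p_value) for a patch against the rest of the surface."""
    rest = [v for i, v in surface_conservation.items() if i not in patch]
    inside = [surface_conservation[i] for i in patch]
    if not inside:
        raise ScoringError("patch is empty")
    if not rest:
        raise ScoringError("non-patch surface is empty; relative score undefined")
    absolute = float(np.mean(inside))
    relative = absolute - float(np.mean(rest))
    p_value = mann_whitney_greater(np.array(inside), np.array(rest))
    return absolute, relative, p_value


def iterate_patches(accessible: frozenset[int],
                    adjacency: frozenset[frozenset[int]],
                    conservation: dict[int, float],
                    max_patches: int = MAX_PATCHES_DEFAULT,
                    p_cutoff: float = P_CUTOFF_DEFAULT,
                    tol: float = 1e-8,
                    max_iter: int = 1000) -> list[ConservedPatch]:
    """Extract up to ``max_patches`` disjoint conserved patches.

    Each round rebuilds the TAC graph on the residues not yet claimed (edge
    weights depend on in-degree, so a full recompute is required),
    recomputes centrality, splits, extracts, and scores. A patch whose
    p-value exceeds ``p_cutoff`` is still reported, flagged non-significant,
    and ends the iteration.
    """
    remaining = set(accessible)
    patches: list[ConservedPatch] = []
    for iteration in range(1, max_patches + 1):
        adj = frozenset(p for p in adjacency if p <= remaining)
        if len(remaining) < 3 or not adj:
            logger.info("patch iteration stopped: graph exhausted after %d patches",
                        len(patches))
            break
        graph = build_tac_graph(frozenset(remaining), adj, conservation)
        try:
            centrality = eigenvector_centrality(graph, tol=tol, max_iter=max_iter)
            high, _low = split_clusters(centrality)
        except DegenerateSplitError:
            logger.info("patch iteration stopped: degenerate centrality split")
            break
        patch = extract_patch(graph, centrality, high)
        seed = min(patch, key=lambda n: (-centrality[n], n))
        surface_cons = {i: conservation[i] for i in remaining}
        try:
            absolute, relative, p_value = score_patch(patch, surface_cons)
        except ScoringError:
            logger.info("patch iteration stopped: patch swallowed the surface")
            break
        significant = p_value <= p_cutoff
        patches.append(ConservedPatch(
            residues=patch, iteration=iteration, seed=seed,
            absolute_conservation=absolute, relative_conservation=relative,
            p_value=p_value, significant=significant))
        if not significant:
            logger.info("patch %d non-significant (p=%.3g > %.3g); stopping",
                        iteration, p_value, p_cutoff)
            break
        remaining -= patch
    return patches
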