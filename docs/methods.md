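# Methods

`casurf` finds conserved accessible surfaces on protein structures: compact,
connected patches of solvent-exposed residues that are more conserved than
the rest of the surface, the classic signature of a functional interface or
active site. This note describes the model, the parameters that matter, the
numerical choices, and what the synthetic benchmark does and does not show.

## The pipeline

1. **Autonomous structural modules.** A full-length predicted model is cut
   into units that fold independently. Residues with pLDDT > 70 become nodes
   of a graph; an edge joins residues i, j when their predicted aligned
   error (PAE) is below 5 Å, weighted 1/PAE, so tightly co-predicted
   residues attract each other. Greedy agglomerative modularity maximisation
   partitions this graph; the resolution parameter γ scales the null-model
   term of modularity Q = Σ_c [Σ_in/2m − γ(Σ_deg/2m)²], with γ = 0
   collapsing everything into one community and larger γ favouring smaller
   ones. Communities under 30 residues — below the size of a stably folded
   domain — are dropped. Experimental structures have no PAE; there the
   selected chain is analysed as a single module.

2. **Surface geometry.** The heavy atoms of one module are tessellated by
   3-D Delaunay triangulation. Faces belonging to exactly one tetrahedron
   form the boundary; their vertices are the surface atoms. A residue is
   *accessible* when at least one **side-chain** heavy atom is a surface
   atom — backbone exposure does not count, which separates residues that
   present their side chain to solvent from those that bury it in the core.
   Two accessible residues are *adjacent* when a tetrahedron contains a
   surface atom of each. Tessellation is per module, so inter-module
   contact surfaces register as surface, not core.

3. **Conservation.** Each ungapped query position receives a weighted
   conservation score (WCS) in [0, 1]: the weighted fraction of orthologues
   whose residue is identical to the query in that alignment column.
   Weights are proportional to patristic distance from the query leaf of a
   guide tree (agreement in distant orthologues is stronger evidence of
   constraint) and normalised to sum to 1; without a tree, weights are
   uniform. Orthologue gaps count as mismatch; query-gap columns produce no
   score; the query's self-match is excluded.

4. **The TAC graph and centrality.** Accessible residues become nodes of a
   directed graph; each adjacency pair contributes both directed edges, and
   every edge *into* node v carries weight c(v)/indeg(v), so incoming
   weights always sum to the node's conservation c(v). Eigenvector
   centrality — the dominant eigenvector x of the operator
   x(v) ∝ Σ_{u→v} w(u→v) x(u) — then scores each residue by the
   conservation of its whole neighbourhood rather than its own value alone,
   which is what turns scattered conserved residues into coherent patches.

5. **Patch extraction and scoring.** Centrality scores are split into a
   high and a low cluster by the minimum-variance two-cluster partition;
   the patch is the connected component of the high cluster containing the
   top-scoring residue. It is scored by (i) absolute conservation (mean
   patch WCS), (ii) relative conservation (mean patch WCS minus mean WCS of
   the remaining surface), and (iii) a one-sided Mann–Whitney U p-value for
   patch conservation being stochastically greater than non-patch surface
   conservation. Removing the patch and recomputing everything on the
   reduced graph yields second and further patches.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `plddt_min` | 70 | pLDDT | strict lower bound for module-graph nodes |
| `pae_max` | 5 | Å | strict upper bound for module-graph edges |
| PAE floor | 0.2 | Å | floor before inversion, bounds edge weights |
| `resolution` | 0.8 | — | modularity null-model scale; re-derivable via `optimize_resolution` |
| `min_module_size` | 30 | residues | strict: modules with fewer are dropped |
| interface cutoff | 6 | Å | strict heavy-atom distance for benchmark interface residues |
| `max_patches` | 3 | — | iteration cap for multi-patch mode |
| `p_cutoff` | 1e-10 | — | iteration stops after the first patch exceeding it (that patch is still reported, flagged non-significant) |
| `centrality_tol` | 1e-8 | — | L1 change between successive power iterates |

All thresholds are strict inequalities at the boundary (pLDDT exactly 70 is
excluded, PAE exactly 5 Å gives no edge, a 30-residue community survives,
6.000 Å is not an interface contact). Every default is overridable from the
CLI and echoed into the result's provenance block.

## Numerical choices

- **PAE asymmetry.** PAE(i,j) ≠ PAE(j,i) in general; both thresholding and
  weighting use the arithmetic-mean symmetrised value. The 0.2 Å floor
  prevents near-zero errors from producing unbounded weights.
- **Two-cluster split.** For one-dimensional data the optimal
  minimum-variance clusters are contiguous in score order, so the split is
  computed exactly as the threshold minimising total within-cluster sum of
  squares (prefix-sum scan, O(n log n)). This is the partition that
  Ward-style agglomeration targets, computed without the greedy
  approximation; an independently coded exhaustive threshold oracle checks
  it in the tests.
- **Power iteration.** Iteration starts from the uniform vector,
  renormalises to unit L2 norm each step, and stops when the L1 change
  falls below `centrality_tol`. The iteration runs on the diagonally
  shifted operator M + σI with σ = 0.1 × (max column sum): the shift leaves
  every eigenvector unchanged but breaks the period-2 oscillation that
  plain iteration exhibits when the adjacency structure is bipartite. The
  unshifted operator is retried for the rare defective cases (e.g. a hub
  whose neighbours all have conservation exactly 0, where the dominant
  mass is reached through a Jordan chain). Agreement with a dense
  eigendecomposition is asserted to cosine > 1 − 1e-6 in the tests.
- **Mann–Whitney branches.** Tie-free samples with min(n, m) ≤ 8 and both
  sizes ≤ 25 use the exact null distribution; tiny tied samples use full
  enumeration of group assignments with midranks; everything else uses the
  normal approximation with tie-corrected variance and continuity
  correction. Pooled samples with zero spread carry no evidence and score
  p = 1.
- **Determinism.** Nothing in the pipeline draws random numbers; greedy
  merges and top-residue selection break ties by lexicographic node order,
  so repeated runs are byte-identical (the provenance timestamp is the only
  run-dependent output field and can be suppressed).
- **Degenerate inputs.** Fewer than four atoms or coplanar coordinates are
  a geometry error (the module is skipped with a logged reason, other
  modules are still reported); identical centrality scores make the
  high/low split undefined and end patch iteration; glycine has no
  side-chain heavy atom and is therefore never accessible under the strict
  rule — an opt-in flag treats CA as its side-chain proxy.

## The synthetic generator

`casurf.synthetic` builds stylised pseudo-proteins for testing without any
downloads. Surface residues sit on a Fibonacci sphere about 5 Å apart;
side-chain pseudo-atoms point radially outward with every residue's
outermost atom on one common convex shell, and a smaller inner shell
provides buried core residues. The layout is spherical rather than
lattice-based for a structural reason: the boundary of a Delaunay
tessellation is exactly the convex hull, so points jittered inward from a
flat face silently become buried — a strictly convex shell is the only
arrangement that guarantees every intended surface residue is accessible
and the planted patch is adjacency-connected. A conserved patch is planted
as a compact spherical cap (default 12 of 60 residues), and an orthologue
alignment (default 50 sequences) is sampled so patch columns match the
query at 0.9 mean identity and background columns at 0.4, with per-column
truncated Gaussian noise (sd 0.05). The PAE matrix is block-structured
(≈2 Å within modules, ≈15 Å between, diagonal 0.2 Å) and pLDDT ≈ 90
everywhere, so segmentation recovers the designed modules. All randomness
flows through the single seed in `FixtureSpec`.

What passing these tests shows: every algorithmic step agrees with an
independent oracle, and the pipeline as a whole recovers a planted
conserved accessible patch (mean Jaccard ≈ 0.99 over 20 seeds at the
default effect size) with no false positives at p < 1e-10 over 50 null
seeds. What it does not show: performance on real structures, where
surfaces are non-convex (the Delaunay-boundary surface definition is
coarser than a rolling-probe SASA on concave geometry), alignments carry
phylogenetic correlation rather than i.i.d. column noise, and AlphaFold
error patterns are richer than block PAE matrices.

## Known limitations

- The WCS formula is identity-to-query with tree weighting; the match
  function is pluggable (`casurf.conservation.MatchFn`) but no
  substitution-matrix variant ships by default.
- Surface detection by hull boundary cannot see deep pockets on strongly
  concave modules; residues lining a narrow cavity may be classed as core.
- Disconnected TAC graphs are handled by letting the dominant component
  win the centrality mass; minor components only surface in later patch
  iterations after the dominant one is removed.
- Renumbering to reference (e.g. UniProt) coordinates is by explicit
  two-column offset map; no database cross-reference service is consulted.
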