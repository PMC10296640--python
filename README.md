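# casurf

**Conserved accessible surface discovery on protein structures.**

Protein interaction interfaces and active sites are usually visible as
patches of unusually conserved residues on a protein's surface — but on
folded domains, conservation alone mixes functional constraint with the
structural constraint of the hydrophobic core. `casurf` separates the two
by combining a structural model, its solvent-exposed side chains, and an
orthologue alignment into a single graph, and extracting the most conserved
connected surface patch with eigenvector centrality. It is aimed at
structural bioinformaticians who want to rank candidate functional surfaces
on predicted (AlphaFold-style) models or experimental structures.

## Method in brief

Given a predicted model, its predicted-aligned-error (PAE) matrix, and an
orthologue alignment:

1. **Module segmentation** — residues with pLDDT > 70 form a graph with
   edges where PAE < 5 Å, weighted 1/PAE; greedy modularity maximisation
   (resolution γ) partitions it into autonomous structural modules;
   communities under 30 residues are dropped. (For experimental structures
   this step is skipped and one chain is one module.)
2. **Surface geometry** — 3-D Delaunay tessellation of the module's heavy
   atoms; surface atoms are vertices of faces in exactly one tetrahedron; a
   residue is accessible iff a **side-chain** heavy atom is on the surface;
   residues are adjacent when their surface atoms share a tetrahedron.
3. **Conservation** — per-position weighted conservation score
   WCS(p) = Σₛ wₛ · 𝟙[sₚ = qₚ] over orthologues s, with weights wₛ
   proportional to guide-tree (patristic) distance from the query.
4. **TAC graph + centrality** — accessible residues are nodes; every edge
   into node v weighs c(v)/indeg(v), so incoming weights sum to the node's
   conservation; eigenvector centrality x(v) ∝ Σ_{u→v} w(u→v) x(u) scores
   each residue by the conservation of its whole neighbourhood.
5. **Patch extraction** — centrality scores are split into high/low by the
   minimum-variance two-cluster partition; the patch is the connected
   high-cluster component containing the top residue, scored by absolute
   conservation, relative conservation (vs the remaining surface), and a
   one-sided Mann–Whitney U p-value. Iterating after patch removal yields
   multiple ranked patches.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

The package ships a deterministic generator of synthetic proteins with a
planted conserved surface patch, useful both for testing and for a quick
tour:

```sh
casurf make-fixture --seed 7 --n-modules 2 --out-dir demo
casurf alphafold --model demo/model.pdb --pae demo/pae.json \
    --alignment demo/alignment.fasta --tree demo/tree.nwk \
    --out demo/result.json
```

prints

```
ok: 2 module(s), 2 patch(es) -> demo/result.json
```

and `demo/result.json` contains, for the first module:

```json
{
  "id": 1,
  "n_residues": 60,
  "n_accessible": 53,
  "mean_plddt": 89.99,
  "mean_pae": 1.997,
  "patches": [{
    "iteration": 1,
    "residues": [9, 14, 17, 19, 22, 27, 30, 35, 40, 43, 48],
    "seed_residue": 22,
    "absolute_conservation": 0.913324,
    "relative_conservation": 0.51345,
    "p_value": 2.149e-07
  }]
}
```

Reading: segmentation recovered the two designed 60-residue modules
(block-structured PAE, mean intra-module PAE ≈ 2 Å, mean pLDDT ≈ 90); 53 of
60 residues present side chains to the surface; the top patch is a connected
11-residue surface cap with mean conservation 0.91 against a surface
background of 0.40 (relative conservation 0.51), and the one-sided
Mann–Whitney test puts the probability of such a contrast under exchangeable
surface conservation at 2.1 × 10⁻⁷. The residue with the highest centrality
(22) seeded the patch. A per-residue table (accessibility, WCS, centrality,
pLDDT) accompanies each module, and `--tsv-dir` writes the same content as
TSV side-products.

For experimental structures use the PDB mode, which treats one chain as a
single module and accepts an optional author-to-reference renumbering map:

```sh
casurf pdb --structure 1abc.pdb --chain A \
    --alignment orthologues.fasta --tree guide.nwk \
    --offset-map offsets.tsv --out result.json
```

The same functionality is available as a library
(`casurf.run_alphafold_mode`, `casurf.run_pdb_mode`, and the per-stage
functions they compose).

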