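"""Per-residue weighted conservation scores from orthologue alignments.

Each ungapped query position receives a weighted conservation score (WCS)
in [0, 1]: the weighted fraction of orthologues carrying the identical
amino acid to the query in that alignment column. Orthologue weights
default to being proportional to patristic (branch-length) distance from
the query leaf of a guide tree, so agreement in distant orthologues counts
for more than agreement in close ones; without a tree, weights are
uniform. Orthologue gaps count as mismatches, columns where the query is
gapped produce no score, and the query's trivial self-match is excluded.

The match function is identity by default but pluggable, since
similarity-matrix variants of column conservation are common.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import dendropy
import numpy as np
from Bio import AlignIO

from .errors import FormatError, MappingError
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

MatchFn = Callable[[str, str], float]


def identity_match(query_aa: str, other_aa: str) -> float:
    """1.0 for the identical amino acid, else 0.0; gaps never match."""
    if other_aa in GAP_CHARS or query_aa in GAP_CHARS:
        return 0.0
    return 1.0 if other_aa == query_aa else 0.0


@dataclass
class Alignment:
    """Orthologue multiple sequence alignment with a designated query row."""

    sequences: list[tuple[str, str]]   # (identifier, gapped sequence)
    query_id: str

    def __post_init__(self):
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: gapped lengths {sorted(lengths)}")
        if self.query_id not in {i for i, _ in self.sequences}:
            raise KeyError(f"query {self.query_id!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.sequences[0][1])

    @property
    def query_sequence(self) -> str:
        return dict(self.sequences)[self.query_id]

    @property
    def orthologue_ids(self) -> list[str]:
        return [i for i, _ in self.sequences if i != self.query_id]


@dataclass
class ConservationProfile:
    """WCS per ungapped query position (1-based), with column coverage."""

    scores: dict[int, float]
    coverage: dict[int, int]    # non-gap orthologue residues per position

    def __len__(self) -> int:
        return len(self.scores)


def read_alignment(path: str | Path, query_id: str,
                   format: str = "auto") -> Alignment:
    """Read an aligned FASTA or Clustal file containing the query."""
    path = Path(path)
    if format == "auto":
        head = path.read_text().lstrip()[:20].upper()
        format = "clustal" if head.startswith("CLUSTAL") else "fasta"
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise FormatError(f"cannot parse alignment {path}: {exc}") from exc
    seqs = [(rec.id, str(rec.seq).upper()) for rec in msa]
    return Alignment(sequences=seqs, query_id=query_id)


def sequence_weights(tree_path: str | Path | None, alignment: Alignment
                     ) -> dict[str, float]:
    """Per-orthologue weights from guide-tree divergence to the query.

    Weights are proportional to the patristic distance from the query leaf
    and normalised to sum to 1 over orthologues. Falls back to uniform
    weights when no tree is given or the tree has zero total branch length.
    Tree leaves absent from the alignment are ignored with a warning.
    """
    orthologues = alignment.orthologue_ids
    if not orthologues:
        return {}
    uniform = {o: 1.0 / len(orthologues) for o in orthologues}
    if tree_path is None:
        return uniform

    tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
    labels = {taxon.label for taxon in tree.taxon_namespace}
    extra = labels - {i for i, _ in alignment.sequences}
    if extra:
        logger.warning("guide tree has %d leaves not in the alignment", len(extra))
    missing = [o for o in orthologues if o not in labels]
    if missing:
        raise FormatError(f"guide tree lacks alignment sequences: {missing[:5]}")
    if alignment.query_id not in labels:
        raise FormatError(f"guide tree lacks the query leaf {alignment.query_id!r}")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    dists = {o: pdm.patristic_distance(taxa[alignment.query_id], taxa[o])
             for o in orthologues}
    total = sum(dists.values())
    if total <= 0:
        logger.warning("guide tree has zero patristic span; uniform weights used")
        return uniform
    return {o: d / total for o, d in dists.items()}


def compute_wcs(alignment: Alignment, weights: dict[str, float] | None = None,
                match: MatchFn = identity_match) -> ConservationProfile:
    """Weighted conservation score for each ungapped query position.

    ``WCS(p) = sum_s w_s * match(query[p], s[p])`` over orthologues s, with
    gaps scoring 0. ``weights`` defaults to uniform.
    """
    if weights is None:
        weights = sequence_weights(None, alignment)
    missing = set(alignment.orthologue_ids) - weights.keys()
    if missing:
        raise FormatError(f"weights missing for orthologues: {sorted(missing)[:5]}")

    query = alignment.query_sequence
    rows = [(weights[i], s) for i, s in alignment.sequences
            if i != alignment.query_id]
    scores: dict[int, float] = {}
    coverage: dict[int, int] = {}
    pos = 0
    for col, q_aa in enumerate(query):
        if q_aa in GAP_CHARS:
            continue
        pos += 1
        scores[pos] = float(sum(w * match(q_aa, s[col]) for w, s in rows))
        coverage[pos] = sum(1 for _, s in rows if s[col] not in GAP_CHARS)
    return ConservationProfile(scores=scores, coverage=coverage)


def map_profile(profile: ConservationProfile, structure: ProteinStructure,
                chain: str | None = None,
                surface: frozenset[int] | None = None,
                max_unmapped_fraction: float = 0.2) -> dict[int, float]:
    """Attach a WCS value to every residue sequence index of one chain.

    Residues lacking a profile entry receive the median score over mapped
    surface residues (or over all mapped residues when no surface set is
    supplied), with a warning; more than ``max_unmapped_fraction`` of the
    chain unmapped is a mapping error.
    """
    if chain is None:
        if len(structure.chains) != 1:
            raise MappingError("ambiguous chain: structure has several")
        chain = structure.chains[0]
    residues = structure.chain_residues(chain)
    mapped = {r.index: profile.scores[r.index] for r in residues
              if r.index in profile.scores}
    unmapped = [r.index for r in residues if r.index not in profile.scores]
    if len(residues) and len(unmapped) / len(residues) > max_unmapped_fraction:
        raise MappingError(
            f"{len(unmapped)}/{len(residues)} residues have no conservation "
            f"score (> {max_unmapped_fraction:.0%} unmapped)")
    if unmapped:
        pool = [v for i, v in mapped.items()
                if surface is None or i in surface] or list(mapped.values())
        fill = float(np.median(pool))
        logger.warning("imputing median WCS %.3f for %d unmapped residues",
                       fill, len(unmapped))
        for i in unmapped:
            mapped[i] = fill
    return mapped
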