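"""Candidate kinase→phosphosite edge construction.

An edge pairs a kinase measured in the protein layer with a substrate
phosphosite measured in the phosphosite layer; the relation catalogue supplies
the candidate pairs.  Edges are binary candidates — catalogue confidence
scores carry no weight here — and a kinase measured only as a phosphosite
forms no edges, keeping the two layers' roles unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import CohortMatrix, KinaseSubstrateRelation

logger = logging.getLogger(__name__)

EDGE_SEP = "→"


def edge_id(kinase_molecule: str, substrate_molecule: str) -> str:
    return f"{kinase_molecule}{EDGE_SEP}{substrate_molecule}"


@dataclass(frozen=True)
class KinaseSubstrateEdge:
    """One directed kinase→phosphosite candidate edge feature."""

    edge_id: str
    kinase_molecule: str    # protein-layer molecule id (u)
    substrate_molecule: str  # phosphosite-layer molecule id (v)


def build_edges(
    relations: Sequence[KinaseSubstrateRelation],
    protein: CohortMatrix,
    phospho: CohortMatrix,
) -> list[KinaseSubstrateEdge]:
    """Join the relation catalogue against the measured molecules.

    One edge per relation whose kinase gene is measured at the protein level
    AND whose substrate site is measured at the phosphosite level; catalogue
    order is preserved and duplicate edge ids collapse to the first
    occurrence.  An empty result is legal (logged as a warning).
    """
    edges: list[KinaseSubstrateEdge] = []
    seen: set[str] = set()
    for rel in relations:
        sub_mol = rel.substrate_molecule
        if rel.kinase_gene in protein and sub_mol in phospho:
            eid = edge_id(rel.kinase_gene, sub_mol)
            if eid in seen:
                continue
            seen.add(eid)
            edges.append(KinaseSubstrateEdge(eid, rel.kinase_gene, sub_mol))
    if not edges:
        logger.warning(
            "no catalogue relation matched the measured molecules "
            "(%d relations, %d proteins, %d phosphosites)",
            len(relations), len(protein.molecule_ids), len(phospho.molecule_ids),
        )
    return edges


def restrict_edges(
    edges: Sequence[KinaseSubstrateEdge], reference_ids: Iterable[str]
) -> list[KinaseSubstrateEdge]:
    """Keep only edges whose id is in ``reference_ids``, preserving input order.

    This is the "built-in edge catalogue" filter: a deployment that ships a
    fixed reference edge set restricts user cohorts to it.  A projection:
    applying it twice equals applying it once.
    """
    reference = set(reference_ids)
    kept = [e for e in edges if e.edge_id in reference]
    if not kept and edges:
        logger.warning("reference edge list matched none of the %d edges", len(edges))
    return kept


def read_reference_edge_ids(path) -> set[str]:
    """Read a plain-text reference edge list, one edge_id per line."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return {line.strip() for line in lines if line.strip()}
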