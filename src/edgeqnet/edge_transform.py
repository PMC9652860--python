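"""State-stratified z-score-product edge strengths, Pearson utilities, and
differential-correlation (DCP) screening.

The edge transformation turns a (kinase protein, substrate phosphosite) pair
into one feature per sample: each molecule is standardized against the mean
and sample standard deviation (ddof=1) of the sample's own state group
(state 1 = primary tumor, state 2 = metastatic tumor), and the edge strength
is the product of the two z-scores,

    strength[j, (u,v)] = (x_ujk − μ_uk)/σ_uk · (x_vjk − μ_vk)/σ_vk .

A useful identity follows from this choice of estimator: summing the
strengths of one edge over the samples of a state gives (n_k − 1) times the
within-state Pearson correlation of the two molecule columns — the edge
matrix is an additive decomposition of within-state co-expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .edge_network import KinaseSubstrateEdge
from .errors import (
    DegenerateInputError,
    DegenerateMoleculeError,
    DegenerateStateError,
    FormatError,
    MissingMoleculeError,
)
from .io_formats import CohortMatrix, PatientProfile

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# State statistics
# ---------------------------------------------------------------------------


@dataclass
class StateStatistics:
    """Per-(molecule, state) mean and sample SD (ddof=1) for one layer."""

    layer: str
    molecule_ids: list[str]
    states: list[int]
    mean: np.ndarray   # (n_molecules, n_states)
    sd: np.ndarray     # (n_molecules, n_states), ddof=1
    n: dict[int, int]  # samples per state
    constant: set[str] = field(default_factory=set)  # molecules with σ=0 somewhere

    def __post_init__(self) -> None:
        self._mol_index = {m: i for i, m in enumerate(self.molecule_ids)}
        self._state_index = {int(s): i for i, s in enumerate(self.states)}

    def has_state(self, state: int) -> bool:
        return int(state) in self._state_index

    def mu(self, molecule_id: str, state: int) -> float:
        return float(self.mean[self._mol_index[molecule_id], self._state_index[int(state)]])

    def sigma(self, molecule_id: str, state: int) -> float:
        return float(self.sd[self._mol_index[molecule_id], self._state_index[int(state)]])

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in self._mol_index

    def to_dict(self) -> dict:
        return {
            "layer": self.layer,
            "molecule_ids": list(self.molecule_ids),
            "states": [int(s) for s in self.states],
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n": {str(k): int(v) for k, v in self.n.items()},
            "constant": sorted(self.constant),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "StateStatistics":
        return cls(
            layer=doc["layer"],
            molecule_ids=list(doc["molecule_ids"]),
            states=[int(s) for s in doc["states"]],
            mean=np.asarray(doc["mean"], dtype=float),
            sd=np.asarray(doc["sd"], dtype=float),
            n={int(k): int(v) for k, v in doc["n"].items()},
            constant=set(doc.get("constant", [])),
        )


def state_stats(matrix: CohortMatrix) -> StateStatistics:
    """Mean and sample SD (ddof=1) of every molecule within every state group.

    Raises :class:`DegenerateStateError` when any state group has fewer than
    two samples; molecules with zero SD in some state are flagged in
    ``constant`` (and warned about) rather than rejected here — they only
    become an error if an edge actually needs them.
    """
    states = matrix.present_states()
    n_mol = len(matrix.molecule_ids)
    mean = np.empty((n_mol, len(states)))
    sd = np.empty((n_mol, len(states)))
    counts: dict[int, int] = {}
    for si, state in enumerate(states):
        mask = matrix.state_mask(state)
        nk = int(mask.sum())
        if nk < 2:
            raise DegenerateStateError(
                f"state {state} has {nk} sample(s); at least 2 required for σ"
            )
        counts[state] = nk
        block = matrix.values[mask]
        mean[:, si] = block.mean(axis=0)
        sd[:, si] = block.std(axis=0, ddof=1)
    constant_idx = np.where((sd == 0).any(axis=1))[0]
    constant = {matrix.molecule_ids[i] for i in constant_idx}
    if constant:
        logger.warning(
            "%s layer: %d molecule(s) constant within a state (σ=0): %s",
            matrix.layer, len(constant),
            ", ".join(sorted(constant)[:10]) + ("..." if len(constant) > 10 else ""),
        )
    return StateStatistics(
        layer=matrix.layer, molecule_ids=list(matrix.molecule_ids),
        states=states, mean=mean, sd=sd, n=counts, constant=constant,
    )


@dataclass
class ReferenceStats:
    """Frozen per-state standardization constants for both layers.

    Saved alongside a trained model so that new patients are standardized
    against the *training cohort's* statistics, never re-estimated.
    """

    protein: StateStatistics
    phospho: StateStatistics

    def to_dict(self) -> dict:
        return {"protein": self.protein.to_dict(), "phospho": self.phospho.to_dict()}

    @classmethod
    def from_dict(cls, doc: dict) -> "ReferenceStats":
        return cls(
            protein=StateStatistics.from_dict(doc["protein"]),
            phospho=StateStatistics.from_dict(doc["phospho"]),
        )


def reference_stats(protein: CohortMatrix, phospho: CohortMatrix) -> ReferenceStats:
    return ReferenceStats(protein=state_stats(protein), phospho=state_stats(phospho))


# ---------------------------------------------------------------------------
# Edge matrix
# ---------------------------------------------------------------------------


@dataclass
class EdgeMatrix:
    """Samples × edges matrix of edge strengths, with per-sample state labels."""

    sample_ids: list[str]
    edge_ids: list[str]
    strengths: np.ndarray  # (n_samples, n_edges)
    states: np.ndarray

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        n, m = self.strengths.shape
        if n != len(self.sample_ids) or m != len(self.edge_ids):
            raise FormatError("edge matrix shape inconsistent with id lists")
        if not np.all(np.isfinite(self.strengths)):
            raise FormatError("non-finite edge strengths")
        self._edge_index = {e: i for i, e in enumerate(self.edge_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, edge_id: str) -> np.ndarray:
        return self.strengths[:, self._edge_index[edge_id]]

    def subset(self, edge_ids: Sequence[str]) -> "EdgeMatrix":
        missing = [e for e in edge_ids if e not in self._edge_index]
        if missing:
            raise MissingMoleculeError(missing, f"edge matrix lacks edges: {missing}")
        idx = [self._edge_index[e] for e in edge_ids]
        return EdgeMatrix(
            sample_ids=list(self.sample_ids), edge_ids=list(edge_ids),
            strengths=self.strengths[:, idx].copy(), states=self.states.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.strengths, index=self.sample_ids, columns=self.edge_ids)
        df.insert(0, "state", self.states)
        df.index.name = "sample_id"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EdgeMatrix":
        df = pd.read_csv(path, index_col=0)
        if "state" not in df.columns:
            raise FormatError("edge matrix CSV lacks a 'state' column")
        states = df["state"].astype(int).to_numpy()
        values = df.drop(columns=["state"])
        return cls(
            sample_ids=[str(s) for s in df.index],
            edge_ids=[str(c) for c in values.columns],
            strengths=values.to_numpy(dtype=float),
            states=states,
        )


def _z_matrix(
    matrix: CohortMatrix, molecules: Sequence[str], stats: StateStatistics
) -> np.ndarray:
    """Per-sample z-scores for the given molecules, each row standardized by
    its own state's μ, σ from ``stats``."""
    for state in matrix.present_states():
        if not stats.has_state(state):
            raise DegenerateStateError(
                f"reference statistics cover states {stats.states}, "
                f"but the data contain state {state}"
            )
    mol_idx = [stats._mol_index[m] for m in molecules]
    col_idx = [matrix.column_index(m) for m in molecules]
    z = np.empty((matrix.n_samples, len(molecules)))
    for state in matrix.present_states():
        mask = matrix.state_mask(state)
        si = stats._state_index[state]
        mu = stats.mean[mol_idx, si]
        sigma = stats.sd[mol_idx, si]
        zero = np.where(sigma == 0)[0]
        if zero.size:
            raise DegenerateMoleculeError(molecules[int(zero[0])], state)
        z[mask] = (matrix.values[np.ix_(mask, col_idx)] - mu) / sigma
    return z


def edge_strength(
    protein: CohortMatrix,
    phospho: CohortMatrix,
    edges: Sequence[KinaseSubstrateEdge],
    protein_stats: StateStatistics | None = None,
    phospho_stats: StateStatistics | None = None,
) -> EdgeMatrix:
    """Compute the edge-strength matrix (z-score product) for a cohort.

    Statistics default to those of the cohort itself; pass frozen reference
    statistics to transform a cohort against another cohort's baseline.
    """
    if protein.sample_ids != phospho.sample_ids:
        raise FormatError("protein and phosphosite matrices list different samples")
    if not np.array_equal(protein.states, phospho.states):
        raise FormatError("protein and phosphosite matrices disagree on states")
    if protein_stats is None:
        protein_stats = state_stats(protein)
    if phospho_stats is None:
        phospho_stats = state_stats(phospho)
    kinases = [e.kinase_molecule for e in edges]
    substrates = [e.substrate_molecule for e in edges]
    missing = [m for m in set(kinases) if m not in protein_stats] + [
        m for m in set(substrates) if m not in phospho_stats
    ]
    if missing:
        raise MissingMoleculeError(missing)
    # z-score once per distinct molecule, then gather per edge
    uk = list(dict.fromkeys(kinases))
    us = list(dict.fromkeys(substrates))
    zk = _z_matrix(protein, uk, protein_stats)
    zs = _z_matrix(phospho, us, phospho_stats)
    ki = {m: i for i, m in enumerate(uk)}
    si = {m: i for i, m in enumerate(us)}
    strengths = zk[:, [ki[m] for m in kinases]] * zs[:, [si[m] for m in substrates]]
    return EdgeMatrix(
        sample_ids=list(protein.sample_ids),
        edge_ids=[e.edge_id for e in edges],
        strengths=strengths,
        states=protein.states.copy(),
    )


def transform_new_sample(
    patient: PatientProfile,
    ref_stats: ReferenceStats,
    edges: Sequence[KinaseSubstrateEdge],
) -> np.ndarray:
    """Edge-strength vector for one new patient against frozen reference stats.

    The reference cohort's μ, σ for the patient's declared state are used as
    given — they are not re-estimated with the new sample — so the result is
    deterministic per patient and independent of upload order.
    """
    state = patient.state
    if not (ref_stats.protein.has_state(state) and ref_stats.phospho.has_state(state)):
        raise DegenerateStateError(
            f"reference statistics do not cover state {state}"
        )
    missing = [
        e.kinase_molecule for e in edges if e.kinase_molecule not in patient.protein
    ] + [
        e.substrate_molecule for e in edges if e.substrate_molecule not in patient.phosphosite
    ]
    if missing:
        raise MissingMoleculeError(set(missing))
    out = np.empty(len(edges))
    for i, e in enumerate(edges):
        mu_u = ref_stats.protein.mu(e.kinase_molecule, state)
        sd_u = ref_stats.protein.sigma(e.kinase_molecule, state)
        mu_v = ref_stats.phospho.mu(e.substrate_molecule, state)
        sd_v = ref_stats.phospho.sigma(e.substrate_molecule, state)
        if sd_u == 0:
            raise DegenerateMoleculeError(e.kinase_molecule, state)
        if sd_v == 0:
            raise DegenerateMoleculeError(e.substrate_molecule, state)
        zu = (patient.protein[e.kinase_molecule] - mu_u) / sd_u
        zv = (patient.phosphosite[e.substrate_molecule] - mu_v) / sd_v
        out[i] = zu * zv
    return out


def pooled_reference_stats(
    protein: CohortMatrix, phospho: CohortMatrix, patient: PatientProfile
) -> ReferenceStats:
    """Reference statistics re-estimated with the new sample pooled into its
    state group (the alternative reading of transforming "the cohort and the
    sample to be diagnosed" together)."""
    def _augment(matrix: CohortMatrix, layer: dict[str, float]) -> CohortMatrix:
        missing = [m for m in matrix.molecule_ids if m not in layer]
        if missing:
            raise MissingMoleculeError(missing)
        row = np.array([[layer[m] for m in matrix.molecule_ids]])
        return CohortMatrix(
            sample_ids=list(matrix.sample_ids) + [patient.sample_id],
            molecule_ids=list(matrix.molecule_ids),
            values=np.vstack([matrix.values, row]),
            states=np.append(matrix.states, patient.state),
            layer=matrix.layer,
        )

    return ReferenceStats(
        protein=state_stats(_augment(protein, patient.protein)),
        phospho=state_stats(_augment(phospho, patient.phosphosite)),
    )


# ---------------------------------------------------------------------------
# Pearson correlation and DCP screening
# ---------------------------------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p-value of the exact t-based null
    (t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("pearson requires two equal-length 1-D vectors")
    if x.size < 3:
        raise DegenerateInputError(f"pearson requires n ≥ 3, got n={x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("pearson undefined for a zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p-value for H0: ρ1 = ρ2 via Fisher's z-transformation."""
    if n1 < 4 or n2 < 4:
        raise DegenerateStateError(
            f"Fisher z needs ≥ 4 samples per state (got {n1}, {n2})"
        )
    # guard |r|=1: atanh diverges; clip just inside the open interval
    eps = 1e-15
    z1 = math.atanh(max(-1 + eps, min(1 - eps, r1)))
    z2 = math.atanh(max(-1 + eps, min(1 - eps, r2)))
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return float(2.0 * sps.norm.sf(abs(z)))


@dataclass
class DcpResult:
    """Differential-correlation screen over candidate (protein, phosphosite)
    pairs; ``table`` reports every candidate, selected or not."""

    table: pd.DataFrame  # molecule_a, molecule_b, r_state1, r_state2, delta, fisher_z_p, selected
    min_abs_delta: float
    alpha_level: float

    @property
    def selected_pairs(self) -> list[tuple[str, str]]:
        sel = self.table[self.table["selected"]]
        return list(zip(sel["molecule_a"], sel["molecule_b"]))


def dcp_screen(
    protein: CohortMatrix,
    phospho: CohortMatrix,
    pairs: Iterable[tuple[str, str] | KinaseSubstrateEdge],
    min_abs_delta: float = 0.5,
    alpha_level: float = 0.05,
) -> DcpResult:
    """Screen candidate pairs for differential within-state correlation.

    A pair is selected iff |r_state1 − r_state2| ≥ ``min_abs_delta`` and the
    Fisher-z two-sided p-value for the difference is ≤ ``alpha_level``.
    Degenerate (constant) columns are skipped with a warning and reported as
    unselected with NaN statistics.
    """
    states = protein.present_states()
    if states != [1, 2]:
        raise DegenerateStateError(
            f"DCP screening needs both states 1 and 2; present: {states}"
        )
    masks = {k: protein.state_mask(k) for k in (1, 2)}
    ns = {k: int(m.sum()) for k, m in masks.items()}
    for k, nk in ns.items():
        if nk < 4:
            raise DegenerateStateError(f"state {k} has {nk} samples; DCP needs ≥ 4")

    records = []
    for pair in pairs:
        if isinstance(pair, KinaseSubstrateEdge):
            mol_a, mol_b = pair.kinase_molecule, pair.substrate_molecule
        else:
            mol_a, mol_b = pair
        xa, xb = protein.column(mol_a), phospho.column(mol_b)
        rs: dict[int, float] = {}
        degenerate = False
        for k in (1, 2):
            a, b = xa[masks[k]], xb[masks[k]]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                degenerate = True
                break
            rs[k], _ = pearson(a, b)
        if degenerate:
            logger.warning("pair (%s, %s): constant column within a state; skipped", mol_a, mol_b)
            records.append((mol_a, mol_b, np.nan, np.nan, np.nan, np.nan, False))
            continue
        delta = rs[1] - rs[2]
        p = fisher_z_test(rs[1], ns[1], rs[2], ns[2])
        selected = abs(delta) >= min_abs_delta and p <= alpha_level
        records.append((mol_a, mol_b, rs[1], rs[2], delta, p, selected))
    table = pd.DataFrame(
        records,
        columns=["molecule_a", "molecule_b", "r_state1", "r_state2", "delta", "fisher_z_p", "selected"],
    )
    return DcpResult(table=table, min_abs_delta=min_abs_delta, alpha_level=alpha_level)
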