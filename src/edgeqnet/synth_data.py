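"""Synthetic cohorts with known kinase–substrate structure and planted
response signal.

The generator emulates the study setting the pipeline targets: a small
two-state tumor cohort (default 31 samples, 16 primary / 15 metastatic)
profiled on a protein layer and a phosphosite layer, a relation catalogue of
candidate kinase→site edges, and one drug response (TCGI, percent) per
sample.

Generative model
----------------
* Each kinase's within-state profile is a latent standard normal; the
  observed protein value is a per-(molecule, state) affine transform of the
  latent plus measurement noise.
* An *informative* substrate site tracks its kinase: latent
  ``ρ·z_kinase + sqrt(1−ρ²)·ε`` with ``ρ = edge_correlation``, so its true
  within-state correlation with the kinase is ρ.  Decoy sites are
  independent noise.
* TCGI is linear in the cohort's *actual* edge strengths (the z-score
  products the transform computes) for the informative edges, plus Gaussian
  response noise: the planted signal lives exactly in the model class the
  pipeline fits, so recovery failures indicate pipeline defects, not model
  mismatch.

``SynthTruth`` records the informative edge ids, their coefficients, and the
noise-free TCGI per sample, so selection and prediction can be scored
against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import edge_network, edge_transform
from .errors import ConfigError
from .io_formats import (
    CohortMatrix,
    DrugResponseTable,
    KinaseSubstrateRelation,
    site_id,
    write_ks_table,
    write_patient_csv,
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target setting: 31 samples split 16 primary / 15
    metastatic, a 53-relation catalogue with 3 informative edges of
    coefficients (3, −2, 1.5) among 50 decoys, within-state kinase–site
    correlation 0.7 for informative pairs, small measurement noise (SD 0.05
    on roughly unit-scale profiles), response noise SD 0.1 (percent TCGI),
    and a TCGI intercept of 50%.
    """

    n_samples: int = 31
    n_state1: int | None = None  # default: ceil(n/2) primary
    n_kinases: int = 20
    n_substrates: int = 53
    n_relations: int = 53
    n_informative_edges: int = 3
    true_coefficients: tuple[float, ...] = (3.0, -2.0, 1.5)
    edge_correlation: float = 0.7
    noise_sd_expression: float = 0.05
    noise_sd_response: float = 0.1
    tcgi_intercept: float = 50.0
    drug: str = "drugA"
    seed: int = 0

    def __post_init__(self) -> None:
        n1 = self.state1_count
        n2 = self.n_samples - n1
        if n1 < 4 or n2 < 4:
            raise ConfigError(
                f"each state needs ≥ 4 samples (got {n1} primary, {n2} metastatic)"
            )
        if self.n_informative_edges > self.n_relations:
            raise ConfigError("n_informative_edges must be ≤ n_relations")
        if len(self.true_coefficients) != self.n_informative_edges:
            raise ConfigError(
                "true_coefficients length must equal n_informative_edges"
            )
        if not (0.0 < self.edge_correlation < 1.0):
            raise ConfigError("edge_correlation must lie in (0, 1)")
        if self.n_substrates < self.n_relations:
            raise ConfigError("need n_substrates ≥ n_relations (one site per relation)")
        if self.n_informative_edges > self.n_kinases:
            raise ConfigError("informative edges need distinct kinases")
        if self.noise_sd_expression < 0 or self.noise_sd_response < 0:
            raise ConfigError("noise SDs must be ≥ 0")

    @property
    def state1_count(self) -> int:
        return self.n_state1 if self.n_state1 is not None else (self.n_samples + 1) // 2


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort."""

    informative_edge_ids: list[str]
    true_coefficients: list[float]
    true_tcgi: dict[str, float]  # sample_id → noise-free TCGI
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SynthTruth":
        return cls(**doc)


def generate_cohort(
    config: SynthConfig | None = None,
) -> tuple[CohortMatrix, CohortMatrix, list[KinaseSubstrateRelation], DrugResponseTable, SynthTruth]:
    """Generate one cohort; identical config (incl. seed) → identical output."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_samples
    n1 = cfg.state1_count
    states = np.array([1] * n1 + [2] * (n - n1), dtype=int)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    kinases = [f"KIN{i + 1:03d}" for i in range(cfg.n_kinases)]
    sub_genes = [f"SUB{i + 1:03d}" for i in range(cfg.n_substrates)]
    residues = rng.choice(np.array(["S", "T", "Y"]), size=cfg.n_substrates)
    positions = rng.integers(1, 1000, size=cfg.n_substrates)
    sites = [f"{r}{p}" for r, p in zip(residues, positions)]

    # one relation per substrate site; informative relations get distinct kinases
    rel_kinase_idx = rng.integers(0, cfg.n_kinases, size=cfg.n_relations)
    informative_rel = rng.choice(cfg.n_relations, size=cfg.n_informative_edges, replace=False)
    distinct_kin = rng.choice(cfg.n_kinases, size=cfg.n_informative_edges, replace=False)
    rel_kinase_idx[informative_rel] = distinct_kin
    informative_set = set(int(i) for i in informative_rel)

    relations = [
        KinaseSubstrateRelation(
            kinase_gene=kinases[int(rel_kinase_idx[ri])],
            substrate_gene=sub_genes[ri],
            substrate_site=sites[ri],
            source="synthetic",
        )
        for ri in range(cfg.n_relations)
    ]

    # latent within-state standard-normal kinase profiles
    z_kin = rng.standard_normal((n, cfg.n_kinases))
    z_sub = np.empty((n, cfg.n_relations))
    rho = cfg.edge_correlation
    for ri in range(cfg.n_relations):
        if ri in informative_set:
            eps = rng.standard_normal(n)
            z_sub[:, ri] = rho * z_kin[:, int(rel_kinase_idx[ri])] + np.sqrt(1 - rho * rho) * eps
        else:
            z_sub[:, ri] = rng.standard_normal(n)

    def observe(z: np.ndarray, n_mol: int) -> np.ndarray:
        """Per-(molecule, state) affine transform + measurement noise."""
        out = np.empty_like(z)
        for si, state in enumerate((1, 2)):
            mask = states == state
            baseline = rng.normal(10.0, 2.0, size=n_mol)
            scale = rng.uniform(0.8, 1.2, size=n_mol)
            out[mask] = baseline + scale * z[mask]
        return out + rng.normal(0.0, cfg.noise_sd_expression, size=z.shape)

    protein_vals = observe(z_kin, cfg.n_kinases)
    phospho_vals = observe(z_sub, cfg.n_relations)

    # protein layer also carries the substrate genes (independent profiles),
    # so the edge join must pick the kinase from the protein layer
    sub_protein = observe(rng.standard_normal((n, cfg.n_substrates)), cfg.n_substrates)

    protein = CohortMatrix(
        sample_ids=list(sample_ids),
        molecule_ids=kinases + sub_genes,
        values=np.hstack([protein_vals, sub_protein]),
        states=states.copy(),
        layer="protein",
    )
    phospho = CohortMatrix(
        sample_ids=list(sample_ids),
        molecule_ids=[site_id(sub_genes[ri], sites[ri]) for ri in range(cfg.n_relations)],
        values=phospho_vals,
        states=states.copy(),
        layer="phosphosite",
    )

    # TCGI is linear in the informative edges' actual (computed) strengths
    edges = edge_network.build_edges(relations, protein, phospho)
    strengths = edge_transform.edge_strength(protein, phospho, edges)
    informative_edge_ids = [
        edge_network.edge_id(relations[ri].kinase_gene, relations[ri].substrate_molecule)
        for ri in sorted(informative_set)
    ]
    coefs = {
        eid: float(c)
        for eid, c in zip(informative_edge_ids, _coeffs_in_order(cfg, informative_set))
    }
    signal = np.zeros(n)
    for eid, c in coefs.items():
        signal += c * strengths.column(eid)
    true_tcgi = cfg.tcgi_intercept + signal
    observed_tcgi = true_tcgi + rng.normal(0.0, cfg.noise_sd_response, size=n)

    responses = DrugResponseTable(
        pd.DataFrame({cfg.drug: observed_tcgi}, index=pd.Index(sample_ids, name="sample_id"))
    )
    truth = SynthTruth(
        informative_edge_ids=informative_edge_ids,
        true_coefficients=[coefs[eid] for eid in informative_edge_ids],
        true_tcgi={sid: float(v) for sid, v in zip(sample_ids, true_tcgi)},
        config=asdict(cfg),
    )
    return protein, phospho, relations, responses, truth


def _coeffs_in_order(cfg: SynthConfig, informative_set: set[int]) -> list[float]:
    # coefficients follow the sorted relation order of the informative edges
    return [float(c) for c in cfg.true_coefficients]


@dataclass
class RecoveryScore:
    sensitivity: float
    specificity: float
    sign_agreement: float  # over recovered informative edges; NaN if none


def score_recovery(selection, truth: SynthTruth) -> RecoveryScore:
    """Score a SelectionResult against the planted ground truth.

    Sensitivity = recovered fraction of informative edges; specificity =
    rejected fraction of decoys; sign agreement = fraction of recovered
    informative edges whose selection coefficient has the planted sign.
    """
    universe = set(selection.candidate_edge_ids)
    informative = set(truth.informative_edge_ids)
    if not informative <= universe:
        raise ConfigError(
            "selection and truth refer to different edge universes: "
            f"{sorted(informative - universe)} not among candidates"
        )
    selected = set(selection.selected_edge_ids)
    decoys = universe - informative
    sensitivity = len(selected & informative) / len(informative) if informative else 1.0
    specificity = 1.0 - (len(selected & decoys) / len(decoys) if decoys else 0.0)
    true_sign = dict(zip(truth.informative_edge_ids, truth.true_coefficients))
    est = dict(zip(selection.selected_edge_ids, selection.coefficients))
    recovered = sorted(selected & informative)
    if recovered:
        agree = sum(
            1 for e in recovered if np.sign(est[e]) == np.sign(true_sign[e])
        )
        sign_agreement = agree / len(recovered)
    else:
        sign_agreement = float("nan")
    return RecoveryScore(sensitivity, specificity, sign_agreement)


# ---------------------------------------------------------------------------
# Fixture tree writer (per-sample CSVs + manifest + catalogue + truth)
# ---------------------------------------------------------------------------


def write_fixture_tree(
    out_dir,
    protein: CohortMatrix,
    phospho: CohortMatrix,
    relations: Sequence[KinaseSubstrateRelation],
    responses: DrugResponseTable,
    truth: SynthTruth | None = None,
) -> Path:
    """Write a cohort as the on-disk layout the readers consume; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, sid in enumerate(protein.sample_ids):
        p_name, s_name = f"{sid}_protein.csv", f"{sid}_phospho.csv"
        write_patient_csv(
            dict(zip(protein.molecule_ids, protein.values[j])), out_dir / p_name
        )
        write_patient_csv(
            dict(zip(phospho.molecule_ids, phospho.values[j])), out_dir / s_name
        )
        row = {
            "sample_id": sid,
            "state": int(protein.states[j]),
            "protein_file": p_name,
            "phospho_file": s_name,
        }
        for drug in responses.drugs:
            row[drug] = float(responses.table.loc[sid, drug])
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    write_ks_table(relations, out_dir / "ks_table.tsv")
    if truth is not None:
        with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
            fh.write("\n")
    return manifest
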