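"""Readers, writers and validators for every external table the pipeline touches.

External contracts
------------------
* Patient input: two 2-column CSV files (molecule id, normalized expression),
  one for the protein layer and one for the phosphosite layer.  A header row is
  optional and auto-detected: the first row is treated as a header when its
  second field is non-empty and non-numeric.  Ids must be unique within a
  layer; values must parse as finite reals.
* Kinase–substrate catalogue: TSV with header columns ``KINASE``, ``SUB_GENE``,
  ``SUB_MOD_RSD`` (the public Kinase_Substrate_Dataset column names); extra
  columns are ignored.
* Cohort manifest: CSV with columns ``sample_id``, ``state``, ``protein_file``,
  ``phospho_file``, then one column per drug holding the observed tumor cell
  growth inhibition (TCGI, percent).  File paths are resolved relative to the
  manifest's directory.
* Model file: versioned JSON document (human-inspectable, language-neutral).

Phosphosite ids use the ``GENE_RESIDUEPOS`` convention (e.g. ``GSK3B_S9``),
which makes the join against the relation catalogue deterministic.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateMoleculeError,
    FormatError,
    MissingSampleError,
    ModelIOError,
)

logger = logging.getLogger(__name__)

VALID_STATES = (1, 2)  # 1 = primary tumor, 2 = metastatic tumor
MODEL_SCHEMA_VERSION = 1

KS_REQUIRED_COLUMNS = ("KINASE", "SUB_GENE", "SUB_MOD_RSD")


def site_id(gene: str, residue_pos: str) -> str:
    """Phosphosite molecule id: ``GENE_RESIDUEPOS`` (e.g. ``GSK3B_S9``)."""
    return f"{gene}_{residue_pos}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PatientProfile:
    """One patient's two-layer expression profile plus tumor-state label."""

    sample_id: str
    state: int
    protein: dict[str, float]
    phosphosite: dict[str, float]

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise FormatError(
                f"state must be one of {VALID_STATES} "
                f"(1 primary, 2 metastatic); got {self.state!r}"
            )
        for layer_name, layer in (("protein", self.protein), ("phosphosite", self.phosphosite)):
            for mol, value in layer.items():
                if not math.isfinite(value):
                    raise FormatError(
                        f"non-finite value for {mol!r} in {layer_name} layer"
                    )

    def layer(self, name: str) -> dict[str, float]:
        if name == "protein":
            return self.protein
        if name == "phosphosite":
            return self.phosphosite
        raise KeyError(name)


@dataclass
class CohortMatrix:
    """Samples × molecules expression values for one layer, with state labels.

    ``values[j, i]`` is the expression of molecule ``molecule_ids[i]`` in
    sample ``sample_ids[j]``, whose state is ``states[j]``.
    """

    sample_ids: list[str]
    molecule_ids: list[str]
    values: np.ndarray
    states: np.ndarray
    layer: str  # "protein" | "phosphosite"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.molecule_ids):
            raise FormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples × {len(self.molecule_ids)} molecules"
            )
        if len(set(self.molecule_ids)) != m:
            raise FormatError("molecule_ids are not unique")
        if self.states.shape != (n,):
            raise FormatError("states must be one label per sample")
        bad = set(self.states) - set(VALID_STATES)
        if bad:
            raise FormatError(f"invalid state codes {sorted(bad)}; allowed: {VALID_STATES}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite values in {self.layer} matrix")
        if self.layer not in ("protein", "phosphosite"):
            raise FormatError(f"unknown layer {self.layer!r}")
        self._col_index = {m_: i for i, m_ in enumerate(self.molecule_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, molecule_id: str) -> np.ndarray:
        return self.values[:, self._col_index[molecule_id]]

    def column_index(self, molecule_id: str) -> int:
        return self._col_index[molecule_id]

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in self._col_index

    def state_mask(self, state: int) -> np.ndarray:
        return self.states == state

    def present_states(self) -> list[int]:
        return sorted(set(int(s) for s in self.states))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.molecule_ids)
        df.insert(0, "state", self.states)
        df.index.name = "sample_id"
        return df


@dataclass(frozen=True)
class KinaseSubstrateRelation:
    """Catalogued assertion: *kinase_gene* phosphorylates *substrate_site* of
    *substrate_gene* (e.g. a PhosphoSitePlus / NetworKIN row)."""

    kinase_gene: str
    substrate_gene: str
    substrate_site: str  # residue + position, e.g. "S473"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.kinase_gene:
            raise FormatError("kinase_gene must be non-empty")
        if not self.substrate_site:
            raise FormatError("substrate_site must be non-empty")

    @property
    def substrate_molecule(self) -> str:
        return site_id(self.substrate_gene, self.substrate_site)

    def key(self) -> tuple[str, str, str]:
        return (self.kinase_gene, self.substrate_gene, self.substrate_site)


@dataclass
class DrugResponseTable:
    """Observed TCGI (percent growth inhibition) per sample per drug."""

    table: pd.DataFrame  # index sample_id, one float column per drug

    def __post_init__(self) -> None:
        if any(not str(c) for c in self.table.columns):
            raise FormatError("drug names must be non-empty")
        self.table = self.table.astype(float)

    @property
    def drugs(self) -> list[str]:
        return [str(c) for c in self.table.columns]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def tcgi(self, drug: str, sample_ids: Sequence[str]) -> np.ndarray:
        if drug not in self.table.columns:
            raise KeyError(f"unknown drug {drug!r}; available: {self.drugs}")
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise MissingSampleError(f"no response recorded for samples {missing}")
        return self.table.loc[list(sample_ids), drug].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Two-column expression CSV
# ---------------------------------------------------------------------------


def _is_numeric(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def _read_two_column_csv(path: Path, layer: str) -> dict[str, float]:
    """Parse one 2-column expression CSV into an ordered id → value mapping.

    Header auto-detection: the first row is a header iff its second field is
    non-empty and non-numeric.  Any other malformed row raises
    :class:`FormatError` with its 1-based data row number; duplicate ids raise
    :class:`DuplicateMoleculeError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{layer} file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row and any(f.strip() for f in row)]
    if not rows:
        raise FormatError(f"empty {layer} file: {path}")

    first = rows[0]
    has_header = len(first) >= 2 and first[1].strip() != "" and not _is_numeric(first[1].strip())
    data_rows = rows[1:] if has_header else rows

    out: dict[str, float] = {}
    for rownum, row in enumerate(data_rows, start=1):
        if len(row) != 2:
            raise FormatError(
                f"{path}: row {rownum}: expected 2 columns, got {len(row)}"
            )
        mol, raw = row[0].strip(), row[1].strip()
        if not mol:
            raise FormatError(f"{path}: row {rownum}: empty molecule id")
        if raw == "" or not _is_numeric(raw):
            raise FormatError(
                f"{path}: row {rownum}: missing or non-numeric value {raw!r} for {mol!r}"
            )
        value = float(raw)
        if not math.isfinite(value):
            raise FormatError(f"{path}: row {rownum}: non-finite value for {mol!r}")
        if mol in out:
            raise DuplicateMoleculeError(mol, f"{path}: duplicate molecule id {mol!r}")
        out[mol] = value
    if not out:
        raise FormatError(f"{path}: no data rows")
    return out


def read_patient_csv(path_protein, path_phospho, state: int, sample_id: str = "patient") -> PatientProfile:
    """Read one patient's protein + phosphosite CSV pair into a validated profile."""
    protein = _read_two_column_csv(Path(path_protein), "protein")
    phospho = _read_two_column_csv(Path(path_phospho), "phosphosite")
    return PatientProfile(sample_id=sample_id, state=int(state), protein=protein, phosphosite=phospho)


def write_patient_csv(profile_layer: Mapping[str, float], path, header: bool = True) -> None:
    """Write one expression layer as a 2-column CSV (id, value)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow(["molecule", "expression"])
        for mol, value in profile_layer.items():
            writer.writerow([mol, repr(float(value))])


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_FIXED_COLUMNS = ("sample_id", "state", "protein_file", "phospho_file")


def read_cohort(manifest_path) -> tuple[CohortMatrix, CohortMatrix, DrugResponseTable]:
    """Load a full cohort from a manifest CSV.

    Returns protein and phosphosite :class:`CohortMatrix` objects aligned to
    the manifest's sample order, restricted per layer to the molecules present
    in *all* samples (the input contract forbids missing values, so alignment
    is by intersection, never imputation); molecules dropped in the process
    are reported through the module logger.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingSampleError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, dtype=str)
    missing_cols = [c for c in MANIFEST_FIXED_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise FormatError(f"manifest lacks required column(s) {missing_cols}")
    if len(manifest) == 0:
        raise MissingSampleError(f"manifest {manifest_path} lists no samples")
    drug_columns = [c for c in manifest.columns if c not in MANIFEST_FIXED_COLUMNS]

    base = manifest_path.parent
    profiles: list[PatientProfile] = []
    for _, row in manifest.iterrows():
        sample_id = str(row["sample_id"])
        try:
            state = int(row["state"])
        except (TypeError, ValueError):
            raise FormatError(f"sample {sample_id!r}: state {row['state']!r} is not an integer")
        if state not in VALID_STATES:
            raise FormatError(
                f"sample {sample_id!r}: state must be 1 (primary) or 2 (metastatic), got {state}"
            )
        p_path, s_path = base / str(row["protein_file"]), base / str(row["phospho_file"])
        for pth in (p_path, s_path):
            if not pth.exists():
                raise MissingSampleError(f"sample {sample_id!r}: file missing: {pth}")
        profiles.append(read_patient_csv(p_path, s_path, state, sample_id=sample_id))

    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample_id in manifest")
    states = np.array([p.state for p in profiles], dtype=int)

    matrices = {}
    for layer in ("protein", "phosphosite"):
        layers = [p.layer(layer) for p in profiles]
        common = set(layers[0])
        union = set(layers[0])
        for lay in layers[1:]:
            common &= set(lay)
            union |= set(lay)
        dropped = sorted(union - common)
        if dropped:
            logger.warning(
                "%s layer: dropped %d molecule(s) absent from at least one sample: %s",
                layer, len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        if not common:
            raise FormatError(f"no {layer} molecule is shared by all samples")
        ordered = [m for m in layers[0] if m in common]
        values = np.array([[lay[m] for m in ordered] for lay in layers], dtype=float)
        matrices[layer] = CohortMatrix(
            sample_ids=list(sample_ids), molecule_ids=ordered,
            values=values, states=states.copy(), layer=layer,
        )

    resp = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for drug in drug_columns:
        try:
            resp[drug] = manifest[drug].astype(float).to_numpy()
        except ValueError:
            raise FormatError(f"non-numeric TCGI value in drug column {drug!r}")
    return matrices["protein"], matrices["phosphosite"], DrugResponseTable(resp)


# ---------------------------------------------------------------------------
# Kinase–substrate relation table
# ---------------------------------------------------------------------------


def read_ks_table(path) -> list[KinaseSubstrateRelation]:
    """Read a kinase–substrate relation TSV, deduplicated in first-seen order."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"relation table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in KS_REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"relation table lacks required column {col!r}")
    seen: set[tuple[str, str, str]] = set()
    relations: list[KinaseSubstrateRelation] = []
    for _, row in table.iterrows():
        rel = KinaseSubstrateRelation(
            kinase_gene=str(row["KINASE"]).strip(),
            substrate_gene=str(row["SUB_GENE"]).strip(),
            substrate_site=str(row["SUB_MOD_RSD"]).strip(),
            source=str(row["SOURCE"]).strip() if "SOURCE" in table.columns else "",
        )
        if rel.key() in seen:
            continue
        seen.add(rel.key())
        relations.append(rel)
    return relations


def write_ks_table(relations: Iterable[KinaseSubstrateRelation], path) -> None:
    rows = [
        {"KINASE": r.kinase_gene, "SUB_GENE": r.substrate_gene,
         "SUB_MOD_RSD": r.substrate_site, "SOURCE": r.source}
        for r in relations
    ]
    pd.DataFrame(rows, columns=["KINASE", "SUB_GENE", "SUB_MOD_RSD", "SOURCE"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Model persistence (versioned JSON)
# ---------------------------------------------------------------------------


def save_model(model, path) -> None:
    """Persist a fitted DrugModel as a versioned JSON document."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "drug": model.drug,
        "alpha": model.alpha,
        "lambda": model.lam,
        "intercept": model.intercept,
        "features": list(model.features),
        "coefficients": [float(c) for c in model.coefficients],
        "training_meta": model.training_meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_model(path):
    from .drug_model import DrugModel  # deferred: avoids a module cycle

    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file not found: {path}")
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"corrupted model file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelIOError(f"corrupted model file {path}: not a JSON object")
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelIOError(
            f"unsupported model schema version {version!r} "
            f"(this build reads version {MODEL_SCHEMA_VERSION})"
        )
    try:
        model = DrugModel(
            drug=doc["drug"],
            alpha=float(doc["alpha"]),
            lam=float(doc["lambda"]),
            intercept=float(doc["intercept"]),
            features=list(doc["features"]),
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            training_meta=doc["training_meta"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"corrupted model file {path}: {exc}") from exc
    return model
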