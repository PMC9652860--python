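"""Final per-drug penalized regression: fit, predict, evaluate.

The per-drug model is an elastic net over the selected edge-strength
features, refit on the full cohort at the (α, λ) the selection loop chose.
Features are standardized for fitting; the model stores the standardization
constants so prediction is self-contained, and coefficients are reported on
the original edge-strength scale.

Evaluation follows the predicted-vs-observed protocol: Pearson r and its
two-sided p-value between predicted and observed TCGI, with "R-squared"
reported as the squared Pearson correlation (the coefficient of
determination is also computed, since the two differ for biased
predictions).  Predictions are not clipped to [0, 100] by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._enet import fit_enet, kkt_residual
from .edge_transform import EdgeMatrix, pearson
from .errors import ConfigError, DegenerateInputError, MissingMoleculeError
from .feature_selection import SelectionResult
from .io_formats import DrugResponseTable


@dataclass
class DrugModel:
    """Fitted penalized linear model predicting TCGI for one drug."""

    drug: str
    alpha: float
    lam: float
    intercept: float
    features: list[str]
    coefficients: np.ndarray  # original edge-strength scale, aligned to features
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != len(self.coefficients):
            raise ConfigError("features and coefficients differ in length")
        if self.lam < 0:
            raise ConfigError("lambda must be ≥ 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError("alpha must lie in [0, 1]")

    def predict_vector(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(self.intercept + x @ self.coefficients)

    def scaled_problem(self, X: np.ndarray, y: np.ndarray):
        """Reconstruct the standardized design the model was fitted on, with
        the coefficients mapped into that space — the basis for independent
        KKT verification of the stored solution."""
        mean = np.asarray(self.training_meta["feature_means"], dtype=float)
        sd = np.asarray(self.training_meta["feature_sds"], dtype=float)
        Xs = (np.asarray(X, dtype=float) - mean) / sd
        beta_s = self.coefficients * sd
        intercept_s = self.intercept + float(np.dot(self.coefficients, mean))
        return Xs, np.asarray(y, dtype=float), intercept_s, beta_s

    def kkt_residual(self, X: np.ndarray, y: np.ndarray) -> float:
        Xs, y, b0, beta_s = self.scaled_problem(X, y)
        return kkt_residual(Xs, y, b0, beta_s, self.alpha, self.lam)


def fit_drug_model(
    edge_matrix: EdgeMatrix,
    responses: DrugResponseTable,
    drug: str,
    alpha: float,
    lam: float,
    seed: int | None = None,
    selection_ref: str | None = None,
) -> DrugModel:
    """Fit the elastic net at fixed (α, λ) on every sample of ``edge_matrix``.

    ``edge_matrix`` should already be restricted to the selected features.
    λ = 0 gives the least-squares solution.
    """
    if lam < 0:
        raise ConfigError("lambda must be ≥ 0")
    if not (0.0 <= alpha <= 1.0):
        raise ConfigError("alpha must lie in [0, 1]")
    if not edge_matrix.edge_ids:
        raise ConfigError("edge matrix has no features")
    if edge_matrix.n_samples < 2:
        raise ConfigError("need at least 2 samples to fit")
    X = edge_matrix.strengths
    y = responses.tcgi(drug, edge_matrix.sample_ids)
    intercept, coef, mean, sd = fit_enet(X, y, l1_ratio=alpha, lam=lam)
    meta = {
        "n_samples": int(edge_matrix.n_samples),
        "feature_means": mean.tolist(),
        "feature_sds": sd.tolist(),
    }
    if seed is not None:
        meta["seed"] = int(seed)
    if selection_ref is not None:
        meta["selection"] = selection_ref
    return DrugModel(
        drug=drug, alpha=float(alpha), lam=float(lam), intercept=float(intercept),
        features=list(edge_matrix.edge_ids), coefficients=coef, training_meta=meta,
    )


def fit_from_selection(
    edge_matrix: EdgeMatrix,
    responses: DrugResponseTable,
    drug: str,
    selection: SelectionResult,
    selection_ref: str | None = None,
) -> DrugModel:
    """Refit on all cohort samples at the selection's (α, λ), restricted to
    the selected edge biomarkers."""
    restricted = edge_matrix.subset(selection.selected_edge_ids)
    return fit_drug_model(
        restricted, responses, drug,
        alpha=selection.best_alpha, lam=selection.best_lambda,
        seed=selection.seed, selection_ref=selection_ref,
    )


def predict_tcgi(
    model: DrugModel, patient_edges: Mapping[str, float] | np.ndarray, clip: bool = False
) -> float:
    """Predicted TCGI (percent) for one patient edge-strength vector.

    ``patient_edges`` is either a mapping edge_id → strength (missing model
    features raise :class:`MissingMoleculeError`) or an array already aligned
    to ``model.features``.
    """
    if isinstance(patient_edges, Mapping):
        missing = [f for f in model.features if f not in patient_edges]
        if missing:
            raise MissingMoleculeError(missing)
        x = np.array([patient_edges[f] for f in model.features], dtype=float)
    else:
        x = np.asarray(patient_edges, dtype=float)
        if x.shape != (len(model.features),):
            raise MissingMoleculeError(
                model.features,
                f"edge vector of length {x.size} does not match {len(model.features)} model features",
            )
    pred = model.predict_vector(x)
    if clip:
        pred = float(np.clip(pred, 0.0, 100.0))
    return pred


def predict_cohort(model: DrugModel, edge_matrix: EdgeMatrix, clip: bool = False) -> np.ndarray:
    """Predicted TCGI for every sample of an edge matrix."""
    restricted = edge_matrix.subset(model.features)
    preds = restricted.strengths @ model.coefficients + model.intercept
    if clip:
        preds = np.clip(preds, 0.0, 100.0)
    return preds


@dataclass
class EvaluationResult:
    """Predicted-vs-observed agreement for one drug."""

    n: int
    pearson_r: float
    r_squared: float  # squared Pearson correlation
    p_value: float
    pairs: list[tuple[float, float]]  # (observed, predicted) per sample
    cod: float = float("nan")  # coefficient of determination (verbose extra)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "cod": self.cod,
            "pairs": [list(p) for p in self.pairs],
        }


def evaluate(predictions: Sequence[float], observed: Sequence[float]) -> EvaluationResult:
    """Pearson r / R² / two-sided p between predicted and observed TCGI."""
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predictions.shape != observed.shape or predictions.ndim != 1:
        raise DegenerateInputError("predictions and observations must be equal-length vectors")
    if predictions.size < 3:
        raise DegenerateInputError("evaluation requires at least 3 pairs")
    r, p = pearson(predictions, observed)
    ss_res = float(np.sum((observed - predictions) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    cod = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return EvaluationResult(
        n=int(predictions.size),
        pearson_r=r,
        r_squared=r * r,
        p_value=p,
        pairs=list(zip(observed.tolist(), predictions.tolist())),
        cod=cod,
    )
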