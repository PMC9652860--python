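"""Edge-biomarker selection: response-correlation pre-filter, then repeated
random train/test splits with an elastic-net hyperparameter search, keeping
the feature set of the minimum-test-MSE fit.

Procedure (per drug):

1. Optionally pre-filter candidate edges by |Pearson r| between edge strength
   and observed TCGI (keep-all, threshold, or top-m variants).
2. Randomly split the cohort into train/test ``n_splits`` times (default 100),
   stratified on the state labels so no split has a single-state test set.
3. For each split and each α on a fixed grid (default 0.0–1.0 in steps of
   0.1): build a 100-point descending λ path from the training data, pick the
   best λ for that α by k-fold cross-validation on the training part, refit on
   the full training part at that λ, and record the held-out test MSE.
4. The globally minimum-MSE (split, α, λ) fit defines the selected edge
   biomarkers: the edges with nonzero coefficients in that refit.

The full (split, α) trace is retained in the result, and a fixed seed gives a
bit-identical result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._enet import ALPHA_FLOOR, cv_split_search
from .edge_transform import EdgeMatrix, pearson
from .errors import ConfigError, DegenerateInputError, EmptyFeatureSetError
from .io_formats import DrugResponseTable


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of the selection loop.

    Defaults: 100 random splits, 30% test fraction, α grid 0.0–1.0 in steps
    of 0.1, 5-fold CV for λ, no pre-filter, global minimum-MSE rule.
    """

    n_splits: int = 100
    test_fraction: float = 0.3
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    cv_folds: int = 5
    prefilter_top_m: int | None = None
    prefilter_min_abs_r: float | None = None
    seed: int = 0
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    mse_rule: str = "global"  # or "median_per_alpha"
    stratify_by_state: bool = True

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ConfigError("n_splits must be ≥ 1")
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigError("test_fraction must be in (0, 1)")
        if not self.alpha_grid:
            raise ConfigError("alpha_grid must be nonempty")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha_grid):
            raise ConfigError("every alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be ≥ 2")
        if self.prefilter_top_m is not None and self.prefilter_top_m < 1:
            raise ConfigError("prefilter_top_m must be ≥ 1 when set")
        if self.prefilter_min_abs_r is not None and not (
            0.0 <= self.prefilter_min_abs_r <= 1.0
        ):
            raise ConfigError("prefilter_min_abs_r must be in [0, 1] when set")
        if self.prefilter_top_m is not None and self.prefilter_min_abs_r is not None:
            raise ConfigError("set at most one of prefilter_top_m / prefilter_min_abs_r")
        if self.mse_rule not in ("global", "median_per_alpha"):
            raise ConfigError("mse_rule must be 'global' or 'median_per_alpha'")
        if self.n_lambdas < 2 or not (0.0 < self.lambda_min_ratio < 1.0):
            raise ConfigError("invalid lambda path settings")


@dataclass
class SelectionResult:
    """Outcome of the selection loop, with the full search trace."""

    drug: str
    selected_edge_ids: list[str]
    coefficients: list[float]  # winning refit, original edge-strength scale
    best_alpha: float
    best_lambda: float
    best_mse: float
    trace: list[dict]  # one record per (split, alpha): chosen λ, test MSE, support size
    seed: int
    candidate_edge_ids: list[str]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SelectionResult":
        return cls(**doc)


def prefilter_by_response(
    edge_matrix: EdgeMatrix,
    responses: DrugResponseTable,
    drug: str,
    config: SelectionConfig,
) -> EdgeMatrix:
    """Keep edges whose strength correlates with the observed TCGI.

    ``prefilter_min_abs_r`` keeps edges with |r| at or above the threshold;
    ``prefilter_top_m`` keeps the m strongest by |r| with the deterministic
    tie-break (|r| descending, edge_id ascending).  Both unset: identity.
    Degenerate (constant) edge columns rank last with |r| treated as 0.
    """
    if config.prefilter_top_m is None and config.prefilter_min_abs_r is None:
        return edge_matrix
    y = responses.tcgi(drug, edge_matrix.sample_ids)
    abs_r = np.empty(len(edge_matrix.edge_ids))
    for i in range(len(edge_matrix.edge_ids)):
        col = edge_matrix.strengths[:, i]
        try:
            r, _ = pearson(col, y)
        except DegenerateInputError:
            r = 0.0
        abs_r[i] = abs(r)
    ids = edge_matrix.edge_ids
    if config.prefilter_min_abs_r is not None:
        kept = [ids[i] for i in range(len(ids)) if abs_r[i] >= config.prefilter_min_abs_r]
    else:
        order = sorted(range(len(ids)), key=lambda i: (-abs_r[i], ids[i]))
        kept_set = set(order[: config.prefilter_top_m])
        kept = [ids[i] for i in range(len(ids)) if i in kept_set]
    if not kept:
        raise EmptyFeatureSetError(
            f"no edge passed the response-correlation pre-filter for drug {drug!r}"
        )
    return edge_matrix.subset(kept)


def _stratified_split(
    states: np.ndarray, test_fraction: float, rng: np.random.Generator, stratify: bool
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test partition; with stratification, every present
    state contributes at least one sample to each side."""
    n = len(states)
    groups = [np.flatnonzero(states == s) for s in np.unique(states)] if stratify else [np.arange(n)]
    test_idx: list[int] = []
    for grp in groups:
        k = int(round(test_fraction * len(grp)))
        k = min(max(k, 1), len(grp) - 1)
        perm = rng.permutation(len(grp))
        test_idx.extend(grp[perm[:k]])
    test = np.sort(np.asarray(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold id per sample, fold sizes as equal as possible."""
    fold_of = np.empty(n, dtype=np.int64)
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    perm = rng.permutation(n)
    start = 0
    for f, s in enumerate(sizes):
        fold_of[perm[start : start + int(s)]] = f
        start += int(s)
    return fold_of


def select_edge_biomarkers(
    edge_matrix: EdgeMatrix,
    responses: DrugResponseTable,
    drug: str,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the repeated-split elastic-net selection loop for one drug."""
    config = config or SelectionConfig()
    if config.prefilter_top_m is not None or config.prefilter_min_abs_r is not None:
        edge_matrix = prefilter_by_response(edge_matrix, responses, drug, config)
    X = edge_matrix.strengths
    y = responses.tcgi(drug, edge_matrix.sample_ids)
    n, p = X.shape
    if p < 1:
        raise EmptyFeatureSetError("no candidate edges")
    if n < config.cv_folds + 2:
        raise ConfigError(
            f"need at least cv_folds + 2 = {config.cv_folds + 2} samples, got {n}"
        )
    rng = np.random.default_rng(config.seed)

    trace: list[dict] = []
    refit_coefs: list[np.ndarray] = []  # original-scale coefficients per trace row

    alphas = np.asarray(config.alpha_grid, dtype=float)
    for split in range(config.n_splits):
        train, test = _stratified_split(
            edge_matrix.states, config.test_fraction, rng, config.stratify_by_state
        )
        Xtr, ytr = np.ascontiguousarray(X[train]), np.ascontiguousarray(y[train])
        Xte, yte = np.ascontiguousarray(X[test]), np.ascontiguousarray(y[test])
        # CV fold assignment over the training part, shared by all alphas
        n_folds = min(config.cv_folds, len(train))
        fold_of = _fold_assignment(len(train), n_folds, rng)
        y_scale = max(float(np.std(ytr)), 1e-12)
        lambdas_a, mse_a, coefs_a, sd_tr = cv_split_search(
            Xtr, ytr, Xte, yte, fold_of, n_folds, alphas,
            config.n_lambdas, config.lambda_min_ratio, ALPHA_FLOOR,
            1e-5 * y_scale, 1e-5 * y_scale, 100,
            1e-8 * y_scale, 1e-8 * y_scale, 10_000,
        )
        for ai, alpha in enumerate(config.alpha_grid):
            beta_s = coefs_a[ai]
            trace.append(
                {
                    "split": split,
                    "alpha": float(alpha),
                    "lambda": float(lambdas_a[ai]),
                    "test_mse": float(mse_a[ai]),
                    "n_nonzero": int(np.count_nonzero(beta_s)),
                }
            )
            refit_coefs.append(beta_s / sd_tr)

    winner = _pick_winner(trace, config.mse_rule)
    win = trace[winner]
    if all(rec["n_nonzero"] == 0 for rec in trace):
        raise EmptyFeatureSetError(
            f"every fit shrank all coefficients to zero for drug {drug!r}", trace=trace
        )
    support = np.flatnonzero(refit_coefs[winner])
    selected = [edge_matrix.edge_ids[i] for i in support]
    return SelectionResult(
        drug=drug,
        selected_edge_ids=selected,
        coefficients=[float(refit_coefs[winner][i]) for i in support],
        best_alpha=win["alpha"],
        best_lambda=win["lambda"],
        best_mse=win["test_mse"],
        trace=trace,
        seed=config.seed,
        candidate_edge_ids=list(edge_matrix.edge_ids),
        config=asdict(config),
    )


def _pick_winner(trace: list[dict], rule: str) -> int:
    if rule == "global":
        return int(min(range(len(trace)), key=lambda i: (trace[i]["test_mse"], i)))
    # median_per_alpha: choose the α with the smallest median test MSE, then
    # the minimum-MSE entry within that α
    alphas = sorted({rec["alpha"] for rec in trace})
    med = {
        a: float(np.median([rec["test_mse"] for rec in trace if rec["alpha"] == a]))
        for a in alphas
    }
    best_alpha = min(alphas, key=lambda a: (med[a], a))
    cands = [i for i, rec in enumerate(trace) if rec["alpha"] == best_alpha]
    return int(min(cands, key=lambda i: (trace[i]["test_mse"], i)))
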