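"""Elastic-net coordinate descent on the Gram formulation.

Objective (the canonical penalized form, with α the L1/L2 mixing parameter
and λ the overall penalty):

    minimize_{β0, β}  (1/(2n))·Σ_j (y_j − β0 − x_j·β)²
                      + λ·( α·‖β‖₁ + ((1−α)/2)·‖β‖₂² )

The selection loop solves hundreds of thousands of tiny (n ≈ 30, p ≈ 50)
instances along warm-started λ paths, so the inner solver works on the
precomputed Gram matrix (cost per sweep O(p²), independent of n) and is
compiled with numba.  Solutions are verified against the KKT subgradient
conditions inside the solver loop; tests additionally cross-check against
scikit-learn's ElasticNet and closed-form least squares.

Convention: features are standardized (zero mean, unit population SD) and the
response centered before solving, so the intercept is the response mean;
coefficients are mapped back to the original scale afterwards.  λ_max — the
smallest λ at which every coefficient is zero — is max|X'y|/(n·α), with α
floored at 1e-3 so a ridge-leaning grid still gets a finite path (the usual
path-solver convention).
"""

from __future__ import annotations

import numpy as np
from numba import njit

ALPHA_FLOOR = 1e-3  # for λ_max when α ≈ 0 (pure ridge has no finite λ_max)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to unit population SD; constant columns get
    scale 1 (they become all-zero and draw a zero coefficient)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def lambda_max(Xs: np.ndarray, yc: np.ndarray, l1_ratio: float) -> float:
    n = Xs.shape[0]
    a = max(l1_ratio, ALPHA_FLOOR)
    lmax = float(np.max(np.abs(Xs.T @ yc)) / (n * a))
    return lmax if lmax > 0 else 1.0


def lambda_grid(
    Xs: np.ndarray, yc: np.ndarray, l1_ratio: float,
    n_lambdas: int = 100, min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced λ path from λ_max down to λ_max·min_ratio."""
    lmax = lambda_max(Xs, yc, l1_ratio)
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


@njit(cache=True)
def enet_path_gram(
    Gn: np.ndarray,       # X'X / n  (p × p), standardized X
    bn: np.ndarray,       # X'y / n  (p,), centered y
    lambdas: np.ndarray,  # descending λ path
    l1_ratio: float,
    tol: float,           # sweep convergence: max |Δβ_j|
    kkt_tol: float,       # KKT subgradient residual target
    max_iter: int,
    df_max: int = -1,     # if > 0: stop descending once the support reaches df_max
) -> np.ndarray:
    """Cyclic coordinate descent along a λ path, warm-started between λs.

    Returns coefficients of shape (len(lambdas), p).  The partial-gradient
    vector q = Gn·β is maintained incrementally (O(p) per coordinate update),
    active-set sweeps run between full sweeps, and each λ iterates until the
    KKT stationarity residual falls below ``kkt_tol`` (or max_iter sweeps).
    """
    p = Gn.shape[0]
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    beta = np.zeros(p)
    q = np.zeros(p)  # Gn @ beta, kept in sync with every update
    for li in range(L):
        lam = lambdas[li]
        l1 = lam * l1_ratio
        l2 = lam * (1.0 - l1_ratio)
        it = 0
        while it < max_iter:
            # full sweep over all coordinates (lets new ones enter)
            for j in range(p):
                gjj = Gn[j, j]
                if gjj <= 0.0:
                    continue
                rho = bn[j] - q[j] + gjj * beta[j]
                if rho > l1:
                    new = (rho - l1) / (gjj + l2)
                elif rho < -l1:
                    new = (rho + l1) / (gjj + l2)
                else:
                    new = 0.0
                d = new - beta[j]
                if d != 0.0:
                    beta[j] = new
                    for k in range(p):
                        q[k] += d * Gn[k, j]
            it += 1
            # active-set sweeps until stable
            while it < max_iter:
                maxd = 0.0
                for j in range(p):
                    if beta[j] == 0.0:
                        continue
                    gjj = Gn[j, j]
                    rho = bn[j] - q[j] + gjj * beta[j]
                    if rho > l1:
                        new = (rho - l1) / (gjj + l2)
                    elif rho < -l1:
                        new = (rho + l1) / (gjj + l2)
                    else:
                        new = 0.0
                    d = new - beta[j]
                    if d != 0.0:
                        beta[j] = new
                        for k in range(p):
                            q[k] += d * Gn[k, j]
                        ad = abs(d)
                        if ad > maxd:
                            maxd = ad
                it += 1
                if maxd < tol:
                    break
            # KKT stationarity over all coordinates, O(p) thanks to q
            kkt = 0.0
            for j in range(p):
                if Gn[j, j] <= 0.0:
                    continue
                g = bn[j] - q[j] - l2 * beta[j]
                if beta[j] > 0.0:
                    resid = abs(g - l1)
                elif beta[j] < 0.0:
                    resid = abs(g + l1)
                else:
                    resid = abs(g) - l1
                    if resid < 0.0:
                        resid = 0.0
                if resid > kkt:
                    kkt = resid
            if kkt < kkt_tol:
                break
        coefs[li] = beta
        if df_max > 0 and l1 > 0.0:
            # saturated fits further down the path are interpolating noise;
            # freeze them at the current solution (early path exit)
            nnz = 0
            for j in range(p):
                if beta[j] != 0.0:
                    nnz += 1
            if nnz >= df_max:
                for lj in range(li + 1, L):
                    coefs[lj] = beta
                break
    return coefs


@njit(cache=True)
def _col_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    mean = np.empty(p)
    sd = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j]
        m = s / n
        v = 0.0
        for i in range(n):
            d = X[i, j] - m
            v += d * d
        mean[j] = m
        sd[j] = np.sqrt(v / n) if v > 0.0 else 1.0
    Xs = np.empty((n, p))
    for i in range(n):
        for j in range(p):
            Xs[i, j] = (X[i, j] - mean[j]) / sd[j]
    return Xs, mean, sd


@njit(cache=True)
def _geomspace_desc(hi: float, lo: float, num: int) -> np.ndarray:
    out = np.empty(num)
    if num == 1:
        out[0] = hi
        return out
    step = (np.log(lo) - np.log(hi)) / (num - 1)
    for i in range(num):
        out[i] = np.exp(np.log(hi) + step * i)
    return out


@njit(cache=True)
def cv_split_search(
    Xtr: np.ndarray,      # (ntr, p) raw training features of one split
    ytr: np.ndarray,
    Xte: np.ndarray,      # (nte, p) raw held-out features of the split
    yte: np.ndarray,
    fold_of: np.ndarray,  # (ntr,) fold id per training sample, 0..F-1
    n_folds: int,
    alphas: np.ndarray,
    n_lambdas: int,
    min_ratio: float,
    alpha_floor: float,
    tol: float,
    kkt_tol: float,
    max_iter: int,
    refit_tol: float,
    refit_kkt_tol: float,
    refit_max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One split's full hyperparameter search, batched for speed.

    For every α: pick λ by k-fold CV on the training part (shared descending
    λ path from the training data), refit on the whole training part at that
    λ, and score on the held-out part.  Returns (chosen λ per α, test MSE per
    α, refit coefficients per α on the *standardized* training scale, and the
    training-column SDs to map those coefficients back to the original scale).

    The CV fold paths — which only rank λs — run at the looser
    (tol, kkt_tol, max_iter); the refit that defines coefficients and support
    runs at the tighter (refit_tol, refit_kkt_tol, refit_max_iter).
    """
    ntr, p = Xtr.shape
    nte = Xte.shape[0]
    A = alphas.shape[0]

    Xtrs, mean_tr, sd_tr = _col_standardize(Xtr)
    ybar = ytr.mean()
    yc = ytr - ybar
    Gtr = (Xtrs.T @ Xtrs) / ntr
    btr = (Xtrs.T @ yc) / ntr
    xty_max = np.max(np.abs(Xtrs.T @ yc))
    if xty_max <= 0.0:
        xty_max = 1.0

    # per-fold Gram systems and standardized validation blocks
    Gf = np.zeros((n_folds, p, p))
    bf = np.zeros((n_folds, p))
    ybar_f = np.zeros(n_folds)
    mean_fold = np.zeros((n_folds, p))
    sd_fold = np.ones((n_folds, p))
    for f in range(n_folds):
        nf = 0
        for i in range(ntr):
            if fold_of[i] != f:
                nf += 1
        Xf = np.empty((nf, p))
        yf = np.empty(nf)
        k = 0
        for i in range(ntr):
            if fold_of[i] != f:
                Xf[k] = Xtr[i]
                yf[k] = ytr[i]
                k += 1
        Xfs, mean_f, sd_f = _col_standardize(Xf)
        ybar_f[f] = yf.mean()
        Gf[f] = (Xfs.T @ Xfs) / nf
        bf[f] = (Xfs.T @ (yf - ybar_f[f])) / nf
        mean_fold[f] = mean_f
        sd_fold[f] = sd_f

    lambdas_out = np.empty(A)
    mse_out = np.empty(A)
    coefs_out = np.zeros((A, p))

    for ai in range(A):
        alpha = alphas[ai]
        a_eff = alpha if alpha > alpha_floor else alpha_floor
        lmax = xty_max / (ntr * a_eff)
        lambdas = _geomspace_desc(lmax, lmax * min_ratio, n_lambdas)
        cv_err = np.zeros(n_lambdas)
        for f in range(n_folds):
            nf = ntr - np.sum(fold_of == f)
            # early path exit only once the support can interpolate the fold
            coefs = enet_path_gram(
                Gf[f], bf[f], lambdas, alpha, tol, kkt_tol, max_iter, nf - 1
            )
            for i in range(ntr):
                if fold_of[i] != f:
                    continue
                for li in range(n_lambdas):
                    pred = ybar_f[f]
                    for j in range(p):
                        pred += (Xtr[i, j] - mean_fold[f, j]) / sd_fold[f, j] * coefs[li, j]
                    d = pred - ytr[i]
                    cv_err[li] += d * d
        best_li = 0
        best = cv_err[0]
        for li in range(1, n_lambdas):
            if cv_err[li] < best:
                best = cv_err[li]
                best_li = li
        refit = enet_path_gram(
            Gtr, btr, lambdas[: best_li + 1], alpha,
            refit_tol, refit_kkt_tol, refit_max_iter,
        )
        beta = refit[best_li]
        sq = 0.0
        for i in range(nte):
            pred = ybar
            for j in range(p):
                pred += (Xte[i, j] - mean_tr[j]) / sd_tr[j] * beta[j]
            d = pred - yte[i]
            sq += d * d
        lambdas_out[ai] = lambdas[best_li]
        mse_out[ai] = sq / nte if nte > 0 else np.nan
        coefs_out[ai] = beta
    return lambdas_out, mse_out, coefs_out, sd_tr


def solve_path(
    Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray, l1_ratio: float,
    tol_scale: float = 1e-7, kkt_tol_scale: float = 1e-9, max_iter: int = 10_000,
) -> np.ndarray:
    """Solve the λ path on standardized X / centered y; tolerances scale with
    the response SD so convergence quality is unit-independent."""
    n = Xs.shape[0]
    Gn = (Xs.T @ Xs) / n
    bn = (Xs.T @ yc) / n
    y_scale = max(float(np.std(yc)), 1e-12)
    return enet_path_gram(
        np.ascontiguousarray(Gn), np.ascontiguousarray(bn),
        np.ascontiguousarray(lambdas, dtype=float),
        float(l1_ratio), tol_scale * y_scale, kkt_tol_scale * y_scale, max_iter,
    )


def fit_enet(
    X: np.ndarray, y: np.ndarray, l1_ratio: float, lam: float,
    kkt_tol: float = 1e-10, max_iter: int = 100_000,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Fit one elastic net at (α=l1_ratio, λ=lam) on raw-scale inputs.

    Returns ``(intercept, coef, feature_means, feature_sds)`` with intercept
    and coefficients already mapped back to the original feature scale.
    λ = 0 is solved exactly by least squares (minimum-norm for rank-deficient
    designs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, mean, sd = standardize(X)
    ybar = float(y.mean())
    yc = y - ybar
    if lam == 0.0:
        beta_s, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        lmax = lambda_max(Xs, yc, l1_ratio)
        if lam >= lmax:
            path = np.array([lam])
        else:
            # warm-start down from λ_max for reliable convergence
            n_steps = 30
            path = np.geomspace(lmax, lam, n_steps)
            path[-1] = lam
        y_scale = max(float(np.std(yc)), 1e-12)
        coefs = enet_path_gram(
            np.ascontiguousarray((Xs.T @ Xs) / len(y)),
            np.ascontiguousarray((Xs.T @ yc) / len(y)),
            path, float(l1_ratio),
            1e-10 * y_scale, kkt_tol * y_scale, max_iter,
        )
        beta_s = coefs[-1]
    coef = beta_s / sd
    intercept = ybar - float(np.dot(coef, mean))
    return intercept, coef, mean, sd


def kkt_residual(
    X: np.ndarray, y: np.ndarray, intercept: float, coef: np.ndarray,
    l1_ratio: float, lam: float,
) -> float:
    """Max subgradient stationarity violation of (intercept, coef) for the
    elastic-net objective on the design exactly as given (no rescaling).

    Independent of the solver: a direct evaluation of the optimality
    conditions, usable as an oracle against any fitted solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.asarray(coef, dtype=float)
    n = len(y)
    r = y - intercept - X @ coef
    grad = -(X.T @ r) / n + lam * (1.0 - l1_ratio) * coef
    l1 = lam * l1_ratio
    resid = np.where(
        coef > 0, np.abs(grad + l1),
        np.where(coef < 0, np.abs(grad - l1), np.maximum(np.abs(grad) - l1, 0.0)),
    )
    # intercept stationarity: mean residual must vanish
    return float(max(resid.max(initial=0.0), abs(r.mean())))
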