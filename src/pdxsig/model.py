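"""Sparse elastic-net mRNA signatures of in vitro drug sensitivity.

The modeling pipeline: z-score transformation of inputs and outputs,
robust removal of training samples whose log rIC50 is inconsistent with a
normal curve, an uncorrected univariate Pearson screen nested inside
10-fold cross-validation, elastic-net fitting by cyclic coordinate descent
along a warm-started regularization path, selection of the (alpha, lambda)
pair with the lowest mean cross-validated squared error, and prediction of
composite sensitivity scores for new cohorts.

The objective minimized is

    (1/2n) sum_i (y_i - b0 - x_i b)^2  +  lambda * P_alpha(b),
    P_alpha(b) = sum_j [ (1-alpha) b_j^2 / 2 + alpha |b_j| ]

with alpha in (0, 1] blending ridge (small alpha) and lasso (alpha = 1).
Inner products in the solver use the 1/n convention of the objective while
features are standardized with the n-1 sample standard deviation, so the
coordinate update divides by the feature's realized 1/n norm rather than
assuming it is one.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from numba import njit

from .io import ExpressionMatrix, SensitivityProfile
from .screening import _pearson_rows, pearson_correlation_pvalues

__all__ = [
    "PreprocessSpec",
    "FitConfig",
    "ZScoreParams",
    "ElasticNetFit",
    "Signature",
    "CVResult",
    "ConvergenceError",
    "soft_threshold",
    "zscore_fit_transform",
    "apply_zscore",
    "remove_nonnormal_outputs",
    "coordinate_descent_fit",
    "elastic_net_objective",
    "kkt_violation",
    "lambda_path",
    "cross_validate",
    "fit_signature",
    "predict",
    "save_signature",
    "load_signature",
]

DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the pass budget."""


@dataclass
class PreprocessSpec:
    """Global and fold-internal pre-processing parameters.

    ``alpha_local`` is the deliberately *uncorrected* per-feature type-I
    rate of the univariate screen; false positives at this stage are
    harmless because the penalized fit removes them.
    """

    zscore_inputs: bool = True
    zscore_outputs: bool = True
    outlier_cutoff: float = 2.5
    max_outlier_frac: float = 0.2
    alpha_local: float = 0.1

    def __post_init__(self) -> None:
        if not (self.outlier_cutoff > 0):
            raise ValueError("outlier_cutoff must be > 0")
        if not (0 < self.alpha_local < 1):
            raise ValueError("alpha_local must lie in (0, 1)")


@dataclass
class FitConfig:
    """End-to-end signature fitting configuration."""

    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-2  # path floor; 1e-2 is standard for n < p
    k_folds: int = 10
    seed: int = 0
    include_censored: bool = True
    tol: float = 1e-6
    cv_tol: float = 1e-4  # looser inside CV; the final fit uses `tol`
    max_passes: int = 100_000


@dataclass
class ZScoreParams:
    """Frozen per-feature standardization (n-1 sd convention)."""

    feature_ids: list[str]
    means: np.ndarray
    sds: np.ndarray


@dataclass
class ElasticNetFit:
    """A single elastic-net solution.

    ``beta`` maps feature_id -> coefficient for the nonzero coefficients
    only; features absent from the map have coefficient exactly zero.
    """

    beta0: float
    feature_ids: list[str]
    coefs: np.ndarray
    alpha: float
    lam: float
    n: int
    p: int
    objective: float
    penalty: float
    n_passes: int
    kkt: float

    @property
    def beta(self) -> dict[str, float]:
        return {
            fid: float(c)
            for fid, c in zip(self.feature_ids, self.coefs)
            if c != 0.0
        }

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefs))


@dataclass
class CVResult:
    """Cross-validation surface and the selected penalty pair."""

    table: pd.DataFrame  # columns: alpha, lam, mse
    selected_alpha: float
    selected_lambda: float

    def min_mse(self) -> float:
        return float(self.table["mse"].min())


@dataclass
class Signature:
    """A fitted in vitro sensitivity signature, ready for translation."""

    fit: ElasticNetFit
    transform: ZScoreParams  # training standardization of candidate features
    y_mean: float
    y_sd: float
    cv: CVResult
    n_features_selected: int
    n_linc_selected: int
    removed_samples: list[str]
    seed: int

    @property
    def selected_alpha(self) -> float:
        return self.cv.selected_alpha

    @property
    def selected_lambda(self) -> float:
        return self.cv.selected_lambda


# ---------------------------------------------------------------------------
# solver kernel

def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@njit(cache=False)
def _cd_sweep(Z, r, beta, v, n, thr, l2, active_only):  # pragma: no cover
    """One coordinate sweep; over the active set only, or over all features.
    Returns the max coefficient change."""
    p = beta.shape[0]
    dmax = 0.0
    for j in range(p):
        if v[j] == 0.0:
            continue
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        s = 0.0
        for i in range(n):
            s += Z[i, j] * r[i]
        rho = bj * v[j] + s / n
        if rho > thr:
            bnew = (rho - thr) / (v[j] + l2)
        elif rho < -thr:
            bnew = (rho + thr) / (v[j] + l2)
        else:
            bnew = 0.0
        if bnew != bj:
            d = bnew - bj
            for i in range(n):
                r[i] -= Z[i, j] * d
            beta[j] = bnew
            ad = abs(d)
            if ad > dmax:
                dmax = ad
    return dmax


@njit(cache=False)
def _cd_path_kernel(Z, y, alpha, lambdas, tol, max_passes):  # pragma: no cover
    n, p = Z.shape
    n_lam = lambdas.shape[0]
    v = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        v[j] = s / n
    beta = np.zeros(p)
    B = np.zeros((n_lam, p))
    passes = np.zeros(n_lam, dtype=np.int64)
    last_delta = np.zeros(n_lam)
    r = y.copy()
    for li in range(n_lam):
        lam = lambdas[li]
        thr = lam * alpha
        l2 = lam * (1.0 - alpha)
        npass = 0
        dmax = 0.0
        # alternate: one full sweep (may activate features), then cycle the
        # active set to convergence; done when a full sweep changes nothing
        while npass < max_passes:
            npass += 1
            dmax = _cd_sweep(Z, r, beta, v, n, thr, l2, False)
            if dmax < tol:
                break
            while npass < max_passes:
                npass += 1
                dmax = _cd_sweep(Z, r, beta, v, n, thr, l2, True)
                if dmax < tol:
                    break
        passes[li] = npass
        last_delta[li] = dmax
        for j in range(p):
            B[li, j] = beta[j]
    return B, passes, last_delta


def _cd_path(
    Z: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float,
    max_passes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coordinate-descent path; raises on non-convergence."""
    Z = np.asfortranarray(Z, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    B, passes, last_delta = _cd_path_kernel(Z, y, alpha, lambdas, tol, max_passes)
    if np.any(passes >= max_passes):
        worst = int(np.argmax(last_delta))
        if last_delta[worst] >= tol:
            raise ConvergenceError(
                f"coordinate descent did not converge at lambda="
                f"{lambdas[worst]:.4g} (last max |d beta| = {last_delta[worst]:.3g})"
            )
    return B, passes


def elastic_net_objective(
    Z: np.ndarray, y: np.ndarray, beta0: float, coefs: np.ndarray,
    alpha: float, lam: float,
) -> tuple[float, float]:
    """(objective, penalty P_alpha) of the elastic-net problem."""
    n = len(y)
    resid = y - beta0 - Z @ coefs
    penalty = float(np.sum((1 - alpha) * coefs**2 / 2 + alpha * np.abs(coefs)))
    return float(resid @ resid / (2 * n) + lam * penalty), penalty


def kkt_violation(
    Z: np.ndarray, y: np.ndarray, beta0: float, coefs: np.ndarray,
    alpha: float, lam: float,
) -> float:
    """Maximum violation of the stationarity/subgradient conditions.

    For b_j = 0 the condition is |(1/n) z_j' r| <= lam*alpha; for b_j != 0,
    (1/n) z_j' r = lam*(1-alpha)*b_j + lam*alpha*sign(b_j).
    """
    n = len(y)
    r = y - beta0 - Z @ coefs
    g = Z.T @ r / n
    active = coefs != 0
    viol_zero = np.maximum(np.abs(g[~active]) - lam * alpha, 0.0)
    viol_act = np.abs(
        g[active] - lam * (1 - alpha) * coefs[active]
        - lam * alpha * np.sign(coefs[active])
    )
    pieces = [v for v in (viol_zero, viol_act) if v.size]
    return float(max(np.max(v) for v in pieces)) if pieces else 0.0


def coordinate_descent_fit(
    Z: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-6,
    max_passes: int = 100_000,
    feature_ids: Optional[Sequence[str]] = None,
) -> ElasticNetFit:
    """Solve the elastic-net problem at a single (alpha, lambda).

    ``Z`` is samples x features, standardized; ``y`` the (standardized)
    outcome. The intercept is handled by centering, so it equals the mean
    of ``y`` when all coefficients are zero.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != len(y):
        raise ValueError("Z must be (n_samples, n_features) aligned with y")
    n, p = Z.shape
    col_means = Z.mean(axis=0)
    Zc = Z - col_means
    y_mean = float(np.mean(y))
    yc = y - y_mean
    B, passes = _cd_path(Zc, yc, alpha, np.array([lam]), tol, max_passes)
    coefs = B[0]
    beta0 = y_mean - float(col_means @ coefs)
    obj, penalty = elastic_net_objective(Z, y, beta0, coefs, alpha, lam)
    kkt = kkt_violation(Zc, yc, 0.0, coefs, alpha, lam)
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(p)]
    return ElasticNetFit(
        beta0=beta0,
        feature_ids=list(feature_ids),
        coefs=coefs,
        alpha=alpha,
        lam=lam,
        n=n,
        p=p,
        objective=obj,
        penalty=penalty,
        n_passes=int(passes[0]),
        kkt=kkt,
    )


def lambda_path(
    Z: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced lambda grid from lambda_max down.

    lambda_max = max_j |(1/n) z_j' (y - ybar)| / alpha is the smallest
    penalty at which the fit is entirely zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0 for a finite lambda_max")
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    if np.all(yc == 0):
        raise ValueError("outcome has zero variance; lambda path undefined")
    Zc = Z - Z.mean(axis=0)
    lam_max = float(np.max(np.abs(Zc.T @ yc)) / n / alpha)
    if lam_max == 0:
        raise ValueError("all features orthogonal to outcome; path undefined")
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


# ---------------------------------------------------------------------------
# preprocessing

def zscore_fit_transform(
    X: ExpressionMatrix,
) -> tuple[np.ndarray, ZScoreParams]:
    """Standardize each feature to mean 0, sd 1 (n-1 convention).

    Returns the standardized feature x sample array for the *kept* features
    and the frozen parameters; zero-variance features are dropped with a
    warning.
    """
    if X.shape[1] < 2:
        raise ValueError("z-scoring requires >= 2 samples")
    means = X.values.mean(axis=1)
    sds = X.values.std(axis=1, ddof=1)
    keep = sds > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"zscore_fit_transform: dropped {n_dropped} constant features")
    ids = [f for f, k in zip(X.feature_ids, keep) if k]
    params = ZScoreParams(feature_ids=ids, means=means[keep], sds=sds[keep])
    Z = (X.values[keep] - params.means[:, None]) / params.sds[:, None]
    return Z, params


def apply_zscore(params: ZScoreParams, X: ExpressionMatrix) -> np.ndarray:
    """Re-apply a stored transform to a matrix (features x samples)."""
    pos = {f: i for i, f in enumerate(X.feature_ids)}
    idx = [pos[f] for f in params.feature_ids]
    return (X.values[idx] - params.means[:, None]) / params.sds[:, None]


def remove_nonnormal_outputs(
    y, cutoff: float = 2.5, max_frac: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Flag outcome values inconsistent with a normal curve.

    A single-pass robust z-score rule: remove samples with
    |y - median| / (1.4826 * MAD) > cutoff. Never removes more than
    ``max_frac`` of the samples; when the rule would, only the most extreme
    values up to the cap are removed, with a warning. Returns (kept indices,
    removed indices), both sorted ascending.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("outlier screening requires n >= 5")
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    if mad == 0:
        warnings.warn("remove_nonnormal_outputs: MAD = 0, no removal possible")
        return np.arange(n), np.array([], dtype=int)
    rz = np.abs(y - med) / (1.4826 * mad)
    removed = np.nonzero(rz > cutoff)[0]
    max_remove = int(math.floor(max_frac * n))
    if len(removed) > max_remove:
        warnings.warn(
            f"outlier rule flagged {len(removed)} of {n} samples; keeping the "
            f"{len(removed) - max_remove} closest to the threshold"
        )
        order = np.argsort(rz[removed])[::-1]  # most extreme first
        removed = removed[order[:max_remove]]
    removed = np.sort(removed)
    kept = np.setdiff1d(np.arange(n), removed)
    return kept, removed


# ---------------------------------------------------------------------------
# cross-validation

def _screen_mask(Z: np.ndarray, y: np.ndarray, alpha_local: float) -> np.ndarray:
    """Boolean mask of rows of Z (features x samples) passing the
    uncorrected Pearson screen against y."""
    r, degenerate = _pearson_rows(Z, y)
    p = pearson_correlation_pvalues(r, len(y))
    mask = (~degenerate) & (p < alpha_local)
    return mask


def cross_validate(
    X: ExpressionMatrix,
    y,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    k: int = 10,
    spec: Optional[PreprocessSpec] = None,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    tol: float = 1e-4,
    max_passes: int = 100_000,
) -> CVResult:
    """K-fold cross-validation over the (alpha, lambda) surface.

    The fold assignment is drawn once from ``seed`` and reused for every
    (alpha, lambda). The univariate screen is re-run *inside* each training
    fold so that feature selection is part of the estimated prediction
    error; standardization parameters likewise come from the training fold
    only. The lambda grid per alpha is anchored at the full-data lambda_max
    so errors are comparable across folds. Ties in mean MSE break toward
    the larger lambda (sparser model), then the larger alpha.
    """
    spec = spec or PreprocessSpec()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[1] != n:
        raise ValueError("X and y sample counts differ")
    if n < 2 * k:
        raise ValueError(f"need n >= 2k samples for {k}-fold CV, got n={n}")
    if not all(0 < a <= 1 for a in alpha_grid):
        raise ValueError("alpha grid must lie in (0, 1]")

    if spec.zscore_outputs:
        y_sd = np.std(y, ddof=1)
        if y_sd == 0:
            raise ValueError("outcome has zero variance")
        y_work = (y - np.mean(y)) / y_sd
    else:
        y_work = y.copy()

    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % k

    # full-data standardization + screen anchors the lambda grids
    Z_full, params_full = zscore_fit_transform(X)
    mask_full = _screen_mask(Z_full, y_work, spec.alpha_local)
    anchor = Z_full[mask_full] if mask_full.any() else Z_full

    fold_cache = []
    for f in range(k):
        train = np.nonzero(assignment != f)[0]
        test = np.nonzero(assignment == f)[0]
        Xtr = X.values[:, train]
        means = Xtr.mean(axis=1)
        sds = Xtr.std(axis=1, ddof=1)
        keep = sds > 0
        Ztr = (Xtr[keep] - means[keep, None]) / sds[keep, None]
        mask = _screen_mask(Ztr, y_work[train], spec.alpha_local)
        ytr = y_work[train]
        if mask.any():
            Ztr_cand = Ztr[mask].T  # samples x candidates
            Xte = X.values[:, test][keep][mask]
            Zte = ((Xte - means[keep][mask, None]) / sds[keep][mask, None]).T
        else:
            Ztr_cand = None
            Zte = None
        fold_cache.append((train, test, Ztr_cand, Zte, ytr))

    rows = []
    for alpha in alpha_grid:
        lambdas = lambda_path(anchor.T, y_work, alpha, n_lambda, lambda_min_ratio)
        sq_err = np.zeros(len(lambdas))
        for train, test, Ztr_cand, Zte, ytr in fold_cache:
            ytr_mean = float(np.mean(ytr))
            if Ztr_cand is None:
                pred = np.full((len(lambdas), len(test)), ytr_mean)
            else:
                B, _ = _cd_path(
                    Ztr_cand - Ztr_cand.mean(axis=0),
                    ytr - ytr_mean,
                    alpha,
                    lambdas,
                    tol,
                    max_passes,
                )
                b0 = ytr_mean - B @ Ztr_cand.mean(axis=0)
                pred = B @ Zte.T + b0[:, None]
            sq_err += ((pred - y_work[test]) ** 2).sum(axis=1)
        mse = sq_err / n
        for lam, m in zip(lambdas, mse):
            rows.append((float(alpha), float(lam), float(m)))

    table = pd.DataFrame(rows, columns=["alpha", "lam", "mse"])
    # argmin with ties toward larger lambda, then larger alpha
    best = table.sort_values(
        ["mse", "lam", "alpha"], ascending=[True, False, False], kind="stable"
    ).iloc[0]
    return CVResult(
        table=table,
        selected_alpha=float(best["alpha"]),
        selected_lambda=float(best["lam"]),
    )


# ---------------------------------------------------------------------------
# end-to-end fit and prediction

def _outcome_vector(
    X: ExpressionMatrix,
    y: Union[np.ndarray, Sequence[SensitivityProfile], Sequence[float]],
    include_censored: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Align the outcome with the matrix columns; from sensitivity profiles
    the outcome is log10 rIC50 (censored values included at the censoring
    dose by default, or dropped when ``include_censored`` is False)."""
    if len(y) and isinstance(next(iter(y)), SensitivityProfile):
        by_sample = {p.sample_id: p for p in y}
        samples, vals = [], []
        for s in X.sample_ids:
            if s not in by_sample:
                continue
            prof = by_sample[s]
            if prof.censored and not include_censored:
                continue
            samples.append(s)
            vals.append(prof.log10_ric50)
        return np.asarray(vals, dtype=float), samples
    arr = np.asarray(y, dtype=float)
    if len(arr) != X.shape[1]:
        raise ValueError("outcome length does not match sample count")
    return arr, list(X.sample_ids)


def fit_signature(
    X: ExpressionMatrix,
    y: Union[np.ndarray, Sequence[SensitivityProfile], Sequence[float]],
    config: Optional[FitConfig] = None,
) -> Signature:
    """Fit the full in vitro signature pipeline.

    Steps: outcome alignment -> robust outlier removal on the outputs ->
    global z-scoring of the outputs -> nested-screen cross-validation over
    the (alpha, lambda) surface -> final screen on all kept samples ->
    coordinate-descent fit at the selected penalties, warm-started along
    the path. Deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    spec = config.preprocess
    y_raw, samples = _outcome_vector(X, y, config.include_censored)
    Xw = X.subset_samples(samples)

    kept, removed = remove_nonnormal_outputs(
        y_raw, cutoff=spec.outlier_cutoff, max_frac=spec.max_outlier_frac
    )
    removed_samples = [samples[i] for i in removed]
    y_kept = y_raw[kept]
    Xw = Xw.subset_samples([samples[i] for i in kept])

    y_mean = float(np.mean(y_kept))
    y_sd = float(np.std(y_kept, ddof=1)) if spec.zscore_outputs else 1.0
    if y_sd == 0:
        raise ValueError("outcome has zero variance after outlier removal")
    y_std = (y_kept - y_mean) / y_sd if spec.zscore_outputs else y_kept

    k_folds = min(config.k_folds, len(y_kept) // 2)
    if k_folds < config.k_folds:
        warnings.warn(
            f"fit_signature: reducing folds from {config.k_folds} to {k_folds} "
            f"for n={len(y_kept)}"
        )
    cv = cross_validate(
        Xw,
        y_kept,
        alpha_grid=config.alpha_grid,
        k=k_folds,
        spec=spec,
        seed=config.seed,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        tol=config.cv_tol,
        max_passes=config.max_passes,
    )

    Z_full, params_full = zscore_fit_transform(Xw)
    mask = _screen_mask(Z_full, y_std, spec.alpha_local)
    if not mask.any():
        raise ValueError(
            "no features pass the univariate screen on the full data; "
            "consider raising alpha_local"
        )
    cand_ids = [f for f, m in zip(params_full.feature_ids, mask) if m]
    transform = ZScoreParams(
        feature_ids=cand_ids,
        means=params_full.means[mask],
        sds=params_full.sds[mask],
    )
    Z_cand = Z_full[mask].T  # samples x candidates

    # warm-start down the path to the selected lambda for solver stability
    path = lambda_path(
        Z_cand, y_std, cv.selected_alpha, config.n_lambda, config.lambda_min_ratio
    )
    lambdas = np.append(path[path > cv.selected_lambda], cv.selected_lambda)
    B, passes = _cd_path(
        Z_cand - Z_cand.mean(axis=0),
        y_std - y_std.mean(),
        cv.selected_alpha,
        lambdas,
        config.tol,
        config.max_passes,
    )
    coefs = B[-1]
    beta0 = float(np.mean(y_std) - Z_cand.mean(axis=0) @ coefs)
    obj, penalty = elastic_net_objective(
        Z_cand, y_std, beta0, coefs, cv.selected_alpha, cv.selected_lambda
    )
    kkt = kkt_violation(
        Z_cand - Z_cand.mean(axis=0),
        y_std - np.mean(y_std),
        0.0,
        coefs,
        cv.selected_alpha,
        cv.selected_lambda,
    )
    fit = ElasticNetFit(
        beta0=beta0,
        feature_ids=cand_ids,
        coefs=coefs,
        alpha=cv.selected_alpha,
        lam=cv.selected_lambda,
        n=Z_cand.shape[0],
        p=Z_cand.shape[1],
        objective=obj,
        penalty=penalty,
        n_passes=int(passes.sum()),
        kkt=kkt,
    )
    biotype = {f.feature_id: f.biotype for f in X.features}
    selected = [fid for fid, c in zip(cand_ids, coefs) if c != 0.0]
    return Signature(
        fit=fit,
        transform=transform,
        y_mean=y_mean,
        y_sd=y_sd,
        cv=cv,
        n_features_selected=len(selected),
        n_linc_selected=sum(1 for f in selected if biotype.get(f) == "lincRNA"),
        removed_samples=removed_samples,
        seed=config.seed,
    )


def predict(
    signature: Signature,
    X_new: ExpressionMatrix,
    standardize: str = "stored",
    max_missing_frac: float = 0.10,
) -> np.ndarray:
    """Composite scores b0 + sum_j b_j z_ij in standardized-output units.

    ``standardize="stored"`` applies the training-cohort transform (same
    platform); ``"cohort"`` z-scores each feature within ``X_new`` itself
    (cross-platform translation). Signature features missing from the new
    matrix contribute zero; more than ``max_missing_frac`` missing is an
    error listing them.
    """
    active = [fid for fid, c in zip(signature.fit.feature_ids, signature.fit.coefs)
              if c != 0.0]
    present = set(X_new.feature_ids)
    missing = [f for f in active if f not in present]
    if active and len(missing) > max_missing_frac * len(active):
        raise ValueError(
            f"{len(missing)}/{len(active)} signature features absent from the "
            f"new cohort: {missing[:10]}"
        )
    if missing:
        warnings.warn(
            f"predict: {len(missing)} signature features missing, contributing 0"
        )
    scores = np.full(X_new.shape[1], signature.fit.beta0)
    coef_map = signature.fit.beta
    if standardize == "stored":
        t = signature.transform
        stats = {f: (m, s) for f, m, s in zip(t.feature_ids, t.means, t.sds)}
    elif standardize == "cohort":
        if X_new.shape[1] < 2:
            raise ValueError("cohort standardization requires >= 2 samples")
        stats = None
    else:
        raise ValueError("standardize must be 'stored' or 'cohort'")
    for fid, c in coef_map.items():
        if fid in missing:
            continue
        row = X_new.row(fid)
        if stats is not None:
            m, s = stats[fid]
        else:
            m, s = float(np.mean(row)), float(np.std(row, ddof=1))
            if s == 0:
                continue  # uninformative on this cohort
        scores = scores + c * (row - m) / s
    return scores


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def save_signature(signature: Signature, path) -> None:
    """Serialize a signature (with its frozen transform and CV surface) to a
    versioned JSON document."""
    doc = {
        "format": "pdxsig-signature",
        "version": _FORMAT_VERSION,
        "seed": signature.seed,
        "fit": {
            "beta0": signature.fit.beta0,
            "feature_ids": signature.fit.feature_ids,
            "coefs": signature.fit.coefs.tolist(),
            "alpha": signature.fit.alpha,
            "lam": signature.fit.lam,
            "n": signature.fit.n,
            "p": signature.fit.p,
            "objective": signature.fit.objective,
            "penalty": signature.fit.penalty,
            "n_passes": signature.fit.n_passes,
            "kkt": signature.fit.kkt,
        },
        "transform": {
            "feature_ids": signature.transform.feature_ids,
            "means": signature.transform.means.tolist(),
            "sds": signature.transform.sds.tolist(),
        },
        "y_mean": signature.y_mean,
        "y_sd": signature.y_sd,
        "cv": {
            "selected_alpha": signature.cv.selected_alpha,
            "selected_lambda": signature.cv.selected_lambda,
            "table": signature.cv.table.to_dict(orient="list"),
        },
        "n_features_selected": signature.n_features_selected,
        "n_linc_selected": signature.n_linc_selected,
        "removed_samples": signature.removed_samples,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_signature(path) -> Signature:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "pdxsig-signature":
        raise ValueError(f"{path}: not a pdxsig signature file")
    if doc.get("version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported signature format version")
    f = doc["fit"]
    fit = ElasticNetFit(
        beta0=f["beta0"],
        feature_ids=list(f["feature_ids"]),
        coefs=np.asarray(f["coefs"], dtype=float),
        alpha=f["alpha"],
        lam=f["lam"],
        n=f["n"],
        p=f["p"],
        objective=f["objective"],
        penalty=f["penalty"],
        n_passes=f["n_passes"],
        kkt=f["kkt"],
    )
    t = doc["transform"]
    transform = ZScoreParams(
        feature_ids=list(t["feature_ids"]),
        means=np.asarray(t["means"], dtype=float),
        sds=np.asarray(t["sds"], dtype=float),
    )
    cv = CVResult(
        table=pd.DataFrame(doc["cv"]["table"]),
        selected_alpha=doc["cv"]["selected_alpha"],
        selected_lambda=doc["cv"]["selected_lambda"],
    )
    return Signature(
        fit=fit,
        transform=transform,
        y_mean=doc["y_mean"],
        y_sd=doc["y_sd"],
        cv=cv,
        n_features_selected=doc["n_features_selected"],
        n_linc_selected=doc["n_linc_selected"],
        removed_samples=list(doc["removed_samples"]),
        seed=doc["seed"],
    )
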