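"""Kernel-weighted recursive elastic net for one (target, focal sample) pair.

Each target gene y is regressed on candidate regulators X under Gaussian
kernel weights centred on the focal sample's modulator value, so the
fitted coefficients beta(m_i) vary smoothly with the modulator.  Sparsity
comes from an L1 penalty with adaptive importance weights gamma_j =
1/(|beta_j| + delta) re-estimated recursively; an L2 penalty adds the
elastic net's grouping effect.  Model selection over the (lam1, lam2)
grid uses a bias-corrected weighted AIC with effective sample size
n_eff = sum(w).

Objective convention (per solve, on weighted-standardized data):

    1/2 sum_k w_k (y_k - x_k' beta)^2
        + lam1 sum_j gamma_j |beta_j| + lam2/2 sum_j beta_j^2

under which beta = 0 is optimal exactly when
lam1 >= lam_max = max_j |sum_k w_k x_kj y_k| / gamma_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from . import _cd
from .errors import (
    ConvergenceFailure,
    DegenerateDesign,
    InvalidBandwidth,
    InvalidParameter,
    PseudoinverseFallback,
)
from .io_formats import ModulatorVector

DEFAULT_LAMBDA2_GRID = (0.01, 0.1, 1.0)
DEFAULT_N_LAMBDA1 = 30
DEFAULT_LAMBDA1_MIN_RATIO = 1e-3
DEFAULT_DELTA = 1e-8
DEFAULT_MAX_ITER = 10
DEFAULT_TOL = 1e-7
DEFAULT_MAX_SWEEPS = 100_000


@dataclass
class SolverConfig:
    """Tuning knobs for the per-(target, sample) fit.

    lambda1 values are not given explicitly: for each gamma the solver
    lays ``n_lambda1`` log-spaced points from lam_max (empty model) down
    to ``lambda1_min_ratio * lam_max``.
    """

    lambda2_grid: tuple[float, ...] = DEFAULT_LAMBDA2_GRID
    n_lambda1: int = DEFAULT_N_LAMBDA1
    lambda1_min_ratio: float = DEFAULT_LAMBDA1_MIN_RATIO
    delta: float = DEFAULT_DELTA
    max_iter: int = DEFAULT_MAX_ITER
    tol: float = DEFAULT_TOL
    max_sweeps: int = DEFAULT_MAX_SWEEPS
    standardize: str = "kernel"  # 'kernel' (weighted moments) or 'global'

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise InvalidParameter("delta must be > 0")
        if self.max_iter < 1:
            raise InvalidParameter("max_iter must be >= 1")
        if self.standardize not in ("kernel", "global"):
            raise InvalidParameter("standardize must be 'kernel' or 'global'")


@dataclass
class KernelWeights:
    """Gaussian kernel weights around one focal sample."""

    focal_sample: str | int
    h: float
    w: np.ndarray  # one weight per sample, in (0, 1], focal weight = 1


@dataclass
class ScalingRecord:
    """Weighted-standardization bookkeeping for mapping back to raw scale."""

    y_mean: float
    y_scale: float
    x_mean: np.ndarray  # per kept column
    x_scale: np.ndarray  # per kept column
    kept: np.ndarray  # bool mask over original columns
    dropped: list[int] = field(default_factory=list)


@dataclass
class ElasticNetFit:
    """Result of one recursive fit, on the raw (unstandardized) scale."""

    beta: np.ndarray  # per original predictor column; exact zeros off-support
    intercept: float
    lambda1: float
    lambda2: float
    gamma: np.ndarray  # importance weights of the winning iteration (kept cols)
    df: float
    aicc: float
    iterations_used: int
    target_id: str | None = None
    focal_sample: str | int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.beta


def _gaussian_weights(m: np.ndarray, m_focal: float, h: float) -> np.ndarray:
    if h <= 0:
        raise InvalidBandwidth(f"bandwidth must be > 0, got {h}")
    d = np.asarray(m, dtype=float) - m_focal
    return np.exp(-(d**2) / (2.0 * h * h))


def gaussian_kernel_weights(
    modulator: ModulatorVector | np.ndarray,
    focal_sample: str | int,
    h: float,
) -> KernelWeights:
    """w_k = exp(-(m_k - m_focal)^2 / (2 h^2)).

    ``focal_sample`` is a sample id when ``modulator`` is a
    :class:`ModulatorVector`, else a positional index.
    """
    if isinstance(modulator, ModulatorVector):
        m = modulator.m
        idx = modulator.sample_ids.index(focal_sample)
    else:
        m = np.asarray(modulator, dtype=float)
        idx = int(focal_sample)
    w = _gaussian_weights(m, float(m[idx]), h)
    return KernelWeights(focal_sample=focal_sample, h=float(h), w=w)


def weighted_standardize(
    y: np.ndarray, X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, ScalingRecord]:
    """Center/scale y and each column of X to weighted mean 0, variance 1.

    Weighted moments use the kernel weights, eliminating the intercept
    from the focal-sample loss.  Candidate columns with zero weighted
    variance are dropped (recorded, with a warning), not an error; a
    fully degenerate design raises :class:`DegenerateDesign`.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise InvalidParameter("weights must have positive sum")
    wn = w / sw
    y_mean = float(wn @ y)
    y_var = float(wn @ (y - y_mean) ** 2)
    y_scale = np.sqrt(y_var) if y_var > 0 else 1.0
    y_std = (y - y_mean) / y_scale

    x_mean = wn @ X
    x_var = wn @ (X - x_mean) ** 2
    kept = x_var > 0
    if not kept.any():
        raise DegenerateDesign("every candidate predictor has zero weighted variance")
    dropped = list(np.flatnonzero(~kept))
    if dropped:
        warnings.warn(
            f"{len(dropped)} constant predictor column(s) dropped",
            UserWarning,
            stacklevel=2,
        )
    x_scale = np.sqrt(x_var[kept])
    X_std = (X[:, kept] - x_mean[kept]) / x_scale
    record = ScalingRecord(
        y_mean=y_mean,
        y_scale=y_scale,
        x_mean=x_mean[kept],
        x_scale=x_scale,
        kept=kept,
        dropped=dropped,
    )
    return y_std, X_std, record


def elastic_net_objective(
    beta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    lambda1: float,
    lambda2: float,
    gamma: np.ndarray | None = None,
) -> float:
    """The solver's objective, exposed for oracle comparisons."""
    beta = np.asarray(beta, dtype=float)
    if gamma is None:
        gamma = np.ones_like(beta)
    r = y - X @ beta
    return float(
        0.5 * (w * r**2).sum()
        + lambda1 * (gamma * np.abs(beta)).sum()
        + 0.5 * lambda2 * (beta**2).sum()
    )


def weighted_elastic_net(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    lambda1: float,
    lambda2: float,
    gamma: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> np.ndarray:
    """Solve one weighted elastic-net problem on standardized inputs.

    Deterministic cyclic coordinate descent in input column order;
    convergence when the largest coefficient change in a sweep falls
    below ``tol``.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise InvalidParameter("penalties must be >= 0")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    q = X.shape[1]
    if gamma is None:
        gamma = np.ones(q)
    gamma = np.asarray(gamma, dtype=float)
    if (gamma <= 0).any():
        raise InvalidParameter("gamma must be > 0")
    Xw = X * w[:, None]
    G = X.T @ Xw
    c = Xw.T @ y
    beta = np.zeros(q)
    sweeps = _cd.cd_gram(G, c, float(lambda1), float(lambda2), gamma, beta,
                         float(tol), int(max_sweeps))
    if sweeps == _cd.NONCONVERGED:
        raise ConvergenceFailure(
            f"coordinate descent did not converge in {max_sweeps} sweeps "
            f"(lambda1={lambda1}, lambda2={lambda2}, q={q})"
        )
    return beta


def lambda_max(y: np.ndarray, X: np.ndarray, w: np.ndarray,
               gamma: np.ndarray | None = None) -> float:
    """Smallest lambda1 at which the fitted model is exactly empty."""
    c = (X * w[:, None]).T @ np.asarray(y, dtype=float)
    if gamma is None:
        gamma = np.ones(c.size)
    return float(np.max(np.abs(c) / gamma))


def update_adaptive_weights(beta_prev: np.ndarray, delta: float) -> np.ndarray:
    """gamma_j = 1 / (|beta_prev_j| + delta); delta > 0 avoids division by 0."""
    if delta <= 0:
        raise InvalidParameter("delta must be > 0")
    return 1.0 / (np.abs(np.asarray(beta_prev, dtype=float)) + delta)


def degrees_of_freedom(X_active: np.ndarray, w: np.ndarray, lambda2: float) -> float:
    """df = trace[X_A (X_A' W X_A + lambda2 I)^-1 X_A' W].

    The unbiased ridge-type estimate on the active set; equals |A| at
    lambda2 = 0 with full-rank columns and tends to 0 as lambda2 grows.
    A singular system at lambda2 = 0 falls back to the pseudoinverse with
    a :class:`PseudoinverseFallback` warning.
    """
    X_active = np.atleast_2d(np.asarray(X_active, dtype=float))
    if X_active.shape[1] == 0:
        return 0.0
    w = np.asarray(w, dtype=float)
    G = X_active.T @ (X_active * w[:, None])
    a = G.shape[0]
    M = G + lambda2 * np.eye(a)
    try:
        if lambda2 == 0.0 and np.linalg.matrix_rank(M) < a:
            raise np.linalg.LinAlgError("rank deficient")
        sol = np.linalg.solve(M, G)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular ridge system; using pseudoinverse for df",
            PseudoinverseFallback,
            stacklevel=2,
        )
        sol = np.linalg.pinv(M) @ G
    return float(np.trace(sol))


def weighted_aicc(rss_w: float, df: float, n_eff: float) -> float:
    """Bias-corrected weighted AIC with effective sample size n_eff = sum(w).

    score = n_eff ln(rss_w / n_eff) + 2 df n_eff / (n_eff - df - 1);
    +inf when df >= n_eff - 1 (model inadmissible).  Reduces to the
    classical AICc (up to constants) at uniform unit weights.
    """
    if rss_w <= 0:
        raise InvalidParameter("weighted RSS must be > 0")
    if df >= n_eff - 1.0:
        return np.inf
    return float(n_eff * np.log(rss_w / n_eff)
                 + 2.0 * df * n_eff / (n_eff - df - 1.0))


def fit_target_sample(
    y: np.ndarray,
    X: np.ndarray,
    kernel_weights: KernelWeights | np.ndarray,
    config: SolverConfig | None = None,
    target_id: str | None = None,
    focal_sample: str | int | None = None,
) -> ElasticNetFit:
    """Full recursive fit for one target gene at one focal sample.

    Standardizes under the kernel weights, grid-searches (lam1, lam2) by
    weighted AICc with gamma = 1, then recursively sharpens gamma from
    the winner until AICc stops improving, and maps the incumbent's
    coefficients back to the raw scale.  Coefficients of dropped
    (zero-variance) columns are exact zeros.
    """
    cfg = config or SolverConfig()
    w = kernel_weights.w if isinstance(kernel_weights, KernelWeights) else \
        np.asarray(kernel_weights, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))

    if cfg.standardize == "kernel":
        std_w = w
    else:
        std_w = np.ones_like(w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        y_std, X_std, rec = weighted_standardize(y, X, std_w)

    Xw = X_std * w[:, None]
    G = X_std.T @ Xw
    c = Xw.T @ y_std
    yWy = float(w @ y_std**2)
    n_eff = float(w.sum())

    (beta_std, gamma, df, aicc, lam1, lam2, iters, status) = _cd.fit_recursive_gram(
        G, c, yWy, n_eff,
        np.asarray(cfg.lambda2_grid, dtype=float),
        int(cfg.n_lambda1), float(cfg.lambda1_min_ratio),
        float(cfg.delta), int(cfg.max_iter), float(cfg.tol),
        int(cfg.max_sweeps),
    )
    if status != 0:
        raise ConvergenceFailure(
            f"inner solve hit the sweep budget (target={target_id}, "
            f"sample={focal_sample})"
        )

    beta_raw = np.zeros(X.shape[1])
    beta_kept = beta_std * rec.y_scale / rec.x_scale
    beta_raw[rec.kept] = beta_kept
    intercept = rec.y_mean - float(beta_kept @ rec.x_mean)
    return ElasticNetFit(
        beta=beta_raw,
        intercept=intercept,
        lambda1=float(lam1),
        lambda2=float(lam2),
        gamma=gamma,
        df=float(df),
        aicc=float(aicc),
        iterations_used=int(iters),
        target_id=target_id,
        focal_sample=focal_sample,
    )
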