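"""Bandwidth selection and assembly of the per-sample network ensemble.

The kernel bandwidth h is the one free smoothing parameter: small h
makes each sample's network depend only on modulator-neighbouring
samples, large h collapses all networks onto a single global fit.  h is
chosen by K-fold cross-validation on held-out squared prediction error,
after which every (target, sample) pair is fitted independently and the
nonzero raw-scale coefficients are collected into one network per
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from joblib import Parallel, delayed
from sklearn.model_selection import KFold

from .errors import FoldTooSmall, UnknownIdentifier
from .io_formats import (
    ExpressionMatrix,
    ModulatorVector,
    NetworkEnsemble,
    RegulatorIndex,
    SampleNetwork,
)
from .vc_solver import SolverConfig, _gaussian_weights, fit_target_sample

DEFAULT_FOLDS = 5
DEFAULT_H_GRID_SD_MULTIPLES = (0.25, 0.5, 1.0, 2.0, 4.0)
MIN_TRAIN_SAMPLES = 10


@dataclass
class BandwidthSelection:
    """Cross-validation record for the bandwidth grid."""

    h_grid: list[float]
    cv_error: list[float]
    folds: int
    seed: int
    h_star: float


def default_h_grid(modulator: ModulatorVector) -> list[float]:
    """Multiples of SD(m): {0.25, 0.5, 1, 2, 4} x SD(m)."""
    sd = float(np.std(modulator.m))
    return [k * sd for k in DEFAULT_H_GRID_SD_MULTIPLES]


def _design(expr: ExpressionMatrix, regulators: RegulatorIndex, target: str):
    """Regressor block for one target: all regulators except the target."""
    reg_ids = [r for r in regulators.regulator_ids if r != target]
    X = expr.rows(reg_ids).T  # samples x q
    y = expr.row(target)
    return y, X, reg_ids


def select_bandwidth(
    expr: ExpressionMatrix,
    regulators: RegulatorIndex,
    targets: list[str],
    modulator: ModulatorVector,
    h_grid: list[float] | None = None,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    solver_config: SolverConfig | None = None,
) -> BandwidthSelection:
    """Choose h by K-fold CV on held-out squared prediction error.

    Each held-out sample's model is fitted from training samples only,
    with kernel weights computed between training modulator values and
    the held-out sample's modulator value; the CV error for one h is the
    mean squared raw-scale prediction error over all targets and
    held-out samples.  Ties in CV error resolve to the larger h
    (smoother model).  Deterministic given the seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not targets:
        raise ValueError("targets must be nonempty")
    regulators.validate_against(expr)
    modulator.validate_against(expr)
    if h_grid is None:
        h_grid = default_h_grid(modulator)
    if not h_grid:
        raise ValueError("h_grid must be nonempty")
    cfg = solver_config or SolverConfig()
    m = modulator.m
    n = expr.n_samples

    designs = [_design(expr, regulators, t) for t in targets]
    splits = list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(
        np.arange(n)))
    for train_idx, _ in splits:
        if len(train_idx) < MIN_TRAIN_SAMPLES:
            raise FoldTooSmall(
                f"fold leaves only {len(train_idx)} training samples"
            )

    cv_error = []
    for h in h_grid:
        sq_err_sum = 0.0
        count = 0
        for train_idx, test_idx in splits:
            m_train = m[train_idx]
            for y, X, _ in designs:
                y_tr, X_tr = y[train_idx], X[train_idx]
                for i in test_idx:
                    w = _gaussian_weights(m_train, float(m[i]), h)
                    fit = fit_target_sample(y_tr, X_tr, w, config=cfg)
                    pred = fit.intercept + float(X[i] @ fit.beta)
                    sq_err_sum += (y[i] - pred) ** 2
                    count += 1
        cv_error.append(sq_err_sum / count)

    # minimum CV error; ties go to the larger h
    best = 0
    for k in range(1, len(h_grid)):
        if cv_error[k] < cv_error[best] or (
            cv_error[k] == cv_error[best] and h_grid[k] > h_grid[best]
        ):
            best = k
    return BandwidthSelection(
        h_grid=[float(h) for h in h_grid],
        cv_error=cv_error,
        folds=folds,
        seed=seed,
        h_star=float(h_grid[best]),
    )


def _fit_one_target(y, X, reg_ids, target, m, h, cfg):
    """Per-sample fits for one target; returns per-sample edge fragments."""
    per_sample_edges = []
    for i in range(len(m)):
        w = _gaussian_weights(m, float(m[i]), h)
        fit = fit_target_sample(y, X, w, config=cfg,
                                target_id=target, focal_sample=i)
        edges = {
            (reg_ids[j], target): float(fit.beta[j])
            for j in np.flatnonzero(fit.beta)
        }
        per_sample_edges.append(edges)
    return per_sample_edges


def infer_networks(
    expr: ExpressionMatrix,
    regulators: RegulatorIndex,
    targets: list[str],
    modulator: ModulatorVector,
    h: float,
    solver_config: SolverConfig | None = None,
    parallel_hint: int = 1,
) -> NetworkEnsemble:
    """Fit every (target, sample) pair and assemble one network per sample.

    When a target is itself a regulator it is excluded from its own
    regressor set, so no self-edges can arise.  Per-target tasks are
    independent; ``parallel_hint`` workers only change scheduling, never
    the result, and fragments are merged in canonical (target-order)
    sequence.
    """
    regulators.validate_against(expr)
    modulator.validate_against(expr)
    unknown = [t for t in targets if t not in expr._gene_pos]
    if unknown:
        raise UnknownIdentifier(f"targets absent from matrix: {unknown[:5]}")
    cfg = solver_config or SolverConfig()
    m = modulator.m

    tasks = [(_design(expr, regulators, t), t) for t in targets]
    if parallel_hint > 1:
        results = Parallel(n_jobs=parallel_hint)(
            delayed(_fit_one_target)(y, X, reg_ids, t, m, h, cfg)
            for (y, X, reg_ids), t in tasks
        )
    else:
        results = [
            _fit_one_target(y, X, reg_ids, t, m, h, cfg)
            for (y, X, reg_ids), t in tasks
        ]

    networks = []
    for i, sid in enumerate(expr.sample_ids):
        edges: dict[tuple[str, str], float] = {}
        for per_sample_edges in results:
            edges.update(per_sample_edges[i])
        networks.append(SampleNetwork(sample_id=sid, edges=edges))
    return NetworkEnsemble(
        networks=networks,
        regulator_ids=list(regulators.regulator_ids),
        target_ids=list(targets),
        provenance={"h": float(h), "solver": asdict(cfg)},
    )
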