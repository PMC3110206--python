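"""Synthetic datasets with the exact structure the inference assumes.

Three generators, each a pure function of (parameters, seed):

* ``generate_switch_scenario`` — a varying-coefficient regression where
  one regulator's effect on the target switches from ``low_coef`` to
  ``high_coef`` at a modulator threshold while decoy regulators carry
  zero coefficients.  This is the canonical "X regulates Y only at high
  modulator" picture, with the planted coefficient functions recorded.
* ``generate_factor_scenario`` — a single-latent-factor block
  x_gi = mu_g + b_g z_i + eps for modulator-extraction tests; the true
  z is recorded.
* ``generate_gsa_scenario`` — a switch scenario whose planted
  regulator's high-modulator targets are drawn from one designated gene
  set, plus the GMT-style sets, for end-to-end enrichment tests.

Modulator values are emitted sorted ascending on [-1, 1] so that the
generated data reads left-to-right along the transition; pass
``permute=True`` to scramble sample order (inference must not care).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    ModulatorVector,
    RegulatorIndex,
)

M_INTERVAL = (-1.0, 1.0)


@dataclass
class SyntheticScenario:
    """A generated dataset plus its complete planted truth."""

    expr: ExpressionMatrix
    modulator: ModulatorVector
    true_coefficients: dict[tuple[str, str], np.ndarray]  # per-sample values
    regulator_index: RegulatorIndex
    gene_sets: GeneSetCollection | None
    seed: int
    noise_sd: float
    truth: dict = field(default_factory=dict)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i+1:04d}" for i in range(n)]


def _modulator_values(rng: np.random.Generator, n: int, permute: bool) -> np.ndarray:
    m = rng.uniform(M_INTERVAL[0], M_INTERVAL[1], size=n)
    m.sort()
    if permute:
        m = m[rng.permutation(n)]
    return m


def switch_coefficient(
    m: np.ndarray,
    switch_location: float,
    low_coef: float,
    high_coef: float,
    smooth_scale: float | None = None,
) -> np.ndarray:
    """Coefficient function of the planted edge: a step (or logistic ramp)."""
    m = np.asarray(m, dtype=float)
    if smooth_scale is None:
        return np.where(m < switch_location, low_coef, high_coef)
    s = 1.0 / (1.0 + np.exp(-(m - switch_location) / smooth_scale))
    return low_coef + (high_coef - low_coef) * s


def generate_switch_scenario(
    n_samples: int = 1000,
    n_regulators: int = 12,
    switch_location: float = 0.0,
    low_coef: float = 0.0,
    high_coef: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    smooth_scale: float | None = None,
    permute: bool = False,
) -> SyntheticScenario:
    """One target, one switching regulator, ``n_regulators - 1`` decoys."""
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    m = _modulator_values(rng, n_samples, permute)
    reg_ids = [f"R{j+1:02d}" for j in range(n_regulators)]
    target_id = "TGT"
    X = rng.standard_normal((n_regulators, n_samples))
    beta = switch_coefficient(m, switch_location, low_coef, high_coef, smooth_scale)
    y = beta * X[0] + noise_sd * rng.standard_normal(n_samples)

    sample_ids = _sample_ids(n_samples)
    expr = ExpressionMatrix(
        gene_ids=reg_ids + [target_id],
        sample_ids=sample_ids,
        values=np.vstack([X, y]),
    )
    true_coefficients = {(reg_ids[0], target_id): beta}
    for rid in reg_ids[1:]:
        true_coefficients[(rid, target_id)] = np.zeros(n_samples)
    return SyntheticScenario(
        expr=expr,
        modulator=ModulatorVector(sample_ids=sample_ids, m=m),
        true_coefficients=true_coefficients,
        regulator_index=RegulatorIndex(regulator_ids=list(reg_ids)),
        gene_sets=None,
        seed=seed,
        noise_sd=noise_sd,
        truth={
            "switching_regulator": reg_ids[0],
            "target": target_id,
            "switch_location": switch_location,
            "low_coef": low_coef,
            "high_coef": high_coef,
        },
    )


def generate_factor_scenario(
    n_genes: int = 50,
    n_samples: int = 200,
    loading_scale: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticScenario:
    """Single-factor block: x_gi = mu_g + b_g z_i + eps, b_g = +-loading_scale."""
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    b = signs * loading_scale
    mu = rng.standard_normal(n_genes)
    values = mu[:, None] + np.outer(b, z) + noise_sd * rng.standard_normal(
        (n_genes, n_samples)
    )
    gene_ids = [f"G{j+1:03d}" for j in range(n_genes)]
    sample_ids = _sample_ids(n_samples)
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    return SyntheticScenario(
        expr=expr,
        modulator=ModulatorVector(sample_ids=sample_ids, m=z),
        true_coefficients={},
        regulator_index=RegulatorIndex(regulator_ids=[gene_ids[0]]),
        gene_sets=None,
        seed=seed,
        noise_sd=noise_sd,
        truth={"z": z, "loadings": b, "intercepts": mu},
    )


def generate_gsa_scenario(
    n_genes: int = 48,
    n_samples: int = 120,
    n_sets: int = 3,
    planted_regulator_fraction: float = 0.125,
    seed: int = 0,
    noise_sd: float = 0.3,
    targets_per_regulator: int = 8,
    decoy_coef: float = 0.8,
) -> SyntheticScenario:
    """Switch scenario with set-concentrated planted targets.

    ``n_genes`` splits into regulators (a ``planted_regulator_fraction``
    share, at least 3) and target genes; the target genes partition into
    ``n_sets`` equal gene sets.  The planted regulator acquires
    ``targets_per_regulator`` targets drawn from the first set, active
    only above the modulator switch; every decoy regulator gets the same
    number of targets drawn from the whole pool with a constant
    coefficient, so only the planted regulator's enrichment changes
    along the modulator.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    n_regulators = max(3, int(round(planted_regulator_fraction * n_genes)))
    n_targets = n_genes - n_regulators
    if n_targets < n_sets * 2:
        raise ValueError("too few target genes for the requested number of sets")
    reg_ids = [f"R{j+1:02d}" for j in range(n_regulators)]
    target_ids = [f"T{j+1:03d}" for j in range(n_targets)]
    sample_ids = _sample_ids(n_samples)

    chunks = np.array_split(np.arange(n_targets), n_sets)
    sets = {
        f"SET{c+1}": [target_ids[i] for i in idx] for c, idx in enumerate(chunks)
    }
    gene_sets = GeneSetCollection(sets=sets, descriptions={})

    m = _modulator_values(rng, n_samples, permute=False)
    Xr = rng.standard_normal((n_regulators, n_samples))
    beta_on = switch_coefficient(m, 0.0, 0.0, 1.0)

    planted = reg_ids[0]
    k = min(targets_per_regulator, len(sets["SET1"]))
    planted_targets = list(rng.choice(sets["SET1"], size=k, replace=False))
    true_coefficients: dict[tuple[str, str], np.ndarray] = {}
    contributions = np.zeros((n_targets, n_samples))
    tpos = {t: i for i, t in enumerate(target_ids)}
    for t in planted_targets:
        true_coefficients[(planted, t)] = beta_on
        contributions[tpos[t]] += beta_on * Xr[0]
    for r_idx, rid in enumerate(reg_ids[1:], start=1):
        decoys = rng.choice(target_ids, size=k, replace=False)
        sign = rng.choice([-1.0, 1.0])
        for t in decoys:
            coef = np.full(n_samples, sign * decoy_coef)
            true_coefficients[(rid, t)] = (
                true_coefficients.get((rid, t), 0) + coef
            )
            contributions[tpos[t]] += coef * Xr[r_idx]
    Yt = contributions + noise_sd * rng.standard_normal((n_targets, n_samples))

    expr = ExpressionMatrix(
        gene_ids=reg_ids + target_ids,
        sample_ids=sample_ids,
        values=np.vstack([Xr, Yt]),
    )
    return SyntheticScenario(
        expr=expr,
        modulator=ModulatorVector(sample_ids=sample_ids, m=m),
        true_coefficients=true_coefficients,
        regulator_index=RegulatorIndex(regulator_ids=list(reg_ids)),
        gene_sets=gene_sets,
        seed=seed,
        noise_sd=noise_sd,
        truth={
            "planted_regulator": planted,
            "planted_set": "SET1",
            "planted_targets": planted_targets,
            "target_ids": target_ids,
        },
    )
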