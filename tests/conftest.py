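"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from vcgrn import ExpressionMatrix, ModulatorVector, RegulatorIndex, SampleNetwork


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["CDH1", "ZEB1", "VIM"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


def random_sparse_network(rng: np.random.Generator,
                          n_regulators: int = 10,
                          n_targets: int = 15,
                          edge_prob: float = 0.15) -> SampleNetwork:
    """Random network respecting the model: only regulators emit edges."""
    regs = [f"R{j}" for j in range(n_regulators)]
    tgts = [f"T{j}" for j in range(n_targets)]
    edges = {}
    for r in regs:
        for node in regs + tgts:
            if node == r:
                continue
            if rng.random() < edge_prob:
                coef = float(rng.normal())
                if coef != 0.0:
                    edges[(r, node)] = coef
    return SampleNetwork(sample_id="s", edges=edges)


def brute_force_paths(network: SampleNetwork, regulator: str, target: str,
                      max_path_length: int) -> list[tuple[str, ...]]:
    """Exhaustive DFS path enumeration, independent of the package routines."""
    found = []

    def walk(node, path):
        if len(path) - 1 > max_path_length:
            return
        if node == target and len(path) > 1:
            found.append(tuple(path))
            return
        if len(path) - 1 == max_path_length:
            return
        for (a, b) in network.edges:
            if a == node and b not in path:
                walk(b, path + [b])

    walk(regulator, [regulator])
    return found


def brute_force_effect(network: SampleNetwork, regulator: str, target: str,
                       max_path_length: int) -> float:
    total = 0.0
    for path in sorted(brute_force_paths(network, regulator, target,
                                         max_path_length)):
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= network.edges[(a, b)]
        total += prod
    return total


def convex_oracle_enet(y, X, w, lam1, lam2, gamma):
    """Independent convex solver for the weighted elastic net.

    Positive/negative splitting beta = bp - bn turns the L1 term into a
    smooth bound-constrained program solved by L-BFGS-B.
    """
    q = X.shape[1]

    def f(z):
        beta = z[:q] - z[q:]
        r = y - X @ beta
        return (0.5 * np.sum(w * r * r) + lam1 * np.sum(gamma * (z[:q] + z[q:]))
                + 0.5 * lam2 * np.sum(beta * beta))

    def g(z):
        beta = z[:q] - z[q:]
        gs = -(X.T * w) @ (y - X @ beta) + lam2 * beta
        return np.concatenate([gs + lam1 * gamma, -gs + lam1 * gamma])

    res = minimize(f, np.zeros(2 * q), jac=g, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * q),
                   options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x[:q] - res.x[q:]


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Hand-written Benjamini-Hochberg step-up with monotonicity."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def toy_modulated_design(seed: int, n: int = 200, q: int = 5,
                         noise_sd: float = 0.3):
    """Constant-coefficient truth: no modulator dependence at all."""
    rng = np.random.default_rng(seed)
    m = np.sort(rng.uniform(-1, 1, n))
    Xr = rng.standard_normal((q, n))
    beta = np.zeros(q)
    beta[:2] = [0.8, -0.5]
    y = beta @ Xr + noise_sd * rng.standard_normal(n)
    gene_ids = [f"R{j}" for j in range(q)] + ["TGT"]
    sample_ids = [f"S{i}" for i in range(n)]
    expr = ExpressionMatrix(gene_ids, sample_ids, np.vstack([Xr, y]))
    mod = ModulatorVector(sample_ids, m)
    regs = RegulatorIndex([f"R{j}" for j in range(q)])
    return expr, regs, mod
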