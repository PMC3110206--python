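"""Signature-based hidden modulator extraction.

When the biological variable that modulates regulatory strengths (e.g.
EMT progression) is not directly observed, it can be estimated from a
seed signature: genes believed to co-vary with the transition.  The
model is a single-factor model

    x_gi = mu_g + b_g * z_i + eps_gi

with a latent per-sample score z.  The pipeline is (1) refine the seed
to an expression-coherent subset, (2) score samples by the largest
principal component of the retained genes' row-centered submatrix, and
(3) orient the global sign against an anchor gene so that, e.g.,
epithelial-like samples receive low scores.

The coherence step is an iterative leave-worst-out refinement against
the subset eigengene with an absolute-correlation floor: a lightweight
stand-in for seed-refinement module extraction, exposing the floor and
minimum size as explicit parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    CoherenceFailure,
    DegenerateInput,
    EmptySeed,
    OrientationAmbiguous,
)
from .io_formats import ExpressionMatrix, ModulatorVector

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_FLOOR = 0.5
DEFAULT_MIN_SIZE = 10


@dataclass
class FactorModelFit:
    """First-principal-component fit of the single-factor model."""

    member_ids: list[str]
    loadings: np.ndarray  # b_g, one per retained gene
    scores: np.ndarray  # z_i, one per sample, mean 0, unit variance
    explained_variance_fraction: float
    sample_ids: list[str]


def _first_pc_scores(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """SVD of the row-centered submatrix; returns (scores, loadings, evf).

    Rows (genes) are mean-centered, columns are not, so sample scores
    retain between-sample structure; row-centering removes the gene
    intercepts mu_g of the factor model.  Because every centered row sums
    to zero the leading right singular vector has exactly zero mean.
    """
    centered = sub - sub.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise DegenerateInput("all member genes are constant across samples")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt[0]
    sd = scores.std()  # population SD; scores have zero mean by construction
    scores = scores / sd
    loadings = u[:, 0] * s[0]
    evf = float(s[0] ** 2 / np.sum(s**2))
    # deterministic sign convention pre-orientation: majority-positive loadings
    if np.sum(loadings) < 0:
        scores, loadings = -scores, -loadings
    return scores, loadings, evf


def coherence_filter(
    seed_ids: Sequence[str],
    expr: ExpressionMatrix,
    correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[str]:
    """Refine a seed gene set to an expression-coherent subset.

    Iteratively computes the first principal component (eigengene) of the
    current subset and drops the single gene whose absolute Pearson
    correlation with it is lowest, until every retained gene clears
    ``correlation_floor``.  Raises :class:`CoherenceFailure` if fewer than
    ``min_size`` genes survive, and :class:`EmptySeed` if the seed shares
    no genes with the matrix.
    """
    members = [g for g in seed_ids if g in expr._gene_pos]
    if not members:
        raise EmptySeed("seed gene set disjoint from expression matrix")
    dropped = [g for g in seed_ids if g not in expr._gene_pos]
    if dropped:
        logger.info("coherence_filter: %d seed genes absent from matrix", len(dropped))
    while True:
        if len(members) < max(min_size, 2):
            raise CoherenceFailure(
                f"only {len(members)} genes survive coherence filtering "
                f"(min_size={min_size})"
            )
        sub = expr.rows(members)
        scores, _, _ = _first_pc_scores(sub)
        cors = np.empty(len(members))
        for i, row in enumerate(sub):
            sd = row.std()
            cors[i] = 0.0 if sd == 0 else np.corrcoef(row, scores)[0, 1]
        worst = int(np.argmin(np.abs(cors)))
        if abs(cors[worst]) >= correlation_floor:
            return members
        logger.debug("dropping %s (|r|=%.3f)", members[worst], abs(cors[worst]))
        members = members[:worst] + members[worst + 1:]


def extract_hidden_modulator(
    expr: ExpressionMatrix, member_ids: Sequence[str]
) -> FactorModelFit:
    """Score samples by the largest principal component of member genes.

    Scores are the leading right singular vector of the row-centered
    member submatrix, scaled to unit variance; loadings are the matching
    left singular vector times the singular value.  Under Gaussian
    equal-variance noise this is the maximum-likelihood fit of the
    single-factor model.
    """
    members = list(member_ids)
    if len(members) < 2:
        raise DegenerateInput("need at least 2 member genes")
    if expr.n_samples < 3:
        raise DegenerateInput("need at least 3 samples")
    sub = expr.rows(members)
    scores, loadings, evf = _first_pc_scores(sub)
    return FactorModelFit(
        member_ids=members,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=evf,
        sample_ids=list(expr.sample_ids),
    )


def orient_modulator(
    fit: FactorModelFit,
    anchor_gene: str,
    expr: ExpressionMatrix,
    desired_sign: int = -1,
) -> ModulatorVector:
    """Fix the global sign of the scores against an anchor gene.

    If the sign of corr(scores, anchor expression) differs from
    ``desired_sign`` the scores are negated.  The default ``-1`` mirrors
    the convention that samples expressing the anchor highly (e.g.
    E-cadherin for epithelial identity) sit at low modulator values.  A
    zero correlation leaves the sign as-is and emits an
    :class:`OrientationAmbiguous` warning.
    """
    if desired_sign not in (-1, 1):
        raise ValueError("desired_sign must be -1 or +1")
    anchor = expr.row(anchor_gene)
    scores = fit.scores.copy()
    if anchor.std() == 0 or scores.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(scores, anchor)[0, 1])
    if r == 0.0 or not np.isfinite(r):
        warnings.warn(
            f"anchor gene {anchor_gene!r} uncorrelated with scores; "
            "sign left as-is",
            OrientationAmbiguous,
            stacklevel=2,
        )
    elif np.sign(r) != desired_sign:
        scores = -scores
    return ModulatorVector(sample_ids=list(fit.sample_ids), m=scores)
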