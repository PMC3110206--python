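"""Path-product regulatory effects and regulator ranking by effect change.

The regulatory effect of regulator j on target l in sample i sums, over
all directed paths of length <= 2 from j to l in that sample's network,
the product of the edge coefficients along each path.  Stacking the
effect over regulators and samples gives an effect profile; the spread
of a regulator's effect across samples (max - min, or a percentile
analogue) measures how strongly the modulator reshapes its influence
and ranks candidate master regulators.

Only regulators have outgoing edges in this model, so intermediate path
nodes are regulators by construction; node repeats are banned, which
rules out cycles at these path lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInput, InvalidParameter, UnknownIdentifier
from .io_formats import NetworkEnsemble, SampleNetwork


@dataclass
class EffectProfile:
    """Regulators x samples matrix of path-summed effects for one target."""

    target_id: str
    regulator_ids: list[str]
    sample_ids: list[str]
    max_path_length: int
    effects: np.ndarray  # (n_regulators, n_samples), signed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects, index=self.regulator_ids,
                            columns=self.sample_ids)


@dataclass
class EffectChangeTable:
    """Per-regulator effect change, activator/inhibitor label and rank."""

    table: pd.DataFrame  # index regulator; columns change, mode_label, rank
    method: str


def _check_length(max_path_length: int) -> None:
    if max_path_length not in (1, 2):
        raise InvalidParameter("max_path_length must be 1 or 2")


def enumerate_paths(
    network: SampleNetwork, regulator: str, target: str, max_path_length: int = 2
) -> list[tuple[str, ...]]:
    """All directed paths regulator -> ... -> target of length <= 2.

    A node never repeats within a path; the empty list is a valid result.
    """
    _check_length(max_path_length)
    paths: list[tuple[str, ...]] = []
    if (regulator, target) in network.edges:
        paths.append((regulator, target))
    if max_path_length >= 2:
        for mid in network.children(regulator):
            if mid in (regulator, target):
                continue
            if (mid, target) in network.edges:
                paths.append((regulator, mid, target))
    return paths


def regulatory_effect(
    network: SampleNetwork, regulator: str, target: str, max_path_length: int = 2
) -> float:
    """Sum over paths of the product of edge coefficients along each path."""
    total = 0.0
    for path in enumerate_paths(network, regulator, target, max_path_length):
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= network.edges[(a, b)]
        total += prod
    return total


def effect_profile(
    ensemble: NetworkEnsemble, target: str, max_path_length: int = 2
) -> EffectProfile:
    """Regulatory effect of every regulator on ``target`` in every sample."""
    _check_length(max_path_length)
    vocabulary = set(ensemble.target_ids) | set(ensemble.regulator_ids)
    if target not in vocabulary:
        raise UnknownIdentifier(f"target {target!r} not in ensemble vocabulary")
    regs = ensemble.regulator_ids
    effects = np.zeros((len(regs), len(ensemble.networks)))
    for i, net in enumerate(ensemble.networks):
        for j, reg in enumerate(regs):
            effects[j, i] = regulatory_effect(net, reg, target, max_path_length)
    return EffectProfile(
        target_id=target,
        regulator_ids=list(regs),
        sample_ids=ensemble.sample_ids,
        max_path_length=max_path_length,
        effects=effects,
    )


def effect_change(
    profile: EffectProfile,
    method: str = "max_min",
    p_lo: float = 5.0,
    p_hi: float = 95.0,
) -> EffectChangeTable:
    """Spread of each regulator's effect across samples, with A/I label.

    ``max_min`` is max_i e_j^(i) - min_i e_j^(i); ``percentile`` replaces
    the extremes with the (p_lo, p_hi) percentiles for robustness at some
    loss of power.  The mode label is 'A' (activator) when the effect
    value of largest magnitude across samples is positive, else 'I'
    (inhibitor) — a stated convention, since only the labels themselves
    are standard.  Ranking is by descending change, ties by regulator id.
    """
    if profile.effects.size == 0:
        raise EmptyInput("effect profile is empty")
    if method not in ("max_min", "percentile"):
        raise InvalidParameter(f"unknown method {method!r}")
    E = profile.effects
    if method == "max_min":
        change = E.max(axis=1) - E.min(axis=1)
        method_record = "max_min"
    else:
        if not (0 <= p_lo < p_hi <= 100):
            raise InvalidParameter("need 0 <= p_lo < p_hi <= 100")
        lo = np.percentile(E, p_lo, axis=1)
        hi = np.percentile(E, p_hi, axis=1)
        change = hi - lo
        method_record = f"percentile({p_lo},{p_hi})"
    extreme = E[np.arange(E.shape[0]), np.argmax(np.abs(E), axis=1)]
    labels = np.where(extreme > 0, "A", "I")
    df = pd.DataFrame(
        {"change": change, "mode_label": labels},
        index=pd.Index(profile.regulator_ids, name="regulator"),
    )
    order = df.sort_values(
        ["change", "regulator"], ascending=[False, True], kind="mergesort"
    ).index
    df.loc[order, "rank"] = np.arange(1, len(order) + 1, dtype=int)
    df["rank"] = df["rank"].astype(int)
    return EffectChangeTable(table=df, method=method_record)
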