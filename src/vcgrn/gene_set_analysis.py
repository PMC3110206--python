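"""Modulator-dependent gene-set enrichment of regulator target sets.

For each sample and each regulator, the regulator's downstream targets
in that sample's network are tested for over-representation in each
functional gene set with a one-sided Fisher exact (hypergeometric
upper-tail) test against the full gene universe, followed by
Benjamini-Hochberg correction.  How the significance *changes* along
the modulator is summarised per (regulator, set) as the enrichment
score

    E = max_i(-log10 q_i) - min_i(-log10 q_i)

and per regulator as the total score T = 2 ln(10) * sum_c E_c, referred
to a chi-square distribution with 2L degrees of freedom (L = number of
sets) to give an "integral" p-value — Fisher's combination of the L
per-set changes.  Regulators with small integral p are candidate master
regulators of the modulated process.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInput, InvalidInput, InvalidParameter
from .io_formats import GeneSetCollection, NetworkEnsemble, SampleNetwork
from .regulatory_effect import regulatory_effect

LN10 = float(np.log(10.0))


@dataclass
class EnrichmentTable:
    """All per-test and per-regulator enrichment results.

    ``tests``: long table (sample, regulator, set, p, q).
    ``scores``: regulators x sets matrix of enrichment scores E.
    ``totals``: per regulator total score T and integral p, sorted by
    ascending integral p (ties by regulator id).
    """

    tests: pd.DataFrame
    scores: pd.DataFrame
    totals: pd.DataFrame
    bh_family: str
    max_path_length: int

    def to_tsv(self, path: str | Path) -> None:
        """Regulators in rows, sets in columns (E values), final integral_p."""
        out = self.scores.loc[self.totals.index].copy()
        out["integral_p"] = self.totals["integral_p"]
        out.to_csv(path, sep="\t", index_label="regulator")


def downstream_target_set(
    network: SampleNetwork, regulator: str, max_path_length: int = 1
) -> set[str]:
    """Genes with a nonzero regulatory effect from ``regulator``.

    At path length 1 these are the direct children; at length 2, genes
    reachable through one intermediate regulator are included unless
    their path products cancel exactly.
    """
    if max_path_length not in (1, 2):
        raise InvalidParameter("max_path_length must be 1 or 2")
    candidates = set(network.children(regulator))
    if max_path_length == 2:
        for mid in network.children(regulator):
            candidates.update(network.children(mid))
    candidates.discard(regulator)
    return {
        g for g in candidates
        if regulatory_effect(network, regulator, g, max_path_length) != 0.0
    }


def fisher_enrichment(
    target_set: Iterable[str],
    functional_set: Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-sided Fisher exact p for over-representation.

    The upper-tail hypergeometric probability of drawing at least the
    observed overlap when |target_set| genes are sampled uniformly from
    the universe — no continuity correction, exact tail always.
    """
    universe = set(universe)
    if not universe:
        raise InvalidInput("empty gene universe")
    targets = set(target_set) & universe
    functional = set(functional_set) & universe
    overlap = len(targets & functional)
    return float(
        hypergeom.sf(overlap - 1, len(universe), len(functional), len(targets))
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise InvalidParameter("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_score(q_across_samples: Sequence[float]) -> float:
    """E = max_i(-log10 q_i) - min_i(-log10 q_i) >= 0."""
    q = np.asarray(list(q_across_samples), dtype=float)
    if q.size == 0:
        raise EmptyInput("no q-values supplied")
    if (q <= 0).any() or (q > 1).any():
        raise InvalidParameter("q-values must lie in (0, 1]")
    neglog = -np.log10(q)
    return float(neglog.max() - neglog.min())


def integral_pvalue(E_per_set: Sequence[float]) -> tuple[float, float]:
    """Fisher-combine per-set enrichment scores.

    T = 2 ln(10) sum_c E_c converts the base-10 scores to the natural-log
    scale of Fisher's statistic; under the global null T ~ chi-square
    with 2L degrees of freedom, L the number of sets.  Returns (T, p).
    """
    E = np.asarray(list(E_per_set), dtype=float)
    if E.size == 0:
        raise EmptyInput("no enrichment scores supplied")
    if (E < 0).any():
        raise InvalidParameter("enrichment scores must be >= 0")
    T = float(2.0 * LN10 * E.sum())
    p = float(chi2.sf(T, df=2 * E.size))
    return T, p


def run_gsa(
    ensemble: NetworkEnsemble,
    gene_sets: GeneSetCollection,
    regulators: Sequence[str],
    universe: Iterable[str],
    max_path_length: int = 1,
    bh_family: str = "sample",
    use_p: bool = False,
) -> EnrichmentTable:
    """Full enrichment analysis over (sample, regulator, set).

    BH correction is applied within each sample across all
    (regulator, set) tests by default (``bh_family='sample'``), or within
    each (sample, regulator) across sets (``bh_family='regulator'``).
    ``use_p`` computes enrichment scores from raw p-values instead of
    q-values.  Output ``totals`` is sorted by ascending integral p.
    """
    if not gene_sets.sets or not len(regulators):
        raise EmptyInput("need at least one gene set and one regulator")
    if bh_family not in ("sample", "regulator"):
        raise InvalidParameter("bh_family must be 'sample' or 'regulator'")
    universe = set(universe)
    set_names = gene_sets.names()
    members = {name: set(gene_sets[name]) & universe for name in set_names}

    records = []
    for net in ensemble.networks:
        sample_p = []
        for reg in regulators:
            targets = downstream_target_set(net, reg, max_path_length)
            for name in set_names:
                p = fisher_enrichment(targets, members[name], universe)
                sample_p.append(p)
        sample_p = np.asarray(sample_p)
        if bh_family == "sample":
            q = bh_adjust(sample_p)
        else:
            q = np.empty_like(sample_p)
            L = len(set_names)
            for r in range(len(regulators)):
                sl = slice(r * L, (r + 1) * L)
                q[sl] = bh_adjust(sample_p[sl])
        k = 0
        for reg in regulators:
            for name in set_names:
                records.append((net.sample_id, reg, name, sample_p[k], q[k]))
                k += 1
    tests = pd.DataFrame(
        records, columns=["sample", "regulator", "set", "p", "q"]
    )

    basis = "p" if use_p else "q"
    scores = pd.DataFrame(index=pd.Index(list(regulators), name="regulator"),
                          columns=set_names, dtype=float)
    for (reg, name), grp in tests.groupby(["regulator", "set"], sort=False):
        scores.loc[reg, name] = enrichment_score(grp[basis].to_numpy())

    totals = pd.DataFrame(index=scores.index,
                          columns=["total_score", "integral_p"], dtype=float)
    for reg in scores.index:
        T, p = integral_pvalue(scores.loc[reg].to_numpy(dtype=float))
        totals.loc[reg] = [T, p]
    totals = totals.sort_values(
        ["integral_p", "regulator"], ascending=[True, True], kind="mergesort"
    )
    return EnrichmentTable(
        tests=tests,
        scores=scores,
        totals=totals,
        bh_family=bh_family,
        max_path_length=max_path_length,
    )
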