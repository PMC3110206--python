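"""Domain types and on-disk formats.

The universal input is a genes x samples matrix of log-scale expression
values (TSV: first column gene id, header row of sample ids).  Gene sets
arrive as GMT, regulator lists as one id per line (optional second column
class), per-sample modulator values as two-column TSV, and inferred
network ensembles leave as a deterministic TSV edge list.

Identifiers are opaque strings throughout: probe-to-gene collapsing and
normalisation are assumed to have happened upstream.  Sample order in a
file is a contract — loaders never reorder, so an expression matrix and a
modulator file produced together stay aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifier,
    EmptyInput,
    IOFailure,
    MissingValue,
    ParseError,
    UnknownIdentifier,
)

logger = logging.getLogger(__name__)

REGULATOR_CLASSES = ("TF", "nuclear_receptor", "miRNA", "other")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples log-expression values with unique identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64, no NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with identifier lists")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise MissingValue("expression matrix contains non-finite values")
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_pos[gene_id]]
        except KeyError:
            raise UnknownIdentifier(f"gene {gene_id!r} not in expression matrix")

    def rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        return np.vstack([self.row(g) for g in gene_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class RegulatorIndex:
    """Candidate parent genes (TFs, nuclear receptors, miRNAs)."""

    regulator_ids: list[str]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regulator_ids:
            raise EmptyInput("regulator index is empty")
        _check_unique(self.regulator_ids, "regulator")
        for rid in self.regulator_ids:
            self.classes.setdefault(rid, "other")
            if self.classes[rid] not in REGULATOR_CLASSES:
                raise ParseError(
                    f"unknown regulator class {self.classes[rid]!r} for {rid!r}"
                )

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [r for r in self.regulator_ids if r not in expr._gene_pos]
        if missing:
            raise UnknownIdentifier(
                f"regulators absent from expression matrix: {missing[:5]}"
            )


@dataclass
class ModulatorVector:
    """One scalar per sample ordering samples along the biological transition."""

    sample_ids: list[str]
    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).ravel()
        if len(self.m) != len(self.sample_ids):
            raise ValueError("modulator length inconsistent with sample ids")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.m).all():
            raise MissingValue("modulator contains non-finite values")
        if len(self.m) > 1 and np.ptp(self.m) == 0.0:
            raise ValueError("modulator values are all equal")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        if self.sample_ids != expr.sample_ids:
            raise ValueError("modulator sample ids do not match expression matrix")


@dataclass
class SampleNetwork:
    """Signed regulator -> target coefficient map for one sample."""

    sample_id: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (reg, tgt), coef in self.edges.items():
            if coef == 0.0:
                raise ValueError(f"zero coefficient stored for edge {reg}->{tgt}")
            if reg == tgt:
                raise ValueError(f"self-edge {reg}->{tgt}")

    def coefficient(self, regulator: str, target: str) -> float:
        return self.edges.get((regulator, target), 0.0)

    def children(self, regulator: str) -> list[str]:
        return [t for (r, t) in self.edges if r == regulator]


@dataclass
class NetworkEnsemble:
    """One SampleNetwork per sample, aligned with a ModulatorVector."""

    networks: list[SampleNetwork]
    regulator_ids: list[str]
    target_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique([n.sample_id for n in self.networks], "sample")

    @property
    def sample_ids(self) -> list[str]:
        return [n.sample_id for n in self.networks]


@dataclass
class GeneSetCollection:
    """Named functional gene sets with GMT semantics."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {name!r}")
            if not members:
                raise ValueError(f"empty gene set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdentifier(f"duplicate {what} identifier {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows unless ``transpose``).

    The first column holds gene ids and the header row sample ids.  Cells
    must be numeric and complete; the loader rejects rather than imputes.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    if transpose:
        df = df.T
    _check_unique(df.index.astype(str), "gene")
    _check_unique(df.columns.astype(str), "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise MissingValue(f"missing expression values in {path}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    try:
        expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc


def read_modulator(path: str | Path) -> ModulatorVector:
    """Read a two-column TSV (sample_id, value); no header required."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    if df.shape[1] < 2:
        raise ParseError(f"modulator file {path} needs two columns")
    first = df.iloc[0]
    try:
        float(first[1])
        start = 0
    except ValueError:
        start = 1  # header row
    body = df.iloc[start:]
    try:
        m = body[1].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric modulator value in {path}") from exc
    return ModulatorVector(sample_ids=[str(s) for s in body[0]], m=m)


def write_modulator(mod: ModulatorVector, path: str | Path) -> None:
    try:
        with open(path, "w") as fh:
            for sid, v in zip(mod.sample_ids, mod.m):
                fh.write(f"{sid}\t{float(v)!r}\n")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc


def read_regulators(path: str | Path) -> RegulatorIndex:
    """One regulator id per line; optional tab-separated class column."""
    ids: list[str] = []
    classes: dict[str, str] = {}
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ids.append(parts[0])
        if len(parts) > 1:
            classes[parts[0]] = parts[1]
    return RegulatorIndex(regulator_ids=ids, classes=classes)


def write_regulators(index: RegulatorIndex, path: str | Path) -> None:
    try:
        with open(path, "w") as fh:
            for rid in index.regulator_ids:
                fh.write(f"{rid}\t{index.classes[rid]}\n")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name<TAB>description<TAB>member..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise DuplicateIdentifier(f"{path}:{lineno}: duplicate set name {name!r}")
        deduped = list(dict.fromkeys(members))
        if len(deduped) != len(members):
            logger.warning("set %r: %d duplicate members removed",
                           name, len(members) - len(deduped))
        sets[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    try:
        with open(path, "w") as fh:
            for name, members in collection.sets.items():
                desc = collection.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc


_ENSEMBLE_HEADER = "sample_id\tregulator\ttarget\tcoefficient"


def write_network_ensemble(ensemble: NetworkEnsemble, path: str | Path) -> None:
    """Write the ensemble as a TSV edge list.

    Rows are ordered (sample order, target lexicographic, regulator
    lexicographic); zero coefficients are never emitted, so an absent row
    means an absent edge.  Coefficients are written with ``repr`` so the
    read/write pair round-trips bit-exactly.
    """
    try:
        with open(path, "w") as fh:
            fh.write(_ENSEMBLE_HEADER + "\n")
            for net in ensemble.networks:
                for (reg, tgt), coef in sorted(
                    net.edges.items(), key=lambda kv: (kv[0][1], kv[0][0])
                ):
                    fh.write(f"{net.sample_id}\t{reg}\t{tgt}\t{float(coef)!r}\n")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc


def read_network_ensemble(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    regulator_ids: Sequence[str] | None = None,
    target_ids: Sequence[str] | None = None,
) -> NetworkEnsemble:
    """Read an edge-list TSV back into an ensemble.

    Sample/vocabulary order can be supplied explicitly; otherwise it is
    taken from first appearance in the file.
    """
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    if not lines or lines[0] != _ENSEMBLE_HEADER:
        raise ParseError(f"{path}: missing ensemble header")
    edges_by_sample: dict[str, dict[tuple[str, str], float]] = {}
    seen_regs: dict[str, None] = {}
    seen_tgts: dict[str, None] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields")
        sid, reg, tgt, coef_s = parts
        try:
            coef = float(coef_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad coefficient {coef_s!r}") from exc
        edges_by_sample.setdefault(sid, {})[(reg, tgt)] = coef
        seen_regs.setdefault(reg)
        seen_tgts.setdefault(tgt)
    if sample_ids is None:
        sample_ids = list(edges_by_sample)
    networks = [
        SampleNetwork(sample_id=sid, edges=edges_by_sample.get(sid, {}))
        for sid in sample_ids
    ]
    return NetworkEnsemble(
        networks=networks,
        regulator_ids=list(regulator_ids) if regulator_ids else list(seen_regs),
        target_ids=list(target_ids) if target_ids else list(seen_tgts),
    )
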