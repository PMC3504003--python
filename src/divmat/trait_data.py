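"""Domain types and basic operations on replicate-level trait tables.

The experimental design this package analyses is a set of evolved lineages,
each measured in a small number of replicate colonies for four phenotypic
traits -- biomass per surface area (BM), colony-forming-unit density (CFU),
percent fast-germinating (diploid) spores (DPL), sexual fruiting body
density (SFB) -- plus a fitness measure, mycelial growth rate (MGR).
Lineages belong to one of two bottleneck treatments ("small" / "large"),
and a common ancestor is measured in triplicate.

This module holds the containers (``TraitTable``, ``LineageMeans``,
``CovarianceMatrix``), delimited-text I/O, the natural-log trait
transforms, trait standardization, per-lineage averaging, and sample
covariance estimation (the divergence or D matrix when applied to lineage
means).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRAITS: tuple[str, ...] = ("BM", "CFU", "DPL", "SFB")
FITNESS: str = "MGR"
TREATMENTS: tuple[str, ...] = ("small", "large", "ancestor")
ANCESTOR: str = "ancestor"

#: traits log-transformed by default ("Except for BM" all traits are
#: analysed on the natural-log scale)
DEFAULT_LOG_TRAITS: tuple[str, ...] = ("CFU", "DPL", "SFB")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class DivmatError(Exception):
    """Base class for package errors."""


class SchemaError(DivmatError):
    """Input file does not match the declared layout."""


class ParseError(DivmatError):
    """A cell could not be parsed as a number."""


class TransformError(DivmatError):
    """Invalid or repeated trait transform."""


class DegenerateTraitError(DivmatError):
    """A trait is constant (or zero-mean) where scaling is required."""


class InsufficientDataError(DivmatError):
    """Too few units for the requested estimate."""


class UsageError(DivmatError):
    """Operation called with incompatible inputs."""


class ConvergenceError(DivmatError):
    """Iterative fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best=None, n_iter: int | None = None):
        super().__init__(message)
        self.best = best
        self.n_iter = n_iter


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableLayout:
    """Column naming and shape of a delimited trait file.

    ``layout="wide"`` is one row per (lineage, replicate) with one column
    per trait; ``layout="long"`` is one row per (lineage, replicate,
    variable) with ``variable``/``value`` columns (traits and MGR stacked).
    """

    lineage: str = "lineage_id"
    treatment: str = "treatment"
    replicate: str = "replicate_id"
    traits: tuple[str, ...] = TRAITS
    fitness: str = FITNESS
    layout: str = "wide"
    variable: str = "variable"
    value: str = "value"


@dataclass(frozen=True)
class TraitTable:
    """Validated replicate-level observations.

    ``data`` has canonical columns lineage_id, treatment, replicate_id,
    BM, CFU, DPL, SFB, MGR.  ``transform_log`` records transforms already
    applied, as (trait, name) pairs, so a transform cannot silently be
    applied twice.
    """

    data: pd.DataFrame
    transform_log: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        _validate_table(self.data)

    @property
    def traits(self) -> tuple[str, ...]:
        return TRAITS

    @property
    def lineage_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["lineage_id"]))

    @property
    def n_lineages(self) -> int:
        return self.data["lineage_id"].nunique()

    def replicate_counts(self) -> dict[str, int]:
        return self.data.groupby("lineage_id", sort=False).size().to_dict()

    def without_ancestor(self) -> "TraitTable":
        sub = self.data[self.data["treatment"] != ANCESTOR].reset_index(drop=True)
        return TraitTable(sub, self.transform_log)

    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data["treatment"]))


def _validate_table(df: pd.DataFrame) -> None:
    required = ["lineage_id", "treatment", "replicate_id", *TRAITS, FITNESS]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    bad = set(df["treatment"]) - set(TREATMENTS)
    if bad:
        raise SchemaError(
            f"unknown treatment label(s) {sorted(bad)}; expected one of {TREATMENTS}"
        )
    num = df[list(TRAITS) + [FITNESS]].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        i, j = np.argwhere(~np.isfinite(num))[0]
        col = (list(TRAITS) + [FITNESS])[j]
        raise ParseError(f"non-finite value in column {col!r} at row {i}")
    dup = df.duplicated(subset=["lineage_id", "replicate_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"duplicate (lineage_id, replicate_id) pair: "
            f"({row['lineage_id']!r}, {row['replicate_id']!r})"
        )
    n_treat = df.groupby("lineage_id", sort=False)["treatment"].nunique()
    if (n_treat > 1).any():
        lin = n_treat[n_treat > 1].index[0]
        raise SchemaError(f"treatment not constant within lineage {lin!r}")


@dataclass(frozen=True)
class LineageMeans:
    """Per-lineage mean trait values (one row per lineage).

    ``values`` is n x p, rows aligned with ``lineage_ids``.  ``fitness``
    optionally carries the per-lineage mean MGR so downstream divergence
    records can relate distance to adaptation.
    """

    lineage_ids: tuple[str, ...]
    treatments: tuple[str, ...]
    values: np.ndarray
    traits: tuple[str, ...] = TRAITS
    fitness: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.lineage_ids), len(self.traits)):
            raise UsageError("mean matrix shape does not match labels")
        if self.fitness is not None:
            f = np.asarray(self.fitness, dtype=float)
            if f.shape != (len(self.lineage_ids),):
                raise UsageError("fitness vector length mismatch")
            object.__setattr__(self, "fitness", f)

    @property
    def n(self) -> int:
        return len(self.lineage_ids)

    def subset(self, mask: np.ndarray) -> "LineageMeans":
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(l for l, m in zip(self.lineage_ids, mask) if m)
        tr = tuple(t for t, m in zip(self.treatments, mask) if m)
        fit = None if self.fitness is None else self.fitness[mask]
        return LineageMeans(ids, tr, self.values[mask], self.traits, fit)

    def without_ancestor(self) -> "LineageMeans":
        return self.subset(np.array([t != ANCESTOR for t in self.treatments]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.traits))
        df.insert(0, "treatment", list(self.treatments))
        df.insert(0, "lineage_id", list(self.lineage_ids))
        if self.fitness is not None:
            df[FITNESS] = self.fitness
        return df


@dataclass(frozen=True)
class CovarianceMatrix:
    """Labeled symmetric p x p covariance matrix with provenance.

    ``estimator`` records how it was obtained: "sample_of_means" (the
    D matrix computed from lineage means), "reml_lineage_level" (the
    lineage variance component from a mixed-model fit), or
    "ground_truth" (a simulation input).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    n: int
    estimator: str

    _ESTIMATORS = ("sample_of_means", "reml_lineage_level", "ground_truth")

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        p = len(self.labels)
        if v.shape != (p, p):
            raise UsageError(f"covariance matrix must be {p}x{p}, got {v.shape}")
        if self.estimator not in self._ESTIMATORS:
            raise UsageError(f"unknown estimator {self.estimator!r}")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > 1e-10 * scale:
            raise UsageError("covariance matrix is not symmetric")
        if np.any(np.diag(v) < -1e-12 * scale):
            raise UsageError("negative diagonal entry")
        w = np.linalg.eigvalsh((v + v.T) / 2.0)
        tr = max(np.trace(v), scale * 1e-16)
        if w.min() < -1e-8 * tr:
            raise UsageError("covariance matrix is not numerically PSD")

    @property
    def p(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trait_table(path: str | Path, layout: TableLayout | None = None) -> TraitTable:
    """Read a delimited trait file into a validated :class:`TraitTable`.

    Comment lines starting with ``#`` are ignored.  Unknown treatment
    labels, missing cells and non-numeric trait cells are rejected with
    errors naming the offending column/row.
    """
    layout = layout or TableLayout()
    df = pd.read_csv(path, comment="#", dtype=str)
    key_cols = [layout.lineage, layout.treatment, layout.replicate]
    if layout.layout == "long":
        for col in key_cols + [layout.variable, layout.value]:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        df = (
            df.pivot_table(
                index=key_cols,
                columns=layout.variable,
                values=layout.value,
                aggfunc="first",
            )
            .reset_index()
        )
        df.columns.name = None
    rename = {
        layout.lineage: "lineage_id",
        layout.treatment: "treatment",
        layout.replicate: "replicate_id",
        layout.fitness: FITNESS,
    }
    rename.update({src: dst for src, dst in zip(layout.traits, TRAITS)})
    for col in [layout.lineage, layout.treatment, layout.replicate,
                *layout.traits, layout.fitness]:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df.rename(columns=rename)
    for col in list(TRAITS) + [FITNESS]:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"non-numeric or missing value {raw.iloc[i]!r} in column "
                f"{col!r} at data row {i}"
            )
        df[col] = num.astype(float)
    df = df[["lineage_id", "treatment", "replicate_id", *TRAITS, FITNESS]]
    return TraitTable(df.reset_index(drop=True))


def write_trait_table(table: TraitTable, path: str | Path,
                      header_comment: str | None = None) -> None:
    """Write a trait table as CSV (wide layout, canonical column names)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.data.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# transforms and standardization
# ---------------------------------------------------------------------------

def apply_transforms(table: TraitTable,
                     spec: Mapping[str, str] | None = None) -> TraitTable:
    """Apply per-trait transforms (currently natural log) to a table.

    The default spec logs CFU, DPL and SFB and leaves BM on the raw scale.
    A trait already transformed (per ``table.transform_log``) is refused,
    and a non-positive value under log raises an error naming the lineage
    and trait.
    """
    if spec is None:
        spec = {t: "ln" for t in DEFAULT_LOG_TRAITS}
    done = set(table.transform_log)
    df = table.data.copy()
    log = list(table.transform_log)
    for trait, name in spec.items():
        if trait not in TRAITS:
            raise UsageError(f"unknown trait {trait!r}")
        if name == "none":
            continue
        if name != "ln":
            raise TransformError(f"unsupported transform {name!r}")
        if any(t == trait for t, _ in done):
            raise TransformError(f"trait {trait!r} already transformed")
        vals = df[trait].to_numpy(dtype=float)
        bad = vals <= 0
        if bad.any():
            i = int(np.argmax(bad))
            raise DivmatError(
                f"cannot ln-transform non-positive value {vals[i]!r} of trait "
                f"{trait!r} in lineage {df['lineage_id'].iloc[i]!r}"
            )
        df[trait] = np.log(vals)
        log.append((trait, "ln"))
    return TraitTable(df, tuple(log))


def standardize(means: LineageMeans, mode: str = "variance",
                reference: str = "evolved_only") -> LineageMeans:
    """Standardize each trait column of a set of lineage means.

    mode="variance": z-score (mean 0, sd 1, sd with divisor n-1) over the
    reference set; mode="mean": divide by the reference-set mean.  The
    reference set is either the evolved lineages only or all rows
    including the ancestor; the transform is applied to every row.
    """
    if means.n < 2:
        raise InsufficientDataError("need at least 2 lineages to standardize")
    if reference == "evolved_only":
        ref_mask = np.array([t != ANCESTOR for t in means.treatments])
        if not ref_mask.any():
            ref_mask = np.ones(means.n, dtype=bool)
    elif reference == "with_ancestor":
        ref_mask = np.ones(means.n, dtype=bool)
    else:
        raise UsageError(f"unknown reference {reference!r}")
    ref = means.values[ref_mask]
    if mode == "variance":
        mu = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=1)
        for j, s in enumerate(sd):
            if s <= 0 or not np.isfinite(s):
                raise DegenerateTraitError(
                    f"trait {means.traits[j]!r} is constant over the reference set"
                )
        vals = (means.values - mu) / sd
    elif mode == "mean":
        mu = ref.mean(axis=0)
        for j, m in enumerate(mu):
            if m == 0 or not np.isfinite(m):
                raise DegenerateTraitError(
                    f"trait {means.traits[j]!r} has zero mean over the reference set"
                )
        vals = means.values / mu
    else:
        raise UsageError(f"unknown mode {mode!r}")
    return replace(means, values=vals)


def standardize_table(table: TraitTable,
                      reference: str = "evolved_only") -> TraitTable:
    """Standardize replicate-level trait values across lineages.

    Each trait column is centred and scaled by the mean and sd (divisor
    n-1) of the *lineage means* over the reference set, so lineage means
    of the returned table have mean 0 / sd 1 per trait.  This is the
    preparation step for the mixed-model fits.
    """
    lm = lineage_means(table)
    if reference == "evolved_only":
        ref = lm.without_ancestor()
        if ref.n == 0:
            ref = lm
    elif reference == "with_ancestor":
        ref = lm
    else:
        raise UsageError(f"unknown reference {reference!r}")
    mu = ref.values.mean(axis=0)
    sd = ref.values.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s <= 0 or not np.isfinite(s):
            raise DegenerateTraitError(
                f"trait {TRAITS[j]!r} is constant over the reference set"
            )
    df = table.data.copy()
    for j, trait in enumerate(TRAITS):
        df[trait] = (df[trait].to_numpy(dtype=float) - mu[j]) / sd[j]
    log = table.transform_log + tuple((t, "standardized") for t in TRAITS)
    return TraitTable(df, log)


# ---------------------------------------------------------------------------
# lineage means and covariance
# ---------------------------------------------------------------------------

def lineage_means(table: TraitTable) -> LineageMeans:
    """Arithmetic mean of each trait (and MGR) over each lineage's replicates.

    The ancestor's replicate isolates are averaged into a single row like
    any other lineage.  Row order follows first appearance in the table.
    """
    if len(table.data) == 0:
        raise InsufficientDataError("empty trait table")
    g = table.data.groupby("lineage_id", sort=False)
    means = g[list(TRAITS) + [FITNESS]].mean()
    treatments = g["treatment"].first()
    return LineageMeans(
        lineage_ids=tuple(means.index),
        treatments=tuple(treatments.loc[means.index]),
        values=means[list(TRAITS)].to_numpy(dtype=float),
        traits=TRAITS,
        fitness=means[FITNESS].to_numpy(dtype=float),
    )


def sample_covariance(means: LineageMeans, ddof: int = 1) -> CovarianceMatrix:
    """Sample covariance of lineage means (the D matrix).

    ``ddof=1`` gives the unbiased divisor n-1 (default); ``ddof=0`` the
    ML divisor n, for likelihood conventions that expect it.
    """
    if means.n < 2:
        raise InsufficientDataError(
            f"need at least 2 lineages for a covariance, got {means.n}"
        )
    v = np.cov(means.values, rowvar=False, ddof=ddof)
    v = np.atleast_2d(v)
    return CovarianceMatrix(means.traits, (v + v.T) / 2.0, means.n, "sample_of_means")


def cov_to_corr(cov: CovarianceMatrix) -> CovarianceMatrix:
    """Rescale a covariance matrix to a correlation matrix (unit diagonal)."""
    d = np.diag(cov.values)
    for j, x in enumerate(d):
        if x <= 0:
            raise DegenerateTraitError(
                f"zero variance for trait {cov.labels[j]!r}; cannot form correlations"
            )
    s = np.sqrt(d)
    corr = cov.values / np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return CovarianceMatrix(cov.labels, (corr + corr.T) / 2.0, cov.n, cov.estimator)


# ---------------------------------------------------------------------------
# serialization of derived objects
# ---------------------------------------------------------------------------

def lineage_means_to_csv(means: LineageMeans, path: str | Path,
                         header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        means.to_frame().to_csv(fh, index=False)


def covariance_to_json(cov: CovarianceMatrix) -> str:
    return json.dumps(
        {
            "labels": list(cov.labels),
            "values": cov.values.tolist(),
            "n": cov.n,
            "estimator": cov.estimator,
        },
        indent=2,
    )


def covariance_from_json(text: str) -> CovarianceMatrix:
    obj = json.loads(text)
    return CovarianceMatrix(
        tuple(obj["labels"]), np.asarray(obj["values"], dtype=float),
        int(obj["n"]), obj["estimator"],
    )


def covariance_to_tsv(cov: CovarianceMatrix, path: str | Path,
                      header_comment: str | None = None) -> None:
    df = pd.DataFrame(cov.values, index=list(cov.labels), columns=list(cov.labels))
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="trait")


def covariance_from_tsv(path: str | Path, n: int = 0,
                        estimator: str = "sample_of_means") -> CovarianceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="trait")
    return CovarianceMatrix(tuple(df.columns), df.to_numpy(dtype=float), n, estimator)
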