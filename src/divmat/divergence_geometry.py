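"""Eigenanalysis of D, Mahalanobis divergence from the ancestor, and the
relationship between divergence and adaptation.

The divergence matrix D summarizes among-lineage (co)variation of trait
means; its eigenvectors are the principal directions of divergence (the
leading one, d_max, being the direction of greatest divergence) and the
eigenvalue spectrum measures how many independent directions carry
appreciable divergence.  Each lineage's total divergence from the common
ancestor is its Mahalanobis distance

    d_i = sqrt( (x_i - x_0)^T  D^{-1}  (x_i - x_0) ),

computed in the metric of a D re-estimated with the ancestral mean
included, which is unit-free and accounts for trait scales and
correlations.  Adaptation (mean fitness gain over the ancestor) is then
related to ln d_i by Pearson correlation (pooled and per treatment), by
an ANCOVA with a treatment x distance interaction, and optionally by an
ordinary-least-squares regression of adaptation on treatment plus the
four traits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .trait_data import (
    ANCESTOR,
    CovarianceMatrix,
    DegenerateTraitError,
    InsufficientDataError,
    LineageMeans,
    UsageError,
)


# ---------------------------------------------------------------------------
# eigenanalysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EigenSummary:
    """Full eigendecomposition of a covariance matrix.

    Eigenvalues descending; loadings columns are the eigenvectors V1..Vp
    under the canonical sign convention (largest-magnitude loading of
    each column positive).
    """

    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: np.ndarray
    traits: tuple[str, ...]

    @property
    def p(self) -> int:
        return len(self.traits)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"V{i + 1}" for i in range(self.p)]
        df = pd.DataFrame(self.loadings.T, index=idx, columns=list(self.traits))
        df.insert(0, "proportion", self.proportions)
        df.insert(0, "lambda", self.eigenvalues)
        return df

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="axis")


def eigen_summary(cov: CovarianceMatrix, sym_tol: float = 1e-8) -> EigenSummary:
    """Eigendecomposition with descending order and canonical signs."""
    v = cov.values
    scale = max(np.abs(v).max(), 1e-30)
    if np.abs(v - v.T).max() > sym_tol * scale:
        raise UsageError("matrix is not symmetric within tolerance")
    w, V = np.linalg.eigh((v + v.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    total = w.sum()
    if total <= 0:
        raise DegenerateTraitError("total variance is not positive")
    return EigenSummary(
        eigenvalues=w, proportions=w / total, loadings=V, traits=cov.labels
    )


def proportion_leading(summary: EigenSummary, m: int) -> float:
    """Proportion of total divergence carried by the leading m axes."""
    if not 1 <= m <= summary.p:
        raise UsageError(f"m={m} out of range 1..{summary.p}")
    return float(summary.proportions[:m].sum())


# ---------------------------------------------------------------------------
# Mahalanobis divergence records
# ---------------------------------------------------------------------------

@dataclass
class DivergenceRecord:
    """One lineage's divergence from the ancestor and its adaptation."""

    lineage_id: str
    treatment: str
    distance: float
    ln_distance: float
    pc_scores: np.ndarray | None
    adaptation: float | None


def mahalanobis_distances(means: LineageMeans, cov: CovarianceMatrix,
                          pseudo_inverse: bool = False,
                          pinv_rcond: float = 1e-10) -> list[DivergenceRecord]:
    """Mahalanobis distance of every lineage from the ancestral mean.

    ``means`` must include the ancestor row (x_0).  The metric is the
    inverse of ``cov`` (normally the ancestor-included D); a singular
    metric raises unless ``pseudo_inverse`` enables the Moore-Penrose
    fallback.  Adaptation is filled as the lineage's mean fitness minus
    the ancestor's when fitness is available.
    """
    if means.traits != cov.labels:
        raise UsageError("trait labels of means and covariance differ")
    anc_mask = np.array([t == ANCESTOR for t in means.treatments])
    if anc_mask.sum() != 1:
        raise UsageError(
            f"means must contain exactly one ancestor row, got {anc_mask.sum()}"
        )
    x0 = means.values[anc_mask][0]
    if pseudo_inverse:
        inv = np.linalg.pinv(cov.values, rcond=pinv_rcond, hermitian=True)
    else:
        cond = np.linalg.cond(cov.values)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "covariance is singular or near-singular; pass "
                "pseudo_inverse=True to use the Moore-Penrose inverse"
            )
        inv = np.linalg.inv(cov.values)
    deltas = means.values - x0
    q = np.einsum("ij,jk,ik->i", deltas, inv, deltas)
    d = np.sqrt(np.clip(q, 0.0, None))
    anc_fit = None
    if means.fitness is not None:
        anc_fit = float(means.fitness[anc_mask][0])
    records = []
    for i, (lin, tr) in enumerate(zip(means.lineage_ids, means.treatments)):
        di = float(d[i])
        if tr == ANCESTOR:
            di, ln_d = 0.0, float("-inf")
        elif di <= 0:
            raise DegenerateTraitError(
                f"evolved lineage {lin!r} has zero distance; ln-distance undefined"
            )
        else:
            ln_d = math.log(di)
        adapt = None
        if means.fitness is not None:
            adapt = float(means.fitness[i] - anc_fit)
        records.append(DivergenceRecord(lin, tr, di, ln_d, None, adapt))
    return records


def pc_scores(means: LineageMeans, summary: EigenSummary, m: int) -> np.ndarray:
    """Scores of each lineage on the leading m eigenvectors.

    Centering is about the grand mean of the rows supplied, so when the
    summary derives from the same means the score variances reproduce
    the eigenvalues.
    """
    if means.traits != summary.traits:
        raise UsageError("trait labels of means and eigen summary differ")
    if not 0 <= m <= summary.p:
        raise UsageError(f"m={m} out of range 0..{summary.p}")
    centered = means.values - means.values.mean(axis=0)
    return centered @ summary.loadings[:, :m]


def attach_pc_scores(records: list[DivergenceRecord],
                     scores: np.ndarray) -> list[DivergenceRecord]:
    if len(records) != len(scores):
        raise UsageError("record/score length mismatch")
    for rec, s in zip(records, scores):
        rec.pc_scores = np.asarray(s, dtype=float)
    return records


def records_to_frame(records: list[DivergenceRecord]) -> pd.DataFrame:
    n_pc = 0
    for r in records:
        if r.pc_scores is not None:
            n_pc = len(r.pc_scores)
            break
    rows = []
    for r in records:
        row = {
            "lineage_id": r.lineage_id,
            "treatment": r.treatment,
            "distance": r.distance,
            "ln_distance": r.ln_distance,
        }
        for j in range(n_pc):
            row[f"pc{j + 1}"] = (
                float(r.pc_scores[j]) if r.pc_scores is not None else np.nan
            )
        row["adaptation"] = r.adaptation
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_csv(records: list[DivergenceRecord], path,
                   header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records_to_frame(records).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# adaptation vs divergence
# ---------------------------------------------------------------------------

@dataclass
class AdaptationAnalysis:
    pooled_r: float
    pooled_p: float
    pooled_n: int
    per_treatment: dict[str, tuple[float, float, int]]   # r, p, n
    ancova: pd.DataFrame                                 # term, F, p
    trait_regression: pd.DataFrame | None

    def to_json_dict(self) -> dict:
        return {
            "pooled": {"r": self.pooled_r, "p": self.pooled_p, "n": self.pooled_n},
            "per_treatment": {
                k: {"r": v[0], "p": v[1], "n": v[2]}
                for k, v in self.per_treatment.items()
            },
            "ancova": self.ancova.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "trait_regression": (
                None
                if self.trait_regression is None
                else self.trait_regression.reset_index()
                .rename(columns={"index": "term"})
                .to_dict(orient="records")
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, default=float)


def adaptation_distance_analysis(records: list[DivergenceRecord],
                                 trait_means: LineageMeans | None = None,
                                 min_per_group: int = 3) -> AdaptationAnalysis:
    """Correlate adaptation with ln distance and test treatment effects.

    The ancestor's own record is excluded.  Reports the pooled and
    per-treatment Pearson correlations (two-sided p from the t transform
    of r), an OLS ANCOVA of adaptation on ln distance, treatment, and
    their interaction (type-II F-tests), and, when lineage trait means
    are supplied, the OLS regression of adaptation on treatment plus the
    traits.
    """
    df = records_to_frame(records)
    df = df[df["treatment"] != ANCESTOR].copy()
    if df["adaptation"].isna().any():
        raise UsageError("records lack adaptation values")
    for g, sub in df.groupby("treatment"):
        if len(sub) < min_per_group:
            raise InsufficientDataError(
                f"treatment {g!r} has fewer than {min_per_group} evolved lineages"
            )
    if df["adaptation"].std(ddof=1) == 0:
        raise DegenerateTraitError("adaptation has zero variance")

    def _corr(sub: pd.DataFrame) -> tuple[float, float, int]:
        r, p = stats.pearsonr(sub["ln_distance"], sub["adaptation"])
        return float(r), float(p), len(sub)

    pooled = _corr(df)
    per = {g: _corr(sub) for g, sub in df.groupby("treatment", sort=False)}

    n_groups = df["treatment"].nunique()
    if n_groups >= 2:
        model = smf.ols(
            "adaptation ~ ln_distance * C(treatment)", data=df
        ).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        ancova = anova[["F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})
    else:
        model = smf.ols("adaptation ~ ln_distance", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        ancova = anova[["F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})

    trait_reg = None
    if trait_means is not None:
        tm = trait_means.without_ancestor().to_frame()
        merged = df.merge(tm, on=["lineage_id", "treatment"], how="inner")
        if len(merged) != len(df):
            raise UsageError("trait means do not cover all evolved lineages")
        terms = " + ".join(trait_means.traits)
        if n_groups >= 2:
            formula = f"adaptation ~ C(treatment) + {terms}"
        else:
            formula = f"adaptation ~ {terms}"
        reg = smf.ols(formula, data=merged).fit()
        trait_reg = pd.DataFrame(
            {
                "estimate": reg.params,
                "se": reg.bse,
                "t": reg.tvalues,
                "p": reg.pvalues,
            }
        )

    return AdaptationAnalysis(
        pooled_r=pooled[0], pooled_p=pooled[1], pooled_n=pooled[2],
        per_treatment=per, ancova=ancova, trait_regression=trait_reg,
    )
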