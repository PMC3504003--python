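"""Flury hierarchy of covariance-matrix similarity (CPC analysis).

Given covariance matrices estimated separately in k groups (here: the
treatment-specific divergence matrices computed from lineage means), the
Flury hierarchy orders hypotheses of similarity from most to least
constrained:

    equality > proportionality > CPC (all eigenvectors shared)
    > partial CPC(q) (q shared axes) > unrelated.

Each model is fitted by (approximate) maximum likelihood on Wishart
sample covariances; the fit statistic against the saturated ("unrelated")
model is

    chi2 = sum_i m_i * ln( det(Sigma_hat_i) / det(S_i) ),

with m_i = n_i - 1 the group degrees of freedom.  Adjacent models are
compared by differencing these statistics (which telescopes cleanly into
the AIC chain), and the best model is chosen by minimum AIC with ties
broken toward the more constrained hypothesis.

Common eigenvectors come from the FG (Flury-Gautschi) algorithm:
pairwise Jacobi-style plane rotations of an orthogonal basis, each
rotation angle chosen to minimize the CPC discrepancy for that pair of
columns (here by a dense 1-D search, robust to tied eigenvalues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trait_data import (
    ANCESTOR,
    ConvergenceError,
    CovarianceMatrix,
    LineageMeans,
    UsageError,
    sample_covariance,
)

MODEL_ORDER_NAMES = ("equality", "proportionality", "cpc")  # then partial, unrelated


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCovariances:
    """Covariance matrices of >= 2 groups sharing the same trait space."""

    labels: tuple[str, ...]          # group labels
    matrices: tuple[np.ndarray, ...]
    ns: tuple[int, ...]              # units each matrix was estimated from
    traits: tuple[str, ...]

    def __post_init__(self):
        if len(self.matrices) < 2:
            raise UsageError("need at least 2 groups")
        p = len(self.traits)
        mats = tuple(np.asarray(m, dtype=float) for m in self.matrices)
        object.__setattr__(self, "matrices", mats)
        for m in mats:
            if m.shape != (p, p):
                raise UsageError("group covariance dimension mismatch")
        for lbl, n in zip(self.labels, self.ns):
            if n <= p:
                warnings.warn(
                    f"group {lbl!r} has n={n} <= p={p}; estimates are unstable"
                )

    @property
    def p(self) -> int:
        return len(self.traits)

    @property
    def k(self) -> int:
        return len(self.matrices)

    @property
    def m(self) -> np.ndarray:
        """Group degrees of freedom m_i = n_i - 1."""
        return np.asarray(self.ns, dtype=float) - 1.0

    @classmethod
    def from_covariances(cls, covs: Sequence[CovarianceMatrix],
                         labels: Sequence[str]) -> "GroupCovariances":
        traits = covs[0].labels
        for c in covs:
            if c.labels != traits:
                raise UsageError("trait labels differ between groups")
        return cls(tuple(labels), tuple(c.values for c in covs),
                   tuple(c.n for c in covs), traits)


def treatment_covariances(means: LineageMeans, ddof: int = 1) -> GroupCovariances:
    """Treatment-specific D matrices from (unstandardized) lineage means."""
    groups = [t for t in dict.fromkeys(means.treatments) if t != ANCESTOR]
    covs, labels = [], []
    for g in groups:
        sub = means.subset(np.array([t == g for t in means.treatments]))
        covs.append(sample_covariance(sub, ddof=ddof))
        labels.append(g)
    return GroupCovariances.from_covariances(covs, labels)


@dataclass
class CPCModelFit:
    model: str                      # canonical label, e.g. "partial_cpc(2)"
    fitted: tuple[np.ndarray, ...]  # Sigma_hat_i per group
    basis: np.ndarray | None        # common axes (columns), when applicable
    rho: np.ndarray | None          # proportionality constants, rho_1 = 1
    chi2_vs_unrelated: float
    df_vs_unrelated: int


@dataclass
class HierarchyStep:
    higher: str
    lower: str
    chi2: float
    df: int
    p_value: float
    chi2_over_df: float
    aic_higher: float


@dataclass
class HierarchyTable:
    steps: list[HierarchyStep]
    aic: dict[str, float]           # per model, including "unrelated"
    fits: dict[str, CPCModelFit]
    best_model: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "higher": s.higher,
                "lower": s.lower,
                "chi2": s.chi2,
                "df": s.df,
                "p": s.p_value,
                "chi2_over_df": s.chi2_over_df,
                "aic": s.aic_higher,
            }
            for s in self.steps
        ]
        rows.append({"higher": "unrelated", "lower": "", "chi2": np.nan,
                     "df": np.nan, "p": np.nan, "chi2_over_df": np.nan,
                     "aic": self.aic["unrelated"]})
        return pd.DataFrame(rows)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model chain and degrees of freedom
# ---------------------------------------------------------------------------

def model_chain(p: int) -> list[str]:
    """Hierarchy order from most constrained to unrelated."""
    chain = ["equality", "proportionality", "cpc"]
    chain += [f"partial_cpc({q})" for q in range(p - 2, 0, -1)]
    chain.append("unrelated")
    return chain


def _parse_partial(model: str) -> int | None:
    if model.startswith("partial_cpc(") and model.endswith(")"):
        return int(model[len("partial_cpc("):-1])
    return None


def step_df(p: int, k_groups: int, higher: str, lower: str) -> int:
    """Degrees of freedom separating adjacent hierarchy models.

    equality->proportionality: k-1; proportionality->cpc: (k-1)(p-1);
    partial_cpc(q)->partial_cpc(q-1): (k-1)(p-q), with cpc acting as
    partial_cpc(p-1) and unrelated as partial_cpc(0).
    """
    chain = model_chain(p)
    try:
        ih, il = chain.index(higher), chain.index(lower)
    except ValueError as e:
        raise UsageError(f"unknown model in pair ({higher!r}, {lower!r})") from e
    if il != ih + 1:
        raise UsageError(f"models {higher!r} and {lower!r} are not adjacent")
    if higher == "equality":
        return k_groups - 1
    if higher == "proportionality":
        return (k_groups - 1) * (p - 1)
    q = p - 1 if higher == "cpc" else _parse_partial(higher)
    return (k_groups - 1) * (p - q)


def df_vs_unrelated(p: int, k_groups: int, model: str) -> int:
    """Cumulative df separating a model from the saturated one."""
    chain = model_chain(p)
    if model not in chain:
        raise UsageError(f"unknown model {model!r}")
    total = 0
    i = chain.index(model)
    for a, b in zip(chain[i:], chain[i + 1:]):
        total += step_df(p, k_groups, a, b)
    return total


# ---------------------------------------------------------------------------
# FG common eigenvectors
# ---------------------------------------------------------------------------

def _pair_criterion(theta: float, T: np.ndarray, m: np.ndarray) -> float:
    c, s = np.cos(theta), np.sin(theta)
    a = c * c * T[:, 0, 0] + 2 * c * s * T[:, 0, 1] + s * s * T[:, 1, 1]
    b = s * s * T[:, 0, 0] - 2 * c * s * T[:, 0, 1] + c * c * T[:, 1, 1]
    if np.any(a <= 0) or np.any(b <= 0):
        return np.inf
    return float(np.sum(m * (np.log(a) + np.log(b))))


def _criterion(B: np.ndarray, mats: Sequence[np.ndarray], m: np.ndarray) -> float:
    tot = 0.0
    for Si, mi in zip(mats, m):
        d = np.einsum("ji,jk,ki->i", B, Si, B)
        if np.any(d <= 0):
            return np.inf
        tot += mi * np.sum(np.log(d))
    return tot


def _canonical_columns(B: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    """Order columns by pooled variance (descending), sign-fix each column."""
    var = np.einsum("ji,jk,ki->i", B, pooled, B)
    B = B[:, np.argsort(var)[::-1]]
    for j in range(B.shape[1]):
        i = np.argmax(np.abs(B[:, j]))
        if B[i, j] < 0:
            B[:, j] = -B[:, j]
    return B


def fg_common_eigenvectors(data: GroupCovariances, tol: float = 1e-10,
                           max_iter: int = 200) -> np.ndarray:
    """Common orthogonal basis minimizing the CPC discrepancy.

    Sweeps all column pairs, rotating each pair in its plane by the angle
    that minimizes the pair's contribution to the df-weighted criterion
    sum_i m_i * ln det diag(B' S_i B); the angle is located by a coarse
    grid over one period followed by bounded refinement, which handles
    degenerate (tied-eigenvalue) pairs without special cases.  Stops when
    a full sweep changes the criterion by less than ``tol``.
    """
    p = data.p
    mats = data.matrices
    m = data.m
    pooled = sum(mi * Si for mi, Si in zip(m, mats)) / m.sum()
    _, B = np.linalg.eigh(pooled)
    B = B[:, ::-1].copy()
    crit = _criterion(B, mats, m)
    grid = np.linspace(-np.pi / 4, np.pi / 4, 61)
    for it in range(max_iter):
        for a in range(p - 1):
            for b in range(a + 1, p):
                cols = B[:, [a, b]]
                T = np.stack([cols.T @ Si @ cols for Si in mats])
                vals = [_pair_criterion(t, T, m) for t in grid]
                j = int(np.argmin(vals))
                lo = grid[max(j - 1, 0)]
                hi = grid[min(j + 1, len(grid) - 1)]
                res = optimize.minimize_scalar(
                    _pair_criterion, args=(T, m), bounds=(lo, hi),
                    method="bounded", options={"xatol": 1e-12},
                )
                theta = float(res.x)
                if _pair_criterion(theta, T, m) >= vals[j]:
                    theta = float(grid[j])
                if abs(theta) < 1e-15:
                    continue
                c, s = np.cos(theta), np.sin(theta)
                B[:, a], B[:, b] = c * cols[:, 0] + s * cols[:, 1], \
                    -s * cols[:, 0] + c * cols[:, 1]
        new_crit = _criterion(B, mats, m)
        if abs(crit - new_crit) < tol:
            return _canonical_columns(B, pooled)
        crit = new_crit
    raise ConvergenceError(
        f"FG algorithm did not converge in {max_iter} sweeps",
        best=_canonical_columns(B, pooled), n_iter=max_iter,
    )


# ---------------------------------------------------------------------------
# similarity model fits
# ---------------------------------------------------------------------------

def _logdet(m: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0:
        raise UsageError("singular or indefinite matrix in CPC fit")
    return float(ld)


def _chi2_vs_unrelated(data: GroupCovariances,
                       fitted: Sequence[np.ndarray]) -> float:
    chi2 = sum(
        mi * (_logdet(F) - _logdet(S))
        for mi, F, S in zip(data.m, fitted, data.matrices)
    )
    return float(max(chi2, 0.0))


def _fit_proportionality(data: GroupCovariances, max_iter: int = 1000,
                         tol: float = 1e-12):
    """Flury's ML iteration for Sigma_i = rho_i * Sigma, rho_1 = 1."""
    m = data.m
    p = data.p
    rho = np.ones(data.k)
    Sigma = sum(mi * Si for mi, Si in zip(m, data.matrices)) / m.sum()
    for _ in range(max_iter):
        Sigma_new = sum(
            (mi / ri) * Si for mi, ri, Si in zip(m, rho, data.matrices)
        ) / m.sum()
        inv = np.linalg.inv(Sigma_new)
        rho_new = np.array(
            [np.trace(inv @ Si) / p for Si in data.matrices]
        )
        rho_new /= rho_new[0]
        delta = max(np.abs(rho_new - rho).max(),
                    np.abs(Sigma_new - Sigma).max())
        Sigma, rho = Sigma_new, rho_new
        if delta < tol:
            break
    return Sigma, rho


def fit_similarity_model(data: GroupCovariances, model: str,
                         options: dict | None = None) -> CPCModelFit:
    """Fit one hypothesis of the hierarchy and its chi2 against unrelated.

    equality: df-weighted pooled matrix for every group; proportionality:
    iterative ML common shape with per-group scale rho_i; cpc: FG basis
    with per-group eigenvalues; partial_cpc(q): the q highest-pooled-
    variance FG axes shared, the complement refitted freely per group;
    unrelated: the sample matrices themselves (chi2 identically 0).
    """
    options = options or {}
    p, k = data.p, data.k
    q = _parse_partial(model)
    basis = None
    rho = None
    if model == "unrelated":
        fitted = data.matrices
    elif model == "equality":
        pooled = sum(mi * Si for mi, Si in zip(data.m, data.matrices)) / data.m.sum()
        fitted = tuple(pooled.copy() for _ in range(k))
    elif model == "proportionality":
        Sigma, rho = _fit_proportionality(data)
        fitted = tuple(ri * Sigma for ri in rho)
    elif model == "cpc" or q is not None:
        basis = fg_common_eigenvectors(
            data, tol=options.get("tol", 1e-10),
            max_iter=options.get("max_iter", 200),
        )
        if model == "cpc":
            fitted = []
            for Si in data.matrices:
                lam = np.einsum("ji,jk,ki->i", basis, Si, basis)
                fitted.append(basis @ np.diag(lam) @ basis.T)
            fitted = tuple(fitted)
        else:
            if not 1 <= q <= p - 2:
                raise UsageError(f"partial CPC order q={q} out of range")
            B1 = basis[:, :q]
            C = basis[:, q:]
            fitted = []
            for Si in data.matrices:
                lam = np.einsum("ji,jk,ki->i", B1, Si, B1)
                block = C.T @ Si @ C
                fitted.append(B1 @ np.diag(lam) @ B1.T + C @ block @ C.T)
            fitted = tuple(fitted)
            basis = B1
    else:
        raise UsageError(f"unknown similarity model {model!r}")
    fitted = tuple((F + F.T) / 2.0 for F in fitted)
    return CPCModelFit(
        model=model,
        fitted=fitted,
        basis=basis,
        rho=rho,
        chi2_vs_unrelated=_chi2_vs_unrelated(data, fitted),
        df_vs_unrelated=df_vs_unrelated(p, k, model),
    )


# ---------------------------------------------------------------------------
# hierarchy table and model selection
# ---------------------------------------------------------------------------

def hierarchy_table(data: GroupCovariances,
                    options: dict | None = None) -> HierarchyTable:
    """Fit the whole hierarchy and assemble the step/AIC decision table.

    Step chi2 values difference the chi2-vs-unrelated statistics of
    adjacent fits (clipped at 0); AIC(model) = chi2_vs_unrelated +
    2 * (T - df_vs_unrelated) with T = (k-1) p(p+1)/2, so
    AIC(unrelated) = 2T.
    """
    p, k = data.p, data.k
    chain = model_chain(p)
    T = (k - 1) * p * (p + 1) // 2
    fits = {mdl: fit_similarity_model(data, mdl, options) for mdl in chain}
    aic = {
        mdl: fits[mdl].chi2_vs_unrelated + 2.0 * (T - fits[mdl].df_vs_unrelated)
        for mdl in chain
    }
    steps = []
    for higher, lower in zip(chain[:-1], chain[1:]):
        chi2 = max(fits[higher].chi2_vs_unrelated
                   - fits[lower].chi2_vs_unrelated, 0.0)
        df = step_df(p, k, higher, lower)
        steps.append(
            HierarchyStep(
                higher=higher, lower=lower, chi2=chi2, df=df,
                p_value=float(stats.chi2.sf(chi2, df)),
                chi2_over_df=chi2 / df,
                aic_higher=aic[higher],
            )
        )
    table = HierarchyTable(steps=steps, aic=aic, fits=fits, best_model="")
    table.best_model = select_best_model(table)
    return table


def select_best_model(table: HierarchyTable) -> str:
    """Minimum-AIC model; ties broken toward the more constrained one."""
    if not table.aic:
        raise UsageError("empty hierarchy table")
    chain = [s.higher for s in table.steps] + ["unrelated"]
    for mdl in chain:
        if mdl not in table.aic:
            raise UsageError(f"hierarchy table missing model {mdl!r}")
    best = chain[0]
    for mdl in chain[1:]:
        if table.aic[mdl] < table.aic[best] - 1e-12:
            best = mdl
    return best
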