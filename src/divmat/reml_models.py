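"""REML fitting of the multivariate mixed model and D-matrix rank tests.

The model: the p-vector of trait values of replicate j in lineage k of
treatment l is

    y_jkl = mu_l + u_k + e_jkl,

with fixed treatment-specific means mu_l, lineage effects u_k ~ N(0, D)
(the among-lineage divergence matrix, possibly constrained to a
factor-analytic structure D = Lambda Lambda^T of rank k), and residuals
e ~ N(0, R) with R unstructured.  A replicate random effect covarying
across traits is not identifiable from this design (traits may be
measured on different colonies) and is absorbed into R; covariance
parameter counts therefore match the factor-analytic ladder exactly
(p(p+1)/2 = 10 residual parameters at rank 0 for p = 4).

The restricted likelihood exploits the nesting structure: an orthogonal
within-lineage transform splits the data into lineage means (covariance
r*D + R on the scaled-mean coordinate) and within-lineage contrasts
(covariance R), so no dense N*p covariance is ever assembled.  A dense
brute-force evaluator of the same restricted likelihood is kept for
oracle comparisons on tiny instances.

Provided tests: nested likelihood-ratio tests for the effective rank of
D (factor-analytic ladder from rank p down to 0), the Wald F-test of the
treatment mean difference, and the pooled-versus-separate-D likelihood
ratio test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trait_data import (
    ANCESTOR,
    TRAITS,
    ConvergenceError,
    CovarianceMatrix,
    InsufficientDataError,
    TraitTable,
    UsageError,
)

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Covariance structure of the lineage-level random effect.

    ``lineage`` is "unstructured" (full PSD D), "fa" (factor-analytic
    rank ``fa_rank``), or "zero" (no lineage variance).  With
    ``separate_by_treatment`` a distinct lineage-level matrix is fitted
    per treatment group.  The residual is always unstructured.
    """

    lineage: str = "unstructured"
    fa_rank: int | None = None
    separate_by_treatment: bool = False

    def __post_init__(self):
        if self.lineage not in ("unstructured", "fa", "zero"):
            raise UsageError(f"unknown lineage structure {self.lineage!r}")
        if self.lineage == "fa":
            if self.fa_rank is None or self.fa_rank < 0:
                raise UsageError("fa structure requires fa_rank >= 0")
        elif self.fa_rank is not None:
            raise UsageError("fa_rank only valid with lineage='fa'")


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 5
    seed: int = 0
    maxiter: int = 1000
    gtol: float = 1e-7
    warn_unstandardized: bool = True


@dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    """Result of one REML fit."""

    minus2ll: float
    n_cov_params: int
    aic: float
    lineage_cov: CovarianceMatrix | dict[str, CovarianceMatrix]
    residual_cov: CovarianceMatrix
    fixed_effects: pd.DataFrame           # one row per treatment group
    converged: bool
    n_iter: int
    spec: ModelSpec
    theta: np.ndarray = field(repr=False, default=None)
    _wald: dict = field(repr=False, default=None)


@dataclass
class RankTestRow:
    dimensions: int
    minus2ll: float
    n_params: int
    aic: float
    p_value: float | None        # test of this rank vs rank-1; None at 0


@dataclass
class RankTestTable:
    rows: list[RankTestRow]      # ordered k = p .. 0
    selected_rank: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dimensions": [r.dimensions for r in self.rows],
                "minus2_log_likelihood": [r.minus2ll for r in self.rows],
                "n_parameters": [r.n_params for r in self.rows],
                "AIC": [r.aic for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
            }
        )

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _n_lineage_params(p: int, spec: ModelSpec) -> int:
    if spec.lineage == "unstructured":
        return p * (p + 1) // 2
    if spec.lineage == "zero":
        return 0
    k = spec.fa_rank
    if k > p:
        raise UsageError(f"fa_rank {k} exceeds dimension {p}")
    return k * (2 * p - k + 1) // 2


def covariance_param_count(p: int, spec: ModelSpec, n_groups: int = 1) -> int:
    """Total covariance parameters: lineage structure + unstructured residual.

    A factor-analytic rank-k lineage term contributes k(2p-k+1)/2; the
    residual always contributes p(p+1)/2.  With separate-by-treatment the
    lineage part is counted once per group.
    """
    blocks = n_groups if spec.separate_by_treatment else 1
    return blocks * _n_lineage_params(p, spec) + p * (p + 1) // 2


def _tril_indices(p):
    return np.tril_indices(p)


def _fa_indices(p, k):
    rows, cols = [], []
    for j in range(k):
        for i in range(j, p):
            rows.append(i)
            cols.append(j)
    return np.array(rows, dtype=int), np.array(cols, dtype=int)


def _unpack(theta: np.ndarray, spec: ModelSpec, p: int, n_blocks: int):
    """theta -> (list of lineage covariance matrices, residual Cholesky)."""
    pos = 0
    Gs = []
    m_lin = _n_lineage_params(p, spec)
    for _ in range(n_blocks):
        if spec.lineage == "zero":
            Gs.append(np.zeros((p, p)))
        elif spec.lineage == "unstructured":
            L = np.zeros((p, p))
            L[_tril_indices(p)] = theta[pos:pos + m_lin]
            Gs.append(L @ L.T)
        else:
            k = spec.fa_rank
            lam = np.zeros((p, k))
            if k:
                ri, ci = _fa_indices(p, k)
                lam[ri, ci] = theta[pos:pos + m_lin]
            Gs.append(lam @ lam.T)
        pos += m_lin
    m_res = p * (p + 1) // 2
    LR = np.zeros((p, p))
    LR[_tril_indices(p)] = theta[pos:pos + m_res]
    return Gs, LR


def _pack_cov_tril(G: np.ndarray) -> np.ndarray:
    """Cholesky-like packing of a PSD matrix (eigen-repair if needed)."""
    p = G.shape[0]
    try:
        L = np.linalg.cholesky(G + 1e-10 * np.eye(p) * max(np.trace(G) / p, 1e-8))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((G + G.T) / 2.0)
        w = np.clip(w, 1e-8, None)
        L = np.linalg.cholesky(V @ np.diag(w) @ V.T)
    return L[np.tril_indices(p)]


def _pack_fa(G: np.ndarray, k: int) -> np.ndarray:
    """Lower-trapezoid loading packing of the best rank-k approximation."""
    p = G.shape[0]
    if k == 0:
        return np.zeros(0)
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(w)[::-1][:k]
    lam = V[:, order] * np.sqrt(np.clip(w[order], 1e-10, None))
    # rotate to lower-trapezoid form: lam.T = Q R  =>  lam = R.T Q.T and
    # R.T (p x k, lower-trapezoid) spans the same covariance
    _, Rt = np.linalg.qr(lam.T)
    L = Rt.T
    ri, ci = _fa_indices(p, k)
    return L[ri, ci]


# ---------------------------------------------------------------------------
# sufficient statistics and the factored restricted likelihood
# ---------------------------------------------------------------------------

class _RemlData:
    """Sufficient statistics of a balanced-or-not nested design."""

    def __init__(self, table: TraitTable):
        df = table.data
        self.p = len(TRAITS)
        groups = list(dict.fromkeys(df["treatment"]))
        self.groups = groups
        self.q = len(groups)
        ybars, rs, gidx = [], [], []
        S_C = np.zeros((self.p, self.p))
        M = 0
        n_obs_rows = 0
        for lin, sub in df.groupby("lineage_id", sort=False):
            Y = sub[list(TRAITS)].to_numpy(dtype=float)
            r = len(Y)
            yb = Y.mean(axis=0)
            dev = Y - yb
            S_C += dev.T @ dev
            M += r - 1
            ybars.append(yb)
            rs.append(r)
            gidx.append(groups.index(sub["treatment"].iloc[0]))
            n_obs_rows += r
        self.ybar = np.asarray(ybars)
        self.r = np.asarray(rs, dtype=float)
        self.gidx = np.asarray(gidx, dtype=int)
        self.S_C = S_C
        self.M = M
        self.N = len(self.r)
        self.n_obs = n_obs_rows * self.p
        self.f_fixed = self.q * self.p
        for g in range(self.q):
            if (self.gidx == g).sum() < 1:
                raise InsufficientDataError("empty treatment group")

    def minus2ll(self, Gs_or_theta, LR=None, spec: ModelSpec | None = None):
        """Restricted -2 log likelihood at given covariance parameters."""
        if LR is None:
            Gs, LR = _unpack(Gs_or_theta, spec,
                             self.p, self.q if spec.separate_by_treatment else 1)
        else:
            Gs = Gs_or_theta
        p = self.p
        d = np.abs(np.diag(LR))
        if np.any(d < 1e-10):
            return _BIG
        logdetR = 2.0 * np.sum(np.log(d))
        R = LR @ LR.T
        try:
            cR = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            return _BIG
        Rinv_SC = np.linalg.solve(R, self.S_C)
        val = self.M * logdetR + np.trace(Rinv_SC)
        for g in range(self.q):
            G = Gs[g] if len(Gs) > 1 else Gs[0]
            mask = self.gidx == g
            rg = self.r[mask]
            yg = self.ybar[mask]
            F = np.zeros((p, p))
            A = np.zeros(p)
            Winvs = {}
            logdetW_sum = 0.0
            for rv in np.unique(rg):
                W = rv * G + R
                try:
                    cW = np.linalg.cholesky(W)
                except np.linalg.LinAlgError:
                    return _BIG
                logdetW = 2.0 * np.sum(np.log(np.diag(cW)))
                Winv = np.linalg.inv(W)
                Winvs[rv] = (Winv, logdetW)
                sel = rg == rv
                logdetW_sum += logdetW * sel.sum()
                F += rv * sel.sum() * Winv
                A += rv * Winv @ yg[sel].sum(axis=0)
            try:
                cF = np.linalg.cholesky(F)
            except np.linalg.LinAlgError:
                return _BIG
            beta = np.linalg.solve(F, A)
            logdetF = 2.0 * np.sum(np.log(np.diag(cF)))
            quad = 0.0
            for rv, (Winv, _) in Winvs.items():
                sel = rg == rv
                dev = yg[sel] - beta
                quad += rv * np.einsum("ij,jk,ik->", dev, Winv, dev)
            val += logdetW_sum + logdetF + quad
        val += (self.n_obs - self.f_fixed) * _LOG2PI
        return float(val)

    def gls_means(self, Gs, R):
        """Per-group GLS mean estimates and their covariance matrices."""
        p = self.p
        betas, covs = [], []
        for g in range(self.q):
            G = Gs[g] if len(Gs) > 1 else Gs[0]
            mask = self.gidx == g
            rg = self.r[mask]
            yg = self.ybar[mask]
            F = np.zeros((p, p))
            A = np.zeros(p)
            for rv in np.unique(rg):
                W = rv * G + R
                Winv = np.linalg.inv(W)
                sel = rg == rv
                F += rv * sel.sum() * Winv
                A += rv * Winv @ yg[sel].sum(axis=0)
            Finv = np.linalg.inv(F)
            betas.append(Finv @ A)
            covs.append(Finv)
        return np.asarray(betas), covs

    def mom_start(self) -> tuple[np.ndarray, np.ndarray]:
        """Method-of-moments (G0, R0) from between/within decompositions."""
        p = self.p
        R0 = self.S_C / max(self.M, 1)
        if not np.all(np.isfinite(R0)) or self.M == 0:
            R0 = np.eye(p)
        S_W = np.zeros((p, p))
        for g in range(self.q):
            mask = self.gidx == g
            yg = self.ybar[mask]
            if mask.sum() >= 2:
                dev = yg - yg.mean(axis=0)
                S_W += dev.T @ dev
        denom = max(self.N - self.q, 1)
        V0 = S_W / denom
        rbar = self.r.mean()
        G0 = V0 - R0 / rbar
        w, V = np.linalg.eigh((G0 + G0.T) / 2.0)
        G0 = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
        w, V = np.linalg.eigh((R0 + R0.T) / 2.0)
        R0 = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
        return G0, R0


def dense_minus2ll(table: TraitTable, spec: ModelSpec, theta: np.ndarray) -> float:
    """Brute-force restricted -2 log likelihood via the full covariance.

    Assembles, per lineage, the dense r*p x r*p covariance
    J_r (x) D + I_r (x) R, stacks lineages into one block-diagonal
    system with the treatment-mean design matrix, and evaluates the
    standard REML expression directly.  Intended for tiny instances as
    an independent check of the factored evaluator.
    """
    df = table.data
    p = len(TRAITS)
    groups = list(dict.fromkeys(df["treatment"]))
    q = len(groups)
    Gs, LR = _unpack(theta, spec, p, q if spec.separate_by_treatment else 1)
    R = LR @ LR.T
    blocks, Xs, ys = [], [], []
    for lin, sub in df.groupby("lineage_id", sort=False):
        Y = sub[list(TRAITS)].to_numpy(dtype=float)
        r = len(Y)
        g = groups.index(sub["treatment"].iloc[0])
        G = Gs[g] if len(Gs) > 1 else Gs[0]
        blocks.append(np.kron(np.ones((r, r)), G) + np.kron(np.eye(r), R))
        X = np.zeros((r * p, q * p))
        X[:, g * p:(g + 1) * p] = np.tile(np.eye(p), (r, 1))
        Xs.append(X)
        ys.append(Y.reshape(-1))
    n = sum(b.shape[0] for b in blocks)
    Sigma = np.zeros((n, n))
    pos = 0
    for b in blocks:
        m = b.shape[0]
        Sigma[pos:pos + m, pos:pos + m] = b
        pos += m
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return _BIG
    Si_X = np.linalg.solve(Sigma, X)
    XtSiX = X.T @ Si_X
    sign2, logdet2 = np.linalg.slogdet(XtSiX)
    if sign2 <= 0:
        return _BIG
    beta = np.linalg.solve(XtSiX, Si_X.T @ y)
    resid = y - X @ beta
    quad = resid @ np.linalg.solve(Sigma, resid)
    f = X.shape[1]
    return float(logdet + logdet2 + quad + (n - f) * _LOG2PI)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _theta_start(data: _RemlData, spec: ModelSpec) -> np.ndarray:
    G0, R0 = data.mom_start()
    parts = []
    n_blocks = data.q if spec.separate_by_treatment else 1
    for _ in range(n_blocks):
        if spec.lineage == "unstructured":
            parts.append(_pack_cov_tril(G0))
        elif spec.lineage == "fa":
            parts.append(_pack_fa(G0, spec.fa_rank))
    parts.append(_pack_cov_tril(R0))
    return np.concatenate(parts) if parts else np.zeros(0)


def _check_standardized(data: _RemlData) -> None:
    mu = data.ybar.mean(axis=0)
    sd = data.ybar.std(axis=0, ddof=1) if data.N > 1 else np.ones(data.p)
    if np.abs(mu).max() > 0.5 or np.abs(sd - 1.0).max() > 0.5:
        warnings.warn(
            "trait table does not look standardized (lineage means far from "
            "mean 0 / sd 1); consider standardize_table()",
            stacklevel=3,
        )


def reml_fit(table: TraitTable, spec: ModelSpec | None = None,
             options: FitOptions | None = None,
             extra_starts: Sequence[np.ndarray] = ()) -> ModelFit:
    """Maximize the restricted likelihood over the spec's parameterization.

    Multi-start quasi-Newton optimization on unconstrained Cholesky /
    loading parameterizations; deterministic given data, spec and the
    options seed.  Raises :class:`ConvergenceError` (carrying the best
    fit found) only when every start fails outright.
    """
    spec = spec or ModelSpec()
    options = options or FitOptions()
    data = _RemlData(table)
    p = data.p
    for g in range(data.q):
        if (data.gidx == g).sum() < 2 and data.groups[g] != ANCESTOR:
            raise InsufficientDataError(
                f"treatment group {data.groups[g]!r} has < 2 lineages"
            )
    if options.warn_unstandardized:
        _check_standardized(data)
    if spec.lineage == "fa" and spec.fa_rank > p:
        raise UsageError(f"fa_rank {spec.fa_rank} > p {p}")

    theta0 = _theta_start(data, spec)
    obj = lambda th: data.minus2ll(th, spec=spec)  # noqa: E731
    rng = np.random.default_rng(options.seed)
    starts = [theta0] + [np.asarray(s, dtype=float) for s in extra_starts]
    scale = max(np.abs(theta0).max(), 0.1) if theta0.size else 0.1
    while len(starts) < max(options.n_starts, 1):
        starts.append(theta0 + 0.3 * scale * rng.standard_normal(theta0.shape))

    best = None
    n_iter_total = 0
    any_success = False
    for th0 in starts:
        if th0.shape != theta0.shape:
            continue
        try:
            res = optimize.minimize(
                obj, th0, method="L-BFGS-B",
                options={"maxiter": options.maxiter, "ftol": 1e-13,
                         "gtol": options.gtol, "maxcor": 20},
            )
        except Exception:
            continue
        n_iter_total += res.nit
        if not np.isfinite(res.fun) or res.fun >= _BIG / 2:
            continue
        any_success = True
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError("all optimizer starts failed", n_iter=n_iter_total)

    theta_hat = best.x
    n_blocks = data.q if spec.separate_by_treatment else 1
    Gs, LR = _unpack(theta_hat, spec, p, n_blocks)
    R = LR @ LR.T
    betas, bcovs = data.gls_means(Gs, R)
    n_params = covariance_param_count(p, spec, data.q)
    m2ll = float(best.fun)
    fixed = pd.DataFrame(betas, index=data.groups, columns=list(TRAITS))
    if spec.separate_by_treatment:
        lin_cov = {
            data.groups[g]: CovarianceMatrix(TRAITS, _sym(Gs[g]),
                                             int((data.gidx == g).sum()),
                                             "reml_lineage_level")
            for g in range(data.q)
        }
    else:
        lin_cov = CovarianceMatrix(TRAITS, _sym(Gs[0]), data.N, "reml_lineage_level")
    fit = ModelFit(
        minus2ll=m2ll,
        n_cov_params=n_params,
        aic=m2ll + 2 * n_params,
        lineage_cov=lin_cov,
        residual_cov=CovarianceMatrix(TRAITS, _sym(R), data.M, "reml_lineage_level"),
        fixed_effects=fixed,
        converged=any_success,
        n_iter=n_iter_total,
        spec=spec,
        theta=theta_hat,
        _wald={
            "betas": betas,
            "beta_covs": bcovs,
            "groups": data.groups,
            "n_obs": data.n_obs,
            "f_fixed": data.f_fixed,
            "p": p,
        },
    )
    return fit


def _sym(m):
    return (m + m.T) / 2.0


# ---------------------------------------------------------------------------
# tests built on fits
# ---------------------------------------------------------------------------

def likelihood_ratio_from_values(minus2ll_full: float, minus2ll_reduced: float,
                                 df: int) -> LRTResult:
    """Chi-square LRT from two -2 log likelihoods and a df."""
    if df < 1:
        raise UsageError("LRT requires df >= 1")
    chi2 = minus2ll_reduced - minus2ll_full
    if chi2 < 0:
        if chi2 < -1e-6:
            warnings.warn(
                f"negative LR statistic {chi2:.3g} clipped to 0 "
                "(reduced model fit better than full; check convergence)"
            )
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=float(chi2), df=int(df), p_value=p)


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Nested LRT between two fits; df from the parameter-count difference."""
    if reduced.n_cov_params >= full.n_cov_params:
        raise UsageError(
            "reduced model must have fewer covariance parameters than the full"
        )
    df = full.n_cov_params - reduced.n_cov_params
    return likelihood_ratio_from_values(full.minus2ll, reduced.minus2ll, df)


def estimate_rank(table: TraitTable, options: FitOptions | None = None,
                  alpha: float = 0.05) -> RankTestTable:
    """Factor-analytic rank ladder for the pooled D matrix.

    Fits FA(k) for k = p down to 0 (ancestor rows excluded), testing each
    rank against the one below; the selected rank is the largest k whose
    k vs k-1 test is significant at ``alpha``, scanning downward from p.
    Warm starts carry the truncated higher-rank solution into each lower
    fit, and a higher-rank fit is refitted from a padded lower-rank
    solution if the ladder ever turns non-monotone.
    """
    options = options or FitOptions()
    table = table.without_ancestor()
    p = len(TRAITS)
    fits: dict[int, ModelFit] = {}
    prev = None
    for k in range(p, -1, -1):
        spec = ModelSpec(lineage="fa", fa_rank=k) if k else ModelSpec(lineage="zero")
        extra = []
        if prev is not None and k:
            extra.append(_truncate_fa_theta(prev, k, p))
        fits[k] = reml_fit(table, spec, options, extra_starts=extra)
        prev = fits[k]
    # monotonicity repair: pad the lower solution upward if needed
    for k in range(0, p):
        if fits[k + 1].minus2ll > fits[k].minus2ll + 1e-6:
            spec = ModelSpec(lineage="fa", fa_rank=k + 1)
            padded = _pad_fa_theta(fits[k], k + 1, p)
            refit = reml_fit(table, spec, options, extra_starts=[padded])
            if refit.minus2ll < fits[k + 1].minus2ll:
                fits[k + 1] = refit

    rows = []
    for k in range(p, 0, -1):
        lrt = likelihood_ratio_test(fits[k], fits[k - 1])
        f = fits[k]
        rows.append(RankTestRow(k, f.minus2ll, f.n_cov_params, f.aic, lrt.p_value))
    f0 = fits[0]
    rows.append(RankTestRow(0, f0.minus2ll, f0.n_cov_params, f0.aic, None))
    selected = 0
    for row in rows[:-1]:
        if row.p_value is not None and row.p_value < alpha:
            selected = row.dimensions
            break
    return RankTestTable(rows=rows, selected_rank=selected, alpha=alpha)


def _truncate_fa_theta(fit: ModelFit, k: int, p: int) -> np.ndarray:
    """Start for FA(k) from a higher-rank (or unstructured) fit's D and R."""
    G = fit.lineage_cov.values if isinstance(fit.lineage_cov, CovarianceMatrix) else None
    R = fit.residual_cov.values
    return np.concatenate([_pack_fa(G, k), _pack_cov_tril(R)])


def _pad_fa_theta(fit: ModelFit, k: int, p: int) -> np.ndarray:
    """Start for FA(k) from a lower-rank fit, extra loadings near zero."""
    G = fit.lineage_cov.values if isinstance(fit.lineage_cov, CovarianceMatrix) \
        else np.zeros((p, p))
    lam_small = _pack_fa(G + 1e-8 * np.eye(p), k)
    return np.concatenate([lam_small, _pack_cov_tril(fit.residual_cov.values)])


def treatment_mean_test(fit: ModelFit) -> tuple[float, int, int, float]:
    """Wald F-test of the treatment difference in multivariate means.

    Tests the joint p-dimensional contrast between treatment-group means
    (ancestor group excluded if present), with denominator df by the
    residual method (total observations minus fixed-effect rank).
    Returns (F, num_df, den_df, p_value).
    """
    if fit._wald is None:
        raise UsageError("fit carries no fixed-effect information")
    w = fit._wald
    groups = [g for g in w["groups"] if g != ANCESTOR]
    if len(groups) < 2:
        raise UsageError("treatment test requires >= 2 non-ancestor groups")
    idx = [w["groups"].index(g) for g in groups]
    p = w["p"]
    # stacked successive contrasts between group means
    deltas, Vs = [], []
    for a, b in zip(idx[:-1], idx[1:]):
        deltas.append(w["betas"][a] - w["betas"][b])
        Vs.append(w["beta_covs"][a] + w["beta_covs"][b])
    num_df = p * (len(groups) - 1)
    if len(deltas) == 1:
        d = deltas[0]
        F = float(d @ np.linalg.solve(Vs[0], d)) / num_df
    else:
        # block system ignoring cross-contrast covariance is wrong for >2
        # groups sharing a middle mean; build the full joint covariance
        k = len(deltas)
        V = np.zeros((k * p, k * p))
        for i in range(k):
            V[i * p:(i + 1) * p, i * p:(i + 1) * p] = Vs[i]
        for i in range(k - 1):
            C = -w["beta_covs"][idx[i + 1]]
            V[i * p:(i + 1) * p, (i + 1) * p:(i + 2) * p] = C
            V[(i + 1) * p:(i + 2) * p, i * p:(i + 1) * p] = C.T
        d = np.concatenate(deltas)
        F = float(d @ np.linalg.solve(V, d)) / num_df
    F = max(F, 0.0)
    den_df = int(w["n_obs"] - w["f_fixed"])
    pval = float(stats.f.sf(F, num_df, den_df))
    return F, num_df, den_df, pval


def separate_vs_pooled_D(table: TraitTable,
                         options: FitOptions | None = None) -> LRTResult:
    """LRT of treatment-specific versus pooled lineage-level covariance.

    Both models use an unstructured lineage covariance; the ancestor is
    excluded.  df = (groups - 1) * p(p+1)/2.
    """
    options = options or FitOptions()
    table = table.without_ancestor()
    groups = table.treatments()
    if len(groups) != 2:
        raise UsageError(
            f"pooled-vs-separate test requires exactly 2 treatment groups, "
            f"got {len(groups)}"
        )
    p = len(TRAITS)
    pooled = reml_fit(table, ModelSpec(lineage="unstructured"), options)
    # warm start each group's block at the pooled solution
    m_lin = p * (p + 1) // 2
    pooled_start = np.concatenate(
        [pooled.theta[:m_lin], pooled.theta[:m_lin], pooled.theta[m_lin:]]
    )
    sep = reml_fit(
        table, ModelSpec(lineage="unstructured", separate_by_treatment=True),
        options, extra_starts=[pooled_start],
    )
    df = (len(groups) - 1) * p * (p + 1) // 2
    return likelihood_ratio_from_values(sep.minus2ll, pooled.minus2ll, df)
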