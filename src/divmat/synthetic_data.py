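"""Synthetic experimental-evolution datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: lineages nested in bottleneck treatments, each lineage carrying a
multivariate-normal "lineage effect" drawn from a true among-lineage
covariance (the true D matrix, whose rank is controllable), replicate
colonies adding independent residual noise, and a fitness (adaptation)
value correlated with each lineage's multivariate distance from the
ancestor.  Defaults mirror the emulated design: 2 treatments x 30 lineages
x 3 replicates plus a triplicate ancestor.

All randomness flows from one root seed through independent child streams
(lineage effects, residuals, fitness, basis generation), so toggling the
fitness model does not perturb the trait draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trait_data import (
    ANCESTOR,
    FITNESS,
    TRAITS,
    CovarianceMatrix,
    LineageMeans,
    TraitTable,
    UsageError,
    lineage_means,
    sample_covariance,
)

#: guard added inside the log of the fitness model so a zero distance
#: cannot produce -inf
LN_DISTANCE_GUARD = 1e-6


def default_true_D() -> CovarianceMatrix:
    """Full-rank among-lineage covariance used as the generator default.

    Values are a realistic 4-trait divergence matrix for this system
    (variances near 1-2 on the analysis scale, a moderate positive
    BM-CFU covariance and a negative DPL-SFB covariance).
    """
    v = np.array(
        [
            [1.727, 0.464, 0.291, -0.002],
            [0.464, 0.881, 0.297, -0.049],
            [0.291, 0.297, 1.518, -0.682],
            [-0.002, -0.049, -0.682, 2.271],
        ]
    )
    return CovarianceMatrix(TRAITS, v, 0, "ground_truth")


@dataclass(frozen=True)
class SimulationConfig:
    """Design and distributional parameters of a simulated experiment.

    Trait values are generated directly on the analysis (post-ln) scale;
    set ``raw_scale=True`` to exponentiate CFU/DPL/SFB so the written
    table exercises the full pipeline including the log transform.

    Fitness model: adaptation_i = alpha + beta * ln(d_i_true + guard) +
    N(0, sigma_f) per lineage, where d_i_true is the lineage's true
    Mahalanobis distance from the ancestor.  The defaults for beta and
    sigma_f were fixed once by the calibration helper so that the
    recovered distance-adaptation correlation at the default design size
    (n = 60 lineages) averages ~0.26.
    """

    n_treatments: int = 2
    lineages_per_treatment: int = 30
    replicates_per_lineage: int = 3
    ancestor_replicates: int = 3
    true_D: CovarianceMatrix = field(default_factory=default_true_D)
    residual_cov: np.ndarray | None = None  # default 0.25 * I
    treatment_shift: np.ndarray | None = None  # default zeros (null result)
    ancestor_mean: np.ndarray | None = None
    ancestor_fitness: float = 5.0
    fitness_intercept: float = 0.5
    fitness_slope: float = 0.05
    fitness_noise_sd: float = 0.0591
    raw_scale: bool = False
    seed: int = 0

    def __post_init__(self):
        p = self.true_D.p
        res = self.residual_cov
        if res is None:
            res = 0.25 * np.eye(p)
        res = np.asarray(res, dtype=float)
        shift = self.treatment_shift
        if shift is None:
            shift = np.zeros(p)
        shift = np.asarray(shift, dtype=float)
        anc = self.ancestor_mean
        if anc is None:
            anc = np.array([7.46, 21.71, 3.88, 3.87])[:p] if p <= 4 else np.zeros(p)
        anc = np.asarray(anc, dtype=float)
        object.__setattr__(self, "residual_cov", res)
        object.__setattr__(self, "treatment_shift", shift)
        object.__setattr__(self, "ancestor_mean", anc)
        if res.shape != (p, p) or shift.shape != (p,) or anc.shape != (p,):
            raise UsageError("dimension mismatch in simulation config")
        w = np.linalg.eigvalsh((res + res.T) / 2.0)
        if w.min() < -1e-8 * max(np.trace(res), 1e-12):
            raise UsageError("residual_cov is not PSD")
        for name in ("n_treatments", "lineages_per_treatment",
                     "replicates_per_lineage", "ancestor_replicates"):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be >= 1")

    @property
    def p(self) -> int:
        return self.true_D.p


@dataclass(frozen=True)
class GroundTruth:
    """Per-lineage ground truth of a simulated experiment."""

    lineage_ids: tuple[str, ...]
    treatments: tuple[str, ...]
    effects: np.ndarray            # n x p lineage effect vectors (incl. shift)
    true_distances: np.ndarray     # true Mahalanobis distance from ancestor
    true_D: CovarianceMatrix
    true_rank: int
    expected_adaptation: np.ndarray  # alpha + beta * ln(d_true + guard)
    adaptation: np.ndarray           # realized, with lineage-level noise

    def to_json_dict(self) -> dict:
        return {
            "lineage_ids": list(self.lineage_ids),
            "treatments": list(self.treatments),
            "effects": self.effects.tolist(),
            "true_distances": self.true_distances.tolist(),
            "true_D": self.true_D.values.tolist(),
            "true_rank": self.true_rank,
            "expected_adaptation": self.expected_adaptation.tolist(),
            "adaptation": self.adaptation.tolist(),
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("lineage", "residual", "fitness", "basis")
    return {k: np.random.default_rng(s) for k, s in zip(names, children)}


def make_rank_k_cov(p: int, k: int, eigenvalues: Sequence[float],
                    seed: int = 0) -> CovarianceMatrix:
    """A p x p PSD matrix with numerical rank exactly k.

    Returns B diag(eigenvalues) B^T with B a seeded random p x k
    orthonormal basis; k = 0 gives the zero matrix.
    """
    if not 0 <= k <= p:
        raise UsageError(f"rank k={k} out of range for p={p}")
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if eigenvalues.shape != (k,):
        raise UsageError(f"need exactly k={k} eigenvalues")
    if k and np.any(eigenvalues <= 0):
        raise UsageError("eigenvalues must be strictly positive")
    labels = TRAITS if p == len(TRAITS) else tuple(f"T{i + 1}" for i in range(p))
    if k == 0:
        return CovarianceMatrix(labels, np.zeros((p, p)), 0, "ground_truth")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    B, _ = np.linalg.qr(rng.standard_normal((p, k)))
    v = B @ np.diag(eigenvalues) @ B.T
    return CovarianceMatrix(labels, (v + v.T) / 2.0, 0, "ground_truth")


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Factor A with A A^T = m, valid for singular PSD matrices."""
    w, V = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _true_mahalanobis(deltas: np.ndarray, true_D: np.ndarray) -> np.ndarray:
    """Distance in the true-D metric; pseudo-inverse for singular truth."""
    if np.allclose(true_D, 0.0):
        return np.zeros(len(deltas))
    inv = np.linalg.pinv(true_D, rcond=1e-10, hermitian=True)
    q = np.einsum("ij,jk,ik->i", deltas, inv, deltas)
    return np.sqrt(np.clip(q, 0.0, None))


def simulate_fitness(truth: GroundTruth, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-lineage adaptation values from the distance-dependent model.

    Uses the config's dedicated fitness stream when no generator is
    passed, so values match those produced inside
    :func:`simulate_experiment` for the same config.
    """
    if rng is None:
        rng = _streams(config.seed)["fitness"]
    expected = (config.fitness_intercept
                + config.fitness_slope
                * np.log(truth.true_distances + LN_DISTANCE_GUARD))
    noise = config.fitness_noise_sd * rng.standard_normal(len(expected))
    return expected + noise


def simulate_experiment(config: SimulationConfig) -> tuple[TraitTable, GroundTruth]:
    """Draw one replicate-level dataset plus its ground truth.

    Each evolved replicate value is ancestor_mean + treatment_shift (one
    treatment only) + lineage effect + residual draw; ancestor replicates
    have zero lineage effect and no shift.  Identical configs (same seed)
    produce identical tables.
    """
    p = config.p
    rngs = _streams(config.seed)
    tD = config.true_D.values
    A_lin = _psd_factor(tD)
    A_res = _psd_factor(config.residual_cov)
    n_lin = config.n_treatments * config.lineages_per_treatment

    z = rngs["lineage"].standard_normal((n_lin, p))
    effects = z @ A_lin.T
    treat_names = ["small", "large"][: config.n_treatments]
    if config.n_treatments > 2:
        raise UsageError("at most 2 treatments are supported")
    treatments, ids = [], []
    for gi, tn in enumerate(treat_names):
        for li in range(config.lineages_per_treatment):
            ids.append(f"{tn[0].upper()}{li + 1:02d}")
            treatments.append(tn)
    # the shift applies to one treatment ("large"); zero by default
    shift = np.zeros((n_lin, p))
    if config.n_treatments == 2:
        shift[np.array(treatments) == "large"] = config.treatment_shift
    deltas = effects + shift
    true_d = _true_mahalanobis(deltas, tD)
    rank = int(np.linalg.matrix_rank(tD, tol=1e-10 * max(np.abs(tD).max(), 1e-30)))

    truth = GroundTruth(
        lineage_ids=tuple(ids),
        treatments=tuple(treatments),
        effects=deltas,
        true_distances=true_d,
        true_D=config.true_D,
        true_rank=rank,
        expected_adaptation=(config.fitness_intercept
                             + config.fitness_slope
                             * np.log(true_d + LN_DISTANCE_GUARD)),
        adaptation=np.zeros(n_lin),
    )
    adaptation = simulate_fitness(truth, config, rngs["fitness"])
    truth = GroundTruth(
        truth.lineage_ids, truth.treatments, truth.effects,
        truth.true_distances, truth.true_D, truth.true_rank,
        truth.expected_adaptation, adaptation,
    )

    r = config.replicates_per_lineage
    rows = []
    res = rngs["residual"].standard_normal((n_lin * r + config.ancestor_replicates, p))
    res = res @ A_res.T
    ri = 0
    for k in range(n_lin):
        base = config.ancestor_mean + deltas[k]
        mgr = config.ancestor_fitness + adaptation[k]
        for j in range(r):
            y = base + res[ri]
            ri += 1
            rows.append((ids[k], treatments[k], f"r{j + 1}", *y, mgr))
    for j in range(config.ancestor_replicates):
        y = config.ancestor_mean + res[ri]
        ri += 1
        rows.append(("ANC", ANCESTOR, f"r{j + 1}", *y, config.ancestor_fitness))

    df = pd.DataFrame(
        rows,
        columns=["lineage_id", "treatment", "replicate_id", *TRAITS, FITNESS],
    )
    transform_log: tuple = ()
    if config.raw_scale:
        for t in ("CFU", "DPL", "SFB"):
            df[t] = np.exp(df[t])
    else:
        # already on the analysis scale: mark ln as applied so the
        # default transform is refused rather than applied twice
        transform_log = tuple((t, "ln") for t in ("CFU", "DPL", "SFB"))
    return TraitTable(df, transform_log), truth


def measured_distance_correlation(config: SimulationConfig) -> tuple[float, int]:
    """Pooled correlation between adaptation and measured ln distance.

    Runs the standard distance pipeline on one simulated dataset: lineage
    means with the ancestor included, ancestor-included D, Mahalanobis
    distances, then the Pearson correlation over evolved lineages.
    Returns (r, n_evolved).
    """
    from .divergence_geometry import adaptation_distance_analysis, mahalanobis_distances

    table, _ = simulate_experiment(config)
    lm = lineage_means(table)
    cov = sample_covariance(lm)
    records = mahalanobis_distances(lm, cov)
    res = adaptation_distance_analysis(records, min_per_group=1)
    return res.pooled_r, res.pooled_n


def calibrate_fitness_noise(config: SimulationConfig | None = None,
                            target_r: float = 0.262,
                            n_seeds: int = 400,
                            seed: int = 12345) -> tuple[float, float]:
    """Find sigma_f so the expected recovered correlation matches a target.

    With beta fixed at the config's slope, simulates noise-free fitness to
    estimate (i) the sd of beta*ln(d_true) across lineages and (ii) the
    attenuation from measuring distance through noisy replicate means,
    then solves r_target = beta*s*rho / sqrt(beta^2 s^2 + sigma_f^2) for
    sigma_f.  Returns (beta, sigma_f).
    """
    import dataclasses

    base = config or SimulationConfig()
    rs, s_true = [], []
    ss = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for s in ss:
        cfg = dataclasses.replace(base, fitness_noise_sd=0.0, seed=int(s))
        r, _ = measured_distance_correlation(cfg)
        rs.append(r)
        _, truth = simulate_experiment(cfg)
        s_true.append(np.std(np.log(truth.true_distances + LN_DISTANCE_GUARD), ddof=1))
    rho = float(np.mean(rs))  # corr at sigma_f = 0 (includes attenuation)
    s = float(np.mean(s_true)) * base.fitness_slope
    if not 0 < target_r < rho:
        raise UsageError(
            f"target r={target_r} not attainable (noise-free r ~= {rho:.3f})"
        )
    sigma_f = s * np.sqrt((rho / target_r) ** 2 - 1.0)
    return base.fitness_slope, float(sigma_f)
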