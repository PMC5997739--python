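"""Synthetic Likert-item data with a binary gold-standard criterion.

The generator emulates a common screener-validation design: ``n``
respondents answer four-point Likert items (scored 0-3) that load on a
small number of correlated latent factors, and each respondent also has
a binary criterion (a diagnosis from a gold-standard interview) linked
to the same factors.  Continuous item responses are loading-weighted
factor scores plus unique noise (unit total variance), discretized at
per-item thresholds; the criterion is a liability (weighted factors plus
independent noise) thresholded at the quantile implied by the target
prevalence.

Population ("design-implied") correlation structures are available in
two flavours: the latent continuous correlations
(:func:`design_implied_structure`) and the exact Pearson correlations of
the *discretized* scores (:func:`discretized_structure`), the latter via
bivariate-normal rectangle probabilities.  Both serve as closed-form
oracles for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .exceptions import DegenerateInputError
from .selection import compare_goals
from .structures import CorrelationStructure

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]

#: default cut points: equal-probability quartiles of a standard normal,
#: giving four Likert categories 0-3 with 25% mass each
DEFAULT_THRESHOLDS = tuple(float(t) for t in norm.ppf([0.25, 0.5, 0.75]))


@dataclass(frozen=True)
class CriterionLink:
    """How the binary criterion hangs off the latent factors.

    ``weights`` are per-factor loadings of the liability; ``noise_var``
    is the variance of its independent noise; ``prevalence`` is the
    population proportion of positives (the liability is cut at its own
    ``1 - prevalence`` quantile).
    """

    weights: np.ndarray
    noise_var: float
    prevalence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterization of one synthetic sample."""

    loadings: np.ndarray
    factor_corr: np.ndarray
    crit_link: CriterionLink
    n: int
    seed: int = 0
    thresholds: Optional[tuple] = None  # per item; None = quartile default
    labels: Optional[tuple] = None  # None = 1..n_items

    def __post_init__(self) -> None:
        L = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        object.__setattr__(self, "loadings", L)
        object.__setattr__(
            self, "factor_corr", np.asarray(self.factor_corr, dtype=float)
        )
        if self.thresholds is not None:
            object.__setattr__(
                self,
                "thresholds",
                tuple(tuple(float(x) for x in t) for t in self.thresholds),
            )
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(range(1, L.shape[0] + 1)))
        else:
            object.__setattr__(self, "labels", tuple(self.labels))
        self.validate()

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def item_thresholds(self) -> list:
        """Per-item threshold arrays, substituting the quartile default."""
        if self.thresholds is None:
            return [np.array(DEFAULT_THRESHOLDS)] * self.n_items
        return [np.asarray(t, dtype=float) for t in self.thresholds]

    def communalities(self) -> np.ndarray:
        """Variance of each latent item response explained by the factors."""
        return np.einsum(
            "if,fg,ig->i", self.loadings, self.factor_corr, self.loadings
        )

    def validate(self) -> None:
        """Raise ``ValueError`` listing every invalid field at once."""
        problems = []
        P = self.factor_corr
        if P.shape != (self.n_factors, self.n_factors):
            problems.append("factor_corr shape does not match the loadings")
        else:
            if not np.allclose(P, P.T, atol=1e-10):
                problems.append("factor_corr is not symmetric")
            if not np.allclose(np.diag(P), 1.0):
                problems.append("factor_corr diagonal must be 1")
            if float(np.linalg.eigvalsh(P).min()) < -1e-8:
                problems.append("factor_corr is not positive semidefinite")
        if np.any(self.communalities() > 1.0 + 1e-10):
            problems.append("item communality exceeds 1 (loadings too large)")
        if self.thresholds is not None:
            if len(self.thresholds) != self.n_items:
                problems.append("one threshold sequence per item is required")
            for lab, t in zip(self.labels, self.thresholds):
                if len(t) < 1 or np.any(np.diff(t) <= 0):
                    problems.append(
                        f"thresholds for item {lab!r} must be strictly increasing"
                    )
        w = self.crit_link.weights
        if w.shape != (self.n_factors,):
            problems.append("criterion weights length must equal factor count")
        if self.crit_link.noise_var < 0:
            problems.append("criterion noise variance must be nonnegative")
        if not 0.0 < self.crit_link.prevalence < 1.0:
            problems.append("prevalence must be in (0, 1)")
        if self.n < 2:
            problems.append("sample size n must be at least 2")
        if len(self.labels) != self.n_items:
            problems.append("labels length must equal the number of items")
        if problems:
            raise ValueError("invalid design: " + "; ".join(problems))

    def liability_sd(self) -> float:
        w = self.crit_link.weights
        return float(np.sqrt(w @ self.factor_corr @ w + self.crit_link.noise_var))


@dataclass(frozen=True)
class ItemResponseData:
    """Respondent-by-item integer scores plus a binary criterion vector."""

    scores: np.ndarray
    criterion: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        c = np.asarray(self.criterion)
        if s.ndim != 2 or c.shape != (s.shape[0],):
            raise ValueError("scores must be n x p with a length-n criterion")
        if not np.isin(np.unique(c), [0, 1]).all():
            raise ValueError("criterion must be binary 0/1")
        object.__setattr__(self, "scores", s.astype(int))
        object.__setattr__(self, "criterion", c.astype(int))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def default_design(n: int = 242, seed: int = 0) -> SimulationDesign:
    """Default emulation preset: a 10-item screener pretest.

    Ten four-point items on two factors correlated at 0.4 — six items on
    the first factor, four on the second, loadings spread over 0.5-0.8 —
    with a binary criterion loading equally on both factors at
    prevalence 0.25 and n = 242.  This mirrors the mixed structure of
    the bundled worked example without claiming to reproduce its
    (unpublished) raw data.
    """
    loadings = np.zeros((10, 2))
    loadings[:6, 0] = np.linspace(0.5, 0.8, 6)
    loadings[6:, 1] = np.linspace(0.5, 0.8, 4)
    factor_corr = np.array([[1.0, 0.4], [0.4, 1.0]])
    w = np.array([0.5, 0.5])
    noise_var = 1.0 - float(w @ factor_corr @ w)  # unit-variance liability
    return SimulationDesign(
        loadings=loadings,
        factor_corr=factor_corr,
        crit_link=CriterionLink(weights=w, noise_var=noise_var, prevalence=0.25),
        n=n,
        seed=seed,
    )


def _factor_sqrt(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(P)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def simulate_sample(design: SimulationDesign, seed: SeedLike = None) -> ItemResponseData:
    """Draw one sample from a design.

    ``seed`` overrides ``design.seed`` when given; the same design and
    seed always produce identical output.
    """
    design.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(design.seed if seed is None else seed)
    )
    n, p, m = design.n, design.n_items, design.n_factors
    F = rng.standard_normal((n, m)) @ _factor_sqrt(design.factor_corr).T
    uniq_sd = np.sqrt(np.clip(1.0 - design.communalities(), 0.0, None))
    z = F @ design.loadings.T + rng.standard_normal((n, p)) * uniq_sd
    scores = np.empty((n, p), dtype=int)
    for j, t in enumerate(design.item_thresholds()):
        scores[:, j] = np.digitize(z[:, j], t)
    link = design.crit_link
    liability = F @ link.weights + rng.standard_normal(n) * np.sqrt(link.noise_var)
    cut = norm.ppf(1.0 - link.prevalence) * design.liability_sd()
    criterion = (liability > cut).astype(int)
    return ItemResponseData(scores=scores, criterion=criterion, labels=design.labels)


def estimate_structure(data: ItemResponseData) -> CorrelationStructure:
    """Pearson correlation structure estimated from raw responses.

    Inter-item Pearson correlations, per-item SDs (denominator n-1),
    and Pearson (point-biserial) item-criterion correlations.
    """
    X = data.scores.astype(float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 respondents, got {n}")
    sds = X.std(axis=0, ddof=1)
    constant = [data.labels[j] for j in range(p) if sds[j] == 0]
    if constant:
        raise DegenerateInputError(
            f"constant item column(s): {constant!r}; correlations are undefined"
        )
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    y = data.criterion.astype(float)
    if y.std() == 0:
        raise DegenerateInputError("criterion column is constant")
    yc = (y - y.mean()) / y.std()
    Xc = (X - X.mean(axis=0)) / X.std(axis=0)
    r_crit = np.clip(Xc.T @ yc / n, -1.0, 1.0)
    return CorrelationStructure(
        labels=data.labels, R=R, sd=sds, r_crit=r_crit, n_obs=n
    )


# -- closed-form population structures --------------------------------------


def design_implied_structure(design: SimulationDesign) -> CorrelationStructure:
    """Correlations of the *latent continuous* item responses.

    ``R = Lambda Phi Lambda' + diag(uniquenesses)`` with unit variances;
    the item-criterion column is the latent response-liability
    correlation.  Pearson correlations of the discretized scores are
    attenuated relative to these; see :func:`discretized_structure`.
    """
    L, P = design.loadings, design.factor_corr
    R = L @ P @ L.T
    np.fill_diagonal(R, 1.0)
    w = design.crit_link.weights
    r_crit = (L @ P @ w) / design.liability_sd()
    return CorrelationStructure(labels=design.labels, R=R, sd=None, r_crit=r_crit)


def _std_bvn_rect(a: float, b: float, rho: float) -> float:
    """P(Z1 > a, Z2 > b) for standard bivariate normal with correlation rho."""
    if rho >= 1.0 - 1e-12:
        return float(norm.sf(max(a, b)))
    if rho <= -1.0 + 1e-12:
        return float(max(0.0, norm.cdf(-a) - norm.cdf(b)))
    cdf = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf
    return float(1.0 - norm.cdf(a) - norm.cdf(b) + cdf([a, b]))


def _discrete_cov(ta: np.ndarray, tb: np.ndarray, rho: float) -> float:
    """Covariance of two threshold-counted scores of correlated normals.

    A score is the number of thresholds the latent value exceeds, so
    ``cov = sum_{a,b} [P(z1 > t_a, z2 > t_b) - P(z1 > t_a) P(z2 > t_b)]``.
    """
    total = 0.0
    for a in ta:
        for b in tb:
            total += _std_bvn_rect(a, b, rho) - norm.sf(a) * norm.sf(b)
    return total


def discretized_structure(design: SimulationDesign) -> CorrelationStructure:
    """Exact population Pearson structure of the *discretized* scores.

    Evaluates bivariate-normal rectangle probabilities over all
    threshold pairs to produce the correlations, SDs, and point-biserial
    criterion correlations that :func:`estimate_structure` converges to
    as n grows.
    """
    design.validate()
    thr = design.item_thresholds()
    latent = design_implied_structure(design)
    p = design.n_items
    var = np.array([_discrete_cov(thr[j], thr[j], 1.0) for j in range(p)])
    sd = np.sqrt(var)
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            c = _discrete_cov(thr[i], thr[j], float(latent.R[i, j]))
            R[i, j] = R[j, i] = c / (sd[i] * sd[j])
    prev = design.crit_link.prevalence
    t_y = norm.ppf(1.0 - prev)
    r_latent = latent.r_crit
    r_crit = np.empty(p)
    for j in range(p):
        cov_jy = sum(
            _std_bvn_rect(a, t_y, float(r_latent[j])) - norm.sf(a) * prev
            for a in thr[j]
        )
        r_crit[j] = cov_jy / (sd[j] * np.sqrt(prev * (1.0 - prev)))
    return CorrelationStructure(labels=design.labels, R=R, sd=sd, r_crit=r_crit)


# -- the measurement-versus-prediction experiment ---------------------------


@dataclass(frozen=True)
class TradeoffResult:
    """Replication-level and summary results of a goal-comparison run."""

    design: SimulationDesign
    k: int
    per_rep: pd.DataFrame
    summary: pd.DataFrame
    mean_overlap: float


def tradeoff_experiment(
    design: SimulationDesign,
    k: int,
    reps: int,
    seed: SeedLike = None,
) -> TradeoffResult:
    """Replicate simulate -> estimate -> select under both objectives.

    Each replication draws a fresh sample, estimates its correlation
    structure, and runs backward selection at size ``k`` under the
    measurement and the prediction objective; both final scales are
    scored on both metrics.  Summary rows give mean and SD per arm and
    metric plus the mean subset overlap.
    """
    if reps < 1:
        raise ValueError(f"need at least 1 replication, got {reps}")
    ss = np.random.SeedSequence(design.seed if seed is None else seed)
    rows = []
    for rep, child in enumerate(ss.spawn(reps)):
        data = simulate_sample(design, seed=np.random.default_rng(child))
        est = estimate_structure(data)
        cmp_ = compare_goals(est, k)
        rows.append(
            {
                "rep": rep,
                "alpha_measurement": cmp_.measurement.alpha,
                "validity_measurement": cmp_.measurement.validity,
                "alpha_prediction": cmp_.prediction.alpha,
                "validity_prediction": cmp_.prediction.validity,
                "overlap": cmp_.overlap_size,
            }
        )
    per_rep = pd.DataFrame(rows)
    metrics = [c for c in per_rep.columns if c not in ("rep", "overlap")]
    summary = pd.DataFrame(
        {
            "mean": per_rep[metrics].mean(),
            "sd": per_rep[metrics].std(ddof=1) if reps > 1 else np.nan,
        }
    )
    return TradeoffResult(
        design=design,
        k=k,
        per_rep=per_rep,
        summary=summary,
        mean_overlap=float(per_rep["overlap"].mean()),
    )
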