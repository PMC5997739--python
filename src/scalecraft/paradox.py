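"""Population true-score models and the reliability-versus-alpha paradox.

In classical test theory an observed item score decomposes as
``X_i = T_i + E_i`` with errors mutually uncorrelated and uncorrelated
with true scores.  A :class:`TrueScoreModel` fixes the true-score
covariance matrix ``Sigma_T`` and per-item error variances, which makes
the *definition* of reliability computable,

    ``reliability = var(sum T_i) / var(sum X_i)``,

alongside coefficient alpha evaluated on the model-implied item
covariance ``Sigma_T + diag(error_var)``.  Alpha is a lower bound to
reliability, and the gap widens as the true scores decorrelate: with
mutually *orthogonal* but individually reliable items
(:func:`build_orthogonal_model`), alpha is exactly zero while the
reliability can be arbitrarily high — the paradox that makes internal
consistency a poor reliability estimate for prediction-oriented scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError

_PSD_TOL = -1e-8


@dataclass(frozen=True)
class TrueScoreModel:
    """Item true-score covariance, error variances, optional criterion link.

    The criterion, when present, is ``Y = w' T + e`` with weights
    ``crit_weights`` over item true scores and independent noise of
    variance ``crit_noise_var`` — the premise under which the validity
    ceiling ``rho_XY <= sqrt(reliability)`` holds.
    """

    Sigma_T: np.ndarray
    error_var: np.ndarray
    crit_weights: Optional[np.ndarray] = None
    crit_noise_var: float = 0.0

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma_T, dtype=float)
        e = np.asarray(self.error_var, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("Sigma_T must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("Sigma_T must be symmetric")
        if float(np.linalg.eigvalsh(S).min()) < _PSD_TOL:
            raise ValueError("Sigma_T must be positive semidefinite")
        if e.shape != (S.shape[0],):
            raise ValueError("error_var length must match Sigma_T")
        if np.any(e < 0):
            raise ValueError("error variances must be nonnegative")
        object.__setattr__(self, "Sigma_T", S)
        object.__setattr__(self, "error_var", e)
        if self.crit_weights is not None:
            w = np.asarray(self.crit_weights, dtype=float)
            if w.shape != (S.shape[0],):
                raise ValueError("crit_weights length must match Sigma_T")
            object.__setattr__(self, "crit_weights", w)
        if self.crit_noise_var < 0:
            raise ValueError("criterion noise variance must be nonnegative")

    @property
    def n_items(self) -> int:
        return self.Sigma_T.shape[0]

    def implied_item_cov(self) -> np.ndarray:
        """Observed-score covariance: ``Sigma_T + diag(error_var)``."""
        return self.Sigma_T + np.diag(self.error_var)

    def sum_score_variance(self) -> float:
        return float(self.implied_item_cov().sum())


def model_reliability(model: TrueScoreModel) -> float:
    """Reliability of the sum score: true-score variance over total variance."""
    var_x = model.sum_score_variance()
    if var_x <= 0:
        raise DegenerateInputError("model implies a zero-variance sum score")
    return float(model.Sigma_T.sum()) / var_x


def model_alpha(model: TrueScoreModel) -> float:
    """Coefficient alpha evaluated on the model-implied item covariance."""
    cov = model.implied_item_cov()
    total = float(cov.sum())
    if total <= 0:
        raise DegenerateInputError("model implies a zero-variance sum score")
    n = model.n_items
    return n / (n - 1) * (1.0 - float(np.trace(cov)) / total)


def model_validity(model: TrueScoreModel) -> float:
    """Population correlation between the sum score and the criterion.

    ``cov(X, Y) = 1' Sigma_T w`` since errors are independent of the
    criterion; never exceeds ``sqrt(model_reliability)``.
    """
    if model.crit_weights is None:
        raise ValueError("model has no criterion weights")
    w = model.crit_weights
    var_y = float(w @ model.Sigma_T @ w) + model.crit_noise_var
    var_x = model.sum_score_variance()
    if var_y <= 0 or var_x <= 0:
        raise DegenerateInputError("criterion or sum score has zero variance")
    cov_xy = float(model.Sigma_T.sum(axis=0) @ w)
    return cov_xy / np.sqrt(var_x * var_y)


def build_orthogonal_model(n: int, item_reliability: float) -> TrueScoreModel:
    """Items that are individually reliable yet mutually uncorrelated.

    Each unit-variance item has true-score variance ``item_reliability``
    and error variance ``1 - item_reliability``; true scores are
    orthogonal.  The sum score's reliability equals ``item_reliability``
    while coefficient alpha is exactly zero — the extremal case of alpha
    underestimating reliability.
    """
    if n < 2:
        raise ValueError(f"need at least 2 items, got {n}")
    if not 0.0 < item_reliability < 1.0:
        raise ValueError(
            f"item reliability must be in (0, 1), got {item_reliability}"
        )
    return TrueScoreModel(
        Sigma_T=np.diag(np.full(n, item_reliability)),
        error_var=np.full(n, 1.0 - item_reliability),
        crit_weights=np.full(n, 1.0 / n),
    )


def alpha_gap_curve(
    n: int, item_reliability: float, inter_trait_correlations: Sequence[float]
) -> pd.DataFrame:
    """Alpha, reliability, and their gap as true scores decorrelate.

    Each grid point ``c`` builds a model whose unit-variance items have
    true-score variance ``item_reliability`` and equicorrelated true
    scores (correlation ``c`` between traits), interpolating between the
    orthogonal construction (``c = 0``, gap = item reliability) and
    parallel items (``c = 1``, gap = 0).  Columns: ``inter_trait_corr``,
    ``inter_item_corr`` (the implied observed-score correlation),
    ``alpha``, ``reliability``, ``gap``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 items, got {n}")
    if not 0.0 < item_reliability < 1.0:
        raise ValueError(
            f"item reliability must be in (0, 1), got {item_reliability}"
        )
    grid = np.asarray(list(inter_trait_correlations), dtype=float)
    if grid.size == 0 or np.any((grid < 0) | (grid > 1)):
        raise ValueError("inter-trait correlations must lie in [0, 1]")
    rows = []
    for c in grid:
        S = item_reliability * ((1.0 - c) * np.eye(n) + c * np.ones((n, n)))
        model = TrueScoreModel(
            Sigma_T=S, error_var=np.full(n, 1.0 - item_reliability)
        )
        a = model_alpha(model)
        rel = model_reliability(model)
        rows.append(
            {
                "inter_trait_corr": float(c),
                "inter_item_corr": float(c * item_reliability),
                "alpha": a,
                "reliability": rel,
                "gap": rel - a,
            }
        )
    return pd.DataFrame(rows)
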