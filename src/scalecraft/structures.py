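"""Correlation structures and scale evaluations.

A :class:`CorrelationStructure` is the empirical substrate of every
closed-form statistic in this package: item labels, the item-by-item
Pearson correlation matrix, optional per-item standard deviations
(omitted = "standardized mode", all variances 1), optional item-criterion
correlations, and the sample size the correlations came from.

Published correlation tables are rounded to two decimals and are
therefore routinely slightly indefinite; a non-positive-semidefinite
matrix is accepted with a warning rather than rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Optional, Sequence

import numpy as np

from .exceptions import ItemLookupError, MissingCriterionError

Label = Hashable

_SYM_TOL = 1e-12
_PSD_TOL = -1e-8


@dataclass(frozen=True)
class CorrelationStructure:
    """Item labels, inter-item correlations, and optional SDs / criterion.

    Parameters
    ----------
    labels
        Ordered item identifiers (the 1-based integers ``1..n`` in the
        bundled worked example).
    R
        Square symmetric correlation matrix, unit diagonal, off-diagonal
        entries in ``[-1, 1]``.
    sd
        Per-item standard deviations in score units.  ``None`` selects
        standardized mode (all SDs 1).
    r_crit
        Per-item Pearson correlations with an external criterion
        (point-biserial when the criterion is binary).
    n_obs
        Sample size the correlations were estimated from; metadata only.
    """

    labels: tuple
    R: np.ndarray
    sd: Optional[np.ndarray] = None
    r_crit: Optional[np.ndarray] = None
    n_obs: Optional[int] = None

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("item labels must be unique")
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        p = len(labels)
        if R.ndim != 2 or R.shape != (p, p):
            raise ValueError(f"R must be {p}x{p}, got {R.shape}")
        if np.isnan(R).any():
            raise ValueError("R contains missing values; imputation is not supported")
        if not np.all(np.abs(R - R.T) <= _SYM_TOL):
            raise ValueError("R is not symmetric within 1e-12")
        if not np.all(np.diag(R) == 1.0):
            raise ValueError("diagonal of R must be exactly 1")
        off = R[~np.eye(p, dtype=bool)]
        if off.size and (off.min() < -1.0 or off.max() > 1.0):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != (p,):
                raise ValueError("sd length must match the number of items")
            if np.isnan(sd).any() or np.any(sd <= 0):
                raise ValueError("all item SDs must be positive")
            object.__setattr__(self, "sd", sd)
        if self.r_crit is not None:
            rc = np.asarray(self.r_crit, dtype=float)
            if rc.shape != (p,):
                raise ValueError("r_crit length must match the number of items")
            if np.isnan(rc).any():
                raise ValueError("r_crit contains missing values")
            if np.any(np.abs(rc) > 1):
                raise ValueError("item-criterion correlations must lie in [-1, 1]")
            object.__setattr__(self, "r_crit", rc)
        if not self.is_positive_semidefinite:
            warnings.warn(
                "correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {self.min_eigenvalue:.3g}); statistics are "
                "computed as written — rounded published matrices are often "
                "slightly indefinite",
                UserWarning,
                stacklevel=2,
            )

    # -- basic introspection -------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.R).min())

    @property
    def is_positive_semidefinite(self) -> bool:
        return self.min_eigenvalue >= _PSD_TOL

    @property
    def has_criterion(self) -> bool:
        return self.r_crit is not None

    @property
    def standardized(self) -> bool:
        return self.sd is None

    def sd_vector(self) -> np.ndarray:
        """Item SDs, substituting 1 for every item in standardized mode."""
        if self.sd is None:
            return np.ones(self.n_items)
        return self.sd

    # -- label handling ------------------------------------------------------

    def indices(self, subset: Iterable[Label]) -> np.ndarray:
        """Positions of ``subset`` labels, in declared item order."""
        subset = list(subset)
        if len(set(subset)) != len(subset):
            raise ValueError("subset contains duplicate labels")
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in subset if lab not in pos]
        if missing:
            raise ItemLookupError(f"unknown item label(s): {missing!r}")
        return np.array(sorted(pos[lab] for lab in subset), dtype=int)

    def subset_cov(self, subset: Iterable[Label]) -> np.ndarray:
        """Implied covariance matrix ``sigma_i sigma_j rho_ij`` of a subset."""
        idx = self.indices(subset)
        sd = self.sd_vector()[idx]
        return np.outer(sd, sd) * self.R[np.ix_(idx, idx)]

    def require_criterion(self) -> np.ndarray:
        if self.r_crit is None:
            raise MissingCriterionError(
                "item-criterion correlations (r_crit) are required for "
                "validity statistics but are absent from this structure"
            )
        return self.r_crit


@dataclass(frozen=True)
class ScaleEvaluation:
    """An item subset with its coefficient alpha and predictive validity.

    ``validity`` is ``None`` when the source structure carries no
    item-criterion correlations.
    """

    subset: tuple
    alpha: Optional[float]
    validity: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "subset", tuple(self.subset))

    @property
    def n_items(self) -> int:
        return len(self.subset)


def evaluate_subset(
    structure: CorrelationStructure, subset: Iterable[Label]
) -> ScaleEvaluation:
    """Evaluate a subset on both metrics (alpha needs >= 2 items).

    Validity is included whenever the structure has a criterion.
    """
    from .ctt import cronbach_alpha, predictive_validity

    subset = tuple(subset)
    alpha = cronbach_alpha(structure, subset) if len(subset) >= 2 else None
    validity = (
        predictive_validity(structure, subset) if structure.has_criterion else None
    )
    return ScaleEvaluation(subset=_ordered(structure, subset), alpha=alpha, validity=validity)


def _ordered(structure: CorrelationStructure, subset: Sequence[Label]) -> tuple:
    """Subset labels in the structure's declared order (canonical form)."""
    idx = structure.indices(subset)
    return tuple(structure.labels[i] for i in idx)
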