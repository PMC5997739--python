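"""Closed-form classical-test-theory statistics.

All statistics are computed from a :class:`~scalecraft.CorrelationStructure`
(inter-item correlations ``rho_ij``, item SDs ``sigma_i``, item-criterion
correlations ``rho_iY``) without touching raw respondent data:

* coefficient alpha
      ``alpha = n/(n-1) * (1 - sum_i sigma_i^2 / sum_ij sigma_i sigma_j rho_ij)``
* sum-score criterion validity
      ``rho_XY = sum_i sigma_i rho_iY / sqrt(sum_ij sigma_i sigma_j rho_ij)``
* corrected item-total correlation, alpha/validity with an item deleted,
  the Spearman-Brown prophecy, and the validity bound
  ``|rho_XY| <= sqrt(reliability)``.

With unit SDs (standardized mode) alpha reduces to the standardized form
``n*rbar / (1 + (n-1)*rbar)`` where ``rbar`` is the mean inter-item
correlation.  Alpha may be negative; it is never floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .exceptions import DegenerateInputError, ItemLookupError, SubsetSizeError
from .structures import CorrelationStructure, Label

_VAR_TOL = 1e-12


def cronbach_alpha(structure: CorrelationStructure, subset: Iterable[Label]) -> float:
    """Coefficient alpha of the sum score over ``subset``.

    Requires at least two items.  For a positive-semidefinite input the
    result never exceeds 1; it may be negative when items covary
    negatively on balance.
    """
    subset = tuple(subset)
    if len(subset) < 2:
        raise SubsetSizeError(f"alpha needs at least 2 items, got {len(subset)}")
    cov = structure.subset_cov(subset)
    total = float(cov.sum())
    if total <= _VAR_TOL:
        raise DegenerateInputError("sum score has zero total variance")
    n = len(subset)
    return n / (n - 1) * (1.0 - float(np.trace(cov)) / total)


def corrected_item_total(
    structure: CorrelationStructure, subset: Iterable[Label], item: Label
) -> float:
    """Correlation of ``item`` with the sum of the *other* subset items.

    The rest-score correlation summarizes an item's inter-item
    correlations into one number; with two items it equals their
    correlation exactly.
    """
    subset = tuple(subset)
    if item not in subset:
        raise ItemLookupError(f"item {item!r} is not in the subset")
    if len(subset) < 2:
        raise SubsetSizeError("corrected item-total needs at least 2 items")
    cov = structure.subset_cov(subset)
    labels_in_order = [structure.labels[i] for i in structure.indices(subset)]
    i = labels_in_order.index(item)
    rest = [j for j in range(len(labels_in_order)) if j != i]
    cov_item_rest = float(cov[i, rest].sum())
    var_rest = float(cov[np.ix_(rest, rest)].sum())
    var_item = float(cov[i, i])
    if var_rest <= _VAR_TOL:
        raise DegenerateInputError("rest score has zero variance")
    return cov_item_rest / math.sqrt(var_item * var_rest)


def alpha_if_deleted(
    structure: CorrelationStructure, subset: Iterable[Label], item: Label
) -> float:
    """Alpha of the subset after removing ``item`` (``alpha_{-i}``)."""
    subset = tuple(subset)
    if item not in subset:
        raise ItemLookupError(f"item {item!r} is not in the subset")
    if len(subset) < 3:
        raise SubsetSizeError("deleting an item would leave fewer than 2 items")
    return cronbach_alpha(structure, tuple(x for x in subset if x != item))


def predictive_validity(
    structure: CorrelationStructure, subset: Iterable[Label]
) -> float:
    """Correlation between the subset sum score and the criterion.

    For a singleton subset this collapses to the item-criterion
    correlation itself.
    """
    subset = tuple(subset)
    if len(subset) < 1:
        raise SubsetSizeError("validity needs at least 1 item")
    structure.require_criterion()
    idx = structure.indices(subset)
    sd = structure.sd_vector()[idx]
    r_crit = structure.r_crit[idx]
    cov = structure.subset_cov(subset)
    total = float(cov.sum())
    if total <= _VAR_TOL:
        raise DegenerateInputError("sum score has zero total variance")
    return float((sd * r_crit).sum()) / math.sqrt(total)


def validity_if_deleted(
    structure: CorrelationStructure, subset: Iterable[Label], item: Label
) -> float:
    """Predictive validity after removing ``item`` (``rho_{X_{-i}Y}``)."""
    subset = tuple(subset)
    if item not in subset:
        raise ItemLookupError(f"item {item!r} is not in the subset")
    if len(subset) < 2:
        raise SubsetSizeError("deleting an item would leave an empty scale")
    return predictive_validity(structure, tuple(x for x in subset if x != item))


def spearman_brown(reliability: float, length_factor: float) -> float:
    """Prophesied reliability when test length is multiplied by ``length_factor``.

    ``k * rho / (1 + (k - 1) * rho)`` for parallel parts; strictly
    increasing in ``k`` for ``rho`` in (0, 1), so shortening a test
    (``k < 1``) always lowers the prophesied reliability.
    """
    if not 0.0 <= reliability < 1.0:
        raise ValueError(f"reliability must be in [0, 1), got {reliability}")
    if length_factor <= 0:
        raise ValueError(f"length factor must be positive, got {length_factor}")
    k = length_factor
    return k * reliability / (1.0 + (k - 1.0) * reliability)


@dataclass(frozen=True)
class BoundReport:
    """Outcome of checking ``|validity| <= sqrt(reliability)``.

    A violation computed with an *alpha estimate* in place of the true
    reliability is not a contradiction of the bound: alpha is a lower
    bound to reliability, and a violation signals that alpha is
    underestimating it (``alpha_underestimates`` flags this reading).
    """

    validity: float
    reliability: float
    bound: float
    slack: float
    satisfied: bool
    alpha_underestimates: bool


def check_validity_bound(validity: float, reliability: float) -> BoundReport:
    """Check the theoretical ceiling of validity at sqrt(reliability)."""
    if not 0.0 <= reliability <= 1.0:
        raise ValueError(f"reliability must be in [0, 1], got {reliability}")
    bound = math.sqrt(reliability)
    slack = bound - abs(validity)
    satisfied = slack >= 0.0
    return BoundReport(
        validity=float(validity),
        reliability=float(reliability),
        bound=bound,
        slack=slack,
        satisfied=satisfied,
        alpha_underestimates=not satisfied,
    )


@dataclass(frozen=True)
class ReductionResult:
    """Percent reduction of a statistic relative to a reference value."""

    percent: float
    rounded: int


def percent_reduction(value: float, reference: float) -> ReductionResult:
    """``100 * (1 - value/reference)``, with a nearest-integer rounding.

    Used to express how much shortening a scale costs in alpha or
    validity relative to the full-length scale.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    pct = 100.0 * (1.0 - value / reference)
    return ReductionResult(percent=pct, rounded=int(round(pct)))
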