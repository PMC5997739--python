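"""Item-subset search under a measurement or a prediction objective.

The measurement objective scores a subset by its coefficient alpha, the
prediction objective by its sum-score criterion validity.  Two searches
are provided:

* :func:`backward_select` — stepwise backward elimination: at each step
  the item whose deletion *maximizes* the objective on the remaining set
  is removed, until a target size is reached or the objective value is
  deemed sufficient.
* :func:`exhaustive_best_subset` — full enumeration of all size-``k``
  subsets, feasible only for small pools (there are ``2^n - 1`` nonempty
  subsets of an ``n``-item pool; 1023 at n=10 but over a trillion at
  n=40), guarded by an enumeration cap.

:func:`compare_goals` runs the backward search under both objectives at
the same target size and reports the trade-off.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

from .ctt import cronbach_alpha, percent_reduction, predictive_validity
from .exceptions import EnumerationCapError, MissingCriterionError, SubsetSizeError
from .structures import CorrelationStructure, ScaleEvaluation, evaluate_subset

OBJECTIVES = ("measurement", "prediction")

# deletions whose objective values differ by less than this are reported
# as near-ties: with correlations printed to 2 decimals, set membership
# can be rounding-sensitive
NEAR_TIE_WARN = 0.01
_TIE_TOL = 1e-12

DEFAULT_ENUMERATION_CAP = 10**6


def count_subsets(n: int) -> int:
    """Number of nonempty item subsets of an ``n``-item pool: ``2^n - 1``."""
    if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"pool size must be a positive integer, got {n!r}")
    return 2**n - 1


def _objective_fn(structure: CorrelationStructure, objective: str):
    if objective == "measurement":
        return lambda subset: cronbach_alpha(structure, subset)
    if objective == "prediction":
        if not structure.has_criterion:
            raise MissingCriterionError(
                "the prediction objective requires item-criterion correlations"
            )
        return lambda subset: predictive_validity(structure, subset)
    raise ValueError(f"objective must be one of {OBJECTIVES}, got {objective!r}")


@dataclass(frozen=True)
class SelectionTrace:
    """Replayable record of one backward-elimination run.

    ``steps`` holds ``(removed_label, objective_value_of_remaining_set)``
    pairs in removal order; re-evaluating the surviving set after each
    step must reproduce the recorded value exactly.
    """

    objective: str
    steps: tuple
    final_subset: tuple
    final_evaluation: ScaleEvaluation
    stop_rule: dict
    warnings: tuple = ()

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def final_value(self) -> float:
        return self.final_evaluation.alpha if self.objective == "measurement" else self.final_evaluation.validity


def backward_select(
    structure: CorrelationStructure,
    objective: str,
    k: Optional[int] = None,
    threshold: Optional[float] = None,
) -> SelectionTrace:
    """Stepwise backward elimination toward a target size or threshold.

    At each step every remaining item's deletion statistic (alpha or
    validity with the item removed) is evaluated and the deletion with
    the *highest* objective value is applied.  Stopping: with ``k``, the
    run stops when ``k`` items remain; with ``threshold``, as soon as
    the current objective value reaches it (a pool that already meets
    the threshold yields an empty trace).  ``k`` takes precedence when
    both are given.  Ties within 1e-12 remove the earliest item in the
    structure's declared order.  A threshold that is never reached
    terminates at the minimum scale size of 2 with a warning recorded
    in the trace.
    """
    pool = list(structure.labels)
    if len(pool) < 2:
        raise SubsetSizeError("backward selection needs a pool of at least 2 items")
    score = _objective_fn(structure, objective)
    if k is None and threshold is None:
        raise ValueError("a stop rule is required: target size k or a threshold")
    if k is not None and not (2 <= k <= len(pool)):
        raise ValueError(f"target size k must be in [2, {len(pool)}], got {k}")
    stop_rule = {"k": k, "threshold": threshold}

    current = list(pool)
    steps = []
    notes = []
    while True:
        if k is not None:
            if len(current) <= k:
                break
        else:
            if score(current) >= threshold:
                break
            if len(current) <= 2:
                notes.append(
                    f"threshold {threshold} unreachable: stopped at minimum size 2 "
                    f"with objective {score(current):.6f}"
                )
                break
        # objective value after each candidate deletion
        values = [(score([x for x in current if x != item]), item) for item in current]
        best_val = max(v for v, _ in values)
        contenders = [item for v, item in values if v >= best_val - _TIE_TOL]
        removed = contenders[0]  # earliest in declared order: deterministic
        if len(contenders) > 1:
            notes.append(
                f"tie at step {len(steps) + 1}: deletions of {contenders!r} agree "
                f"within 1e-12; removed {removed!r}"
            )
        near = [item for v, item in values if item != removed and best_val - v < NEAR_TIE_WARN]
        if near:
            notes.append(
                f"near-tie at step {len(steps) + 1}: removing {removed!r}, but "
                f"{near!r} are within {NEAR_TIE_WARN} — membership is rounding-sensitive"
            )
        current = [x for x in current if x != removed]
        steps.append((removed, score(current)))

    return SelectionTrace(
        objective=objective,
        steps=tuple(steps),
        final_subset=tuple(current),
        final_evaluation=evaluate_subset(structure, current),
        stop_rule=stop_rule,
        warnings=tuple(notes),
    )


def exhaustive_best_subset(
    structure: CorrelationStructure,
    objective: str,
    k: int,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> ScaleEvaluation:
    """Best size-``k`` subset by full enumeration.

    Refuses to enumerate when ``C(pool, k)`` exceeds ``cap``.  Ties
    within 1e-12 keep the lexicographically earliest subset in the
    structure's declared item order.
    """
    pool = structure.labels
    min_size = 2 if objective == "measurement" else 1
    if not (min_size <= k <= len(pool)):
        raise ValueError(f"k must be in [{min_size}, {len(pool)}], got {k}")
    n_comb = math.comb(len(pool), k)
    if n_comb > cap:
        raise EnumerationCapError(
            f"C({len(pool)}, {k}) = {n_comb} size-{k} subsets exceeds the cap of "
            f"{cap}; the pool admits {count_subsets(len(pool))} nonempty subsets "
            "in total — consider backward_select instead"
        )
    score = _objective_fn(structure, objective)
    best_subset = None
    best_val = -math.inf
    for subset in itertools.combinations(pool, k):
        v = score(subset)
        if v > best_val + _TIE_TOL:
            best_val = v
            best_subset = subset
    return evaluate_subset(structure, best_subset)


@dataclass(frozen=True)
class GoalComparison:
    """Both selection arms at the same size, each scored on both metrics."""

    k: int
    measurement: ScaleEvaluation
    prediction: ScaleEvaluation
    measurement_trace: SelectionTrace
    prediction_trace: SelectionTrace
    overlap: tuple
    reductions: Optional[dict] = None

    @property
    def overlap_size(self) -> int:
        return len(self.overlap)


def compare_goals(
    structure: CorrelationStructure,
    k: int,
    reference: Optional[ScaleEvaluation] = None,
) -> GoalComparison:
    """Backward-select under both objectives at size ``k`` and compare.

    Each arm's final set is evaluated on *both* metrics.  When a
    ``reference`` evaluation is supplied (e.g., the full-length scale),
    percent reductions of alpha and validity against it are included.
    """
    m_trace = backward_select(structure, "measurement", k=k)
    p_trace = backward_select(structure, "prediction", k=k)
    m_eval, p_eval = m_trace.final_evaluation, p_trace.final_evaluation
    overlap = tuple(x for x in m_eval.subset if x in set(p_eval.subset))
    reductions = None
    if reference is not None:
        reductions = {}
        for arm, ev in (("measurement", m_eval), ("prediction", p_eval)):
            entry = {}
            if reference.alpha is not None and ev.alpha is not None:
                entry["alpha"] = percent_reduction(ev.alpha, reference.alpha)
            if reference.validity is not None and ev.validity is not None:
                entry["validity"] = percent_reduction(ev.validity, reference.validity)
            reductions[arm] = entry
    return GoalComparison(
        k=k,
        measurement=m_eval,
        prediction=p_eval,
        measurement_trace=m_trace,
        prediction_trace=p_trace,
        overlap=overlap,
        reductions=reductions,
    )
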