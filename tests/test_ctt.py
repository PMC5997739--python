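"""Closed-form statistics against printed values and brute-force oracles."""

import math

import numpy as np
import pytest

from scalecraft import (
    CorrelationStructure,
    DegenerateInputError,
    ItemLookupError,
    MissingCriterionError,
    SubsetSizeError,
    alpha_if_deleted,
    check_validity_bound,
    corrected_item_total,
    cronbach_alpha,
    percent_reduction,
    predictive_validity,
    spearman_brown,
    validity_if_deleted,
)
from oracles import oracle_alpha, oracle_best_deletion, oracle_item_total, oracle_validity


def equicorrelated(p, rho, r_crit=None, sd=None):
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    return CorrelationStructure(
        labels=tuple(range(1, p + 1)),
        R=R,
        sd=sd,
        r_crit=None if r_crit is None else np.asarray(r_crit, dtype=float),
    )


class TestCronbachAlpha:
    @pytest.mark.parametrize(
        "subset, expected",
        [({2, 3, 5, 8, 10}, 0.80), ({4, 6, 7, 9, 10}, 0.63)],
    )
    def test_worked_example_scales(self, table1, subset, expected):
        """The published five-item scales round to the printed alphas."""
        assert round(cronbach_alpha(table1, subset), 2) == expected

    def test_two_uncorrelated_items_give_zero(self):
        assert cronbach_alpha(equicorrelated(2, 0.0), (1, 2)) == 0.0

    def test_matches_termwise_evaluation(self):
        """3 equicorrelated items agree with the summed covariance oracle."""
        s = equicorrelated(3, 0.5)
        assert cronbach_alpha(s, (1, 2, 3)) == pytest.approx(
            oracle_alpha(s, (1, 2, 3)), abs=1e-12
        )
        # standardized closed form n*rbar / (1 + (n-1)*rbar)
        assert cronbach_alpha(s, (1, 2, 3)) == pytest.approx(1.5 / 2.0, abs=1e-12)

    def test_oracle_agreement_on_fixture_subsets(self, table1):
        """Every statistic equals the brute-force covariance-summing oracle."""
        for subset in [(1, 2), (2, 3, 5, 8, 10), table1.labels, (4, 6, 7, 9, 10)]:
            assert cronbach_alpha(table1, subset) == pytest.approx(
                oracle_alpha(table1, subset), abs=1e-12
            )

    def test_respects_item_sds_in_covariance_mode(self, table1):
        s = CorrelationStructure(
            labels=table1.labels,
            R=table1.R,
            sd=np.linspace(0.5, 1.5, 10),
            r_crit=table1.r_crit,
        )
        assert cronbach_alpha(s, s.labels) == pytest.approx(
            oracle_alpha(s, s.labels), abs=1e-12
        )
        assert cronbach_alpha(s, s.labels) != pytest.approx(
            cronbach_alpha(table1, table1.labels), abs=1e-6
        )

    def test_errors(self, table1):
        with pytest.raises(SubsetSizeError):
            cronbach_alpha(table1, (1,))
        with pytest.raises(ItemLookupError):
            cronbach_alpha(table1, (1, 99))
        degenerate = equicorrelated(2, -1.0)
        with pytest.raises(DegenerateInputError):
            cronbach_alpha(degenerate, (1, 2))


class TestCorrectedItemTotal:
    def test_two_items_equals_their_correlation(self, table1):
        assert corrected_item_total(table1, (3, 7), 3) == pytest.approx(
            table1.R[2, 6], abs=1e-12
        )

    def test_item9_from_printed_correlations(self, table1):
        """Item 9's rest-correlation from the printed matrix is 0.287.

        The published column (0.28) used unpublished raw SDs, so only the
        unit-SD recomputation is asserted exactly.
        """
        r = corrected_item_total(table1, table1.labels, 9)
        assert r == pytest.approx(oracle_item_total(table1, table1.labels, 9), abs=1e-12)
        assert round(r, 3) == 0.287
        # closed form: sum r_9j / sqrt(9 + 2 * sum of pairwise among the rest)
        rest = [lab for lab in table1.labels if lab != 9]
        num = sum(table1.R[8, lab - 1] for lab in rest)
        pair = sum(
            table1.R[a - 1, b - 1] for i, a in enumerate(rest) for b in rest[i + 1 :]
        )
        assert r == pytest.approx(num / math.sqrt(9 + 2 * pair), abs=1e-12)

    def test_uncorrelated_item_gives_zero(self):
        s = equicorrelated(4, 0.0)
        assert corrected_item_total(s, s.labels, 2) == pytest.approx(0.0, abs=1e-12)

    def test_item_must_be_in_subset(self, table1):
        with pytest.raises(ItemLookupError):
            corrected_item_total(table1, (1, 2, 3), 9)


class TestAlphaIfDeleted:
    def test_equals_alpha_of_reduced_set(self, table1):
        for item in table1.labels:
            rest = tuple(x for x in table1.labels if x != item)
            assert alpha_if_deleted(table1, table1.labels, item) == cronbach_alpha(
                table1, rest
            )

    def test_parallel_items_closed_form(self):
        s = equicorrelated(3, 0.4)
        for item in (1, 2, 3):
            assert alpha_if_deleted(s, (1, 2, 3), item) == pytest.approx(
                2 * 0.4 / 1.4, abs=1e-12
            )

    def test_fixture_best_deletion_is_item9(self, table1):
        """Enumerating all 10 deletions, removing item 9 maximizes alpha."""
        best_val, best_item = oracle_best_deletion(table1, table1.labels, oracle_alpha)
        assert best_item == 9
        values = {
            item: alpha_if_deleted(table1, table1.labels, item)
            for item in table1.labels
        }
        assert max(values, key=values.get) == 9
        assert values[9] == pytest.approx(best_val, abs=1e-12)

    def test_too_small(self, table1):
        with pytest.raises(SubsetSizeError):
            alpha_if_deleted(table1, (1, 2), 1)


class TestPredictiveValidity:
    def test_singleton_collapses_to_item_criterion_correlation(self, table1):
        for j, lab in enumerate(table1.labels):
            assert predictive_validity(table1, (lab,)) == pytest.approx(
                table1.r_crit[j], abs=1e-12
            )

    def test_worked_example_scales(self, table1):
        assert round(predictive_validity(table1, {2, 3, 5, 8, 10}), 2) == 0.33
        # the paper's raw-data value (.40) used unpublished SDs; from the
        # printed correlations with unit SDs the value is 0.392
        assert round(predictive_validity(table1, {4, 6, 7, 9, 10}), 3) == 0.392

    def test_oracle_agreement(self, table1):
        for subset in [(1,), (2, 9), (4, 6, 7, 9, 10), table1.labels]:
            assert predictive_validity(table1, subset) == pytest.approx(
                oracle_validity(table1, subset), abs=1e-12
            )

    def test_requires_criterion(self):
        s = equicorrelated(3, 0.2)
        with pytest.raises(MissingCriterionError):
            predictive_validity(s, (1, 2))


class TestValidityIfDeleted:
    def test_fixture_best_deletion_is_item2(self, table1):
        best_val, best_item = oracle_best_deletion(
            table1, table1.labels, oracle_validity
        )
        assert best_item == 2
        values = {
            item: validity_if_deleted(table1, table1.labels, item)
            for item in table1.labels
        }
        assert max(values, key=values.get) == 2
        assert values[2] == pytest.approx(best_val, abs=1e-12)

    def test_duplicate_items_with_equal_criterion_correlation(self):
        s = equicorrelated(2, 1.0 - 1e-13, r_crit=[0.3, 0.3])
        for item in (1, 2):
            assert validity_if_deleted(s, (1, 2), item) == pytest.approx(0.3, abs=1e-6)

    def test_deleting_the_only_predictive_item_lowers_validity(self):
        s = equicorrelated(3, 0.3, r_crit=[0.5, 0.0, 0.0])
        full = predictive_validity(s, (1, 2, 3))
        assert validity_if_deleted(s, (1, 2, 3), 1) < full
        assert validity_if_deleted(s, (1, 2, 3), 1) == pytest.approx(
            oracle_validity(s, (2, 3)), abs=1e-12
        )


class TestSpearmanBrown:
    def test_identity_at_unit_length(self):
        assert spearman_brown(0.37, 1.0) == pytest.approx(0.37, abs=1e-15)

    def test_doubling_half_reliability(self):
        assert spearman_brown(0.5, 2.0) == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_shortening_lowers_reliability(self):
        for rho in (0.2, 0.5, 0.9):
            assert spearman_brown(rho, 0.5) < rho

    def test_domain(self):
        with pytest.raises(ValueError):
            spearman_brown(1.0, 2.0)
        with pytest.raises(ValueError):
            spearman_brown(0.5, 0.0)


class TestValidityBound:
    def test_published_scale_satisfies_bound(self):
        rep = check_validity_bound(0.40, 0.63)
        assert rep.satisfied
        assert rep.slack == pytest.approx(math.sqrt(0.63) - 0.40, abs=1e-12)
        assert round(rep.slack, 3) == 0.394

    def test_boundary_zero_slack(self):
        rep = check_validity_bound(1.0, 1.0)
        assert rep.satisfied and rep.slack == 0.0

    def test_violation_flags_alpha_underestimation(self):
        rep = check_validity_bound(0.9, 0.5)
        assert not rep.satisfied
        assert rep.alpha_underestimates


class TestPercentReduction:
    @pytest.mark.parametrize(
        "value, reference, expected",
        [(0.63, 0.93, 32), (0.80, 0.93, 14), (0.33, 0.40, 18), (0.55, 0.55, 0)],
    )
    def test_printed_reductions(self, value, reference, expected):
        assert percent_reduction(value, reference).rounded == expected

    def test_unrounded_value_returned(self):
        res = percent_reduction(0.63, 0.93)
        assert res.percent == pytest.approx(100 * (1 - 0.63 / 0.93), abs=1e-12)

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            percent_reduction(0.5, 0.0)
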