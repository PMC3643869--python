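"""Point estimates, chance terms and standard errors on 2x2 tables."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from agreemetrics import (
    ac1_chance_agreement,
    ac1_se,
    build_table_from_counts as T,
    cohen_kappa,
    gwet_ac1,
    gwet_q,
    jackknife_se,
    kappa_chance_agreement,
    kappa_se,
    percent_agreement,
)
from agreemetrics.contingency import RatingDataError
from agreemetrics.formatting import round_half_away


class TestPointEstimates:
    @pytest.mark.parametrize(
        "cells, expected",
        [((15, 1, 1, 2), 17 / 19), ((13, 2, 1, 3), 16 / 19), ((5, 0, 0, 0), 1.0)],
    )
    def test_percent_agreement(self, cells, expected):
        assert percent_agreement(T(*cells)).estimate == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cells, expected",
        [((15, 1, 1, 2), 265 / 361), ((4, 0, 0, 0), 1.0), ((0, 0, 0, 4), 1.0)],
    )
    def test_kappa_chance_term(self, cells, expected):
        assert kappa_chance_agreement(T(*cells)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cells, expected",
        [((15, 1, 1, 2), 32 / 38), ((1, 1, 1, 1), 0.5), ((0, 0, 0, 6), 0.0)],
    )
    def test_gwet_q(self, cells, expected):
        assert gwet_q(T(*cells)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((15, 1, 1, 2), 2 * (16 / 19) * (3 / 19)),
            ((1, 1, 1, 1), 0.5),
            ((7, 0, 0, 0), 0.0),
        ],
    )
    def test_ac1_chance_term(self, cells, expected):
        assert ac1_chance_agreement(T(*cells)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((15, 1, 1, 2), 0.604),
            ((13, 2, 1, 3), 0.565),
            ((10, 0, 2, 4), 0.714),
            ((16, 1, 1, 1), 0.441),
        ],
    )
    def test_cohen_kappa_study_values(self, cells, expected):
        est = cohen_kappa(T(*cells), compute_se=False)
        assert round_half_away(est.estimate, 3) == expected
        assert est.degenerate_flag == "none"

    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((15, 1, 1, 2), 0.857),
            ((16, 1, 1, 1), 0.870),
            ((7, 1, 0, 0), 0.858),
            ((9, 1, 0, 0), 0.890),
            ((9, 0, 1, 0), 0.890),
        ],
    )
    def test_gwet_ac1_study_values(self, cells, expected):
        est = gwet_ac1(T(*cells), compute_se=False)
        assert round_half_away(est.estimate, 3) == expected


class TestDegenerateConventions:
    def test_perfect_agreement_single_cell_resolves_to_one(self):
        for cells in [(8, 0, 0, 0), (0, 0, 0, 8)]:
            k = cohen_kappa(T(*cells))
            assert k.estimate == 1.0
            assert k.degenerate_flag == "perfect_agreement"
            assert k.se == 0.0
            a = gwet_ac1(T(*cells))
            assert a.estimate == 1.0

    def test_concentrated_marginal_gives_kappa_exactly_zero(self):
        k = cohen_kappa(T(7, 1, 0, 0), compute_se=False)
        assert k.estimate == 0.0
        assert k.degenerate_flag == "kappa_zero_marginal"

    def test_constant_disagreeing_raters(self):
        # both raters constant but never agreeing: kappa 0 by convention
        k = cohen_kappa(T(0, 4, 0, 0), compute_se=False)
        assert k.estimate == 0.0

    def test_negative_kappa_is_permitted(self):
        # systematic disagreement must produce a negative coefficient
        k = cohen_kappa(T(1, 5, 5, 1), compute_se=False)
        assert k.estimate < 0

    def test_perfect_agreement_with_mixed_marginals_is_not_flagged(self):
        k = cohen_kappa(T(7, 0, 0, 1))
        assert k.estimate == 1.0
        assert k.degenerate_flag == "none"


class TestStandardErrors:
    @pytest.mark.parametrize(
        "cells, printed",
        [
            ((15, 1, 1, 2), 0.254),
            ((13, 1, 0, 2), 0.221),
            ((16, 1, 1, 1), 0.330),
            ((17, 1, 0, 1), 0.326),
        ],
    )
    def test_kappa_se_matches_study(self, cells, printed):
        assert kappa_se(T(*cells)) == pytest.approx(printed, abs=1e-3)

    @pytest.mark.parametrize(
        "cells, printed",
        [
            ((15, 1, 1, 2), 0.104),
            ((13, 1, 0, 2), 0.087),
            ((16, 1, 1, 1), 0.095),
            ((17, 1, 0, 1), 0.063),
        ],
    )
    def test_ac1_se_matches_study(self, cells, printed):
        assert ac1_se(T(*cells)) == pytest.approx(printed, abs=1e-3)

    def test_se_requires_two_subjects(self):
        with pytest.raises(RatingDataError):
            kappa_se(T(1, 0, 0, 0))
        with pytest.raises(RatingDataError):
            ac1_se(T(0, 0, 0, 1))
        with pytest.raises(RatingDataError):
            jackknife_se(T(1, 0, 0, 0), "gwet_ac1")

    def test_jackknife_zero_for_constant_statistic(self):
        assert jackknife_se(T(6, 0, 0, 0), "cohen_kappa") == 0.0
        assert jackknife_se(T(6, 0, 0, 0), "gwet_ac1") == 0.0

    # Frozen values from the brute-force leave-one-out oracle run at
    # build time (all n deletions enumerated explicitly).
    @pytest.mark.parametrize(
        "cells, method, expected",
        [
            ((15, 1, 1, 2), "gwet_ac1", 0.10478),
            ((10, 0, 2, 4), "gwet_ac1", 0.15632),
            ((15, 1, 1, 2), "cohen_kappa", 0.32294),
            ((16, 1, 1, 1), "cohen_kappa", 0.55736),
        ],
    )
    def test_jackknife_frozen_oracle_values(self, cells, method, expected):
        assert jackknife_se(T(*cells), method) == pytest.approx(expected, abs=1e-5)

    def test_ac1_analytic_close_to_jackknife(self):
        # AC1 is nearly linear in the cell frequencies, so the two SE
        # routes agree tightly even at n ~ 10
        for cells in [(15, 1, 1, 2), (10, 0, 2, 4), (13, 2, 1, 3), (7, 1, 0, 2)]:
            t = T(*cells)
            analytic, jk = ac1_se(t), jackknife_se(t, "gwet_ac1")
            assert abs(jk - analytic) / analytic < 0.2


cells_strategy = st.tuples(
    st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
).filter(lambda t: sum(t) >= 1)


class TestInvariants:
    @given(cells_strategy)
    def test_bounds_and_equality_at_perfect_agreement(self, cells):
        t = T(*cells)
        p = percent_agreement(t).estimate
        k = cohen_kappa(t, compute_se=False).estimate
        a = gwet_ac1(t, compute_se=False).estimate
        assert k <= p + 1e-12
        assert a <= 1.0 + 1e-12
        assert k <= 1.0 + 1e-12
        if p == 1.0:
            assert k == 1.0 and a == 1.0
        else:
            assert k < 1.0 and a < 1.0

    @given(cells_strategy)
    def test_chance_term_ranges(self, cells):
        t = T(*cells)
        assert 0.0 <= kappa_chance_agreement(t) <= 1.0
        assert 0.0 <= ac1_chance_agreement(t) <= 0.5 + 1e-12

    @given(cells_strategy)
    def test_rater_swap_invariance(self, cells):
        t = T(*cells)
        s = t.transpose()
        for f in (lambda x: percent_agreement(x).estimate,
                  kappa_chance_agreement, ac1_chance_agreement,
                  lambda x: cohen_kappa(x, compute_se=False).estimate,
                  lambda x: gwet_ac1(x, compute_se=False).estimate):
            assert f(t) == pytest.approx(f(s), abs=1e-12)

    @given(cells_strategy)
    def test_category_relabel_invariance(self, cells):
        t = T(*cells)
        s = t.relabel()
        assert gwet_q(s) == pytest.approx(1 - gwet_q(t), abs=1e-12)
        for f in (lambda x: percent_agreement(x).estimate,
                  kappa_chance_agreement, ac1_chance_agreement,
                  lambda x: cohen_kappa(x, compute_se=False).estimate,
                  lambda x: gwet_ac1(x, compute_se=False).estimate):
            assert f(t) == pytest.approx(f(s), abs=1e-12)

    @given(cells_strategy, st.integers(2, 5))
    def test_count_scaling_preserves_estimates_and_shrinks_se(self, cells, m):
        t = T(*cells)
        s = T(*(m * x for x in cells))
        assert cohen_kappa(t, compute_se=False).estimate == pytest.approx(
            cohen_kappa(s, compute_se=False).estimate, abs=1e-12
        )
        assert gwet_ac1(t, compute_se=False).estimate == pytest.approx(
            gwet_ac1(s, compute_se=False).estimate, abs=1e-12
        )
        if t.n >= 2:
            assert ac1_se(s) <= ac1_se(t) + 1e-12
            assert kappa_se(s) <= kappa_se(t) + 1e-12

    @given(cells_strategy)
    def test_exact_point_estimates_are_rational(self, cells):
        """Estimates computed via exact rationals match a float redo."""
        t = T(*cells)
        n = t.n
        p = (t.a + t.d) / n
        ek = (t.a1 * t.b1 + t.a2 * t.b2) / n**2
        k = cohen_kappa(t, compute_se=False)
        if ek < 1:
            assert k.estimate == pytest.approx((p - ek) / (1 - ek), abs=1e-12)
        q = (t.a1 + t.b1) / (2 * n)
        eg = 2 * q * (1 - q)
        a = gwet_ac1(t, compute_se=False)
        assert a.estimate == pytest.approx((p - eg) / (1 - eg), abs=1e-12)
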