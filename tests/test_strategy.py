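import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cctask.design import DesignSpec, RoundParams, generate_design
from cctask.strategy import (
    deviation_score,
    ev_curve,
    expected_bonus,
    expected_score,
    first_loss_pmf,
    optimal_reveal,
    recovery_cards,
)

COMBOS = [(g, l, m) for g in (10, 30) for l in (250, 750) for m in (1, 3)]


def brute_force_first_loss(N, m, k):
    """Enumerate every equally likely loss-card placement."""
    pmf = {j: Fraction(0) for j in range(1, k + 1)}
    p_no_loss = Fraction(0)
    placements = list(itertools.combinations(range(1, N + 1), m))
    for placement in placements:
        hit = [p for p in placement if p <= k]
        if hit:
            pmf[min(hit)] += 1
        else:
            p_no_loss += 1
    total = Fraction(len(placements))
    return p_no_loss / total, {j: v / total for j, v in pmf.items()}


def brute_force_ev(g, l, N, m, k):
    p_no, pmf = brute_force_first_loss(N, m, k)
    ev = g * k * p_no
    for j, pj in pmf.items():
        ev += (g * (j - 1) - l) * pj
    return ev


class TestFirstLossDistribution:
    @pytest.mark.parametrize("N, m, k", [(8, 1, 5), (8, 3, 8), (12, 4, 6), (32, 3, 4)])
    def test_matches_enumeration_oracle(self, N, m, k):
        dist = first_loss_pmf(N, m, k)
        p_no, pmf = brute_force_first_loss(N, m, k)
        assert dist.p_no_loss == p_no
        for j in range(1, k + 1):
            assert dist.pmf[j - 1] == pmf[j]

    def test_all_loss_deck(self):
        dist = first_loss_pmf(32, 32, 1)
        assert dist.pmf[0] == 1
        assert dist.p_no_loss == 0

    def test_single_loss_closed_form(self):
        # for m = 1, P(no loss in k draws) = (N - k) / N
        for k in range(33):
            assert first_loss_pmf(32, 1, k).p_no_loss == Fraction(32 - k, 32)
        assert first_loss_pmf(32, 1, 16).p_no_loss == Fraction(1, 2)

    def test_three_loss_example(self):
        dist = first_loss_pmf(32, 3, 4)
        assert dist.p_no_loss == Fraction(28 * 27 * 26, 32 * 31 * 30)
        assert float(dist.p_no_loss) == pytest.approx(0.66048, abs=5e-6)

    @given(
        N=st.integers(1, 40),
        m_frac=st.floats(0, 1),
        k_frac=st.floats(0, 1),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_normalization_property(self, N, m_frac, k_frac):
        m = int(round(m_frac * N))
        k = int(round(k_frac * N))
        dist = first_loss_pmf(N, m, k)
        assert dist.p_no_loss + sum(dist.pmf) == 1
        assert all(p >= 0 for p in dist.pmf)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            first_loss_pmf(32, 33, 1)
        with pytest.raises(ValueError):
            first_loss_pmf(32, 1, 33)


class TestExpectedScore:
    def test_worked_examples_from_enumeration(self):
        assert expected_score(RoundParams(10, 250, 1), 7) == pytest.approx(6.5625)
        assert expected_score(RoundParams(30, 250, 1), 23) == pytest.approx(251.5625)
        assert expected_score(RoundParams(10, 750, 3), 0) == 0.0

    @pytest.mark.parametrize("g, l, m", COMBOS)
    def test_matches_brute_force_for_all_study_combos(self, g, l, m):
        params = RoundParams(g, l, m)
        for k in (1, 5, 13, 27, 32):
            assert expected_score(params, k) == pytest.approx(
                float(brute_force_ev(g, l, 32, m, k)), abs=1e-9
            )

    def test_single_loss_closed_form(self):
        # m=1: EV(k) = g k (1 - k/N) + (g k (k-1)/2 - l k) / N
        g, l, N = 30, 250, 32
        params = RoundParams(g, l, 1, N)
        for k in range(N + 1):
            closed = g * k * (1 - k / N) + (g * k * (k - 1) / 2 - l * k) / N
            assert expected_score(params, k) == pytest.approx(closed, abs=1e-9)

    def test_monotone_in_loss_amount_and_loss_cards(self):
        for k in (1, 8, 20):
            assert expected_score(RoundParams(10, 250, 1), k) > expected_score(
                RoundParams(10, 750, 1), k
            )
            assert expected_score(RoundParams(10, 250, 1), k) > expected_score(
                RoundParams(10, 250, 3), k
            )

    def test_scales_linearly_in_stakes(self):
        for k in (3, 17):
            assert expected_score(RoundParams(30, 750, 2), k) == pytest.approx(
                3 * expected_score(RoundParams(10, 250, 2), k)
            )


class TestOptimalReveal:
    # printed optimum table for the standard deck: (g, l, m) -> printed k
    PRINTED = {
        (10, 250, 1): 7, (30, 250, 1): 23, (10, 750, 1): 0, (30, 750, 1): 6,
        (10, 250, 3): 0, (30, 250, 3): 4, (10, 750, 3): 0, (30, 750, 3): 0,
    }

    @pytest.mark.parametrize("combo", COMBOS)
    def test_printed_value_attains_the_maximum(self, combo):
        params = RoundParams(*combo)
        argmax = optimal_reveal(params, tie_break="all")
        assert self.PRINTED[combo] in argmax
        assert optimal_reveal(params, tie_break="published") == self.PRINTED[combo]

    def test_exact_ties(self):
        assert optimal_reveal(RoundParams(10, 250, 1)) == (6, 7)
        assert optimal_reveal(RoundParams(30, 750, 1)) == (6, 7)
        assert optimal_reveal(RoundParams(30, 250, 3)) == (4, 5)
        assert optimal_reveal(RoundParams(10, 250, 1), "smallest") == 6
        assert optimal_reveal(RoundParams(10, 250, 1), "largest") == 7

    def test_ev_curve_starts_at_zero(self):
        curve = ev_curve(RoundParams(10, 750, 3))
        assert curve.values[0] == 0.0
        assert curve.argmax_set == (0,)


class TestDerivedQuantities:
    def test_deviation_worked_example(self):
        assert deviation_score(12.3, RoundParams(10, 250, 1)) == pytest.approx(5.3)
        assert deviation_score(7.0, RoundParams(10, 250, 1)) == 0.0

    def test_deviation_is_linear_in_the_observed_mean(self):
        base = [deviation_score(float(optimal_reveal(RoundParams(*c), "published")),
                                RoundParams(*c)) for c in COMBOS]
        plus2 = [deviation_score(optimal_reveal(RoundParams(*c), "published") + 2.0,
                                 RoundParams(*c)) for c in COMBOS]
        assert np.mean(base) == 0.0
        assert np.mean(plus2) == pytest.approx(2.0)

    @pytest.mark.parametrize("l, g, n", [(750, 30, 25), (750, 10, 75), (250, 250, 1)])
    def test_recovery_cards(self, l, g, n):
        assert recovery_cards(l, g) == n

    def test_recovery_cards_rejects_nonpositive_gain(self):
        with pytest.raises(ValueError):
            recovery_cards(750, 0)


class TestExpectedBonus:
    def test_zero_policy_earns_nothing(self):
        design = generate_design(DesignSpec(seed=0))
        out = expected_bonus(design, lambda p: 0, floor_mode="total", n_sims=500)
        assert out["raw"] == 0.0
        assert out["per_round"] == 0.0
        assert out["total"] == 0.0

    def test_raw_diagnostic_equals_summed_maximum_ev(self):
        design = generate_design(DesignSpec(seed=0))
        counts = {c: optimal_reveal(RoundParams(*c), "smallest") for c in COMBOS}
        out = expected_bonus(design, counts, floor_mode="per_round")
        expected_raw = 3 * sum(max(ev_curve(RoundParams(*c)).values) for c in COMBOS) / 100
        assert out["raw"] == pytest.approx(expected_raw)

    def test_per_round_floor_single_round_enumeration(self):
        # single (30, 250, 1) round at k = 23: E[max(score, 0)] enumerated
        # over the 32 equally likely loss positions
        design = [r for r in generate_design(DesignSpec(seed=0)) if
                  (r.params.gain_amount, r.params.loss_amount, r.params.n_loss_cards)
                  == (30, 250, 1)][:1]
        out = expected_bonus(design, {(30, 250, 1): 23}, floor_mode="per_round")
        expected = (690 * Fraction(9, 32)
                    + sum(Fraction(30 * (j - 1) - 250, 32)
                          for j in range(1, 24) if 30 * (j - 1) > 250))
        assert out["per_round"] == pytest.approx(float(expected) / 100)

    def test_total_floor_monte_carlo_tracks_raw_when_always_positive(self):
        # with only the safest round and k far below any loss exposure the
        # floor never binds, so total == raw up to MC error
        design = [r for r in generate_design(DesignSpec(seed=0))][:1]
        params = design[0].params
        out = expected_bonus(design, {
            (params.gain_amount, params.loss_amount, params.n_loss_cards): 0
        }, floor_mode="total", n_sims=200)
        assert out["total"] == pytest.approx(out["raw"])
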