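"""Sampling probabilities, burden expectations and the architectural factor."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crownburden import (
    STAR,
    STICK,
    MutationParams,
    allocate_time,
    architectural_factor,
    burden_expectations,
    detection_prob,
    expected_crown_tips_burden,
    expected_crown_unique_burden,
    expected_per_tip_burden,
    expected_tips_per_mutation,
    lateral_entry_prob,
    make_crown,
    sampling_profile,
    tilt_weights,
)
from conftest import GENOME_SIZE, MU, SUPPLY_TIMES_T, TOTAL_TIME
from enumeration_oracle import enumerate_founder_tuples, enumerate_success_patterns


class TestSamplingProbabilities:
    @pytest.mark.parametrize(
        "m,b,expected",
        [(3, 0, 0.0), (1, 5, 1.0), (3, 2, 5 / 9)],
    )
    def test_lateral_entry_examples(self, m, b, expected):
        assert lateral_entry_prob(m, b) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "m,b,expected",
        [(1, 0, 1.0), (1, 7, 1.0), (2, 0, 0.5), (3, 1, 5 / 9)],
    )
    def test_detection_examples(self, m, b, expected):
        assert detection_prob(m, b) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "m,b,expected",
        [(1, 3, 8.0), (2, 2, 2.0), (4, 0, 0.25)],
    )
    def test_expected_tips_examples(self, m, b, expected):
        assert expected_tips_per_mutation(m, b) == pytest.approx(expected)

    def test_invalid_m_rejected(self):
        for fn in (lateral_entry_prob, detection_prob, expected_tips_per_mutation):
            with pytest.raises(ValueError):
                fn(0, 3)

    @given(m=st.integers(1, 50), b=st.integers(0, 50))
    @settings(derandomize=True, max_examples=300)
    def test_detection_decomposition(self, m, b):
        """p_det = q + (1 - q)/m: lateral entry, or terminal-draw success."""
        q = lateral_entry_prob(m, b)
        assert detection_prob(m, b) == pytest.approx(q + (1 - q) / m, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    def test_matches_exhaustive_enumeration(self, m):
        """Brute-force enumeration of all founder-draw outcomes reproduces
        q, p_det and E[tips] exactly."""
        for b in range(11):
            q_o, p_o, tips_o = enumerate_success_patterns(m, b)
            assert q_o == 1 - Fraction(m - 1, m) ** b
            assert p_o == 1 - Fraction(m - 1, m) ** (b + 1)
            assert tips_o == Fraction(2**b, m)
            assert lateral_entry_prob(m, b) == pytest.approx(float(q_o), abs=1e-12)
            assert detection_prob(m, b) == pytest.approx(float(p_o), abs=1e-12)
            assert expected_tips_per_mutation(m, b) == pytest.approx(
                float(tips_o), abs=1e-12
            )

    @pytest.mark.parametrize("m,b", [(1, 4), (2, 6), (3, 5)])
    def test_two_oracles_agree(self, m, b):
        assert enumerate_founder_tuples(m, b) == enumerate_success_patterns(m, b)

    def test_profile_monotone_in_depth(self):
        prof = sampling_profile(8, m=4)
        # deeper segments (smaller s) face more bottlenecks: p_det decreases with s
        assert (np.diff(prof["detection"]) <= 1e-15).all()
        np.testing.assert_allclose(
            prof["detection"],
            prof["lateral_entry"] + (1 - prof["lateral_entry"]) / 4,
            atol=1e-12,
        )

    def test_single_asc_always_detected(self):
        prof = sampling_profile(6, m=1)
        assert (prof["detection"] == 1.0).all()
        assert (prof["lateral_entry"][prof["bottlenecks"] >= 1] == 1.0).all()


class TestBurdenExpectations:
    def test_per_tip_is_supply_times_time(self):
        alloc = allocate_time(make_crown(6), 1.3, TOTAL_TIME)
        params = MutationParams(GENOME_SIZE, MU, 4)
        expected = SUPPLY_TIMES_T
        assert expected_per_tip_burden(params, alloc) == pytest.approx(expected)
        # cross-check: summing 2*G*mu*t_s over the root-to-tip path
        assert sum(params.supply_rate * alloc.times) == pytest.approx(expected)

    def test_per_tip_zero_supply(self):
        alloc = allocate_time(make_crown(3), 0.0, 10.0)
        assert expected_per_tip_burden(MutationParams(1e9, 0.0, 3), alloc) == 0.0

    @pytest.mark.parametrize("tilt", [-3.0, 3.0, STICK, STAR])
    @pytest.mark.parametrize("m", [1, 5])
    def test_per_tip_allocation_and_m_free(self, tilt, m):
        alloc = allocate_time(make_crown(5), tilt, TOTAL_TIME)
        assert expected_per_tip_burden(
            MutationParams(GENOME_SIZE, MU, m), alloc
        ) == pytest.approx(SUPPLY_TIMES_T)

    def test_crown_tips_closed_form_and_level_sum(self):
        depth = 10
        topo = make_crown(depth)
        alloc = allocate_time(topo, 0.8, 1.0)
        params = MutationParams(0.5, 1.0, 3)  # 2*G*mu = 1
        value = expected_crown_tips_burden(params, topo, alloc)
        assert value == pytest.approx(2**depth)
        # identity: sum_s 2^s * m * (2*G*mu*t_s) * (2^{D-s}/m)
        m = params.asc_count
        level_sum = sum(
            2**s * m * params.supply_rate * alloc.times[s]
            * expected_tips_per_mutation(m, depth - s)
            for s in range(depth + 1)
        )
        assert value == pytest.approx(level_sum, rel=1e-12)

    def test_crown_tips_reduces_to_per_tip_at_depth_zero(self):
        topo = make_crown(0)
        alloc = allocate_time(topo, 0.0, TOTAL_TIME)
        params = MutationParams(GENOME_SIZE, MU, 3)
        assert expected_crown_tips_burden(params, topo, alloc) == pytest.approx(
            expected_per_tip_burden(params, alloc)
        )

    @pytest.mark.parametrize("tilt", [-5.0, 0.0, 5.0])
    @pytest.mark.parametrize("m", [1, 3, 10])
    def test_crown_tips_invariant_to_allocation_and_m(self, tilt, m):
        topo = make_crown(8)
        alloc = allocate_time(topo, tilt, TOTAL_TIME)
        params = MutationParams(GENOME_SIZE, MU, m)
        ref = SUPPLY_TIMES_T * 2**8
        assert expected_crown_tips_burden(params, topo, alloc) == pytest.approx(
            ref, rel=1e-12
        )

    def test_depth_mismatch_rejected(self):
        params = MutationParams(GENOME_SIZE, MU, 3)
        with pytest.raises(ValueError):
            expected_crown_tips_burden(
                params, make_crown(4), allocate_time(make_crown(5), 0.0, 1.0)
            )
        with pytest.raises(ValueError):
            expected_crown_unique_burden(
                params, make_crown(4), allocate_time(make_crown(5), 0.0, 1.0)
            )


class TestArchitecturalFactor:
    def test_stick_limit(self):
        a = architectural_factor(5, STICK, 3)
        assert a.factor == pytest.approx(1 - (2 / 3) ** 6, abs=1e-12)
        assert a.factor == pytest.approx(a.stick_limit, abs=1e-12)

    def test_star_limit(self):
        a = architectural_factor(5, STAR, 1)
        assert a.factor == pytest.approx(32.0)
        assert a.factor == pytest.approx(a.star_limit)

    def test_uniform_ratio_is_one(self):
        assert architectural_factor(7, 0.0, 4).ratio_to_uniform == pytest.approx(1.0)

    def test_sentinels_match_closed_forms_on_grid(self):
        for depth in range(13):
            for m in range(1, 11):
                stick = architectural_factor(depth, STICK, m)
                star = architectural_factor(depth, STAR, m)
                assert stick.factor == pytest.approx(
                    1 - (1 - 1 / m) ** (depth + 1), abs=1e-9
                )
                assert star.factor == pytest.approx(2**depth / m, rel=1e-9)
                assert star.ratio_star_stick == pytest.approx(
                    (2**depth / m) / (1 - (1 - 1 / m) ** (depth + 1)), rel=1e-9
                )

    def test_convexity_bound_and_monotonicity(self):
        tilts = np.arange(-20.0, 20.5, 1.0)
        for depth in range(1, 13):
            for m in (1, 2, 3, 5, 10):
                values = [architectural_factor(depth, t, m).factor for t in tilts]
                stick = architectural_factor(depth, STICK, m).factor
                star = architectural_factor(depth, STAR, m).factor
                assert all(stick - 1e-12 <= v <= star + 1e-12 for v in values)
                assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_log_ratios(self):
        a = architectural_factor(5, 1.0, 3)
        assert a.log10_ratio_star_stick == pytest.approx(np.log10(a.ratio_star_stick))
        assert a.log10_ratio_to_uniform == pytest.approx(np.log10(a.ratio_to_uniform))


class TestUniqueBurden:
    def test_single_asc_stick(self):
        """m=1 stick crown: every mutation sits on the basal segment and is
        detected exactly once, so the unique burden is the per-tip burden."""
        topo = make_crown(6)
        alloc = allocate_time(topo, STICK, TOTAL_TIME)
        params = MutationParams(GENOME_SIZE, MU, 1)
        assert expected_crown_unique_burden(params, topo, alloc) == pytest.approx(
            SUPPLY_TIMES_T
        )

    def test_single_asc_star(self):
        topo = make_crown(4)
        alloc = allocate_time(topo, STAR, TOTAL_TIME)
        params = MutationParams(GENOME_SIZE, MU, 1)
        assert expected_crown_unique_burden(params, topo, alloc) == pytest.approx(
            SUPPLY_TIMES_T * 16
        )

    def test_direct_sum_evaluation(self):
        # 2*G*mu = 1, T = 1, D = 3, m = 2, uniform tilt
        topo = make_crown(3)
        alloc = allocate_time(topo, 0.0, 1.0)
        params = MutationParams(0.5, 1.0, 2)
        expected = (2 / 4) * sum(2**s * (1 - 0.5 ** (4 - s)) for s in range(4))
        assert expected_crown_unique_burden(params, topo, alloc) == pytest.approx(
            expected, rel=1e-12
        )

    def test_single_asc_counts_every_event(self):
        """With m=1 every event is detected: unique burden = supply
        2*G*mu*T * sum_s 2^s w_s."""
        topo = make_crown(5)
        for tilt in (-2.0, 0.0, 2.0):
            alloc = allocate_time(topo, tilt, TOTAL_TIME)
            params = MutationParams(GENOME_SIZE, MU, 1)
            expected = SUPPLY_TIMES_T * float(
                np.sum(2.0 ** np.arange(6) * alloc.weights)
            )
            assert expected_crown_unique_burden(params, topo, alloc) == pytest.approx(
                expected, rel=1e-12
            )

    @pytest.mark.parametrize("m", [1, 2, 5])
    @pytest.mark.parametrize("tilt", [-4.0, 0.0, 4.0, STICK, STAR])
    def test_unique_never_exceeds_total(self, m, tilt):
        topo = make_crown(7)
        alloc = allocate_time(topo, tilt, TOTAL_TIME)
        params = MutationParams(GENOME_SIZE, MU, m)
        exp = burden_expectations(params, topo, alloc)
        assert exp.crown_unique <= exp.crown_tips * (1 + 1e-12)
        assert exp.crown_tips == pytest.approx(2**7 * exp.per_tip)
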