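"""Unit and property tests of the concentration and integrity models."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ddpcr_integrity import (
    DropletCounts,
    InfeasibleFractionError,
    SaturationError,
    SpeciesProbabilities,
    closed_form_single_positive_probability,
    concentration_from_counts,
    copies_per_ul_to_lambda,
    expected_category_probabilities,
    integrity_linkage_avg,
    integrity_linkage_comp,
    integrity_poisson_multinomial,
    integrity_simple,
    lambda_from_negative_fraction,
    lambda_to_copies_per_ul,
    linkage_concentration,
    solve_single_positive_probability,
    target_lambdas,
)


# ---------------------------------------------------------------------------
# concentration
# ---------------------------------------------------------------------------

class TestConcentration:
    def test_no_positives_gives_zero_lambda(self):
        assert lambda_from_negative_fraction(DropletCounts(0, 0, 0, 20000)) == 0.0

    def test_worked_lambda(self, worked_counts):
        assert lambda_from_negative_fraction(worked_counts) == pytest.approx(
            0.510826, abs=1e-6
        )

    def test_dynamic_range_ceiling_round_trip(self):
        # 4.25 copies/droplet at 0.85 nL is the 5000 copies/uL ceiling
        d = 20000
        neg = round(d * math.exp(-4.25))
        counts = DropletCounts(d - neg, 0, 0, neg)
        est = concentration_from_counts(counts)
        assert est.copies_per_ul == pytest.approx(5000, rel=2e-3)
        assert lambda_to_copies_per_ul(4.25) == pytest.approx(5000, abs=1e-9)
        assert copies_per_ul_to_lambda(5000) == pytest.approx(4.25, abs=1e-12)

    def test_half_positive_concentration(self):
        counts = DropletCounts(0, 5000, 5000, 10000)
        est = concentration_from_counts(counts)
        assert est.copies_per_ul == pytest.approx(math.log(2) / 0.85e-3, rel=1e-9)
        assert est.copies_per_ul == pytest.approx(815.47, abs=0.01)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            lambda_from_negative_fraction(DropletCounts(20000, 0, 0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            DropletCounts(-1, 0, 0, 10)
        with pytest.raises(ValueError):
            DropletCounts(0, 0, 0, 0)


class TestTargetLambdas:
    def test_worked_values(self, worked_counts):
        l1, l2, lt = target_lambdas(worked_counts)
        assert l1 == pytest.approx(-math.log(0.7), abs=1e-12)
        assert l2 == pytest.approx(-math.log(0.7), abs=1e-12)
        assert lt == pytest.approx(-math.log(0.6), abs=1e-12)

    def test_all_negative(self):
        assert target_lambdas(DropletCounts(0, 0, 0, 100)) == (0.0, 0.0, 0.0)

    def test_channel_lambda_bounded_by_total(self):
        c = DropletCounts(0, 0, 500, 19500)  # no target-1 positives
        l1, l2, lt = target_lambdas(c)
        assert l1 == 0.0 and l1 <= lt and l2 <= lt

    def test_channel_saturation_names_channel(self):
        # no droplet lacks target 1 -> channel 1's Poisson correction fails
        with pytest.raises(SaturationError, match="channel 1"):
            target_lambdas(DropletCounts(10, 5, 0, 0))


# ---------------------------------------------------------------------------
# linkage concentration & the two linkage models
# ---------------------------------------------------------------------------

class TestLinkage:
    def test_worked_linkage_concentration(self, worked_counts):
        assert linkage_concentration(worked_counts) == pytest.approx(238.26, abs=0.01)

    def test_chance_only_colocalization_is_zero(self):
        # counts built so the double-positive fraction equals
        # (1-e^-l1)(1-e^-l2) exactly: independent targets
        lam1 = lam2 = 0.3
        d = 1e6
        p1 = 1 - math.exp(-lam1)
        p2 = 1 - math.exp(-lam2)
        counts = DropletCounts(
            d * p1 * p2, d * p1 * (1 - p2), d * (1 - p1) * p2, d * (1 - p1) * (1 - p2)
        )
        assert linkage_concentration(counts) == pytest.approx(0.0, abs=1e-9)
        assert integrity_linkage_avg(counts).integrity_percent == pytest.approx(0.0, abs=1e-9)

    def test_fully_linked_equals_total(self):
        counts = DropletCounts(5000, 0, 0, 15000)
        lam_total = lambda_from_negative_fraction(counts)
        assert linkage_concentration(counts) == pytest.approx(
            lambda_to_copies_per_ul(lam_total), rel=1e-12
        )
        assert integrity_linkage_avg(counts).integrity_percent == pytest.approx(100.0)

    def test_worked_linkage_models(self, worked_counts):
        avg = integrity_linkage_avg(worked_counts)
        comp = integrity_linkage_comp(worked_counts)
        assert avg.integrity_percent == pytest.approx(56.78, abs=0.01)
        # symmetric targets: |diff| = 0 reduces compensated to average
        assert comp.integrity_percent == pytest.approx(avg.integrity_percent, abs=1e-12)

    def test_compensated_pathology_all_single_species(self):
        # all molecules 5'-only still scores 100% (known flaw, kept as-is)
        counts = DropletCounts(0, 4000, 0, 16000)
        assert integrity_linkage_comp(counts).integrity_percent == pytest.approx(100.0)

    def test_no_amplification_is_na(self):
        res = integrity_linkage_comp(DropletCounts(0, 0, 0, 100))
        assert res.is_na and "no amplification" in res.na_reason
        assert integrity_linkage_avg(DropletCounts(0, 0, 0, 100)).is_na


# ---------------------------------------------------------------------------
# simple percentage model
# ---------------------------------------------------------------------------

class TestSimple:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (DropletCounts(0, 300, 200, 19500), 0.0),
            (DropletCounts(700, 0, 0, 19300), 100.0),
            (DropletCounts(4000, 2000, 2000, 12000), 50.0),
        ],
    )
    def test_examples(self, counts, expected):
        res = integrity_simple(counts)
        assert res.method == "simple"
        assert res.integrity_percent == pytest.approx(expected)

    def test_no_positive_droplets_na(self):
        res = integrity_simple(DropletCounts(0, 0, 0, 100))
        assert res.is_na and res.na_reason == "no positive droplets"

    def test_concentration_variant_agrees_when_dilute(self):
        counts = DropletCounts(10, 45, 45, 19900)
        a = integrity_simple(counts).integrity_percent
        b = integrity_simple(counts, use_concentration=True).integrity_percent
        assert b == pytest.approx(a, rel=0.01)


# ---------------------------------------------------------------------------
# polynomial solver
# ---------------------------------------------------------------------------

class TestSolver:
    def test_zero_fraction(self):
        assert solve_single_positive_probability(0.0, 1.0) == 0.0

    def test_worked_root(self):
        p = solve_single_positive_probability(0.1, 0.510826)
        assert p == pytest.approx(0.301769, abs=1e-5)

    def test_limit_all_single_species(self):
        lam = 0.8
        s = (1 - math.exp(-lam)) * (1 - 1e-9)
        assert solve_single_positive_probability(s, lam) == pytest.approx(1.0, abs=1e-3)

    def test_infeasible_fraction_raises(self):
        lam = 0.5
        with pytest.raises(InfeasibleFractionError):
            solve_single_positive_probability(1.01 * (1 - math.exp(-lam)), lam)
        with pytest.raises(InfeasibleFractionError):
            solve_single_positive_probability(0.1, 0.0)

    def test_fraction_at_bound_is_unity(self):
        # every positive droplet single-species: p = 1 exactly
        lam = 0.5
        assert solve_single_positive_probability(1 - math.exp(-lam), lam) == 1.0

    @given(
        lam=st.floats(0.01, 4.25),
        frac=st.floats(0.001, 0.999),
    )
    def test_matches_closed_form(self, lam, frac):
        """Truncation at k=20 is numerically irrelevant below 4.25
        copies/droplet: the polynomial root agrees with the untruncated
        closed form to 1e-6."""
        s = frac * (1 - math.exp(-lam))
        p_trunc = solve_single_positive_probability(s, lam)
        p_exact = closed_form_single_positive_probability(s, lam)
        assert abs(p_trunc - p_exact) < 1e-6


# ---------------------------------------------------------------------------
# Poisson-multinomial model
# ---------------------------------------------------------------------------

class TestPoissonMultinomial:
    def test_worked_example(self, worked_counts):
        res = integrity_poisson_multinomial(worked_counts)
        assert res.method == "poisson_multinomial"
        assert res.integrity_percent == pytest.approx(39.65, abs=0.01)
        assert res.species.p_t1_only == pytest.approx(0.301769, abs=1e-5)
        assert res.integrity_percent == pytest.approx(res.species.p_full * 100, abs=1e-12)

    def test_strict_na_rule(self):
        res = integrity_poisson_multinomial(DropletCounts(4000, 0, 2000, 14000))
        assert res.is_na and "n_t1_only" in res.na_reason

    def test_relaxed_rule_fully_intact(self):
        counts = DropletCounts(7000, 0, 0, 13000)
        assert integrity_poisson_multinomial(counts).is_na  # strict
        res = integrity_poisson_multinomial(counts, na_rule="relaxed")
        assert res.integrity_percent == pytest.approx(100.0, abs=1e-9)

    def test_closed_form_identity(self):
        """The estimator equals 100 (l1 + l2 - ltot)/ltot wherever both
        are defined (untruncated algebraic identity)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p1, p2 = rng.dirichlet([1, 1, 1])[:2]
            lam = rng.uniform(0.05, 4.0)
            probs = expected_category_probabilities(lam, SpeciesProbabilities(p1, p2))
            n = rng.multinomial(20000, probs)
            if (n == 0).any():
                continue
            counts = DropletCounts(*[int(x) for x in n])
            res = integrity_poisson_multinomial(counts)
            l1, l2, lt = target_lambdas(counts)
            assert res.integrity_percent == pytest.approx(
                100 * (l1 + l2 - lt) / lt, abs=1e-4
            )

    def test_negative_estimates_not_clamped(self):
        # more single positives than an intact population could explain
        lam = 1.0
        probs = expected_category_probabilities(lam, SpeciesProbabilities(0.6, 0.4))
        d = 1e6
        # perturb doubles downward / singles upward to push p1+p2 past 1
        counts = DropletCounts(
            probs[0] * d * 0.5,
            probs[1] * d + probs[0] * d * 0.25,
            probs[2] * d + probs[0] * d * 0.25,
            probs[3] * d,
        )
        res = integrity_poisson_multinomial(counts)
        assert res.integrity_percent < 0
        assert res.species.out_of_range

    @given(
        lam=st.floats(0.01, 4.25),
        w=st.floats(0.0, 1.0),
        split=st.floats(0.0, 1.0),
    )
    def test_round_trip_identity(self, lam, w, split):
        """Exact expected counts fed back through the estimator recover
        the generative intact fraction."""
        p_full = w
        p1 = (1 - p_full) * split
        p2 = (1 - p_full) * (1 - split)
        probs = expected_category_probabilities(lam, SpeciesProbabilities(p1, p2))
        d = 20000
        counts = DropletCounts(*(probs * d))
        res = integrity_poisson_multinomial(counts, na_rule="relaxed")
        assert abs(res.integrity_percent / 100 - p_full) < 1e-4


# ---------------------------------------------------------------------------
# category probabilities & cross-model invariants
# ---------------------------------------------------------------------------

class TestCategoryProbabilities:
    def test_zero_lambda(self):
        probs = expected_category_probabilities(0.0, SpeciesProbabilities(0.3, 0.3))
        assert np.allclose(probs, [0, 0, 0, 1])

    def test_fully_intact(self):
        lam = 0.7
        probs = expected_category_probabilities(lam, SpeciesProbabilities(0.0, 0.0))
        assert np.allclose(probs, [1 - math.exp(-lam), 0, 0, math.exp(-lam)])

    def test_inverts_worked_example(self):
        probs = expected_category_probabilities(
            0.510826, SpeciesProbabilities(0.301769, 0.301769)
        )
        assert np.allclose(probs, [0.2, 0.1, 0.1, 0.6], atol=2e-6)

    @given(
        lam=st.floats(0.0, 4.25),
        a=st.floats(0.0, 1.0),
        b=st.floats(0.0, 1.0),
    )
    def test_valid_distribution(self, lam, a, b):
        p1 = a * b
        p2 = a * (1 - b)
        probs = expected_category_probabilities(lam, SpeciesProbabilities(p1, p2))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= -1e-12).all()


@given(
    m=st.integers(1, 50),
    nd=st.integers(1, 500),
    n1=st.integers(1, 500),
    n2=st.integers(1, 500),
    nn=st.integers(1, 5000),
)
def test_scale_invariance_of_all_models(m, nd, n1, n2, nn):
    """Multiplying all four counts by a positive integer leaves every
    integrity model unchanged."""
    base = DropletCounts(nd, n1, n2, nn)
    big = base.scaled(m)
    for fn in (
        integrity_simple,
        integrity_linkage_avg,
        integrity_linkage_comp,
        integrity_poisson_multinomial,
    ):
        a, b = fn(base), fn(big)
        assert a.integrity_percent == pytest.approx(b.integrity_percent, abs=1e-8)
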