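import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dmnstab as d
from dmnstab.inference import (
    _consistency_gain,
    _swap_efferents,
    bh_adjust,
    binomial_two_sided,
    paired_label_null,
    published_stability_table,
    stability_table,
    swap_null_between,
    swap_null_within,
)
from dmnstab.stability import AsymmetryResult


class TestBinomialTwoSided:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(9, 10, 0.021), (8, 12, 0.388), (7, 8, 0.070), (4, 10, 0.754)],
    )
    def test_exact_values_at_three_decimals(self, k, n, expected):
        assert round(binomial_two_sided(k, n), 3) == expected

    def test_central_value_gives_one(self):
        assert binomial_two_sided(5, 10) == 1.0
        assert binomial_two_sided(20, 40) == 1.0

    @given(st.integers(1, 60), st.data())
    @settings(max_examples=60, deadline=None)
    def test_symmetric_in_k_about_half(self, n, data):
        k = data.draw(st.integers(0, n))
        assert binomial_two_sided(k, n) == pytest.approx(
            binomial_two_sided(n - k, n), abs=1e-12
        )

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            binomial_two_sided(0, 0)
        with pytest.raises(ValueError):
            binomial_two_sided(5, 4)


class TestBhAdjust:
    def test_equal_pvalues_are_unchanged(self):
        adj, _ = bh_adjust([0.03] * 7)
        assert np.allclose(adj, 0.03)

    def test_single_pvalue_is_unchanged(self):
        adj, rej = bh_adjust([0.04])
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12),
        st.integers(0, 11),
        st.floats(1.01, 2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_input(self, ps, idx, factor):
        idx = idx % len(ps)
        bumped = list(ps)
        bumped[idx] = min(1.0, bumped[idx] * factor)
        adj_a, _ = bh_adjust(ps)
        adj_b, _ = bh_adjust(bumped)
        assert np.all(adj_b >= adj_a - 1e-12)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestPublishedTable:
    def test_k_recovery_is_consistent_with_printed_effects(self):
        df = published_stability_table()
        back = 100.0 * df["k_matching"] / df["n_asymmetric_sessions"]
        assert np.all(np.abs(back - df["effect_size_pct"]) < 0.5)

    def test_nine_subjects_significant_at_fdr_5(self):
        df = published_stability_table()
        assert int(df["significant"].sum()) == 9


class TestStabilityTable:
    @staticmethod
    def results(labels, subject="S1"):
        return [
            AsymmetryResult(
                index=0.1 if lab == "left" else (-0.1 if lab == "right" else 0.0),
                posterior_probability=0.99 if lab != "none" else 0.6,
                dominance=lab, subject_id=subject,
            )
            for lab in labels
        ]

    def test_all_matching_extreme_case(self):
        rows = stability_table(
            {"S1": self.results(["left"] * 8)}, {"S1": "left"}
        )
        assert rows[0].k_matching == 8
        assert rows[0].effect_size_pct == 100.0
        assert rows[0].p_uncorrected == pytest.approx(2 * 0.5**8)

    def test_nonsignificant_sessions_are_discarded(self):
        labels = ["left"] * 6 + ["none"] * 4
        rows = stability_table({"S1": self.results(labels)}, {"S1": "left"})
        assert rows[0].n_asymmetric_sessions == 6
        assert rows[0].pct_asymmetric == pytest.approx(60.0)

    def test_symmetric_subject_is_excluded(self):
        rows = stability_table(
            {"S1": self.results(["left"] * 5), "S2": self.results(["left"] * 5, "S2")},
            {"S1": "left", "S2": "none"},
        )
        assert [r.subject_id for r in rows] == ["S1"]

    def test_zero_significant_sessions_yields_flagged_row(self):
        rows = stability_table(
            {"S1": self.results(["none"] * 5)}, {"S1": "left"}
        )
        assert rows[0].flagged_empty
        assert rows[0].n_asymmetric_sessions == 0

    def test_null_cohorts_rarely_reject(self):
        """FDR rejections stay near nominal on no-dominance, no-stability data."""
        from dmnstab.stability import asymmetry

        rejected = tested = 0
        for seed in range(30):
            spec = d.CohortSpec(
                n_subjects=8, sessions_per_subject=10, asymmetry_magnitude=0.0,
                self_offset=0.0, afferent_offset=0.0, between_subject_sd=0.0,
                seed=61_000 + seed,
            )
            truth = d.sample_cohort(spec)
            posts = d.emit_session_posteriors(truth)
            sess = {}
            for p in posts:
                sess.setdefault(p.subject_id, []).append(asymmetry(p))
            dom = {f"S{i+1}": lab for i, lab in enumerate(truth.dominance_labels)}
            rows = [r for r in stability_table(sess, dom) if not r.flagged_empty]
            tested += len(rows)
            rejected += sum(r.p_fdr is not None and r.p_fdr < 0.05 for r in rows)
        assert rejected / tested <= 0.06


class TestSwapNull:
    def test_identical_left_dominant_subjects_show_no_gain(self):
        spec = d.CohortSpec(
            n_subjects=6, sessions_per_subject=0, between_subject_sd=0.0,
            dominance_probability=1.0, seed=0,
        )
        truth = d.sample_cohort(spec)
        res = swap_null_between(truth.subject_vectors(), n_rand=400, seed=1)
        assert res.observed_effect == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_mixed_dominance_cohort_is_significant(self):
        spec = d.CohortSpec(
            n_subjects=16, sessions_per_subject=0, asymmetry_magnitude=0.5,
            between_subject_sd=0.05, seed=4,
        )
        truth = d.sample_cohort(spec)
        res = swap_null_between(truth.subject_vectors(), n_rand=2000, seed=2)
        assert res.observed_effect > 0
        assert res.p_value < 0.01

    def test_seeded_null_is_reproducible(self, rng):
        V = rng.normal(0, 0.3, (6, 16))
        a = swap_null_between(V, n_rand=100, seed=9)
        b = swap_null_between(V, n_rand=100, seed=9)
        assert np.array_equal(a.null_distribution, b.null_distribution)
        assert a.p_value == b.p_value

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        """Bernoulli-mask sampling agrees with the full 2^n swap group."""
        n = 8
        spec = d.CohortSpec(n_subjects=n, sessions_per_subject=0, seed=12)
        V = d.sample_cohort(spec).subject_vectors()
        observed = _consistency_gain(V)
        exact_ge = 0
        for bits in itertools.product([False, True], repeat=n):
            g = _consistency_gain(_swap_efferents(V, np.array(bits), False))
            exact_ge += g >= observed
        exact_p = exact_ge / 2**n
        res = swap_null_between(V, n_rand=4000, seed=3)
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert abs(res.p_value - exact_p) < 4 * se + 1e-3

    def test_pvalues_are_in_unit_interval_with_add_one_rule(self, rng):
        V = rng.normal(0, 0.3, (5, 16))
        res = swap_null_between(V, n_rand=50, seed=0)
        assert 1 / 51 <= res.p_value <= 1.0

    def test_too_few_subjects_is_an_error(self, rng):
        with pytest.raises(ValueError):
            swap_null_between(rng.normal(size=(2, 16)), n_rand=10, seed=0)


class TestSwapNullWithin:
    def test_uniform_dominance_sessions_show_zero_effect(self):
        spec = d.CohortSpec(
            n_subjects=2, sessions_per_subject=8, dominance_probability=1.0,
            between_session_sd=0.02, seed=6,
        )
        truth = d.sample_cohort(spec)
        mats = {f"S{i+1}": truth.session_vectors(i) for i in range(2)}
        results = swap_null_within(mats, n_rand=200, seed=1)
        for res in results.values():
            # every session is left-dominant: reordering is a no-op
            assert abs(res.observed_effect) < 0.02
            assert res.p_fdr is not None

    def test_session_dominance_flips_are_detected(self):
        spec = d.CohortSpec(
            n_subjects=3, sessions_per_subject=12, asymmetry_magnitude=0.4,
            flip_probability=0.5, between_session_sd=0.05, seed=8,
        )
        truth = d.sample_cohort(spec)
        mats = {f"S{i+1}": truth.session_vectors(i) for i in range(3)}
        results = swap_null_within(mats, n_rand=1000, seed=2)
        assert sum(r.p_value < 0.05 for r in results.values()) >= 2


class TestPairedLabelNull:
    def test_equal_lists_show_no_effect(self, rng):
        a = rng.normal(size=10)
        res = paired_label_null(a, a, n_rand=200, seed=0)
        assert res.observed_effect == 0.0
        assert res.p_value > 0.4

    def test_constant_positive_shift_is_near_floor(self, rng):
        a = rng.normal(0, 0.1, 20)
        res = paired_label_null(a, a + 0.5, n_rand=2000, seed=1)
        assert res.p_value == pytest.approx(1 / 2001)

    def test_sampled_p_matches_sign_flip_enumeration(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.3, 0.5, 10)
        diff = b - a
        observed = diff.mean()
        exact_ge = 0
        for signs in itertools.product([-1.0, 1.0], repeat=10):
            exact_ge += (np.array(signs) * diff).mean() >= observed
        exact_p = exact_ge / 2**10
        res = paired_label_null(a, b, n_rand=4000, seed=7)
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert abs(res.p_value - exact_p) < 4 * se + 1e-3

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            paired_label_null([1, 2, 3], [1, 2], n_rand=10, seed=0)
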