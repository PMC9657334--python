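import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surromark.errors import DataError, ParameterError, StatisticError
from surromark.metrics import (
    evaluate_candidates,
    exclusion_at_reference_specificity,
    pearson_correlation,
    rescue_fraction,
    status_discordance,
)


def brute_force_exclusion(values, ref_high, q):
    """Oracle: scan all observed values as candidate thresholds."""
    values = np.asarray(values, float)
    ref_high = np.asarray(ref_high, bool)
    low = values[~ref_high]
    best_t = None
    for t in sorted(values):
        if np.mean(low <= t) >= q:
            best_t = t
            break
    high = values[ref_high]
    return best_t, float(np.mean(high <= best_t))


class TestPearson:
    def test_exact_linearity(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        # cov/sd formula by hand: r = 0.8 for this permutation pattern
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_raises(self):
        with pytest.raises(StatisticError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestExclusion:
    def test_hand_worked_example(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 8, 9.5, 11, 12, 20.0])
        ref_high = np.array([False] * 10 + [True] * 5)
        res = exclusion_at_reference_specificity(values, ref_high, q=0.9)
        assert res.threshold == 9.0
        assert res.excluded_high_fraction == pytest.approx(0.2)
        assert res.excluded_low_fraction >= 0.9

    def test_separated_classes_exclude_no_high(self, rng):
        low = rng.normal(0, 1, 80)
        high = low.max() + 1 + rng.random(40)
        res = exclusion_at_reference_specificity(
            np.concatenate([low, high]),
            np.array([False] * 80 + [True] * 40), q=0.95)
        assert res.excluded_high_fraction == 0.0

    def test_q_one_with_overlapping_high_excludes_all(self, rng):
        low = rng.normal(0, 1, 50)
        high = low.min() + 0.5 * (low.max() - low.min()) * rng.random(30)
        res = exclusion_at_reference_specificity(
            np.concatenate([low, high]),
            np.array([False] * 50 + [True] * 30), q=1.0)
        assert res.excluded_high_fraction == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(5, 60))
        values = np.array(data.draw(st.lists(
            st.integers(-20, 20), min_size=n, max_size=n)), dtype=float)
        n_high = data.draw(st.integers(1, n - 1))
        ref_high = np.zeros(n, bool)
        ref_high[data.draw(st.permutations(range(n)))[:n_high]] = True
        q = data.draw(st.sampled_from([0.5, 0.75, 0.9, 0.95, 1.0]))
        res = exclusion_at_reference_specificity(values, ref_high, q=q)
        t, ehf = brute_force_exclusion(values, ref_high, q)
        assert res.threshold == t
        assert res.excluded_high_fraction == pytest.approx(ehf)

    def test_excluded_high_monotone_in_q(self, rng):
        values = rng.normal(0, 1, 200)
        ref_high = rng.random(200) < 0.6
        prev = -1.0
        for q in (0.5, 0.7, 0.8, 0.9, 0.95, 1.0):
            res = exclusion_at_reference_specificity(values, ref_high, q=q)
            assert res.excluded_high_fraction >= prev
            prev = res.excluded_high_fraction

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.normal(0, 1, 150)
        ref_high = rng.random(150) < 0.5
        a = exclusion_at_reference_specificity(values, ref_high, q=0.9)
        b = exclusion_at_reference_specificity(np.exp(values), ref_high, q=0.9)
        assert a.excluded_high_fraction == b.excluded_high_fraction
        assert a.excluded_low_fraction == b.excluded_low_fraction

    def test_empty_class_raises(self):
        with pytest.raises(DataError):
            exclusion_at_reference_specificity([1.0, 2.0], [True, True], q=0.9)

    def test_bad_q_raises(self):
        with pytest.raises(ParameterError):
            exclusion_at_reference_specificity([1.0, 2.0], [True, False], q=1.5)


class TestDiscordance:
    def test_identical_classes_zero_rate(self):
        rna = np.array([True, False, True])
        status = np.array(["positive", "negative", "positive"], object)
        res = status_discordance(rna, status)
        assert res.discordance_rate == 0.0

    def test_fully_flipped_rate_one(self):
        rna = np.array([True, False])
        status = np.array(["negative", "positive"], object)
        assert status_discordance(rna, status).discordance_rate == 1.0

    def test_constructed_mismatch_count(self, rng):
        n = 1000
        rna = rng.random(n) < 0.5
        status = np.where(rna, "positive", "negative").astype(object)
        flip_idx = rng.choice(n, size=134, replace=False)
        for i in flip_idx:
            status[i] = "negative" if status[i] == "positive" else "positive"
        res = status_discordance(rna, status)
        assert res.n_discordant == 134
        assert res.discordance_rate == pytest.approx(0.134)

    def test_unknown_excluded_from_denominator(self):
        rna = np.array([True, True, False])
        status = np.array(["positive", "unknown", "positive"], object)
        res = status_discordance(rna, status)
        assert res.n_compared == 2
        assert res.n_unknown_excluded == 1
        assert res.discordance_rate == pytest.approx(0.5)

    def test_symmetry_on_fully_known_data(self, rng):
        a = rng.random(50) < 0.5
        b = rng.random(50) < 0.5
        status_b = np.where(b, "positive", "negative").astype(object)
        status_a = np.where(a, "positive", "negative").astype(object)
        assert (status_discordance(a, status_b).n_discordant
                == status_discordance(b, status_a).n_discordant)

    def test_all_unknown_raises(self):
        with pytest.raises(DataError):
            status_discordance([True], np.array(["unknown"], object))


class TestRescue:
    def test_direct_count(self):
        ref = np.array([True] * 4 + [False] * 2)
        primary = np.array([False] * 4 + [True, False])
        alt = {"TFF1": np.array([True, True, True, False, False, False])}
        res = rescue_fraction(ref, primary, alt)
        assert res.n_target_group == 4
        assert res.per_gene_high_fraction["TFF1"] == pytest.approx(0.75)

    def test_all_alternatives_low(self):
        ref = np.array([True, True, False])
        primary = np.array([False, False, False])
        alt = {"A": np.zeros(3, bool), "B": np.zeros(3, bool)}
        res = rescue_fraction(ref, primary, alt)
        assert res.union_high_fraction == 0.0

    def test_union_bound_tight_case(self):
        ref = np.array([True, True])
        primary = np.array([False, False])
        alt = {"A": np.array([True, False]), "B": np.array([False, True])}
        res = rescue_fraction(ref, primary, alt)
        assert res.per_gene_high_fraction == {"A": 0.5, "B": 0.5}
        assert res.union_high_fraction == 1.0

    def test_union_at_least_max_per_gene(self, rng):
        ref = rng.random(100) < 0.7
        primary = rng.random(100) < 0.4
        if not (ref & ~primary).any():
            pytest.skip("degenerate draw")
        alt = {g: rng.random(100) < 0.5 for g in ("A", "B", "C")}
        res = rescue_fraction(ref, primary, alt)
        assert res.union_high_fraction >= max(res.per_gene_high_fraction.values())

    def test_empty_target_group_raises(self):
        with pytest.raises(DataError, match="0"):
            rescue_fraction([True], [True], {"A": [True]})


class TestEvaluateCandidates:
    def test_self_comparison(self, default_cohort):
        rep = evaluate_candidates(default_cohort.expression, "ESR1", ["ESR1"],
                                  seed=0)
        row = rep.table.iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        # ESR1's modes separate beyond the low-group q-quantile
        assert row.excluded_high_fraction == 0.0

    def test_empty_candidate_list(self, default_cohort):
        rep = evaluate_candidates(default_cohort.expression, "ESR1", [], seed=0)
        assert len(rep.table) == 0
        assert rep.reference_fit.is_bimodal

    def test_missing_gene_raises_key_error(self, default_cohort):
        with pytest.raises(KeyError, match="NOPE"):
            evaluate_candidates(default_cohort.expression, "ESR1", ["NOPE"], seed=0)

    def test_full_report_structure(self, default_cohort):
        rep = evaluate_candidates(
            default_cohort.expression, "ESR1", ["PGR", "CA12", "TFF1", "GREB1"],
            clinical=default_cohort.clinical, seed=0)
        assert set(rep.table.candidate) == {"PGR", "CA12", "TFF1", "GREB1"}
        assert "ESR1" in rep.discordance
        assert rep.rescue is not None
        assert set(rep.rescue.per_gene_high_fraction) == {"CA12", "TFF1", "GREB1"}

    def test_sample_permutation_invariance(self, default_cohort):
        expr = default_cohort.expression
        perm = np.random.default_rng(0).permutation(expr.n_samples)
        from surromark.io import ExpressionMatrix

        shuffled = ExpressionMatrix(expr.data.iloc[:, perm])
        a = evaluate_candidates(expr, "ESR1", ["PGR", "CA12"], seed=0)
        b = evaluate_candidates(shuffled, "ESR1", ["PGR", "CA12"], seed=0)
        for col in ("pearson_r", "excluded_high_fraction", "threshold"):
            np.testing.assert_allclose(a.table[col], b.table[col], rtol=1e-9)
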