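"""Pre-calibration screening battery."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from catgrm.screening import (
    ResponseMatrix,
    ScreeningError,
    comonotonic_cov,
    drop_complete_case,
    drop_unused_categories,
    item_remainder_correlations,
    local_dependence_check,
    monotonicity_check,
    run_screening,
    scalability_coefficients,
    unidimensionality_check,
)
from catgrm.synth import Injection, SyntheticConfig, choose_injection_targets, generate_bank, generate_dataset


def make_matrix(values, k=5, group=None):
    values = np.asarray(values, float)
    n, p = values.shape
    return ResponseMatrix(values, tuple(f"i{j}" for j in range(p)),
                          tuple(f"r{j}" for j in range(n)), k, group=group)


class TestCompleteCase:
    def test_counts(self, rng):
        values = rng.integers(1, 6, (10, 4)).astype(float)
        values[0, 1] = np.nan
        values[3, 0] = np.nan
        values[7, 3] = np.nan
        out = drop_complete_case(make_matrix(values))
        assert out.n_respondents == 7
        assert not np.isnan(out.values).any()

    def test_complete_matrix_unchanged(self, rng):
        data = make_matrix(rng.integers(1, 6, (12, 5)).astype(float))
        out = drop_complete_case(data)
        assert np.array_equal(out.values, data.values)

    def test_all_incomplete_is_error(self):
        values = np.full((4, 3), np.nan)
        values[:, 0] = 2
        with pytest.raises(ScreeningError):
            drop_complete_case(make_matrix(values))


class TestUnusedCategories:
    def test_item_missing_a_category_excluded(self, rng):
        values = rng.integers(1, 6, (200, 4)).astype(float)
        values[:, 2] = np.clip(values[:, 2], 1, 4)  # category 5 never used
        out, excluded = drop_unused_categories(make_matrix(values))
        assert list(excluded) == ["i2"]
        assert out.item_ids == ("i0", "i1", "i3")

    def test_full_usage_is_identity(self, clean_dataset):
        data, _, _ = clean_dataset
        out, excluded = drop_unused_categories(data)
        assert excluded == {}
        assert out.item_ids == data.item_ids


class TestItemRemainder:
    def test_independent_item_excluded_duplicate_retained(self):
        data, bank, theta = generate_dataset(SyntheticConfig(
            n_items=10, seed=5,
            injections=(Injection("low_item_remainder", (4,)),)))
        out, excluded, rs = item_remainder_correlations(data)
        assert "item005" in excluded
        assert abs(excluded["item005"]) < 0.15

    def test_decisions_follow_strict_cutoff(self, clean_dataset):
        """Items are excluded exactly when their independently computed r < 0.3."""
        data, _, _ = clean_dataset
        out, excluded, rs = item_remainder_correlations(data, threshold=0.3)
        X = data.values
        total = X.sum(axis=1)
        for j, item in enumerate(data.item_ids):
            r = np.corrcoef(X[:, j], total - X[:, j])[0, 1]
            assert (item in excluded) == (r < 0.3)
            assert rs[j] == pytest.approx(r)

    def test_zero_variance_item_excluded_with_warning(self, rng):
        values = rng.integers(1, 6, (50, 4)).astype(float)
        values[:, 1] = 3.0
        with pytest.warns(UserWarning, match="zero variance"):
            _, excluded, _ = item_remainder_correlations(make_matrix(values))
        assert "i1" in excluded


class TestUnidimensionality:
    def test_single_factor_data_passes_without_removals(self, clean_dataset):
        data, _, _ = clean_dataset
        out, excluded, detail = unidimensionality_check(data)
        assert excluded == {}
        assert detail["first_proportion"] >= 0.20
        assert detail["ratio"] >= 4.0

    def test_independent_items_fail(self, rng):
        values = rng.integers(1, 6, (600, 10)).astype(float)
        with pytest.raises(ScreeningError):
            unidimensionality_check(make_matrix(values))

    def test_two_factor_data_triggers_removals(self):
        cfg = SyntheticConfig(n_items=8, seed=3)
        d1, _, _ = generate_dataset(cfg)
        d2, _, _ = generate_dataset(replace(cfg, seed=30))
        values = np.hstack([d1.values, d2.values])  # two independent factors
        data = make_matrix(values)
        out, excluded, detail = unidimensionality_check(data)
        assert len(excluded) > 0
        assert detail["ratio"] >= 4.0


class TestLocalDependence:
    def test_injected_pair_flagged_one_member_excluded(self):
        base = SyntheticConfig(n_items=20, seed=1)
        bank = generate_bank(base)
        inj = choose_injection_targets(bank, ["local_dependence_pair"])
        data, bank, _ = generate_dataset(replace(base, injections=inj))
        out, excluded, flagged = local_dependence_check(data)
        pair_ids = {bank.item_ids[i] for i in inj[0].items}
        assert any({a, b} == pair_ids for a, b, _ in flagged)
        assert len(set(excluded) & pair_ids) == 1

    def test_clean_data_flags_nothing(self, clean_dataset):
        data, _, _ = clean_dataset
        out, excluded, flagged = local_dependence_check(data)
        assert flagged == []
        assert out.item_ids == data.item_ids


class TestScalability:
    def test_duplicate_item_has_unit_pair_h(self, rng):
        x = rng.integers(1, 6, 300).astype(float)
        values = np.column_stack([x, x, rng.integers(1, 6, 300)])
        H_pair, _ = scalability_coefficients(make_matrix(values))
        assert H_pair[0, 1] == pytest.approx(1.0)

    def test_toy_table_matches_sort_oracle(self):
        # 4 respondents, 2 items, printed by hand
        values = np.array([[1.0, 2.0], [3.0, 2.0], [4.0, 5.0], [2.0, 1.0]])
        H_pair, _ = scalability_coefficients(make_matrix(values))
        x, y = values[:, 0], values[:, 1]
        covmax = np.cov(np.sort(x), np.sort(y), ddof=1)[0, 1]
        assert comonotonic_cov(x, y) == pytest.approx(covmax)
        assert H_pair[0, 1] == pytest.approx(np.cov(x, y, ddof=1)[0, 1] / covmax)

    def test_covmax_dominates_cov(self, rng):
        """Frechet bound: H_ij <= 1 for arbitrary ordinal pairs."""
        for _ in range(30):
            x = rng.integers(1, 6, 80).astype(float)
            y = rng.integers(1, 6, 80).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            assert np.cov(x, y, ddof=1)[0, 1] <= comonotonic_cov(x, y) + 1e-12

    def test_independent_item_excluded(self):
        data, bank, _ = generate_dataset(SyntheticConfig(
            n_items=10, seed=7,
            injections=(Injection("low_item_remainder", (2,)),)))
        out, excluded, H = monotonicity_check(data)
        assert "item003" in excluded


class TestBattery:
    def test_clean_run_retains_items_and_is_deterministic(self, clean_dataset):
        data, _, _ = clean_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out1, rep1 = run_screening(data)
            out2, rep2 = run_screening(data)
        assert out1.item_ids == out2.item_ids
        assert rep1.to_dict() == rep2.to_dict()
        stages = [r.stage for r in rep1.stages]
        assert stages == ["complete_case", "unused_category", "item_remainder",
                          "unidimensionality", "local_dependence", "monotonicity"]

    def test_funnel_counts_are_consistent(self, clean_dataset):
        data, _, _ = clean_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, rep = run_screening(data)
        for rec in rep.stages[1:]:
            assert rec.n_items_out == rec.n_items_in - len(rec.excluded)
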