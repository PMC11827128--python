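"""EM calibration, MAP scoring, item fit, DIF, and alpha."""

import itertools
import warnings
from dataclasses import replace

import numpy as np
import pytest

from catgrm.calibration import (
    cronbach_alpha,
    dif_screen,
    fit_grm,
    latent_grid,
    never_modal_category_screen,
    normal_weights,
    s_x2_item_fit,
    score_map,
    summed_score_distribution,
)
from catgrm.grm import ItemBank, ItemParameters, bank_category_probs
from catgrm.screening import ResponseMatrix
from catgrm.synth import SyntheticConfig, generate_bank, generate_dataset

from conftest import random_item


def grid_search_map(items, responses, step=1e-4):
    """Brute-force posterior mode on a dense grid (independent oracle)."""
    grid = np.arange(-6, 6 + step / 2, step)
    lp = -(grid**2) / 2
    for it, x in zip(items, responses):
        z = it.discrimination * (grid[:, None] - it.thresholds[None, :])
        c = 1 / (1 + np.exp(-z))
        full = np.hstack([np.ones((len(grid), 1)), c, np.zeros((len(grid), 1))])
        P = np.maximum(full[:, :-1] - full[:, 1:], 1e-12)
        lp += np.log(P[:, int(x) - 1])
    return grid[np.argmax(lp)]


class TestScoreMap:
    def test_no_items_returns_prior(self):
        t = score_map([], [])
        assert t.value == 0.0
        assert t.se == 1.0

    def test_matches_grid_oracle(self, toy_bank, rng):
        for _ in range(10):
            resp = rng.integers(1, 6, len(toy_bank))
            got = score_map(toy_bank.items, resp).value
            assert got == pytest.approx(grid_search_map(toy_bank.items, resp), abs=1e-3)

    def test_extreme_patterns_are_symmetric(self):
        items = tuple(
            ItemParameters(f"s{i}", 1.5, np.array([-1.2, -0.4, 0.4, 1.2])) for i in range(10)
        )
        hi = score_map(items, [5] * 10).value
        lo = score_map(items, [1] * 10).value
        assert hi > 0 > lo
        assert hi == pytest.approx(-lo, abs=1e-4)

    def test_se_includes_prior_precision(self, std_item):
        t = score_map([std_item], [3])
        assert t.se < 1.0  # posterior is tighter than the prior alone


class TestFitGRM:
    def test_loglik_ascends_and_converges(self):
        data, _, _ = generate_dataset(SyntheticConfig(n_respondents=250, n_items=5, seed=2))
        res = fit_grm(data, tol=1e-3)
        assert res.converged
        assert np.all(np.diff(res.ll_history) > -1e-8)

    def test_identical_items_get_identical_estimates(self, rng):
        data, _, _ = generate_dataset(SyntheticConfig(n_respondents=400, n_items=4, seed=9))
        values = np.column_stack([data.values, data.values[:, 0]])
        dup = ResponseMatrix(values, tuple(list(data.item_ids) + ["copy"]),
                             data.respondent_ids, 5)
        res = fit_grm(dup, tol=1e-4)
        i, j = 0, 4
        assert res.bank.a[i] == pytest.approx(res.bank.a[j], abs=1e-3)
        assert np.allclose(res.bank.b[i], res.bank.b[j], atol=1e-3)

    def test_recovers_generating_parameters(self):
        data, bank, _ = generate_dataset(SyntheticConfig(n_respondents=1000, n_items=10, seed=4))
        res = fit_grm(data, tol=1e-3)
        assert np.corrcoef(bank.a, res.bank.a)[0, 1] > 0.85
        assert np.sqrt(np.mean((bank.b - res.bank.b) ** 2)) < 0.25

    def test_estimated_thresholds_strictly_increasing(self):
        data, _, _ = generate_dataset(SyntheticConfig(n_respondents=300, n_items=6, seed=6))
        res = fit_grm(data, tol=1e-3)
        for item in res.bank:
            assert np.all(np.diff(item.thresholds) > 0)


class TestNeverModal:
    def test_widely_spaced_item_retained(self):
        bank = ItemBank((ItemParameters("w", 2.0, np.array([-2.0, -0.7, 0.7, 2.0])),))
        assert never_modal_category_screen(bank) == {}

    def test_coincident_thresholds_hide_a_category(self):
        bank = ItemBank((ItemParameters("c", 2.0, np.array([-1.0, 0.0, 0.05, 1.5])),))
        flagged = never_modal_category_screen(bank)
        assert "c" in flagged
        assert 3 in flagged["c"]  # the pinched middle category

    def test_binary_items_never_flagged(self, rng):
        items = tuple(ItemParameters(f"b{i}", rng.uniform(0.5, 3), np.array([rng.normal()]))
                      for i in range(10))
        assert never_modal_category_screen(ItemBank(items)) == {}


class TestSummedScore:
    @pytest.mark.parametrize("n_items", [3, 4])
    def test_recursion_matches_exhaustive_enumeration(self, n_items, rng):
        """Lord-Wingersky equals the brute-force sum over all response patterns."""
        items = tuple(random_item(rng, k=3, item_id=f"e{i}") for i in range(n_items))
        bank = ItemBank(items)
        grid = latent_grid(11)
        P = bank_category_probs(bank.a, bank.b, grid)  # p x Q x 3
        S = summed_score_distribution(P)
        max_score = n_items * 2
        brute = np.zeros((len(grid), max_score + 1))
        for pattern in itertools.product(range(3), repeat=n_items):
            prob = np.ones(len(grid))
            for i, k in enumerate(pattern):
                prob *= P[i, :, k]
            brute[:, sum(pattern)] += prob
        assert np.allclose(S, brute, atol=1e-12)


class TestSX2:
    def test_well_fitting_items_rarely_excluded(self):
        data, _, _ = generate_dataset(SyntheticConfig(n_items=10, seed=11))
        res = fit_grm(data, tol=1e-3)
        fit = s_x2_item_fit(res.bank, data)
        assert fit["statistic"].ge(0).all()
        assert fit["p"].between(0, 1).all()
        assert fit["excluded"].sum() <= 1

    def test_gross_misfit_detected(self):
        """An item calibrated with badly wrong parameters fails its fit test."""
        data, _, _ = generate_dataset(SyntheticConfig(n_items=10, seed=12))
        res = fit_grm(data, tol=1e-3)
        items = list(res.bank.items)
        items[0] = ItemParameters(items[0].item_id, 4.0, items[0].thresholds - 1.5)
        fit = s_x2_item_fit(ItemBank(tuple(items)), data)
        assert bool(fit["excluded"].iloc[0])


class TestDIF:
    def test_identical_groups_give_zero_lr(self):
        data, _, _ = generate_dataset(SyntheticConfig(n_respondents=150, n_items=5, seed=8))
        values = np.vstack([data.values, data.values])
        group = np.array(["A"] * 150 + ["B"] * 150)
        dup = ResponseMatrix(values, data.item_ids,
                             tuple(f"r{j}" for j in range(300)), 5, group=group)
        res = dif_screen(dup, tol=5e-3, max_iter=100)
        assert np.nanmax(res["statistic"]) < 0.5
        assert not res["excluded"].any()

    def test_unused_category_in_group_skips_item(self):
        data, _, _ = generate_dataset(SyntheticConfig(n_respondents=200, n_items=4, seed=14))
        values = data.values.copy()
        group = np.array(["A", "B"] * 100)
        values[group == "B", 0] = np.clip(values[group == "B", 0], 1, 4)
        values[np.flatnonzero(group == "A")[:5], 0] = 5  # keep overall usage
        dup = ResponseMatrix(values, data.item_ids, data.respondent_ids, 5, group=group)
        with pytest.warns(UserWarning, match="skipped"):
            res = dif_screen(dup, tol=5e-3, max_iter=60)
        assert np.isnan(res["p"].iloc[0])


class TestCronbachAlpha:
    def test_duplicated_column_is_perfectly_consistent(self, rng):
        x = rng.integers(1, 6, 100).astype(float)
        assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)

    def test_parallel_items_match_spearman_brown(self, rng):
        n, p, r = 5000, 6, 0.4
        common = rng.normal(size=n)
        X = np.sqrt(r) * common[:, None] + np.sqrt(1 - r) * rng.normal(size=(n, p))
        expected = p * r / (1 + (p - 1) * r)
        assert cronbach_alpha(X) == pytest.approx(expected, abs=0.01)

    def test_independent_items_near_zero(self, rng):
        X = rng.normal(size=(2000, 8))
        assert abs(cronbach_alpha(X)) < 0.1

    def test_zero_variance_total_is_error(self):
        X = np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            cronbach_alpha(X)
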