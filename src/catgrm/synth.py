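"""Synthetic response-matrix generator.

Emulates the structure of a typical calibration sample: several hundred
respondents with a standard-normal unidimensional trait answering
5-point Likert items under a graded response model, with two-group
labels (for DIF and discriminant validity) and noisy external criterion
scores (for concurrent validity). Controlled violations can be injected
so that each screening rule has a known target:

- ``unused_category``: one item's rarest category is merged into its
  neighbor, leaving a category with zero observations.
- ``low_item_remainder``: one item's column is replaced by independent
  uniform draws (no relation to the trait).
- ``local_dependence_pair``: two items are regenerated from the trait
  plus a shared nuisance factor, creating residual correlation.
- ``non_monotone``: one item's responses are drawn at ``-theta`` for a
  random subset of respondents, degrading monotone homogeneity (low
  Loevinger H) while leaving the item-remainder correlation intact.
- ``dif``: one item's thresholds are shifted upward for the focal group.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grm import ItemBank, ItemParameters, bank_category_probs
from .screening import ResponseMatrix

INJECTION_TYPES = ("unused_category", "low_item_remainder", "local_dependence_pair", "non_monotone", "dif")


@dataclass(frozen=True)
class Injection:
    kind: str
    items: tuple[int, ...]  # item indices targeted
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in INJECTION_TYPES:
            raise ValueError(f"unknown injection type {self.kind!r}")
        need = 2 if self.kind == "local_dependence_pair" else 1
        if len(self.items) != need:
            raise ValueError(f"{self.kind} targets {need} item(s)")


@dataclass(frozen=True)
class SyntheticConfig:
    n_respondents: int = 600
    n_items: int = 20
    n_categories: int = 5
    discrimination_range: tuple[float, float] = (1.0, 2.5)
    threshold_spread: float = 1.0
    min_threshold_gap: float = 0.3
    seed: int = 0
    injections: tuple[Injection, ...] = ()
    group_fraction: float = 0.5
    group_labels: tuple[str, str] = ("F", "M")
    external_score_signs: dict = field(default_factory=lambda: {"ext_plus": 1.0, "ext_minus": -1.0})
    external_score_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_respondents < 1 or self.n_items < 3:
            raise ValueError("need n_respondents >= 1 and n_items >= 3")
        targeted = [i for inj in self.injections for i in inj.items]
        if any(i < 0 or i >= self.n_items for i in targeted):
            raise ValueError("injection item index out of range")
        if len(set(targeted)) != len(targeted):
            raise ValueError("injections must target non-overlapping items")


def generate_bank(config: SyntheticConfig, rng: np.random.Generator | None = None) -> ItemBank:
    """Draw a GRM bank: a ~ U(range), sorted normal thresholds with a gap floor."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.discrimination_range
    items = []
    for i in range(config.n_items):
        a = float(rng.uniform(lo, hi))
        b = np.sort(rng.normal(0.0, config.threshold_spread, config.n_categories - 1))
        b = _spread_thresholds(b, config.min_threshold_gap)
        items.append(ItemParameters(f"item{i + 1:03d}", a, b))
    return ItemBank(tuple(items))


def _spread_thresholds(b: np.ndarray, min_gap: float) -> np.ndarray:
    """Enforce a minimum gap by pushing thresholds apart, keeping the mean."""
    out = b.copy()
    for k in range(1, len(out)):
        out[k] = max(out[k], out[k - 1] + min_gap)
    return out - (out.mean() - b.mean())


def sample_matrix(bank: ItemBank, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized GRM sampling: one response row (1..K) per theta value."""
    P = bank_category_probs(bank.a, bank.b, np.asarray(theta, float))  # p x n x K
    cum = np.cumsum(P, axis=2)
    u = rng.random((len(bank), len(theta)))
    resp = (u[:, :, None] > cum).sum(axis=2)
    return np.clip(resp.T, 0, bank.n_categories - 1).astype(float) + 1.0


def generate_responses(
    bank: ItemBank, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ResponseMatrix, np.ndarray]:
    """Standard-normal trait draws, GRM responses, group labels, external scores."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_respondents
    theta = rng.normal(0.0, 1.0, n)
    values = sample_matrix(bank, theta, rng)
    group = np.where(rng.random(n) < config.group_fraction,
                     config.group_labels[0], config.group_labels[1])
    external = pd.DataFrame({
        name: sign * theta + rng.normal(0.0, config.external_score_noise_sd, n)
        for name, sign in config.external_score_signs.items()
    })
    data = ResponseMatrix(
        values=values,
        item_ids=tuple(bank.item_ids),
        respondent_ids=tuple(f"r{j + 1:04d}" for j in range(n)),
        n_categories=config.n_categories,
        group=group,
        external_scores=external,
    )
    return data, theta


def inject_violation(
    data: ResponseMatrix,
    bank: ItemBank,
    theta: np.ndarray,
    injection: Injection,
    rng: np.random.Generator,
) -> ResponseMatrix:
    """Apply one controlled violation to the response matrix."""
    values = data.values.copy()
    K = data.n_categories
    idx = injection.items

    if injection.kind == "unused_category":
        col = values[:, idx[0]]
        counts = np.bincount(col.astype(int), minlength=K + 1)[1:]
        rare = int(np.argmin(counts)) + 1
        neighbor = rare - 1 if rare > 1 else rare + 1
        col[col == rare] = neighbor
        values[:, idx[0]] = col

    elif injection.kind == "low_item_remainder":
        values[:, idx[0]] = rng.integers(1, K + 1, size=values.shape[0]).astype(float)

    elif injection.kind == "local_dependence_pair":
        sd = injection.params.get("nuisance_sd", 0.8)
        delta = rng.normal(0.0, sd, values.shape[0])
        shared = theta + delta
        pair_bank = ItemBank(tuple(bank.items[i] for i in idx))
        values[:, list(idx)] = sample_matrix(pair_bank, shared, rng)

    elif injection.kind == "non_monotone":
        frac = injection.params.get("reversal_fraction", 0.25)
        flip = rng.random(values.shape[0]) < frac
        eff_theta = np.where(flip, -theta, theta)
        one_bank = ItemBank((bank.items[idx[0]],))
        values[:, idx[0]] = sample_matrix(one_bank, eff_theta, rng)[:, 0]

    elif injection.kind == "dif":
        shift = injection.params.get("threshold_shift", 0.75)
        focal_label = injection.params.get("focal", data.group[0] if data.group is not None else None)
        if data.group is None:
            raise ValueError("dif injection requires group labels")
        focal = data.group == focal_label
        item = bank.items[idx[0]]
        shifted = ItemBank((ItemParameters(item.item_id, item.discrimination, item.thresholds + shift),))
        values[focal, idx[0]] = sample_matrix(shifted, theta[focal], rng)[:, 0]

    from dataclasses import replace

    return replace(data, values=values)


def choose_injection_targets(bank: ItemBank, kinds: Sequence[str], params: Sequence[dict] | None = None) -> tuple[Injection, ...]:
    """Assign injections to the most discriminating items, one per slot.

    Injecting into high-``a`` items keeps detection attributable to the
    violation itself rather than to weak discrimination (which the
    item-remainder and monotonicity screens would catch on their own).
    Items are consumed in descending discrimination order, deterministically.
    """
    order = list(np.argsort([-it.discrimination for it in bank.items]))
    params = params or [{}] * len(kinds)
    out = []
    for kind, prm in zip(kinds, params):
        need = 2 if kind == "local_dependence_pair" else 1
        # screens for unused categories / noise columns fire regardless of a,
        # so those injections take the weakest items and leave strong ones
        # for the association-sensitive violations
        if kind in ("unused_category", "low_item_remainder"):
            idx = tuple(int(order.pop()) for _ in range(need))
        else:
            idx = tuple(int(order.pop(0)) for _ in range(need))
        out.append(Injection(kind, idx, dict(prm)))
    return tuple(out)


def generate_dataset(config: SyntheticConfig) -> tuple[ResponseMatrix, ItemBank, np.ndarray]:
    """Bank + responses + truth thetas, with all configured injections applied."""
    rng = np.random.default_rng(config.seed)
    bank = generate_bank(config, rng)
    data, theta = generate_responses(bank, config, rng)
    for injection in config.injections:
        data = inject_violation(data, bank, theta, injection, rng)
    return data, bank, theta
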