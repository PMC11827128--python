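"""Samejima graded response model primitives.

Every item is a logistic GRM item: one discrimination ``a`` and ``K - 1``
strictly increasing category-boundary locations ``b_1 < ... < b_{K-1}``.
The boundary curves are ``P*_k(theta) = 1 / (1 + exp(-a (theta - b_k)))``
(pure logistic metric, no 1.7 scaling constant) and the category
probabilities are adjacent differences of the boundary curves.

Responses are coded 1..K at the API surface (matching Likert labels) and
0..K-1 only inside array code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: floor applied to category probabilities before logs/divisions
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ItemParameters:
    """One GRM item: discrimination and ordered threshold locations."""

    item_id: str
    discrimination: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", thr)
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError(f"item {self.item_id!r}: discrimination must be > 0")
        if thr.ndim != 1 or thr.size < 1:
            raise ValueError(f"item {self.item_id!r}: need at least one threshold")
        if not np.all(np.diff(thr) > 0):
            raise ValueError(f"item {self.item_id!r}: thresholds must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of GRM items sharing one category count."""

    items: tuple[ItemParameters, ...]
    n_categories: int = field(default=0)

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ValueError("item bank must contain at least one item")
        k = items[0].n_categories
        if self.n_categories == 0:
            object.__setattr__(self, "n_categories", k)
        if any(it.n_categories != self.n_categories for it in items):
            raise ValueError("all items in a bank must share n_categories")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique within a bank")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> ItemParameters:
        return self.items[i]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index_of(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        lookup = {it.item_id: it for it in self.items}
        return ItemBank(tuple(lookup[i] for i in item_ids))

    # dense arrays for vectorized evaluation
    @property
    def a(self) -> np.ndarray:
        return np.array([it.discrimination for it in self.items])

    @property
    def b(self) -> np.ndarray:
        return np.stack([it.thresholds for it in self.items])

    def to_json(self, path) -> None:
        payload = {
            "n_categories": int(self.n_categories),
            "items": [
                {"id": it.item_id, "a": float(it.discrimination), "b": [float(x) for x in it.thresholds]}
                for it in self.items
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemBank":
        with open(path) as fh:
            payload = json.load(fh)
        if not isinstance(payload, dict) or "items" not in payload or "n_categories" not in payload:
            raise ValueError("item bank JSON must contain 'n_categories' and 'items'")
        items = []
        for rec in payload["items"]:
            try:
                items.append(ItemParameters(str(rec["id"]), float(rec["a"]), np.asarray(rec["b"], float)))
            except KeyError as exc:
                raise ValueError(f"item record missing field {exc}") from exc
        bank = cls(tuple(items))
        if bank.n_categories != int(payload["n_categories"]):
            raise ValueError("declared n_categories does not match item thresholds")
        return bank


@dataclass(frozen=True)
class Theta:
    """A latent-trait score, optionally with its standard error of measurement."""

    value: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.se is not None and self.se < 0:
            raise ValueError("se must be nonnegative")


def cumulative_probs(item: ItemParameters, theta: float) -> np.ndarray:
    """Boundary probabilities ``(P*_0, ..., P*_K)`` with ``P*_0 = 1``, ``P*_K = 0``."""
    z = item.discrimination * (theta - item.thresholds)
    interior = 1.0 / (1.0 + np.exp(-z))
    return np.concatenate(([1.0], interior, [0.0]))


def category_probs(item: ItemParameters, theta: float) -> np.ndarray:
    """Probability of each response category 1..K at ``theta``."""
    cum = cumulative_probs(item, theta)
    return np.maximum(-np.diff(cum), PROB_FLOOR)


def item_information(item: ItemParameters, theta: float) -> float:
    """Observed-category Fisher information ``sum_k (P*'_{k-1} - P*'_k)^2 / P_k``."""
    cum = cumulative_probs(item, theta)
    dcum = item.discrimination * cum * (1.0 - cum)  # endpoints give 0
    probs = np.maximum(-np.diff(cum), PROB_FLOOR)
    num = -np.diff(dcum)
    return float(np.sum(num * num / probs))


def test_information(bank_subset: Iterable[ItemParameters], theta: float) -> float:
    """Sum of item informations over a non-empty subset."""
    items = list(bank_subset)
    if not items:
        raise ValueError("test information requires at least one item")
    return float(sum(item_information(it, theta) for it in items))


def sample_response(item: ItemParameters, theta: float, rng: np.random.Generator) -> int:
    """Draw one response category (1..K) from the item's category distribution."""
    probs = category_probs(item, theta)
    u = rng.random()
    return int(np.searchsorted(np.cumsum(probs), u * probs.sum(), side="right")) + 1


# ---------------------------------------------------------------------------
# Vectorized bank-level kernels (used by the EM calibrator and the CAT engine)

def bank_cumulative(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Interior boundary curves for a whole bank on a theta grid.

    Returns an array of shape (n_items, n_theta, K-1).
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    z = a[:, None, None] * (theta[None, :, None] - b[:, None, :])
    return 1.0 / (1.0 + np.exp(-z))


def bank_category_probs(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (n_items, n_theta, K)."""
    cum = bank_cumulative(a, b, theta)
    n_items, n_theta, _ = cum.shape
    full = np.empty((n_items, n_theta, cum.shape[2] + 2))
    full[:, :, 0] = 1.0
    full[:, :, -1] = 0.0
    full[:, :, 1:-1] = cum
    return np.maximum(-np.diff(full, axis=2), PROB_FLOOR)


def bank_information(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Fisher information per item, shape (n_items, n_theta)."""
    cum = bank_cumulative(a, b, theta)
    n_items, n_theta, _ = cum.shape
    full = np.empty((n_items, n_theta, cum.shape[2] + 2))
    full[:, :, 0] = 1.0
    full[:, :, -1] = 0.0
    full[:, :, 1:-1] = cum
    probs = np.maximum(-np.diff(full, axis=2), PROB_FLOOR)
    dfull = a[:, None, None] * full * (1.0 - full)
    num = -np.diff(dfull, axis=2)
    return np.sum(num * num / probs, axis=2)


def threshold_intercepts(item: ItemParameters) -> np.ndarray:
    """Slope-intercept form ``d_k = -a b_k`` (so ``z = a theta + d_k``)."""
    return -item.discrimination * item.thresholds


def intercepts_to_thresholds(a: float, d: np.ndarray) -> np.ndarray:
    """Inverse of :func:`threshold_intercepts`."""
    return -np.asarray(d, float) / a
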