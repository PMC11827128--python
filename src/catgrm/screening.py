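"""Pre-calibration item screening.

Implements the descriptive and IRT-assumption screens applied before any
model is fitted: complete-case filtering, unused-category exclusion,
item-remainder correlation (< 0.3 excluded), principal-component
unidimensionality (first component >= 20% of variance and first/second
ratio >= 4), one-factor residual local dependence (> 0.2 flags a pair),
and Mokken-type monotone homogeneity via Loevinger scalability
coefficients (H_i < 0.3 excluded).

Each screen is a pure function of the response matrix it receives; the
screens are chained in a fixed order by :func:`run_screening` and every
decision is logged in a :class:`ScreeningReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

STAGES = (
    "complete_case",
    "unused_category",
    "item_remainder",
    "unidimensionality",
    "local_dependence",
    "monotonicity",
)


class ScreeningError(RuntimeError):
    """Raised when a screen leaves the scale unusable (too few items/rows)."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Respondents x items ordinal responses with optional metadata.

    ``values`` holds floats in 1..K with NaN for missing.  ``group`` is an
    optional per-respondent label (e.g. sex) used by the DIF screen and
    discriminant validity; ``external_scores`` holds named per-respondent
    criterion scores for concurrent validity.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    respondent_ids: tuple[str, ...]
    n_categories: int = 5
    group: np.ndarray | None = None
    external_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "respondent_ids", tuple(self.respondent_ids))
        n, p = vals.shape
        if p != len(self.item_ids) or n != len(self.respondent_ids):
            raise ValueError("matrix dimensions inconsistent with id vectors")
        obs = vals[~np.isnan(vals)]
        if obs.size and (np.any(obs != np.round(obs)) or obs.min() < 1 or obs.max() > self.n_categories):
            raise ValueError(f"observed responses must be integers in 1..{self.n_categories}")
        if self.group is not None and len(self.group) != n:
            raise ValueError("group labels must match respondent count")
        if self.external_scores is not None and len(self.external_scores) != n:
            raise ValueError("external scores must match respondent count")

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def complete_cases(self) -> np.ndarray:
        return ~np.any(np.isnan(self.values), axis=1)

    def select_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return replace(self, values=self.values[:, idx], item_ids=tuple(item_ids))

    def select_respondents(self, mask: np.ndarray) -> "ResponseMatrix":
        return replace(
            self,
            values=self.values[mask],
            respondent_ids=tuple(np.asarray(self.respondent_ids)[mask]),
            group=None if self.group is None else np.asarray(self.group)[mask],
            external_scores=None if self.external_scores is None else self.external_scores.iloc[mask].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.respondent_ids), columns=list(self.item_ids))


@dataclass
class StageRecord:
    stage: str
    n_items_in: int
    n_items_out: int
    excluded: dict[str, float]  # item_id -> triggering statistic
    detail: dict = field(default_factory=dict)


@dataclass
class ScreeningReport:
    """Funnel log: per-stage exclusions plus scale-level diagnostics."""

    stages: list[StageRecord] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, excluded: dict[str, float], **detail) -> None:
        self.stages.append(StageRecord(stage, n_in, n_out, dict(excluded), dict(detail)))

    @property
    def excluded_items(self) -> dict[str, str]:
        """item_id -> stage at which it was excluded."""
        out: dict[str, str] = {}
        for rec in self.stages:
            for item in rec.excluded:
                out.setdefault(item, rec.stage)
        return out

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": r.stage,
                    "n_items_in": r.n_items_in,
                    "n_items_out": r.n_items_out,
                    "excluded": r.excluded,
                    "detail": _jsonable(r.detail),
                }
                for r in self.stages
            ]
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# individual screens

def drop_complete_case(data: ResponseMatrix) -> ResponseMatrix:
    """Keep only respondents with no missing answers to any item."""
    mask = data.complete_cases()
    if not mask.any():
        raise ScreeningError("no complete-case respondents remain")
    return data.select_respondents(mask)


def drop_unused_categories(data: ResponseMatrix) -> tuple[ResponseMatrix, dict[str, float]]:
    """Exclude items with at least one response category never observed.

    Such items cannot be calibrated: the boundary parameter of an empty
    category has no data.
    """
    excluded: dict[str, float] = {}
    keep: list[str] = []
    for j, item in enumerate(data.item_ids):
        col = data.values[:, j]
        col = col[~np.isnan(col)]
        used = np.unique(col).size
        if used < data.n_categories:
            excluded[item] = float(used)
        else:
            keep.append(item)
    if not keep:
        raise ScreeningError("all items have unused categories")
    return data.select_items(keep), excluded


def item_remainder_correlations(data: ResponseMatrix, threshold: float = 0.3) -> tuple[ResponseMatrix, dict[str, float], np.ndarray]:
    """Pearson correlation of each item with the sum of the other items.

    Items with r strictly below ``threshold`` are excluded in a single
    pass computed on the entering item set.
    """
    if data.n_items < 3:
        raise ScreeningError("item-remainder screen needs >= 3 items")
    X = data.values
    if np.isnan(X).any():
        raise ValueError("item-remainder screen requires complete data")
    total = X.sum(axis=1)
    rs = np.empty(data.n_items)
    excluded: dict[str, float] = {}
    keep: list[str] = []
    for j, item in enumerate(data.item_ids):
        remainder = total - X[:, j]
        sx, sr = X[:, j].std(), remainder.std()
        if sx == 0 or sr == 0:
            warnings.warn(f"item {item}: zero variance, item-remainder correlation undefined")
            rs[j] = np.nan
            excluded[item] = np.nan
            continue
        r = float(np.corrcoef(X[:, j], remainder)[0, 1])
        rs[j] = r
        if r < threshold:
            excluded[item] = r
        else:
            keep.append(item)
    if len(keep) == 0:
        raise ScreeningError("all items failed the item-remainder screen")
    return data.select_items(keep), excluded, rs


def _first_component(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and first-eigenvector loadings of a correlation matrix."""
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    v1 = vecs[:, order[0]]
    # orient so the dominant direction is positive
    if v1.sum() < 0:
        v1 = -v1
    return vals, v1 * np.sqrt(max(vals[0], 0.0))


def unidimensionality_check(
    data: ResponseMatrix,
    min_first_proportion: float = 0.20,
    min_ratio: float = 4.0,
) -> tuple[ResponseMatrix, dict[str, float], dict]:
    """Principal-component screen for a single dominant dimension.

    Passes when the first component explains >= ``min_first_proportion``
    of total variance and the first/second eigenvalue ratio is
    >= ``min_ratio``; otherwise removes the item with the smallest
    absolute first-component loading and retries.
    """
    if data.n_items < 3:
        raise ScreeningError("unidimensionality screen needs >= 3 items")
    current = data
    excluded: dict[str, float] = {}
    while True:
        R = np.corrcoef(current.values, rowvar=False)
        vals, loadings = _first_component(R)
        prop1 = vals[0] / vals.sum()
        ratio = vals[0] / max(vals[1], 1e-12)
        if prop1 >= min_first_proportion and ratio >= min_ratio:
            detail = {"first_proportion": float(prop1), "second_proportion": float(vals[1] / vals.sum()), "ratio": float(ratio)}
            return current, excluded, detail
        if current.n_items <= 3:
            raise ScreeningError("unidimensionality criteria unreachable with >= 3 items")
        worst = int(np.argmin(np.abs(loadings)))
        item = current.item_ids[worst]
        excluded[item] = float(loadings[worst])
        keep = [i for i in current.item_ids if i != item]
        current = current.select_items(keep)


def one_factor_loadings(R: np.ndarray) -> np.ndarray:
    """Maximum-likelihood one-factor loadings of a correlation matrix.

    Minimizes the normal-theory discrepancy ``log|Sigma| + tr(R Sigma^-1)``
    with ``Sigma = ll' + diag(1 - l^2)``. Loadings are bounded in
    (-0.999, 0.999); a solution at the bound is a clamped Heywood case.
    """
    p = R.shape[0]
    vals, loadings0 = _first_component(R)
    start = np.clip(loadings0, -0.9, 0.9)

    def negfit(lam: np.ndarray) -> float:
        psi = 1.0 - lam**2
        sigma = np.outer(lam, lam)
        np.fill_diagonal(sigma, 1.0)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        inv = np.linalg.inv(sigma)
        return logdet + float(np.sum(inv * R))

    res = minimize(negfit, start, method="L-BFGS-B", bounds=[(-0.999, 0.999)] * p)
    lam = res.x
    if np.any(np.abs(lam) >= 0.999 - 1e-9):
        warnings.warn("Heywood case in one-factor fit; loading clamped to 0.999")
    return lam


def local_dependence_check(
    data: ResponseMatrix, residual_threshold: float = 0.2
) -> tuple[ResponseMatrix, dict[str, float], list[tuple[str, str, float]]]:
    """One-factor residual-correlation screen for local dependence.

    Residual = observed correlation minus the one-factor implied
    correlation. For each pair exceeding the threshold the member with the
    smaller absolute first-principal-component loading is removed, and the
    factor model is re-fitted before looking for further pairs.
    """
    if data.n_items < 3:
        raise ScreeningError("local-dependence screen needs >= 3 items")
    current = data
    excluded: dict[str, float] = {}
    flagged: list[tuple[str, str, float]] = []
    while True:
        R = np.corrcoef(current.values, rowvar=False)
        lam = one_factor_loadings(R)
        resid = R - np.outer(lam, lam)
        np.fill_diagonal(resid, 0.0)
        iu = np.triu_indices(current.n_items, k=1)
        vals = resid[iu]
        if not np.any(vals > residual_threshold):
            return current, excluded, flagged
        worst = int(np.argmax(vals))
        i, j = iu[0][worst], iu[1][worst]
        _, pc_loadings = _first_component(R)
        drop = i if abs(pc_loadings[i]) < abs(pc_loadings[j]) else j
        pair = (current.item_ids[i], current.item_ids[j], float(vals[worst]))
        flagged.append(pair)
        item = current.item_ids[drop]
        excluded[item] = float(vals[worst])
        if current.n_items <= 3:
            raise ScreeningError("local-dependence screen exhausted the scale")
        current = current.select_items([x for x in current.item_ids if x != item])


def comonotonic_cov(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum covariance attainable with the observed margins of x and y.

    This is the Frechet upper bound for equal-length samples: pair the
    sorted values of both margins.
    """
    return float(np.cov(np.sort(x), np.sort(y), ddof=1)[0, 1])


def scalability_coefficients(data: ResponseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Loevinger H for pairs and items.

    ``H_ij = cov(X_i, X_j) / cov_max(X_i, X_j)``;
    ``H_i = sum_j cov(X_i, X_j) / sum_j cov_max(X_i, X_j)``.
    """
    X = data.values
    p = data.n_items
    cov = np.cov(X, rowvar=False, ddof=1)
    covmax = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            covmax[i, j] = covmax[j, i] = comonotonic_cov(X[:, i], X[:, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        H_pair = np.where(covmax != 0, cov / np.where(covmax == 0, 1.0, covmax), np.nan)
    np.fill_diagonal(H_pair, np.nan)
    off = ~np.eye(p, dtype=bool)
    num = np.where(off, cov, 0.0).sum(axis=1)
    den = covmax.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        H_item = np.where(den != 0, num / np.where(den == 0, 1.0, den), np.nan)
    return H_pair, H_item


def monotonicity_check(data: ResponseMatrix, threshold: float = 0.3) -> tuple[ResponseMatrix, dict[str, float], np.ndarray]:
    """Exclude items with Loevinger scalability H_i below the threshold (one pass)."""
    if data.n_items < 3:
        raise ScreeningError("monotonicity screen needs >= 3 items")
    _, H_item = scalability_coefficients(data)
    excluded: dict[str, float] = {}
    keep: list[str] = []
    for j, item in enumerate(data.item_ids):
        h = H_item[j]
        if np.isnan(h):
            warnings.warn(f"item {item}: scalability undefined (zero variance); excluded")
            excluded[item] = np.nan
        elif h < threshold:
            excluded[item] = float(h)
        else:
            keep.append(item)
    if not keep:
        raise ScreeningError("all items failed the monotonicity screen")
    return data.select_items(keep), excluded, H_item


# ---------------------------------------------------------------------------

def run_screening(
    data: ResponseMatrix,
    item_remainder_threshold: float = 0.3,
    pca_first_proportion: float = 0.20,
    pca_ratio: float = 4.0,
    residual_threshold: float = 0.2,
    scalability_threshold: float = 0.3,
) -> tuple[ResponseMatrix, ScreeningReport]:
    """Apply the full pre-calibration battery in its fixed order.

    complete-case -> unused categories -> item-remainder ->
    unidimensionality -> local dependence -> monotonicity.
    """
    report = ScreeningReport()

    n0 = data.n_respondents
    data = drop_complete_case(data)
    report.record("complete_case", data.n_items, data.n_items, {}, n_respondents_in=n0, n_respondents_out=data.n_respondents)

    n_in = data.n_items
    data, excl = drop_unused_categories(data)
    report.record("unused_category", n_in, data.n_items, excl)

    n_in = data.n_items
    data, excl, rs = item_remainder_correlations(data, item_remainder_threshold)
    report.record("item_remainder", n_in, data.n_items, excl)

    n_in = data.n_items
    data, excl, detail = unidimensionality_check(data, pca_first_proportion, pca_ratio)
    report.record("unidimensionality", n_in, data.n_items, excl, **detail)

    n_in = data.n_items
    data, excl, pairs = local_dependence_check(data, residual_threshold)
    report.record("local_dependence", n_in, data.n_items, excl, flagged_pairs=pairs)

    n_in = data.n_items
    data, excl, H = monotonicity_check(data, scalability_threshold)
    report.record("monotonicity", n_in, data.n_items, excl)

    return data, report
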