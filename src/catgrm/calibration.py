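"""GRM calibration and model-based item screens.

Marginal maximum likelihood estimation by Bock-Aitkin EM over a fixed
standard-normal quadrature, maximum a posteriori (Bayesian mode) trait
scoring, the never-modal-category screen, the summed-score S-X2 item-fit
statistic (rest-score conditioning, Lord-Wingersky recursion), a
multigroup likelihood-ratio DIF screen, and Cronbach's alpha.

The EM M-step maximizes each item's expected complete-data log-likelihood
with L-BFGS on an unconstrained parameterization (log slope, first
threshold, log threshold gaps), which enforces ``a > 0`` and strictly
increasing thresholds by construction. Warm starts from the previous
cycle make this a generalized EM with guaranteed ascent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from .grm import (
    PROB_FLOOR,
    ItemBank,
    ItemParameters,
    Theta,
    bank_category_probs,
    test_information,
)
from .screening import ResponseMatrix

# fixed latent quadrature: 61 equally spaced nodes on [-6, 6]
QUAD_POINTS = 61
QUAD_RANGE = (-6.0, 6.0)


def latent_grid(n_points: int = QUAD_POINTS) -> np.ndarray:
    return np.linspace(*QUAD_RANGE, n_points)


def normal_weights(grid: np.ndarray, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    w = norm.pdf(grid, loc=mean, scale=sd)
    return w / w.sum()


@dataclass
class CalibrationResult:
    """Output of a GRM calibration run plus any model-based screens."""

    bank: ItemBank
    theta: list[Theta]
    log_likelihood: float
    n_em_iterations: int
    converged: bool
    ll_history: np.ndarray
    item_fit: pd.DataFrame | None = None
    dif: pd.DataFrame | None = None
    alpha: float | None = None

    @property
    def theta_values(self) -> np.ndarray:
        return np.array([t.value for t in self.theta])


# ---------------------------------------------------------------------------
# parameterization helpers: params row = (a, b_1..b_{K-1})

def _pack(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.diff(b)
    return np.concatenate(([np.log(a), b[0]], np.log(np.maximum(gaps, 1e-8))))


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(x[0]))
    b = x[1] + np.concatenate(([0.0], np.cumsum(np.exp(x[2:]))))
    return a, b


def _item_objective(x: np.ndarray, r: np.ndarray, grid: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative expected log-likelihood for one item and its gradient.

    ``r`` has shape (Q, K): expected category counts at each quadrature node.
    """
    a, b = _unpack(x)
    K = r.shape[1]
    z = a * (grid[:, None] - b[None, :])                      # Q x (K-1)
    c = 1.0 / (1.0 + np.exp(-z))
    full = np.concatenate([np.ones((len(grid), 1)), c, np.zeros((len(grid), 1))], axis=1)
    P = np.maximum(full[:, :-1] - full[:, 1:], PROB_FLOOR)    # Q x K
    obj = -float(np.sum(r * np.log(P)))

    w = r / P                                                 # Q x K
    dgdc = w[:, 1:] - w[:, :-1]                               # Q x (K-1): dg/dc_k
    s = c * (1.0 - c)
    dg_da = np.sum(dgdc * s * (grid[:, None] - b[None, :]))
    dg_db = np.sum(dgdc * (-a) * s, axis=0)                   # (K-1,)
    grad = np.empty_like(x)
    grad[0] = -(a * dg_da)                                    # d/d log a
    grad[1] = -np.sum(dg_db)                                  # d/d b_1
    gaps = np.exp(x[2:])
    # b_m depends on gap_j for j <= m (j indexes gaps 2..K-1)
    csum = np.cumsum(dg_db[::-1])[::-1]                       # sum_{m>=j} dg_db[m]
    grad[2:] = -(gaps * csum[1:])
    return obj, grad


def _start_params(X: np.ndarray, K: int) -> np.ndarray:
    """Deterministic starts: a = 1, thresholds at normal quantiles of the margins."""
    n, p = X.shape
    params = np.empty((p, K))
    for i in range(p):
        cum = np.cumsum(np.bincount(X[:, i], minlength=K)) / n
        q = norm.ppf(np.clip(cum[:-1], 0.01, 0.99))
        # enforce a minimal gap so the log-gap parameterization is valid
        for k in range(1, K - 1):
            q[k] = max(q[k], q[k - 1] + 0.05)
        params[i, 0] = 1.0
        params[i, 1:] = q
    return params


def _estep(X: np.ndarray, params: np.ndarray, grid: np.ndarray, logw: np.ndarray) -> tuple[float, np.ndarray]:
    """Posterior weights over the grid for each respondent and the marginal ll."""
    a = params[:, 0]
    b = params[:, 1:]
    P = bank_category_probs(a, b, grid)                       # p x Q x K
    logP = np.log(P)
    n, p = X.shape
    logL = np.zeros((n, len(grid)))
    for i in range(p):
        logL += logP[i][:, X[:, i]].T
    joint = logL + logw[None, :]
    lse = logsumexp(joint, axis=1)
    post = np.exp(joint - lse[:, None])
    return float(lse.sum()), post


def _expected_counts(X: np.ndarray, post: np.ndarray, K: int) -> np.ndarray:
    """r[i, q, k]: expected number of category-k responses to item i at node q."""
    n, p = X.shape
    r = np.zeros((p, post.shape[1], K))
    for i in range(p):
        for k in range(K):
            mask = X[:, i] == k
            if mask.any():
                r[i, :, k] = post[mask].sum(axis=0)
    return r


#: box constraints keep the slope and thresholds in a numerically sane range
#: (log a, b_1, log gaps); near-duplicate response columns would otherwise
#: drive the slope toward infinity
_MSTEP_BOUNDS_HEAD = [(np.log(0.05), np.log(25.0)), (-8.0, 8.0)]
_GAP_BOUND = (np.log(1e-4), np.log(12.0))


def _mstep_item(r_i: np.ndarray, grid: np.ndarray, start: np.ndarray, maxiter: int = 25) -> np.ndarray:
    x0 = _pack(start[0], start[1:])
    x0[0] = np.clip(x0[0], *_MSTEP_BOUNDS_HEAD[0])
    x0[1] = np.clip(x0[1], *_MSTEP_BOUNDS_HEAD[1])
    x0[2:] = np.clip(x0[2:], *_GAP_BOUND)
    bounds = _MSTEP_BOUNDS_HEAD + [_GAP_BOUND] * (len(x0) - 2)
    res = minimize(_item_objective, x0, args=(r_i, grid), jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": maxiter})
    a, b = _unpack(res.x)
    return np.concatenate(([a], b))


def fit_grm(
    data: ResponseMatrix,
    tol: float = 1e-4,
    max_iter: int = 500,
    n_quadrature: int = QUAD_POINTS,
) -> CalibrationResult:
    """Calibrate a GRM by Bock-Aitkin EM with a standard-normal latent prior.

    Returns estimated item parameters and MAP trait scores for every
    respondent. Convergence is declared when the largest absolute
    parameter change falls below ``tol``.
    """
    X = data.values
    if np.isnan(X).any():
        raise ValueError("calibration requires complete data")
    X = X.astype(int) - 1
    K = data.n_categories
    for i, item in enumerate(data.item_ids):
        if np.unique(X[:, i]).size < K:
            raise ValueError(f"item {item} does not use all {K} categories")

    grid = latent_grid(n_quadrature)
    logw = np.log(normal_weights(grid))
    params = _start_params(X, K)
    ll_hist = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, post = _estep(X, params, grid, logw)
        ll_hist.append(ll)
        r = _expected_counts(X, post, K)
        new_params = np.stack([_mstep_item(r[i], grid, params[i]) for i in range(X.shape[1])])
        delta = np.max(np.abs(new_params - params))
        params = new_params
        if delta < tol:
            converged = True
            break
    ll, post = _estep(X, params, grid, logw)
    ll_hist.append(ll)

    items = []
    for i, item_id in enumerate(data.item_ids):
        a = params[i, 0]
        if a > 8:
            warnings.warn(f"item {item_id}: estimated discrimination {a:.2f} > 8 (quasi-Guttman)")
        items.append(ItemParameters(item_id, a, params[i, 1:]))
    bank = ItemBank(tuple(items))
    theta = [score_map(bank.items, resp) for resp in (X + 1)]
    return CalibrationResult(bank, theta, ll, it, converged, np.array(ll_hist))


# ---------------------------------------------------------------------------
# MAP (Bayesian mode) scoring

def score_map(
    bank_subset,
    responses,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
    bounds: tuple[float, float] = (-6.0, 6.0),
) -> Theta:
    """Posterior-mode trait estimate with posterior-curvature standard error.

    ``responses`` are categories 1..K aligned with ``bank_subset``. With no
    responses the prior mode and prior SD are returned.
    """
    items = list(bank_subset)
    responses = [int(x) for x in responses]
    if len(items) != len(responses):
        raise ValueError("responses must align with items")
    if not items:
        return Theta(prior_mean, prior_sd)
    a = np.array([it.discrimination for it in items])
    b = np.stack([it.thresholds for it in items])
    x = np.asarray(responses) - 1

    def neg_log_post(theta: float) -> float:
        P = bank_category_probs(a, b, np.array([theta]))[:, 0, :]
        ll = np.log(P[np.arange(len(items)), x]).sum()
        return -(ll - 0.5 * ((theta - prior_mean) / prior_sd) ** 2)

    res = minimize_scalar(neg_log_post, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    mode = float(res.x)
    info = test_information(items, mode) + 1.0 / prior_sd**2
    return Theta(mode, 1.0 / np.sqrt(info))


def score_map_matrix(bank: ItemBank, data: ResponseMatrix, **kwargs) -> list[Theta]:
    """MAP scores for every (complete) respondent of a response matrix."""
    order = [data.item_ids.index(i) for i in bank.item_ids]
    X = data.values[:, order]
    if np.isnan(X).any():
        raise ValueError("scoring requires complete data")
    return [score_map(bank.items, row.astype(int)) for row in X]


# ---------------------------------------------------------------------------
# never-modal-category screen

def never_modal_category_screen(
    bank: ItemBank, theta_grid: np.ndarray | None = None
) -> dict[str, list[int]]:
    """Items with a category that is never the modal response at any theta.

    Returns ``{item_id: [non-modal categories (1..K)]}`` for excluded items.
    Ties at the maximum count for every tied category.
    """
    if theta_grid is None:
        theta_grid = np.arange(-4.0, 4.0 + 1e-9, 0.01)
    flagged: dict[str, list[int]] = {}
    P = bank_category_probs(bank.a, bank.b, theta_grid)       # p x Q x K
    modal = np.isclose(P, P.max(axis=2, keepdims=True), rtol=0.0, atol=1e-12)
    ever_modal = modal.any(axis=1)                            # p x K
    for i, item_id in enumerate(bank.item_ids):
        missing = np.where(~ever_modal[i])[0]
        if missing.size:
            flagged[item_id] = [int(k) + 1 for k in missing]
    return flagged


# ---------------------------------------------------------------------------
# S-X2 item fit

def summed_score_distribution(P: np.ndarray) -> np.ndarray:
    """Lord-Wingersky recursion for the summed-score likelihood.

    ``P`` has shape (p, Q, K): category probabilities per item and node.
    Returns (Q, p*(K-1)+1): probability of each summed score (0-based
    item scores) at each node.
    """
    p, Q, K = P.shape
    S = np.ones((Q, 1))
    for i in range(p):
        L = S.shape[1]
        new = np.zeros((Q, L + K - 1))
        for k in range(K):
            new[:, k : k + L] += P[i, :, k][:, None] * S
        S = new
    return S


def _collapse_table(O: np.ndarray, E: np.ndarray, min_expected: float = 1.0):
    """Collapse a rest-score x category table so every expected cell >= min_expected.

    Rows (adjacent rest scores) are merged first until each row's expected
    total can support K cells; then adjacent categories are merged within
    each row. Returns lists of observed and expected cell arrays per row.
    """
    K = O.shape[1]
    rows_O = [O[i].astype(float) for i in range(O.shape[0])]
    rows_E = [E[i] for i in range(E.shape[0])]
    # merge upward any row whose expected total is below K * min_expected
    merged_O, merged_E = [], []
    for o, e in zip(rows_O, rows_E):
        if merged_O and merged_E[-1].sum() < K * min_expected:
            merged_O[-1] = merged_O[-1] + o
            merged_E[-1] = merged_E[-1] + e
        else:
            merged_O.append(o)
            merged_E.append(e)
    if len(merged_O) > 1 and merged_E[-1].sum() < K * min_expected:
        merged_O[-2] += merged_O[-1]
        merged_E[-2] += merged_E[-1]
        merged_O.pop()
        merged_E.pop()
    # collapse adjacent categories within each row
    out_O, out_E = [], []
    for o, e in zip(merged_O, merged_E):
        co, ce = list(o), list(e)
        idx = 0
        while idx < len(ce) and len(ce) > 1:
            if ce[idx] < min_expected:
                j = idx + 1 if idx + 1 < len(ce) else idx - 1
                lo, hi = min(idx, j), max(idx, j)
                co[lo] += co[hi]
                ce[lo] += ce[hi]
                del co[hi], ce[hi]
                idx = 0
            else:
                idx += 1
        out_O.append(np.array(co))
        out_E.append(np.array(ce))
    return out_O, out_E


def s_x2_item_fit(
    bank: ItemBank,
    data: ResponseMatrix,
    alpha: float = 0.01,
    n_quadrature: int = QUAD_POINTS,
) -> pd.DataFrame:
    """Summed-score chi-square fit statistic per item (rest-score version).

    Observed category frequencies conditional on the rest score are
    compared with model-expected frequencies from the Lord-Wingersky
    summed-score distribution over the latent quadrature. Returns a frame
    with columns ``statistic, df, p, excluded``.
    """
    order = [data.item_ids.index(i) for i in bank.item_ids]
    X = data.values[:, order].astype(int) - 1
    n, p = X.shape
    K = bank.n_categories
    grid = latent_grid(n_quadrature)
    w = normal_weights(grid)
    P = bank_category_probs(bank.a, bank.b, grid)
    total = X.sum(axis=1)

    records = []
    for i, item_id in enumerate(bank.item_ids):
        others = [j for j in range(p) if j != i]
        S_rest = summed_score_distribution(P[others])         # Q x L
        L = S_rest.shape[1]
        # conditional category distribution given the rest score
        num = np.einsum("q,qk,ql->lk", w, P[i], S_rest)
        den = w @ S_rest
        rest = total - X[:, i]
        scores = np.flatnonzero(np.bincount(rest, minlength=L))
        O = np.zeros((scores.size, K))
        E = np.zeros((scores.size, K))
        for si, s in enumerate(scores):
            mask = rest == s
            O[si] = np.bincount(X[mask, i], minlength=K)
            E[si] = mask.sum() * num[s] / max(den[s], PROB_FLOOR)
        rows_O, rows_E = _collapse_table(O, E)
        stat = 0.0
        cells = 0
        for o, e in zip(rows_O, rows_E):
            stat += float(np.sum((o - e) ** 2 / np.maximum(e, PROB_FLOOR)))
            cells += len(o) - 1                               # row totals are fixed
        df = cells - K                                        # K free item parameters
        if df <= 0:
            warnings.warn(f"item {item_id}: S-X2 not testable after collapsing (df <= 0)")
            records.append((item_id, stat, df, np.nan, False))
            continue
        pval = float(chi2.sf(stat, df))
        records.append((item_id, stat, df, pval, pval < alpha))
    return pd.DataFrame(records, columns=["item_id", "statistic", "df", "p", "excluded"]).set_index("item_id")


# ---------------------------------------------------------------------------
# multigroup likelihood-ratio DIF

def _fit_multigroup(
    X: np.ndarray,
    focal: np.ndarray,
    K: int,
    free_item: int | None = None,
    start_params: np.ndarray | None = None,
    start_free: np.ndarray | None = None,
    start_moments: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-3,
    max_iter: int = 200,
    n_quadrature: int = QUAD_POINTS,
):
    """EM for a two-group GRM with shared item parameters.

    The reference group's latent distribution is fixed at N(0, 1); the
    focal group's mean and variance are free. If ``free_item`` is given,
    that item gets separate parameters in the focal group.
    Returns (log-likelihood, params, focal_params, (mu, sigma)).
    """
    n, p = X.shape
    grid = latent_grid(n_quadrature)
    params = _start_params(X, K) if start_params is None else start_params.copy()
    free_params = None
    if free_item is not None:
        free_params = params[free_item].copy() if start_free is None else start_free.copy()
    mu, sigma = start_moments
    ref = ~focal
    n_f = int(focal.sum())

    ll = -np.inf
    for _ in range(max_iter):
        logw_ref = np.log(normal_weights(grid))
        logw_foc = np.log(normal_weights(grid, mu, sigma))
        a = params[:, 0]
        b = params[:, 1:]
        P = bank_category_probs(a, b, grid)
        logP = np.log(P)
        logL = np.zeros((n, len(grid)))
        for i in range(p):
            if free_item is not None and i == free_item:
                logP_foc = np.log(bank_category_probs(
                    np.array([free_params[0]]), free_params[None, 1:], grid)[0])
                logL[ref] += logP[i][:, X[ref, i]].T
                logL[focal] += logP_foc[:, X[focal, i]].T
            else:
                logL += logP[i][:, X[:, i]].T
        joint = logL.copy()
        joint[ref] += logw_ref[None, :]
        joint[focal] += logw_foc[None, :]
        lse = logsumexp(joint, axis=1)
        new_ll = float(lse.sum())
        post = np.exp(joint - lse[:, None])

        # M-step: shared counts pool both groups; the free item splits
        new_params = params.copy()
        for i in range(p):
            if free_item is not None and i == free_item:
                r_ref = _expected_counts(X[ref][:, [i]], post[ref], K)[0]
                r_foc = _expected_counts(X[focal][:, [i]], post[focal], K)[0]
                new_params[i] = _mstep_item(r_ref, grid, params[i])
                free_params = _mstep_item(r_foc, grid, free_params)
            else:
                r_i = _expected_counts(X[:, [i]], post, K)[0]
                new_params[i] = _mstep_item(r_i, grid, params[i])
        # focal latent moments from posterior expectations
        post_f = post[focal]
        new_mu = float((post_f @ grid).sum() / n_f)
        new_sigma = float(np.sqrt((post_f @ grid**2).sum() / n_f - new_mu**2))
        new_sigma = max(new_sigma, 0.1)

        delta = max(
            np.max(np.abs(new_params - params)),
            abs(new_mu - mu),
            abs(new_sigma - sigma),
        )
        params = new_params
        mu, sigma = new_mu, new_sigma
        ll = new_ll
        if delta < tol:
            break
    return ll, params, free_params, (mu, sigma)


def dif_screen(
    data: ResponseMatrix,
    group: np.ndarray | None = None,
    alpha: float = 0.01,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Per-item likelihood-ratio DIF test between two groups.

    The baseline constrains every item equal across groups while freeing
    the focal group's latent mean and variance; each item's test frees
    that item's K parameters in the focal group (all other items anchor).
    Returns a frame with ``statistic, df, p, excluded``.
    """
    if group is None:
        group = data.group
    if group is None:
        raise ValueError("DIF screen requires a group label per respondent")
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("DIF screen requires exactly two groups")
    focal = group == levels[1]
    X = data.values.astype(int) - 1
    K = data.n_categories

    ll0, params0, _, moments0 = _fit_multigroup(X, focal, K, tol=tol, max_iter=max_iter)
    records = []
    for i, item_id in enumerate(data.item_ids):
        cats_ref = np.unique(X[~focal, i])
        cats_foc = np.unique(X[focal, i])
        if cats_ref.size < K or cats_foc.size < K:
            warnings.warn(f"item {item_id}: a group has an unused category; DIF test skipped")
            records.append((item_id, np.nan, K, np.nan, False))
            continue
        ll1, _, _, _ = _fit_multigroup(
            X, focal, K, free_item=i, start_params=params0,
            start_moments=moments0, tol=tol, max_iter=max_iter,
        )
        lr = max(2.0 * (ll1 - ll0), 0.0)
        pval = float(chi2.sf(lr, K))
        records.append((item_id, lr, K, pval, pval < alpha))
    return pd.DataFrame(records, columns=["item_id", "statistic", "df", "p", "excluded"]).set_index("item_id")


# ---------------------------------------------------------------------------

def cronbach_alpha(data: ResponseMatrix | np.ndarray) -> float:
    """Internal-consistency coefficient alpha of the retained items.

    Accepts a response matrix or a plain respondents x items array.
    """
    X = data if isinstance(data, np.ndarray) else data.values
    if np.isnan(X).any():
        raise ValueError("alpha requires complete data")
    p = X.shape[1]
    if p < 2:
        raise ValueError("alpha requires at least two items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(p / (p - 1) * (1.0 - item_vars / total_var))
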