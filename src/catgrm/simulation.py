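"""CAT simulation and validity statistics.

The accuracy experiment: for each respondent with a known full-bank trait
score (theta_true), run an adaptive test with responses sampled from the
calibrated model at theta_true, and summarize agreement between the
adaptive estimates (theta_est) and theta_true by the Pearson correlation
with a Fisher-z 95% interval, together with the mean number of items
administered. Concurrent validity correlates theta_est with external
criterion scores; discriminant validity compares groups with Welch
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cat import CATConfig, run_session
from .grm import ItemBank


@dataclass
class SimulationResult:
    per_respondent: pd.DataFrame  # theta_true, theta_est, n_items, stop_reason
    pcc: float
    pcc_ci: tuple[float, float]
    mean_items: float

    def summary(self) -> dict:
        return {
            "n_respondents": int(len(self.per_respondent)),
            "pcc": self.pcc,
            "pcc_ci_low": self.pcc_ci[0],
            "pcc_ci_high": self.pcc_ci[1],
            "mean_items_administered": self.mean_items,
        }


@dataclass
class ValidityResult:
    concurrent: pd.DataFrame | None = None  # r, ci_low, ci_high per external column
    discriminant: pd.DataFrame | None = None  # group stats + Welch t per comparison


def pearson_ci(x: np.ndarray, y: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Pearson r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(len(x) - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def simulate_cat(
    bank: ItemBank,
    theta_true: np.ndarray,
    config: CATConfig | None = None,
    seed: int = 0,
    replay_responses: np.ndarray | None = None,
) -> SimulationResult:
    """Run one adaptive test per respondent and pool the accuracy metrics.

    By default responses are freshly sampled from the GRM at each
    respondent's theta_true. ``replay_responses`` (n x n_items, categories
    1..K, column order matching the bank) instead replays fixed response
    vectors, which makes a full-bank run reproduce the full-bank scores
    exactly.
    """
    config = config or CATConfig()
    theta_true = np.asarray(theta_true, float)
    rows = []
    for j, t in enumerate(theta_true):
        if replay_responses is not None:
            fixed = replay_responses[j]

            def responder(item_id: str, _fixed=fixed) -> int:
                return int(_fixed[bank.index_of(item_id)])

            session = run_session(bank, responder=responder, config=config)
        else:
            # key the respondent's stream to their trait value, not their
            # position, so pooled statistics are order-invariant
            key = int(np.abs(np.float64(t).view(np.int64)))
            session = run_session(
                bank, theta_true=t, rng=np.random.default_rng([seed, key]),
                config=config,
            )
        rows.append((t, session.theta.value, session.theta.se,
                     session.n_administered, session.stop_reason))
    frame = pd.DataFrame(rows, columns=["theta_true", "theta_est", "sem", "n_items", "stop_reason"])
    r, lo, hi = pearson_ci(frame["theta_true"], frame["theta_est"])
    return SimulationResult(frame, r, (lo, hi), float(frame["n_items"].mean()))


def concurrent_validity(
    theta_est: np.ndarray, external: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations (with 95% CI) between theta_est and each external column."""
    theta_est = np.asarray(theta_est, float)
    if len(external) != len(theta_est):
        raise ValueError("external scores must match the respondents scored")
    records = []
    for col in external.columns:
        r, lo, hi = pearson_ci(theta_est, external[col].to_numpy())
        records.append((col, r, lo, hi))
    return pd.DataFrame(records, columns=["external", "r", "ci_low", "ci_high"]).set_index("external")


def discriminant_validity(
    theta_est: np.ndarray,
    group: np.ndarray,
    comparisons: list[tuple[str, str]] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests (Welch by default) between configured group pairs."""
    theta_est = np.asarray(theta_est, float)
    group = np.asarray(group)
    if comparisons is None:
        levels = list(pd.unique(group))
        if len(levels) != 2:
            raise ValueError("specify comparisons when there are not exactly two groups")
        comparisons = [(levels[0], levels[1])]
    records = []
    for g1, g2 in comparisons:
        x1 = theta_est[group == g1]
        x2 = theta_est[group == g2]
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError(f"comparison {g1} vs {g2}: each group needs >= 2 respondents")
        res = stats.ttest_ind(x1, x2, equal_var=equal_var)
        records.append((g1, g2, x1.mean(), x1.std(ddof=1), x2.mean(), x2.std(ddof=1),
                        float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(
        records,
        columns=["group1", "group2", "mean1", "sd1", "mean2", "sd2", "t", "p"],
    )
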