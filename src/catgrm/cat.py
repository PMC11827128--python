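"""Adaptive testing engine.

Items are selected by maximum Fisher information at the current trait
estimate; the trait is re-estimated by posterior mode (MAP) after every
response; the session stops once the standard error of measurement drops
to the configured threshold (after a minimum number of items) or the
item budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .calibration import score_map
from .grm import ItemBank, Theta, bank_information, sample_response


@dataclass
class CATConfig:
    sem_threshold: float = 0.32
    min_items: int = 3
    max_items: int | None = None  # None: full bank
    theta_start: float = 0.0
    prior_mean: float = 0.0
    prior_sd: float = 1.0


@dataclass
class CATSession:
    """State of one adaptive test."""

    bank: ItemBank
    config: CATConfig = field(default_factory=CATConfig)
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    theta_trajectory: list[Theta] = field(default_factory=list)
    stopped: bool = False
    stop_reason: str | None = None

    @property
    def max_items(self) -> int:
        return self.config.max_items or len(self.bank)

    @property
    def theta(self) -> Theta:
        if self.theta_trajectory:
            return self.theta_trajectory[-1]
        return Theta(self.config.theta_start, None)

    @property
    def n_administered(self) -> int:
        return len(self.administered)

    def remaining_indices(self) -> list[int]:
        done = set(self.administered)
        return [i for i, item_id in enumerate(self.bank.item_ids) if item_id not in done]


def next_item(session: CATSession) -> str:
    """The unadministered item with maximum information at the current theta.

    Ties break toward earlier bank order.
    """
    if session.stopped:
        raise RuntimeError("session has stopped")
    remaining = session.remaining_indices()
    if not remaining:
        raise RuntimeError("all items administered")
    info = bank_information(session.bank.a, session.bank.b,
                            np.array([session.theta.value]))[:, 0]
    best = remaining[int(np.argmax(info[remaining]))]
    return session.bank.item_ids[best]


def administer(session: CATSession, item_id: str, response: int) -> CATSession:
    """Record a response, re-score, and evaluate the stopping rules."""
    if session.stopped:
        raise RuntimeError("session has stopped")
    if item_id in session.administered:
        raise ValueError(f"item {item_id} already administered")
    if not 1 <= int(response) <= session.bank.n_categories:
        raise ValueError(f"response {response} outside 1..{session.bank.n_categories}")
    session.administered.append(item_id)
    session.responses.append(int(response))
    subset = session.bank.subset(session.administered)
    est = score_map(subset.items, session.responses,
                    session.config.prior_mean, session.config.prior_sd)
    session.theta_trajectory.append(est)

    n = session.n_administered
    if n >= session.config.min_items and est.se is not None and est.se <= session.config.sem_threshold:
        session.stopped = True
        session.stop_reason = "sem_criterion"
    elif n >= session.max_items or n >= len(session.bank):
        session.stopped = True
        session.stop_reason = "max_items"
    return session


def run_session(
    bank: ItemBank,
    responder: Callable[[str], int] | None = None,
    theta_true: float | None = None,
    rng: np.random.Generator | None = None,
    config: CATConfig | None = None,
) -> CATSession:
    """Run a full adaptive test.

    Responses come either from ``responder(item_id)`` (live use) or are
    sampled from the GRM at ``theta_true`` with ``rng`` (simulation).
    """
    config = config or CATConfig()
    if responder is None:
        if theta_true is None or rng is None:
            raise ValueError("simulation mode needs theta_true and a seeded rng")

        def responder(item_id: str) -> int:
            item = bank[bank.index_of(item_id)]
            return sample_response(item, theta_true, rng)

    session = CATSession(bank, config)
    while not session.stopped:
        item_id = next_item(session)
        administer(session, item_id, responder(item_id))
    return session
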