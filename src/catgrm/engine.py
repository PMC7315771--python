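"""Adaptive test administration.

The administration loop mirrors the simulated adaptive screener: the
first item is drawn uniformly at random from the bank, the trait is
re-estimated after every response by expected a posteriori (EAP) over a
quadrature grid with a Normal(0, 1) prior, the next item is the
unadministered item with maximum Fisher information at the current
estimate, and the test stops once the information-based standard error
SE = 1/sqrt(I(theta_hat)) of the administered items drops below the
configured threshold, the item cap (default 20) is reached, or the bank
is exhausted.

The stop check uses the information-based SE; the EAP posterior SD is
recorded alongside for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .models import (
    ItemBank,
    ThetaGrid,
    default_grid,
    standard_error_from_information,
)
from .models import category_probabilities

__all__ = [
    "CATConfig",
    "CATState",
    "CATResult",
    "eap_estimate",
    "current_se",
    "select_next_item",
    "run_cat",
]


@dataclass(frozen=True)
class CATConfig:
    """Stopping rule and administration settings.

    ``se_threshold=None`` means no precision rule: the whole bank is
    administered. With a threshold set the default cap is 20 items.
    """

    se_threshold: float | None = 0.3
    max_items: int | None = None
    prior: ThetaGrid | None = None
    seed: int = 0
    first_item: str | None = None  # None -> random start

    def __post_init__(self) -> None:
        if self.se_threshold is not None and not self.se_threshold > 0:
            raise ValueError("se_threshold must be positive when set")
        if self.max_items is not None and self.max_items < 1:
            raise ValueError("max_items must be >= 1")

    def resolved_max_items(self, bank_size: int) -> int:
        if self.max_items is not None:
            return min(self.max_items, bank_size)
        return 20 if self.se_threshold is not None else bank_size

    @property
    def label(self) -> str:
        return "none" if self.se_threshold is None else f"SE<{self.se_threshold:g}"


@dataclass
class CATState:
    administered: list = field(default_factory=list)
    responses: list = field(default_factory=list)
    theta_hat: float = 0.0
    se: float = np.inf
    posterior_sd: float = np.inf
    finished: bool = False
    stop_reason: str | None = None


@dataclass
class CATResult:
    administered: list
    responses: list
    theta_hat: float
    se: float
    posterior_sd: float
    stop_reason: str
    trajectory: list  # (item_id, response, theta_hat, se) per step

    @property
    def n_items(self) -> int:
        return len(self.administered)


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def _posterior(loglik_grid: np.ndarray, grid: ThetaGrid) -> tuple[float, float]:
    a = loglik_grid + np.log(grid.weights)
    mx = a.max()
    if not np.isfinite(mx):
        raise FloatingPointError(
            "posterior mass vanished on the grid; use log-space likelihoods"
        )
    p = np.exp(a - mx)
    p /= p.sum()
    mean = float(p @ grid.points)
    var = float(p @ (grid.points - mean) ** 2)
    return mean, float(np.sqrt(var))


def eap_estimate(responses: Sequence, items, prior: ThetaGrid | None = None
                 ) -> tuple[float, float]:
    """Posterior mean and SD of theta given observed category codes.

    With no (observed) responses this returns the prior mean and SD.
    """
    if prior is None:
        prior = default_grid()
    ll = np.zeros(prior.points.size)
    for code, item in zip(responses, items):
        if code is None or (isinstance(code, float) and np.isnan(code)):
            continue
        k = int(code)
        if not 0 <= k < item.n_categories:
            raise ValueError(f"item {item.item_id!r}: code {k} out of range")
        P = category_probabilities(item, prior.points)
        ll += np.log(np.maximum(P[:, k], 1e-300))
    return _posterior(ll, prior)


def current_se(state: CATState, bank: ItemBank) -> float:
    """Information-based SE at the current estimate, from the
    administered items only."""
    if not state.administered:
        raise ValueError("no items administered yet")
    sub = bank.subset(state.administered)
    info = float(sub.information_matrix(state.theta_hat).sum())
    return standard_error_from_information(info)


def select_next_item(state: CATState, bank: ItemBank) -> str:
    """Unadministered item with maximum Fisher information at theta_hat;
    ties break to the lowest bank index."""
    taken = set(state.administered)
    info = bank.information_matrix(state.theta_hat)
    best, best_info = None, -np.inf
    for j, iid in enumerate(bank.ids):
        if iid in taken:
            continue
        if info[j] > best_info:
            best, best_info = iid, info[j]
    if best is None:
        raise ValueError("bank exhausted; no unadministered items remain")
    return best


# ---------------------------------------------------------------------------
# administration loop
# ---------------------------------------------------------------------------

class _BankTables:
    """Per-(bank, grid) precomputation shared across many administrations."""

    def __init__(self, bank: ItemBank, grid: ThetaGrid):
        self.bank = bank
        self.grid = grid
        Q = grid.points.size
        maxm = int(bank.n_categories.max())
        logP = np.full((len(bank), maxm, Q), -np.inf)
        for j, item in enumerate(bank):
            P = category_probabilities(item, grid.points)  # (Q, m)
            logP[j, : item.n_categories, :] = np.log(np.maximum(P.T, 1e-300))
        self.logP = logP


def _normalize_answer_source(answer_source, bank: ItemBank) -> Callable[[str], float]:
    if callable(answer_source):
        return answer_source
    if isinstance(answer_source, Mapping):
        return lambda iid: answer_source.get(iid, np.nan)
    vec = np.asarray(answer_source, dtype=float)
    if vec.shape != (len(bank),):
        raise ValueError("answer vector length does not match bank size")
    index = {iid: j for j, iid in enumerate(bank.ids)}
    return lambda iid: vec[index[iid]]


def run_cat(answer_source, bank: ItemBank, config: CATConfig,
            _tables: "_BankTables | None" = None) -> CATResult:
    """Run one adaptive administration against a respondent oracle.

    ``answer_source`` is a callable ``item_id -> category code``, a
    mapping, or a full response vector aligned with the bank (post-hoc
    mode). A missing answer (NaN) removes the item from further
    selection with a warning. Identical seeds and inputs give identical
    trajectories.
    """
    grid = config.prior if config.prior is not None else default_grid()
    tables = _tables if _tables is not None and _tables.grid is grid else _BankTables(bank, grid)
    answer = _normalize_answer_source(answer_source, bank)
    rng = np.random.default_rng(config.seed)
    max_items = config.resolved_max_items(len(bank))
    index = {iid: j for j, iid in enumerate(bank.ids)}

    state = CATState()
    ll = np.zeros(grid.points.size)
    unavailable: set[str] = set()
    trajectory: list[tuple] = []
    info_fn = bank.information_matrix
    info = None  # item informations at the current theta_hat

    if config.first_item is not None:
        next_id = config.first_item
        if next_id not in index:
            raise KeyError(f"first_item {next_id!r} not in bank")
    else:
        next_id = bank.ids[int(rng.integers(len(bank)))]

    while True:
        code = answer(next_id)
        if code is None or (isinstance(code, float) and np.isnan(code)):
            warnings.warn(f"no response available for item {next_id!r}; skipping",
                          RuntimeWarning, stacklevel=2)
            unavailable.add(next_id)
        else:
            j = index[next_id]
            k = int(code)
            if not 0 <= k < bank[j].n_categories:
                raise ValueError(f"item {next_id!r}: code {k} out of range")
            state.administered.append(next_id)
            state.responses.append(k)
            ll += tables.logP[j, k, :]
            state.theta_hat, state.posterior_sd = _posterior(ll, grid)
            info = info_fn(state.theta_hat)
            admin_idx = [index[i] for i in state.administered]
            state.se = standard_error_from_information(float(info[admin_idx].sum()))
            trajectory.append((next_id, k, state.theta_hat, state.se))
            # stop checks, evaluated only after a recorded response
            if config.se_threshold is not None and state.se < config.se_threshold:
                state.finished, state.stop_reason = True, "se_met"
                break
            if len(state.administered) >= max_items:
                state.finished = True
                state.stop_reason = ("bank_exhausted"
                                     if len(state.administered) == len(bank)
                                     else "max_items")
                break

        taken = set(state.administered) | unavailable
        if len(taken) >= len(bank):
            state.finished, state.stop_reason = True, "bank_exhausted"
            break
        if not state.administered:
            remaining = [i for i in bank.ids if i not in taken]
            next_id = remaining[int(rng.integers(len(remaining)))]
        else:
            masked = info.copy()
            for i in taken:
                masked[index[i]] = -np.inf
            next_id = bank.ids[int(np.argmax(masked))]

    return CATResult(administered=state.administered, responses=state.responses,
                     theta_hat=state.theta_hat, se=state.se,
                     posterior_sd=state.posterior_sd, stop_reason=state.stop_reason,
                     trajectory=trajectory)
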