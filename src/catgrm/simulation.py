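"""Synthetic respondents and the post-hoc CAT study.

Respondents are drawn with latent traits theta ~ Normal(0, 1) (the scale
the bank is calibrated on) and full-bank response vectors sampled from
each item's category distribution at the respondent's theta. The study
then replays adaptive administration against those complete vectors
(post-hoc design) under each stopping rule and compares the adaptive
trait estimates with full-bank EAP scores: mean/SD of items used, mean
final SE, marginal reliability 1 - mean(SE^2), and the Pearson
correlation of adaptive with full-bank estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import CATConfig, CATResult, _BankTables, run_cat
from .evaluation import marginal_reliability
from .models import ItemBank, ThetaGrid, category_probabilities, default_grid
from .models import standard_error_from_information

__all__ = [
    "Respondent",
    "StudySummary",
    "generate_respondents",
    "full_bank_scores",
    "run_rule",
    "run_study",
    "study_table",
    "default_rules",
]


@dataclass
class Respondent:
    """One simulated person: true trait and a complete response vector
    aligned with the bank; ``seed`` keys the person's first-item draw so
    study summaries do not depend on respondent ordering."""

    true_theta: float
    responses: np.ndarray
    seed: int = 0


@dataclass
class StudySummary:
    stopping_rule: str
    mean_items: float
    sd_items: float
    mean_se: float
    marginal_reliability: float
    correlation_with_full: float


def generate_respondents(n: int, bank: ItemBank, theta_dist=("normal", 0.0, 1.0),
                         seed: int = 0) -> list[Respondent]:
    """Draw ``n`` respondents and sample their full response vectors.

    ``theta_dist`` is ``("normal", mean, sd)`` or an explicit sequence of
    trait values of length ``n``. Responses are drawn by inverse CDF from
    each item's category probabilities, so the same seed reproduces the
    same matrix exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(theta_dist, tuple) and theta_dist and theta_dist[0] == "normal":
        thetas = rng.normal(theta_dist[1], theta_dist[2], size=n)
    else:
        thetas = np.asarray(theta_dist, dtype=float)
        if thetas.shape != (n,):
            raise ValueError("fixed theta list must have length n")
    X = np.empty((n, len(bank)), dtype=int)
    for j, item in enumerate(bank):
        P = category_probabilities(item, thetas)          # (n, m)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        X[:, j] = (u[:, None] > cum[:, :-1]).sum(axis=1)
    person_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [Respondent(float(thetas[i]), X[i].copy(), int(person_seeds[i]))
            for i in range(n)]


def full_bank_scores(respondents, bank: ItemBank,
                     grid: ThetaGrid | None = None) -> tuple[np.ndarray, np.ndarray]:
    """EAP estimate and information-based SE for every respondent when
    all items are administered."""
    if grid is None:
        grid = default_grid()
    tables = _BankTables(bank, grid)
    Q = grid.points.size
    logw = np.log(grid.weights)
    thetas = np.empty(len(respondents))
    ses = np.empty(len(respondents))
    for i, r in enumerate(respondents):
        ll = np.zeros(Q)
        for j, k in enumerate(r.responses):
            ll += tables.logP[j, int(k), :]
        a = ll + logw
        p = np.exp(a - a.max())
        p /= p.sum()
        thetas[i] = p @ grid.points
        info = float(bank.information_matrix(thetas[i]).sum())
        ses[i] = standard_error_from_information(info)
    return thetas, ses


def run_rule(respondents, bank: ItemBank, config: CATConfig,
             grid: ThetaGrid | None = None) -> list[CATResult]:
    """Adaptive administration of every respondent under one stopping rule.

    Each respondent's first item is drawn from a generator seeded by
    (rule seed, respondent seed), so results attach to respondent
    identity, not list position.
    """
    if grid is None:
        grid = config.prior if config.prior is not None else default_grid()
    tables = _BankTables(bank, grid)
    out = []
    for r in respondents:
        cfg = replace(config, prior=grid,
                      seed=np.random.SeedSequence([config.seed, r.seed]).generate_state(1)[0])
        out.append(run_cat(r.responses, bank, cfg, _tables=tables))
    return out


def default_rules(seed: int = 0, thresholds=(0.3, 0.4, 0.5), max_items: int = 20,
                  grid: ThetaGrid | None = None) -> list[CATConfig]:
    """The study's rule ladder: no stopping rule, then each SE threshold."""
    rules = [CATConfig(se_threshold=None, prior=grid, seed=seed)]
    rules += [CATConfig(se_threshold=t, max_items=max_items, prior=grid, seed=seed)
              for t in thresholds]
    return rules


def run_study(respondents, bank: ItemBank, rules=None,
              grid: ThetaGrid | None = None, seed: int = 0) -> list[StudySummary]:
    """Run the post-hoc CAT study and summarize each stopping rule."""
    if grid is None:
        grid = default_grid()
    if rules is None:
        rules = default_rules(seed=seed, grid=grid)
    full_theta, _ = full_bank_scores(respondents, bank, grid)
    summaries = []
    for cfg in rules:
        results = run_rule(respondents, bank, cfg, grid)
        n_items = np.array([res.n_items for res in results], dtype=float)
        ses = np.array([res.se for res in results])
        thetas = np.array([res.theta_hat for res in results])
        corr = float(np.corrcoef(thetas, full_theta)[0, 1])
        summaries.append(StudySummary(
            stopping_rule=cfg.label,
            mean_items=float(n_items.mean()),
            sd_items=float(n_items.std(ddof=1)) if n_items.size > 1 else 0.0,
            mean_se=float(ses.mean()),
            marginal_reliability=marginal_reliability(ses),
            correlation_with_full=corr,
        ))
    return summaries


def study_table(summaries) -> pd.DataFrame:
    """Summaries as a study-report table (one row per stopping rule)."""
    return pd.DataFrame(
        [{"stopping_rule": s.stopping_rule, "mean_items": s.mean_items,
          "sd_items": s.sd_items, "mean_se": s.mean_se,
          "marginal_reliability": s.marginal_reliability,
          "correlation_with_full": s.correlation_with_full} for s in summaries]
    )
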