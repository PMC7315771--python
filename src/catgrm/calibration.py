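"""Marginal-maximum-likelihood (EM) item calibration and model comparison.

The E-step computes each person's posterior over a fixed quadrature grid
(default: 81 equally spaced points on [-4, 4] with renormalized
Normal(0, 1) masses); the M-step maximizes the expected complete-data
log-likelihood item by item over an unconstrained reparameterization
(log slope; GRM thresholds as first threshold plus log increments, which
keeps them strictly ordered by construction). Missing responses are
ignored (missing-at-random likelihood contribution of 1).

Model fit across GRM / GPCM / NRM is compared with

    AIC = -2 ln L + 2 p,        BIC = -2 ln L + p ln N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .io import ResponseMatrix
from .models import ItemBank, ItemParameters, ThetaGrid, category_probabilities, default_grid

__all__ = [
    "CalibrationResult",
    "ModelComparison",
    "fit_mml_em",
    "information_criteria",
    "select_by_criteria",
    "compare_models",
]


@dataclass
class CalibrationResult:
    bank: ItemBank
    loglik: float
    n_params: int
    n_iter: int
    converged: bool
    model: str = "GRM"
    loglik_path: np.ndarray | None = None


@dataclass
class ModelComparison:
    aic: dict
    bic: dict
    selected: str
    results: dict


# -- parameter transforms ----------------------------------------------------
# x is the unconstrained optimizer vector; params the natural ItemParameters.

def _pack(item: ItemParameters) -> np.ndarray:
    if item.model == "GRM":
        inc = np.diff(item.b)
        return np.concatenate([[np.log(item.a), item.b[0]], np.log(np.maximum(inc, 1e-3))])
    if item.model == "GPCM":
        return np.concatenate([[np.log(item.a)], item.b])
    return np.concatenate([item.a[1:], item.b[1:]])  # NRM


def _unpack(x: np.ndarray, model: str, m: int, item_id: str) -> ItemParameters:
    if model == "GRM":
        a = np.exp(x[0])
        b = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(x[2:]))])
        return ItemParameters(item_id, "GRM", m, a, b)
    if model == "GPCM":
        return ItemParameters(item_id, "GPCM", m, np.exp(x[0]), x[1:])
    a = np.concatenate([[0.0], x[: m - 1]])
    c = np.concatenate([[0.0], x[m - 1:]])
    return ItemParameters(item_id, "NRM", m, a, c)


def _start_values(codes_j: np.ndarray, model: str, m: int, item_id: str) -> ItemParameters:
    """Moment-style starting values from marginal category proportions."""
    obs = codes_j[~np.isnan(codes_j)].astype(int)
    counts = np.bincount(obs, minlength=m).astype(float) + 0.5
    p_ge = counts[::-1].cumsum()[::-1] / counts.sum()  # P(X >= k)
    with np.errstate(divide="ignore"):
        b0 = -np.log(p_ge[1:] / (1.0 - p_ge[1:]))
    b0 = np.clip(b0, -3.0, 3.0)
    b0 = np.maximum.accumulate(b0 + 1e-3 * np.arange(m - 1))  # enforce order
    b0 += 1e-6 * np.arange(m - 1)
    if model == "GRM":
        return ItemParameters(item_id, "GRM", m, 1.0, b0)
    if model == "GPCM":
        return ItemParameters(item_id, "GPCM", m, 1.0, b0)
    a0 = np.concatenate([[0.0], 0.5 * np.arange(1, m)])
    c0 = np.concatenate([[0.0], np.log(counts[1:] / counts[0])])
    return ItemParameters(item_id, "NRM", m, a0, c0)


def _expected_negll(x, model, m, item_id, r, grid_points):
    item = _unpack(x, model, m, item_id)
    P = category_probabilities(item, grid_points)
    return -float(np.sum(r * np.log(np.maximum(P, 1e-300))))


def fit_mml_em(responses: ResponseMatrix | np.ndarray, model: str = "GRM",
               grid: ThetaGrid | None = None, tol: float = 1e-4,
               loglik_tol: float = 1e-7, max_iter: int = 500) -> CalibrationResult:
    """Fit one polytomous IRT model to a response matrix by MML-EM.

    The marginal log-likelihood is non-decreasing across EM cycles (up to
    optimizer slack); convergence is declared when the maximum absolute
    parameter change falls below ``tol`` or the relative log-likelihood
    change falls below ``loglik_tol``.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float),
                                   [str(j) for j in range(np.asarray(responses).shape[1])])
    if grid is None:
        grid = default_grid()
    codes = responses.codes
    n, J = codes.shape
    if n < 50:
        warnings.warn(f"only {n} persons; estimates may be unstable", RuntimeWarning,
                      stacklevel=2)
    m_j = []
    for j, iid in enumerate(responses.item_ids):
        obs = codes[~np.isnan(codes[:, j]), j].astype(int)
        if np.unique(obs).size < 2:
            raise ValueError(f"item {iid!r} has a single observed category")
        m_j.append(int(obs.max()) + 1)

    items = [_start_values(codes[:, j], model, m_j[j], responses.item_ids[j])
             for j in range(J)]
    Q = grid.points.size
    logw = np.log(grid.weights)
    obs_mask = ~np.isnan(codes)
    codes_int = np.where(obs_mask, codes, 0).astype(int)

    prev_ll = -np.inf
    prev_x = None
    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: person-by-grid posterior
        L = np.zeros((n, Q))
        for j, item in enumerate(items):
            logP = np.log(np.maximum(category_probabilities(item, grid.points), 1e-300))
            rows = obs_mask[:, j]
            L[rows] += logP[:, codes_int[rows, j]].T
        A = L + logw[None, :]
        ll_i = logsumexp(A, axis=1)
        ll = float(ll_i.sum())
        ll_path.append(ll)
        W = np.exp(A - ll_i[:, None])

        x_all = np.concatenate([_pack(item) for item in items])
        if prev_x is not None:
            dx = float(np.max(np.abs(x_all - prev_x)))
            dll = abs(ll - prev_ll) / max(abs(ll), 1.0)
            if dx < tol or dll < loglik_tol:
                converged = True
                break
        prev_ll, prev_x = ll, x_all

        # M-step: per-item expected complete-data likelihood
        new_items = []
        for j, item in enumerate(items):
            m = m_j[j]
            rows = obs_mask[:, j]
            r = np.zeros((Q, m))
            cj = codes_int[rows, j]
            Wj = W[rows]
            for k in range(m):
                sel = cj == k
                if sel.any():
                    r[:, k] = Wj[sel].sum(axis=0)
            x0 = _pack(item)
            res = minimize(_expected_negll, x0,
                           args=(model, m, item.item_id, r, grid.points),
                           method="L-BFGS-B", options={"maxiter": 50})
            new_items.append(_unpack(res.x, model, m, item.item_id))
        items = new_items

    bank = ItemBank(items)
    n_params = int(sum(item.n_free_params for item in items))
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} cycles", RuntimeWarning,
                      stacklevel=2)
    return CalibrationResult(bank=bank, loglik=ll_path[-1], n_params=n_params,
                             n_iter=it, converged=converged, model=model,
                             loglik_path=np.asarray(ll_path))


def information_criteria(result: CalibrationResult, n_persons: int) -> tuple[float, float]:
    """(AIC, BIC) from the marginal log-likelihood and parameter count."""
    aic = -2.0 * result.loglik + 2.0 * result.n_params
    bic = -2.0 * result.loglik + result.n_params * np.log(n_persons)
    return float(aic), float(bic)


def select_by_criteria(aic: dict, bic: dict) -> str:
    """Pick the model minimizing both criteria; on disagreement BIC
    decides (with a warning)."""
    best_aic = min(aic, key=aic.get)
    best_bic = min(bic, key=bic.get)
    if best_aic != best_bic:
        warnings.warn(
            f"AIC prefers {best_aic}, BIC prefers {best_bic}; selecting by BIC",
            RuntimeWarning, stacklevel=2,
        )
    return best_bic


def compare_models(responses: ResponseMatrix, grid: ThetaGrid | None = None,
                   models: tuple = ("GRM", "GPCM", "NRM"),
                   **fit_kwargs) -> ModelComparison:
    """Fit each candidate model on identical data/grid and compare AIC/BIC."""
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float),
                                   [str(j) for j in range(np.asarray(responses).shape[1])])
    aic, bic, results = {}, {}, {}
    for model in models:
        res = fit_mml_em(responses, model=model, grid=grid, **fit_kwargs)
        aic[model], bic[model] = information_criteria(res, responses.n_persons)
        results[model] = res
    return ModelComparison(aic=aic, bic=bic, selected=select_by_criteria(aic, bic),
                           results=results)
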