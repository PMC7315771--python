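"""Item-bank quality control.

The screening pipeline runs, in order: (1) a unidimensionality check —
principal-component analysis of the Pearson inter-item correlation
matrix, dropping items with first-factor loadings below 0.30 (at most
two passes) and requiring a first-to-second eigenvalue ratio >= 3 and a
first-factor variance share >= 20%; (2) GRM calibration; (3) the S-X^2
summed-score item-fit statistic (items with p < 0.05 are flagged);
(4) differential item functioning via nested proportional-odds logits
and the change in McFadden's pseudo-R^2; (5) a discrimination filter
removing items with slope a < 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .io import ResponseMatrix
from .models import ItemBank, ThetaGrid, category_probabilities, default_grid

__all__ = [
    "UnidimReport",
    "ItemFitResult",
    "DIFResult",
    "unidimensionality_check",
    "item_fit_sx2",
    "dif_analysis",
    "discrimination_filter",
    "qc_pipeline",
]


@dataclass
class UnidimReport:
    eigenvalues: np.ndarray
    ratio_1_2: float
    variance_pct_first: float
    loadings_first: dict
    removed_items: list
    passed: bool


@dataclass
class ItemFitResult:
    item_id: str
    sx2: float
    df: int
    p_value: float
    flagged: bool


@dataclass
class DIFResult:
    item_id: str
    grouping: str
    delta_pseudo_r2: float
    flagged: bool


# ---------------------------------------------------------------------------
# unidimensionality
# ---------------------------------------------------------------------------

def _first_factor(codes: np.ndarray, item_ids) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and first-principal-component loadings of
    the Pearson correlation matrix."""
    sd = np.nanstd(codes, axis=0)
    constant = [iid for iid, s in zip(item_ids, sd) if s == 0 or np.isnan(s)]
    if constant:
        raise ValueError(f"correlation matrix singular; constant items: {constant}")
    # pairwise-complete Pearson correlations on the raw ordinal codes
    df_corr = np.ma.corrcoef(np.ma.masked_invalid(codes), rowvar=False).data
    vals, vecs = np.linalg.eigh(df_corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    loadings = vecs[:, 0] * np.sqrt(max(vals[0], 0.0))
    if loadings.sum() < 0:
        loadings = -loadings
    return vals, loadings


def unidimensionality_check(responses: ResponseMatrix, loading_min: float = 0.30,
                            ratio_min: float = 3.0,
                            variance_min_pct: float = 20.0) -> UnidimReport:
    """Two-pass first-factor screen: drop low-loading items once, refit,
    and judge the eigenvalue ratio and first-factor variance share."""
    if responses.n_items < 3:
        raise ValueError("need at least 3 items")
    if responses.n_persons < 50:
        warnings.warn("fewer than 50 persons; factor screen is unstable",
                      RuntimeWarning, stacklevel=2)
    item_ids = list(responses.item_ids)
    codes = responses.codes
    removed: list[str] = []
    vals, loadings = _first_factor(codes, item_ids)
    low = [iid for iid, l in zip(item_ids, loadings) if abs(l) < loading_min]
    if low:
        removed = low
        keep = [i for i, iid in enumerate(item_ids) if iid not in set(low)]
        item_ids = [item_ids[i] for i in keep]
        codes = codes[:, keep]
        vals, loadings = _first_factor(codes, item_ids)  # confirmation pass
    ratio = float(vals[0] / vals[1])
    var_pct = float(100.0 * vals[0] / len(item_ids))
    return UnidimReport(
        eigenvalues=vals,
        ratio_1_2=ratio,
        variance_pct_first=var_pct,
        loadings_first=dict(zip(item_ids, loadings)),
        removed_items=removed,
        passed=bool(ratio >= ratio_min and var_pct >= variance_min_pct),
    )


# ---------------------------------------------------------------------------
# S-X^2 item fit
# ---------------------------------------------------------------------------

def _score_distribution(tables: list[np.ndarray]) -> np.ndarray:
    """Generalized summed-score recursion: P(sum of category codes = s | theta)
    for each grid point. ``tables`` holds per-item (Q, m) probabilities."""
    Q = tables[0].shape[0]
    f = np.ones((Q, 1))
    for P in tables:
        m = P.shape[1]
        S_old = f.shape[1]
        new = np.zeros((Q, S_old + m - 1))
        for k in range(m):
            new[:, k:k + S_old] += f * P[:, [k]]
        f = new
    return f


def _collapse_rows(obs: np.ndarray, exp: np.ndarray, min_cell: float):
    """Merge adjacent rest-score rows (then adjacent category cells)
    until every expected cell count reaches ``min_cell``. Returns lists
    of (obs_cells, exp_cells) per merged group."""
    groups = []
    acc_o = np.zeros(obs.shape[1])
    acc_e = np.zeros(obs.shape[1])
    for s in range(obs.shape[0]):
        acc_o = acc_o + obs[s]
        acc_e = acc_e + exp[s]
        if acc_e.sum() > 0 and acc_e.min() >= min_cell:
            groups.append((acc_o, acc_e))
            acc_o = np.zeros(obs.shape[1])
            acc_e = np.zeros(obs.shape[1])
    if acc_e.sum() > 0:
        if groups:
            o, e = groups[-1]
            groups[-1] = (o + acc_o, e + acc_e)
        else:
            groups.append((acc_o, acc_e))
    # category-level collapse inside each group for stubbornly sparse cells
    out = []
    for o, e in groups:
        o, e = o.copy(), e.copy()
        while e.size > 2 and e.min() < min_cell:
            i = int(np.argmin(e))
            j = i - 1 if i > 0 else i + 1
            e[j] += e[i]
            o[j] += o[i]
            e = np.delete(e, i)
            o = np.delete(o, i)
        out.append((o, e))
    return out


def item_fit_sx2(responses: ResponseMatrix, bank: ItemBank,
                 grid: ThetaGrid | None = None, alpha: float = 0.05,
                 min_cell: float = 1.0) -> list[ItemFitResult]:
    """Summed-score (rest-score) chi-square item fit.

    Observed category frequencies within rest-score groups are compared
    with model-expected frequencies obtained from the summed-score
    recursion under the calibrated parameters; sparse cells are merged
    until each expected count reaches ``min_cell``.
    """
    if grid is None:
        grid = default_grid()
    rm = responses.subset_items(bank.ids)
    complete = ~rm.mask.any(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} incomplete rows for S-X2",
                      RuntimeWarning, stacklevel=2)
    codes = rm.codes[complete].astype(int)
    n = codes.shape[0]
    tables = [category_probabilities(item, grid.points) for item in bank]
    w = grid.weights
    results = []
    for j, item in enumerate(bank):
        m = item.n_categories
        f_rest = _score_distribution([t for i, t in enumerate(tables) if i != j])
        S_rest = f_rest.shape[1]
        rest = codes.sum(axis=1) - codes[:, j]
        obs = np.zeros((S_rest, m))
        for s, k in zip(rest, codes[:, j]):
            obs[s, k] += 1
        n_s = obs.sum(axis=1)
        # E[category k | rest score s] under the model
        num = (w[:, None, None] * f_rest[:, :, None] * tables[j][:, None, :]).sum(axis=0)
        den = (w[:, None] * f_rest).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_cond = np.where(den[:, None] > 0, num / np.maximum(den[:, None], 1e-300), 0.0)
        exp = n_s[:, None] * e_cond
        groups = _collapse_rows(obs, exp, min_cell)
        x2 = 0.0
        cells = 0
        for o, e in groups:
            ok = e > 0
            x2 += float(((o[ok] - e[ok]) ** 2 / e[ok]).sum())
            cells += int(ok.sum()) - 1
        df = cells - item.n_free_params
        if df <= 0 or n == 0:
            warnings.warn(f"item {item.item_id!r}: too few persons/cells for S-X2",
                          RuntimeWarning, stacklevel=2)
            results.append(ItemFitResult(item.item_id, x2, 0, np.nan, False))
            continue
        p = float(stats.chi2.sf(x2, df))
        results.append(ItemFitResult(item.item_id, x2, df, p, bool(p < alpha)))
    return results


# ---------------------------------------------------------------------------
# DIF
# ---------------------------------------------------------------------------

def _mcfadden_ll(y: np.ndarray) -> float:
    """Log-likelihood of the intercepts-only ordinal model (category
    proportions)."""
    counts = np.bincount(y)
    counts = counts[counts > 0]
    return float((counts * np.log(counts / counts.sum())).sum())


def dif_analysis(responses: ResponseMatrix, theta_hat, group,
                 threshold: float = 0.02, grouping: str = "group") -> list[DIFResult]:
    """Ordinal-logistic DIF screen.

    For each item, nested proportional-odds models are fitted on the
    same rows — M0: response ~ theta; M2: response ~ theta + group +
    theta x group — and the item is flagged when the McFadden pseudo-R^2
    gain of M2 over M0 reaches ``threshold``. The statistic is invariant
    to swapping the group coding.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    group = np.asarray(group, dtype=float)
    if np.unique(group[~np.isnan(group)]).size < 2:
        raise ValueError("grouping variable is constant")
    counts = np.bincount(group[~np.isnan(group)].astype(int))
    if counts.min() < 25:
        warnings.warn(f"smallest group has {counts.min()} persons (< 25)",
                      RuntimeWarning, stacklevel=2)
    results = []
    for j, iid in enumerate(responses.item_ids):
        col = responses.codes[:, j]
        rows = ~np.isnan(col) & ~np.isnan(theta_hat) & ~np.isnan(group)
        y_raw = col[rows].astype(int)
        # map to dense 0..K-1 for the ordinal fit
        cats = np.unique(y_raw)
        if cats.size < 2:
            warnings.warn(f"item {iid!r}: single observed category; DIF skipped",
                          RuntimeWarning, stacklevel=2)
            results.append(DIFResult(iid, grouping, np.nan, False))
            continue
        y = np.searchsorted(cats, y_raw)
        th = theta_hat[rows]
        g = group[rows]
        ll0 = _mcfadden_ll(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m0 = OrderedModel(y, th[:, None], distr="logit").fit(
                method="bfgs", maxiter=200, disp=False)
            X2 = np.column_stack([th, g, th * g])
            m2 = OrderedModel(y, X2, distr="logit").fit(
                method="bfgs", maxiter=200, disp=False)
        delta = (m2.llf - m0.llf) / (-ll0)
        delta = float(max(delta, 0.0))  # guard tiny optimizer noise
        results.append(DIFResult(iid, grouping, delta, bool(delta >= threshold)))
    return results


# ---------------------------------------------------------------------------
# discrimination filter and the full pipeline
# ---------------------------------------------------------------------------

def discrimination_filter(bank: ItemBank, min_a: float = 0.8
                          ) -> tuple[ItemBank, list[str]]:
    """Drop GRM/GPCM items with slope below ``min_a``; order preserved."""
    for item in bank:
        if item.model not in ("GRM", "GPCM"):
            raise ValueError(f"item {item.item_id!r}: discrimination filter "
                             "applies to GRM/GPCM banks")
    retained = [item for item in bank if item.a >= min_a]
    removed = [item.item_id for item in bank if item.a < min_a]
    return ItemBank(retained), removed


def qc_pipeline(responses: ResponseMatrix, grid: ThetaGrid | None = None,
                loading_min: float = 0.30, ratio_min: float = 3.0,
                variance_min_pct: float = 20.0, sx2_alpha: float = 0.05,
                dif_threshold: float = 0.02, min_a: float = 0.8,
                group_cols=None, calibrate_kwargs=None) -> dict:
    """Run the full screen (unidimensionality -> calibration -> S-X^2 ->
    DIF -> discrimination) and return a stage-by-stage report with the
    surviving bank. Each stage consumes the previous stage's survivors.
    """
    from .calibration import fit_mml_em
    from .engine import eap_estimate

    if grid is None:
        grid = default_grid()
    calibrate_kwargs = calibrate_kwargs or {}
    report: dict = {"stages": []}
    current = responses

    unidim = unidimensionality_check(current, loading_min, ratio_min, variance_min_pct)
    survivors = [i for i in current.item_ids if i not in set(unidim.removed_items)]
    current = current.subset_items(survivors)
    report["unidimensionality"] = unidim
    report["stages"].append({"stage": "unidimensionality", "removed": unidim.removed_items,
                             "surviving": len(survivors)})

    calib = fit_mml_em(current, model="GRM", grid=grid, **calibrate_kwargs)
    bank = calib.bank
    report["calibration"] = calib

    fits = item_fit_sx2(current, bank, grid, alpha=sx2_alpha)
    misfit = [f.item_id for f in fits if f.flagged]
    bank = ItemBank([it for it in bank if it.item_id not in set(misfit)])
    current = current.subset_items(bank.ids)
    report["item_fit"] = fits
    report["stages"].append({"stage": "item_fit", "removed": misfit,
                             "surviving": len(bank)})

    dif_removed: list[str] = []
    report["dif"] = {}
    if group_cols and current.groups is not None:
        theta = np.array([eap_estimate(row, bank, grid)[0] for row in current.codes])
        for col in group_cols:
            res = dif_analysis(current, theta, current.groups[col].to_numpy(),
                               threshold=dif_threshold, grouping=col)
            report["dif"][col] = res
            flagged = [r.item_id for r in res if r.flagged]
            if flagged:
                bank = ItemBank([it for it in bank if it.item_id not in set(flagged)])
                current = current.subset_items(bank.ids)
                # condition on the surviving bank for the next grouping
                theta = np.array([eap_estimate(row, bank, grid)[0]
                                  for row in current.codes])
                dif_removed.extend(flagged)
    report["stages"].append({"stage": "dif", "removed": dif_removed,
                             "surviving": len(bank)})

    bank, low_a = discrimination_filter(bank, min_a)
    report["stages"].append({"stage": "discrimination", "removed": low_a,
                             "surviving": len(bank)})
    report["final_bank"] = bank
    return report
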