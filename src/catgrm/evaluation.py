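"""Reliability, validity, and screening evaluation.

Marginal reliability aggregates per-person information-based standard
errors on the unit-variance trait scale as 1 - mean(SE^2). Screening
accuracy against a binary criterion (here: a criterion-scale total at or
above its clinical cutoff) is summarized by sensitivity, specificity,
the Youden index J = sensitivity + specificity - 1, and the area under
the ROC curve computed from the rank (Mann-Whitney) formulation with
ties counted 1/2. A logistic diagnosis-probability curve maps adaptive
scores to the probability of meeting the criterion, alongside empirical
percentile ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io import ResponseMatrix
from .models import ItemBank

__all__ = [
    "ScreeningMetrics",
    "DiagnosisCurve",
    "marginal_reliability",
    "classify_by_criterion",
    "screening_metrics",
    "auc_mann_whitney",
    "roc_table",
    "optimal_cutpoint",
    "diagnosis_curve",
    "response_descriptives",
    "plot_information_curve",
    "plot_diagnosis_curve",
]


@dataclass
class ScreeningMetrics:
    cutpoint: float
    sensitivity: float
    specificity: float
    youden: float
    auc: float


@dataclass
class DiagnosisCurve:
    """Logistic model of diagnosis on score plus a percentile lookup."""

    intercept: float
    slope: float
    scores: np.ndarray          # sorted observed scores
    percentiles: np.ndarray     # matching sample percentile ranks

    @property
    def score_at_p50(self) -> float:
        """Score with fitted diagnosis probability 0.50 (= -intercept/slope)."""
        return -self.intercept / self.slope

    def probability(self, score):
        z = self.intercept + self.slope * np.asarray(score, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    def percentile(self, score):
        return np.interp(np.asarray(score, dtype=float), self.scores, self.percentiles)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "percentile": self.percentiles,
                             "probability": self.probability(self.scores)})


def marginal_reliability(se_values) -> float:
    """1 - mean(SE^2) on the unit-variance trait scale."""
    se = np.asarray(se_values, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    r = 1.0 - float(np.mean(se**2))
    if r < 0:
        warnings.warn(f"negative marginal reliability {r:.4f}", RuntimeWarning,
                      stacklevel=2)
    return r


def classify_by_criterion(criterion_scores, cutoff: float = 75.0) -> np.ndarray:
    """Binary labels from a criterion total score; the cutoff is inclusive
    (score >= cutoff -> positive)."""
    return (np.asarray(criterion_scores, dtype=float) >= cutoff).astype(int)


def auc_mann_whitney(scores, labels) -> float:
    """AUC via ranks: (sum of positive ranks - n1(n1+1)/2) / (n1 n0),
    ties counted 0.5 through midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def screening_metrics(scores, labels, cutpoint: float) -> ScreeningMetrics:
    """Sensitivity/specificity/Youden at one cutpoint (score >= cutpoint
    is test-positive) plus the cutpoint-free AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    pred = scores >= cutpoint
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[neg]))
    return ScreeningMetrics(cutpoint=float(cutpoint), sensitivity=sens,
                            specificity=spec, youden=sens + spec - 1.0,
                            auc=auc_mann_whitney(scores, labels))


def roc_table(scores, labels) -> pd.DataFrame:
    """Sensitivity/specificity/Youden at every observed score used as a
    cutpoint."""
    cuts = np.unique(np.asarray(scores, dtype=float))
    rows = []
    for c in cuts:
        m = screening_metrics(scores, labels, c)
        rows.append({"cutpoint": c, "sensitivity": m.sensitivity,
                     "specificity": m.specificity, "youden": m.youden})
    return pd.DataFrame(rows)


def optimal_cutpoint(scores, labels) -> tuple[float, ScreeningMetrics]:
    """Cutpoint maximizing the Youden index over observed scores; ties
    resolve to the lowest cutpoint."""
    tab = roc_table(scores, labels)
    best = tab.loc[tab["youden"].idxmax()]  # idxmax returns the first maximum
    m = screening_metrics(scores, labels, float(best["cutpoint"]))
    return float(best["cutpoint"]), m


def diagnosis_curve(cat_scores, labels) -> DiagnosisCurve:
    """Logistic regression of diagnosis on adaptive score, with empirical
    percentile ranks (midrank convention) of the score distribution."""
    scores = np.asarray(cat_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    if scores.size < 50:
        warnings.warn("fewer than 50 observations; curve may be unstable",
                      RuntimeWarning, stacklevel=2)
    X = sm.add_constant(scores)
    fit = sm.Logit(labels, X).fit(disp=False)
    order = np.argsort(scores)
    sorted_scores = scores[order]
    ranks = stats.rankdata(scores)[order]
    pct = 100.0 * (ranks - 0.5) / scores.size
    # collapse duplicate scores for a clean interpolation table
    uniq, first = np.unique(sorted_scores, return_index=True)
    return DiagnosisCurve(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                          scores=uniq, percentiles=pct[first])


def response_descriptives(responses: ResponseMatrix) -> pd.DataFrame:
    """Per-item sample moments of the observed codes: mean, SD (n-1
    denominator), skewness (standardized third moment), and excess
    kurtosis (normal = 0). Constant items give NaN shape moments."""
    rows = []
    for j, iid in enumerate(responses.item_ids):
        col = responses.codes[:, j]
        x = col[~np.isnan(col)]
        if x.size < 2:
            raise ValueError(f"item {iid!r}: fewer than 2 observed responses")
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            warnings.warn(f"item {iid!r} is constant; shape moments undefined",
                          RuntimeWarning, stacklevel=2)
            skew = kurt = np.nan
        else:
            skew = float(stats.skew(x))
            kurt = float(stats.kurtosis(x))  # excess (Fisher) kurtosis
        rows.append({"item_id": iid, "n": int(x.size), "mean": float(np.mean(x)),
                     "sd": sd, "skewness": skew, "kurtosis": kurt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots (generic renderings of the information/SE and diagnosis curves)
# ---------------------------------------------------------------------------

def plot_information_curve(bank: ItemBank, path, theta_range=(-4.0, 4.0)) -> None:
    """Test information and SE across the trait range, written to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thetas = np.linspace(*theta_range, 161)
    info = bank.information_matrix(thetas).sum(axis=1)
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(thetas, info, label="test information")
    ax1.set_xlabel(r"$\theta$")
    ax1.set_ylabel(r"$I(\theta)$")
    ax2 = ax1.twinx()
    with np.errstate(divide="ignore"):
        ax2.plot(thetas, 1.0 / np.sqrt(info), "--", color="C1", label="SE")
    ax2.set_ylabel(r"SE$(\theta)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diagnosis_curve(curve: DiagnosisCurve, path) -> None:
    """Diagnosis probability and percentile rank against the score."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.linspace(curve.scores.min(), curve.scores.max(), 200)
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(xs, curve.probability(xs), label="P(diagnosis)")
    ax1.set_xlabel("adaptive score")
    ax1.set_ylabel("probability of diagnosis")
    ax1.set_ylim(-0.02, 1.02)
    ax2 = ax1.twinx()
    ax2.plot(xs, curve.percentile(xs), "--", color="C1")
    ax2.set_ylabel("sample percentile")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
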