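"""Polytomous item response models and their information functions.

Implements the three models compared during item-bank construction — the
graded response model (GRM), the generalized partial credit model (GPCM)
and the nominal response model (NRM) — together with the quantities the
adaptive test is built on: category response probabilities, response
log-likelihoods, item/test Fisher information, and the standard-error and
reliability identities

    SE(theta) = 1 / sqrt(I(theta)),      r_xx(theta) = 1 - 1 / I(theta)

on a latent-trait scale with mean 0 and standard deviation 1.

All three models use the unscaled logistic link (no 1.7 constant); the
GRM is in slope-threshold form, P(X >= k | theta) = logistic(a (theta - b_k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, log_softmax, softmax

MODEL_TAGS = ("GRM", "GPCM", "NRM")

__all__ = [
    "MODEL_TAGS",
    "ItemParameters",
    "ItemBank",
    "ThetaGrid",
    "category_probabilities",
    "response_loglik",
    "item_information",
    "test_information",
    "standard_error_from_information",
    "reliability_from_information",
]


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single polytomous item.

    Parameters
    ----------
    item_id : str
        Identifier, unique within a bank.
    model : {"GRM", "GPCM", "NRM"}
        Model family tag.
    n_categories : int
        Number of ordered (GRM/GPCM) or nominal (NRM) response
        categories, coded 0 .. n_categories-1.
    a : float or array
        Discrimination. A positive scalar for GRM/GPCM; for NRM a vector
        of per-category slopes of length n_categories with the first
        entry fixed to 0 for identification.
    b : array
        GRM: strictly increasing thresholds b_1..b_{m-1}.
        GPCM: step difficulties d_1..d_{m-1} (no order constraint).
        NRM: per-category intercepts, length n_categories, first fixed 0.
    """

    item_id: str
    model: str
    n_categories: int
    a: float | np.ndarray
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.model not in MODEL_TAGS:
            raise ValueError(
                f"item {self.item_id!r}: unknown model tag {self.model!r}; "
                f"expected one of {MODEL_TAGS}"
            )
        m = int(self.n_categories)
        if m < 2:
            raise ValueError(f"item {self.item_id!r}: n_categories must be >= 2, got {m}")
        object.__setattr__(self, "n_categories", m)
        b = np.asarray(self.b, dtype=float).ravel()
        object.__setattr__(self, "b", b)
        if self.model in ("GRM", "GPCM"):
            a = float(np.asarray(self.a).reshape(()))
            if not a > 0:
                raise ValueError(f"item {self.item_id!r}: discrimination must be > 0, got {a}")
            object.__setattr__(self, "a", a)
            if b.size != m - 1:
                raise ValueError(
                    f"item {self.item_id!r}: expected {m - 1} category parameters, got {b.size}"
                )
            if self.model == "GRM" and b.size > 1 and not np.all(np.diff(b) > 0):
                raise ValueError(
                    f"item {self.item_id!r}: GRM thresholds must be strictly increasing, got {b}"
                )
        else:  # NRM
            a = np.asarray(self.a, dtype=float).ravel()
            if a.size != m or b.size != m:
                raise ValueError(
                    f"item {self.item_id!r}: NRM needs {m} slopes and {m} intercepts, "
                    f"got {a.size} and {b.size}"
                )
            if a[0] != 0.0 or b[0] != 0.0:
                raise ValueError(
                    f"item {self.item_id!r}: NRM first-category slope and intercept "
                    "must be fixed to 0"
                )
            object.__setattr__(self, "a", a)
        if not np.all(np.isfinite(b)):
            raise ValueError(f"item {self.item_id!r}: non-finite category parameters")

    @property
    def n_free_params(self) -> int:
        """Free parameters: m for GRM/GPCM (a + m-1 thresholds), 2(m-1) for NRM."""
        if self.model in ("GRM", "GPCM"):
            return self.n_categories
        return 2 * (self.n_categories - 1)


class ItemBank(Sequence):
    """Ordered collection of :class:`ItemParameters` with unique ids."""

    def __init__(self, items: Iterable[ItemParameters]):
        self.items: list[ItemParameters] = list(items)
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in bank: {dup}")
        self._index = {iid: pos for pos, iid in enumerate(ids)}

    # -- sequence protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ItemBank(self.items[i])
        return self.items[i]

    def __iter__(self):
        return iter(self.items)

    # -- lookup -----------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index(self, item_id: str) -> int:
        return self._index[item_id]

    def get(self, item_id: str) -> ItemParameters:
        return self.items[self._index[item_id]]

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        return ItemBank([self.get(i) for i in item_ids])

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([it.n_categories for it in self.items], dtype=int)

    @property
    def is_grm(self) -> bool:
        return all(it.model == "GRM" for it in self.items)

    # -- vectorized GRM arrays (padded thresholds) ------------------------
    def grm_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (a, B) with B the (n_items, max_m-1) threshold matrix
        padded with +inf so padded categories get zero probability."""
        if not self.is_grm:
            raise ValueError("grm_arrays requires an all-GRM bank")
        cached = getattr(self, "_grm_cache", None)
        if cached is not None:
            return cached
        maxk = int(self.n_categories.max()) - 1
        a = np.array([it.a for it in self.items], dtype=float)
        B = np.full((len(self), maxk), np.inf)
        for j, it in enumerate(self.items):
            B[j, : it.b.size] = it.b
        self._grm_cache = (a, B)
        return a, B

    def information_matrix(self, thetas) -> np.ndarray:
        """Item Fisher information for every item at each theta.

        Returns an array of shape (n_theta, n_items); scalar theta gives
        shape (n_items,).
        """
        thetas = np.asarray(thetas, dtype=float)
        scalar = thetas.ndim == 0
        t = np.atleast_1d(thetas)
        if self.is_grm:
            a, B = self.grm_arrays()
            cum = expit(a[None, :, None] * (t[:, None, None] - B[None, :, :]))
            dcum = a[None, :, None] * cum * (1.0 - cum)
            ones = np.ones(cum.shape[:2] + (1,))
            zeros = np.zeros_like(ones)
            P = np.concatenate([ones, cum], axis=2) - np.concatenate([cum, zeros], axis=2)
            dP = np.concatenate([zeros, dcum], axis=2) - np.concatenate([dcum, zeros], axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(P > 1e-300, dP * dP / np.where(P > 0, P, 1.0), 0.0)
            info = terms.sum(axis=2)
        else:
            info = np.array([[item_information(it, ti) for it in self.items] for ti in t])
        return info[0] if scalar else info


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature grid over the latent trait with prior masses."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).ravel()
        w = np.asarray(self.weights, dtype=float).ravel()
        if pts.size != w.size or pts.size < 2:
            raise ValueError("grid points and weights must have equal length >= 2")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("grid weights must be nonnegative and sum to 1 (tol 1e-10)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @classmethod
    def normal(cls, n: int = 81, bounds: tuple[float, float] = (-4.0, 4.0),
               mean: float = 0.0, sd: float = 1.0) -> "ThetaGrid":
        """Equally spaced grid with renormalized Normal(mean, sd) masses."""
        pts = np.linspace(bounds[0], bounds[1], n)
        w = np.exp(-0.5 * ((pts - mean) / sd) ** 2)
        return cls(pts, w / w.sum())

    @property
    def mean(self) -> float:
        return float(self.points @ self.weights)


def default_grid() -> ThetaGrid:
    """81 equally spaced points on [-4, 4] with Normal(0, 1) masses."""
    return ThetaGrid.normal()


# ---------------------------------------------------------------------------
# probabilities and information
# ---------------------------------------------------------------------------

def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Category response probabilities P(X = k | theta), k = 0..m-1.

    ``theta`` may be a scalar (returns shape (m,)) or a vector (returns
    shape (n_theta, m)). Rows sum to 1 within 1e-12.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    t = np.atleast_1d(theta)[:, None]
    m = item.n_categories
    if item.model == "GRM":
        cum = expit(item.a * (t - item.b[None, :]))  # P(X >= k), k=1..m-1
        full = np.concatenate(
            [np.ones((t.shape[0], 1)), cum, np.zeros((t.shape[0], 1))], axis=1
        )
        P = full[:, :-1] - full[:, 1:]
    elif item.model == "GPCM":
        # cumulative step logits: s_k = sum_{v<=k} a (theta - d_v), s_0 = 0
        steps = item.a * (t - item.b[None, :])
        z = np.concatenate([np.zeros((t.shape[0], 1)), np.cumsum(steps, axis=1)], axis=1)
        P = softmax(z, axis=1)
    else:  # NRM
        z = t * item.a[None, :] + item.b[None, :]
        P = softmax(z, axis=1)
    assert P.shape[1] == m
    return P[0] if scalar else P


def _category_prob_derivatives(item: ItemParameters, theta) -> tuple[np.ndarray, np.ndarray]:
    """(P, dP/dtheta) with shapes (n_theta, m)."""
    t = np.atleast_1d(np.asarray(theta, dtype=float))[:, None]
    if item.model == "GRM":
        cum = expit(item.a * (t - item.b[None, :]))
        dcum = item.a * cum * (1.0 - cum)
        zero = np.zeros((t.shape[0], 1))
        full = np.concatenate([np.ones_like(zero), cum, zero], axis=1)
        dfull = np.concatenate([zero, dcum, zero], axis=1)
        return full[:, :-1] - full[:, 1:], dfull[:, :-1] - dfull[:, 1:]
    P = category_probabilities(item, np.atleast_1d(theta))
    if item.model == "GPCM":
        scores = item.a * np.arange(item.n_categories)[None, :]
    else:
        scores = item.a[None, :]
    mean_score = (P * scores).sum(axis=1, keepdims=True)
    return P, P * (scores - mean_score)


def response_loglik(responses, items: ItemBank | Sequence[ItemParameters], theta: float) -> float:
    """Log-likelihood of a response vector at theta; missing entries
    (None or NaN) contribute 0."""
    total = 0.0
    for code, item in zip(responses, items):
        if code is None or (isinstance(code, float) and np.isnan(code)):
            continue
        k = int(code)
        if not 0 <= k < item.n_categories:
            raise ValueError(
                f"item {item.item_id!r}: response code {k} outside "
                f"[0, {item.n_categories - 1}]"
            )
        total += float(np.log(category_probabilities(item, theta)[k]))
    return total


def item_information(item: ItemParameters, theta) -> float | np.ndarray:
    """Fisher information of one item: sum_k (dP_k/dtheta)^2 / P_k."""
    theta_arr = np.asarray(theta, dtype=float)
    P, dP = _category_prob_derivatives(item, theta_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 1e-300, dP * dP / np.where(P > 0, P, 1.0), 0.0)
    info = terms.sum(axis=1)
    return float(info[0]) if theta_arr.ndim == 0 else info


def test_information(bank: ItemBank | Sequence[ItemParameters], theta) -> float | np.ndarray:
    """Test information I(theta) = sum of item informations."""
    if isinstance(bank, ItemBank):
        info = bank.information_matrix(theta)
        return info.sum(axis=-1) if np.asarray(theta).ndim else float(info.sum())
    total = sum(item_information(it, theta) for it in bank)
    return total


def standard_error_from_information(info: float) -> float:
    """SE(theta) = 1 / sqrt(I(theta))."""
    if not info > 0:
        raise ValueError(f"non-positive information: {info}")
    return 1.0 / np.sqrt(info)


def reliability_from_information(info: float) -> float:
    """Per-person reliability r_xx(theta) = 1 - 1/I(theta) on the
    unit-variance trait scale. Values below 0 (information < 1) are
    returned as-is with a warning."""
    if not info > 0:
        raise ValueError(f"non-positive information: {info}")
    r = 1.0 - 1.0 / info
    if r < 0:
        warnings.warn(
            f"information {info} < 1 yields negative reliability {r:.4f}",
            RuntimeWarning,
            stacklevel=2,
        )
    return r
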