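"""Unidimensional divide-by-total building blocks.

Two item response function (IRF) families are provided:

* the generalized partial credit model (GPCM), a *dominance* model whose
  expected score increases monotonically in the latent trait, and
* the generalized graded unfolding model (GGUM), an *ideal point* model
  whose expected score is unimodal and symmetric about the item location.

Both are divide-by-total models: the probability of ordinal category
``y in {0, ..., K}`` is a category-specific component divided by the sum
of the components of all K+1 categories.  The GPCM component is a single
exponential of a linear predictor; the GGUM component is the sum of two
exponentials, corresponding to latent "from below" and "from above"
categories with scoring weights ``s_y`` and ``M - s_y`` (``M = 2K + 1``).

All probabilities are computed in log space with max-subtraction so that
extreme trait values (|linear predictor| up to ~700) remain finite.
Categories are 0-based throughout, and scoring weights are always stored
explicitly: non-default weights such as ``(2, 1, 0)`` are first class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_softmax, logsumexp

__all__ = [
    "ScoringWeights",
    "DominanceItemParams",
    "IdealPointItemParams",
    "CategoryDistribution",
    "gpcm_category_probs",
    "ggum_category_probs",
    "expected_score",
    "default_weights",
    "params_to_frame",
    "params_from_frame",
]


def default_weights(n_categories: int) -> np.ndarray:
    """Standard ordinal scoring weights ``s_y = y`` for K+1 categories."""
    return np.arange(n_categories, dtype=float)


@dataclass(frozen=True)
class ScoringWeights:
    """Category scores relating a trait to the K+1 response categories."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("scoring weights must be a non-empty 1-d vector")
        if not np.all(np.isfinite(s)):
            raise ValueError("scoring weights must be finite")
        object.__setattr__(self, "s", s)

    def __len__(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class DominanceItemParams:
    """GPCM item parameters.

    ``thresholds`` holds the free thresholds (beta_1, ..., beta_K); beta_0
    is fixed at 0 by convention.  The location/deviation decomposition
    ``beta_k = location + deviation_k`` used on the generation side is
    available through :meth:`from_location`.
    """

    alpha: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"discrimination alpha must be > 0, got {self.alpha}")
        t = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if not np.all(np.isfinite(t)):
            raise ValueError("thresholds must be finite")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def location(self) -> float:
        """Item location: the mean of the K thresholds."""
        return float(np.mean(self.thresholds))

    @classmethod
    def from_location(
        cls, alpha: float, location: float, deviations: np.ndarray
    ) -> "DominanceItemParams":
        return cls(alpha=alpha, thresholds=location + np.asarray(deviations, float))


@dataclass(frozen=True)
class IdealPointItemParams:
    """GGUM item parameters (discrimination, location, thresholds xi_1..xi_K)."""

    lam: float
    delta: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"discrimination lambda must be > 0, got {self.lam}")
        t = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if not np.all(np.isfinite(t)):
            raise ValueError("thresholds must be finite")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def M(self) -> int:
        """Number of latent categories minus one: ``M = 2K + 1``."""
        return 2 * self.thresholds.size + 1


@dataclass(frozen=True)
class CategoryDistribution:
    """A valid probability distribution over K+1 response categories."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "p", p)

    def __len__(self) -> int:
        return self.p.size

    @property
    def n_categories(self) -> int:
        return self.p.size


def _check_weights(weights, n_categories: int, item_id: str | None) -> np.ndarray:
    s = weights.s if isinstance(weights, ScoringWeights) else np.asarray(weights, float)
    if s.size != n_categories:
        where = f" in pseudo-item {item_id!r}" if item_id else ""
        raise ValueError(
            f"scoring weights of length {s.size} do not match "
            f"{n_categories} categories{where}"
        )
    return s


def gpcm_log_probs(
    theta, item: DominanceItemParams, weights=None, item_id: str | None = None
) -> np.ndarray:
    """Log category probabilities of the GPCM, vectorized over ``theta``.

    The linear predictor of category y is
    ``alpha * (s_y * theta - sum_{k<=y} beta_k)`` with beta_0 = 0.
    Returns an array of shape ``theta.shape + (K+1,)``.
    """
    if weights is None:
        weights = default_weights(item.n_categories)
    s = _check_weights(weights, item.n_categories, item_id)
    theta = np.asarray(theta, dtype=float)
    cum_beta = np.concatenate([[0.0], np.cumsum(item.thresholds)])
    eta = item.alpha * (theta[..., None] * s - cum_beta)
    return log_softmax(eta, axis=-1)


def gpcm_category_probs(
    theta: float, item: DominanceItemParams, weights=None, item_id: str | None = None
) -> CategoryDistribution:
    """GPCM category probabilities at a single trait level."""
    return CategoryDistribution(np.exp(gpcm_log_probs(float(theta), item, weights, item_id)))


def ggum_log_probs(
    theta, item: IdealPointItemParams, weights=None, item_id: str | None = None
) -> np.ndarray:
    """Log category probabilities of the GGUM, vectorized over ``theta``.

    Each observable category is the (normalized) sum of a from-below term
    with weight ``s_y`` and a from-above term with weight ``M - s_y``, both
    sharing the cumulative thresholds.
    """
    if weights is None:
        weights = default_weights(item.n_categories)
    s = _check_weights(weights, item.n_categories, item_id)
    theta = np.asarray(theta, dtype=float)
    cum_xi = np.concatenate([[0.0], np.cumsum(item.thresholds)])
    d = theta[..., None] - item.delta
    below = item.lam * (s * d - cum_xi)
    above = item.lam * ((item.M - s) * d - cum_xi)
    omega = np.logaddexp(below, above)
    return omega - logsumexp(omega, axis=-1, keepdims=True)


def ggum_category_probs(
    theta: float, item: IdealPointItemParams, weights=None, item_id: str | None = None
) -> CategoryDistribution:
    """GGUM category probabilities at a single trait level."""
    return CategoryDistribution(np.exp(ggum_log_probs(float(theta), item, weights, item_id)))


def expected_score(dist: CategoryDistribution | np.ndarray) -> float:
    """Expected response ``sum_y y * p(y)``: the IRF value at one trait level."""
    p = dist.p if isinstance(dist, CategoryDistribution) else np.asarray(dist, float)
    return float(np.dot(np.arange(p.size), p))


# ---------------------------------------------------------------------------
# Parameter-table CSV interchange
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def params_to_frame(items: dict[str, DominanceItemParams | IdealPointItemParams]) -> pd.DataFrame:
    """Long-format parameter table (item_id, param_name, category_index, value)."""
    rows = []
    for item_id, it in items.items():
        if isinstance(it, DominanceItemParams):
            rows.append((item_id, "alpha", 0, it.alpha))
            for k, b in enumerate(it.thresholds, start=1):
                rows.append((item_id, "beta", k, b))
        elif isinstance(it, IdealPointItemParams):
            rows.append((item_id, "lambda", 0, it.lam))
            rows.append((item_id, "delta", 0, it.delta))
            for k, x in enumerate(it.thresholds, start=1):
                rows.append((item_id, "xi", k, x))
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported item parameter type: {type(it)}")
    return pd.DataFrame(rows, columns=["item_id", "param_name", "category_index", "value"])


def params_from_frame(frame: pd.DataFrame) -> dict[str, DominanceItemParams | IdealPointItemParams]:
    """Inverse of :func:`params_to_frame`."""
    out: dict[str, DominanceItemParams | IdealPointItemParams] = {}
    for item_id, grp in frame.groupby("item_id", sort=False):
        names = set(grp["param_name"])
        by = {
            (r.param_name, int(r.category_index)): float(r.value)
            for r in grp.itertuples()
        }
        if "alpha" in names:
            ks = sorted(k for (n, k) in by if n == "beta")
            out[str(item_id)] = DominanceItemParams(
                alpha=by[("alpha", 0)],
                thresholds=np.array([by[("beta", k)] for k in ks]),
            )
        else:
            ks = sorted(k for (n, k) in by if n == "xi")
            out[str(item_id)] = IdealPointItemParams(
                lam=by[("lambda", 0)],
                delta=by[("delta", 0)],
                thresholds=np.array([by[("xi", k)] for k in ks]),
            )
    return out


def write_params_csv(items, path) -> None:
    params_to_frame(items).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_params_csv(path) -> dict:
    return params_from_frame(pd.read_csv(path, float_precision="round_trip"))
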