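"""The DI-MIRT model: co-occurring dominance and ideal-point processes.

A pseudo-item response with K+1 categories may be driven by R co-occurring
response processes, each a dominance (GPCM-type) or ideal-point (GGUM-type)
divide-by-total process with its own trait, scoring weights and
discrimination.  The joint category distribution is formed by summing the
process-specific linear predictors inside each of the *two* exponential
terms of the ideal-point formulation:

* dominance processes contribute the same term ``a * s_y * theta`` to both
  exponentials (which merely doubles every category component and leaves
  the distribution unchanged in the single-process case);
* ideal-point processes contribute ``l * s_y * (theta - delta)`` to the
  from-below term and ``l * (M - s_y) * (theta - delta)`` to the
  from-above term, with ``M = 2K + 1``.

The process-specific thresholds are not separable: only the per-category
*intercepts* ``tau_k = sum_r a_r b_kr  (dominance)  +  l_r xi_kr (ideal)``
are identified, with ``tau_0 = 0``.  The estimation-facing parameterization
is therefore (discriminations, locations, tau); process-specific thresholds
exist only on the data-generation side (see :func:`category_intercepts`).

An equivalent *probability aggregation* formulation multiplies the
process-specific category distributions and renormalizes
(:func:`aggregate_probability_form`); it serves as an independent oracle
for the linear-predictor form.  For pseudo-items with two or more
ideal-point processes the two formulations genuinely differ (the product
of sums of two exponentials contains cross terms that the summed
linear-predictor form does not), so equivalence only holds with at most
one ideal-point process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.special import log_softmax, logsumexp

from .irf_core import (
    CategoryDistribution,
    DominanceItemParams,
    IdealPointItemParams,
    ScoringWeights,
)

__all__ = [
    "ProcessSpec",
    "PseudoItemParams",
    "category_intercepts",
    "dimirt_probs",
    "dimirt_log_probs",
    "aggregate_probability_form",
]

IRFKind = Literal["dominance", "ideal_point"]


@dataclass(frozen=True)
class ProcessSpec:
    """One response process within a pseudo-item.

    ``discrimination`` and ``location`` may be numbers, or *strings naming
    entries of a parameter table* (resolved via :meth:`resolve`).  Tied
    parameters — e.g. an ideal-point location set equal to an agreement
    threshold — are expressed by two processes referencing the same name,
    so the tie survives estimation.
    """

    kind: IRFKind
    trait: str
    weights: np.ndarray
    discrimination: float | str
    location: float | str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("dominance", "ideal_point"):
            raise ValueError(f"unknown IRF kind: {self.kind!r}")
        w = self.weights.s if isinstance(self.weights, ScoringWeights) else self.weights
        w = np.asarray(w, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.kind == "ideal_point" and self.location is None:
            raise ValueError("ideal-point process requires a location")
        if self.kind == "dominance" and self.location is not None:
            raise ValueError("dominance process must not carry a location")
        if isinstance(self.discrimination, (int, float)) and not self.discrimination > 0:
            raise ValueError("discrimination must be > 0")

    @property
    def n_categories(self) -> int:
        return self.weights.size

    @property
    def M(self) -> int:
        return 2 * (self.n_categories - 1) + 1

    def resolve(self, params: Mapping[str, float]) -> "ProcessSpec":
        """Replace string parameter references by their numeric values."""
        disc = self.discrimination
        loc = self.location
        if isinstance(disc, str):
            disc = float(params[disc])
        if isinstance(loc, str):
            loc = float(params[loc])
        return replace(self, discrimination=disc, location=loc)


@dataclass(frozen=True)
class PseudoItemParams:
    """A pseudo-item: K+1 categories, R processes, shared intercepts tau.

    ``tau`` holds the free intercepts (tau_1, ..., tau_K); tau_0 = 0.
    """

    processes: tuple[ProcessSpec, ...]
    tau: np.ndarray
    name: str = "pseudo-item"

    def __post_init__(self) -> None:
        procs = tuple(self.processes)
        if len(procs) < 1:
            raise ValueError("a pseudo-item needs at least one process")
        ncat = procs[0].n_categories
        for p in procs:
            if p.n_categories != ncat:
                raise ValueError(
                    f"process weight lengths disagree in {self.name!r}: "
                    f"{[q.n_categories for q in procs]}"
                )
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if tau.size != ncat - 1:
            raise ValueError(
                f"{self.name!r}: expected {ncat - 1} intercepts for "
                f"{ncat} categories, got {tau.size}"
            )
        object.__setattr__(self, "processes", procs)
        object.__setattr__(self, "tau", tau)

    @property
    def K(self) -> int:
        return self.processes[0].n_categories - 1

    @property
    def n_categories(self) -> int:
        return self.K + 1

    def resolve(self, params: Mapping[str, float]) -> "PseudoItemParams":
        return replace(self, processes=tuple(p.resolve(params) for p in self.processes))


def category_intercepts(
    processes: Sequence[tuple[ProcessSpec, np.ndarray]],
) -> np.ndarray:
    """Identified category intercepts from generation-side thresholds.

    ``tau_k = sum_r (a_r * b_kr)`` over dominance processes plus
    ``(l_r * xi_kr)`` over ideal-point processes, for k = 1..K.  The
    returned vector includes the fixed ``tau_0 = 0`` in position 0.
    """
    if not processes:
        raise ValueError("need at least one (process, thresholds) pair")
    K = processes[0][0].n_categories - 1
    tau = np.zeros(K + 1)
    for proc, thresholds in processes:
        t = np.atleast_1d(np.asarray(thresholds, dtype=float))
        if t.size != K:
            raise ValueError(
                f"process on trait {proc.trait!r} has {t.size} thresholds, "
                f"expected {K}"
            )
        disc = proc.discrimination
        if isinstance(disc, str):
            raise TypeError(f"unresolved discrimination reference {disc!r}")
        tau[1:] += disc * t
    return tau


def _trait_level(traits: Mapping[str, float], proc: ProcessSpec, name: str):
    try:
        return traits[proc.trait]
    except KeyError:
        raise KeyError(
            f"trait {proc.trait!r} required by {name!r} is missing from "
            f"the supplied trait levels {sorted(traits)}"
        ) from None


def dimirt_log_probs(traits: Mapping[str, float], item: PseudoItemParams) -> np.ndarray:
    """Log category probabilities of the DI-MIRT model (linear-predictor form).

    Trait levels may be scalars or broadcastable arrays; the category axis
    is appended last.
    """
    cum_tau = np.concatenate([[0.0], np.cumsum(item.tau)])
    below = -cum_tau
    above = -cum_tau
    for proc in item.processes:
        disc = proc.discrimination
        if isinstance(disc, str):
            raise TypeError(f"unresolved discrimination reference {disc!r} in {item.name!r}")
        level = np.asarray(_trait_level(traits, proc, item.name), dtype=float)
        s = proc.weights
        if proc.kind == "dominance":
            term = disc * s * level[..., None]
            below = below + term
            above = above + term
        else:
            loc = proc.location
            if isinstance(loc, str):
                raise TypeError(f"unresolved location reference {loc!r} in {item.name!r}")
            d = level[..., None] - loc
            below = below + disc * s * d
            above = above + disc * (proc.M - s) * d
    omega = np.logaddexp(below, above)
    return omega - logsumexp(omega, axis=-1, keepdims=True)


def dimirt_probs(traits: Mapping[str, float], item: PseudoItemParams) -> CategoryDistribution:
    """DI-MIRT category distribution at one point of the trait space."""
    return CategoryDistribution(np.exp(dimirt_log_probs(traits, item)))


def aggregate_probability_form(
    process_dists: Sequence[CategoryDistribution | np.ndarray],
) -> CategoryDistribution:
    """Aggregate process-specific category distributions: softmax of summed logs.

    This is the probability-level formulation of co-occurrence; it equals
    the linear-predictor form whenever at most one process is ideal-point.
    """
    if not process_dists:
        raise ValueError("need at least one category distribution")
    total = None
    size = None
    for d in process_dists:
        p = d.p if isinstance(d, CategoryDistribution) else np.asarray(d, float)
        if size is None:
            size = p.size
        elif p.size != size:
            raise ValueError("category distributions have different lengths")
        if np.any(p <= 0):
            raise ValueError("probability aggregation requires strictly positive probabilities")
        logp = np.log(p)
        total = logp if total is None else total + logp
    return CategoryDistribution(np.exp(log_softmax(total)))


def process_distribution(
    traits: Mapping[str, float], proc: ProcessSpec, thresholds: np.ndarray
) -> CategoryDistribution:
    """Single-process category distribution from generation-side thresholds.

    Convenience used by the probability-aggregation oracle: evaluates the
    GPCM or GGUM for one process with its own thresholds.
    """
    from . import irf_core

    level = float(np.asarray(_trait_level(traits, proc, "process")))
    if proc.kind == "dominance":
        it = DominanceItemParams(alpha=float(proc.discrimination), thresholds=thresholds)
        return irf_core.gpcm_category_probs(level, it, proc.weights)
    it = IdealPointItemParams(
        lam=float(proc.discrimination),
        delta=float(proc.location),
        thresholds=thresholds,
    )
    return irf_core.ggum_category_probs(level, it, proc.weights)


# ---------------------------------------------------------------------------
# JSON interchange for pseudo-item specifications
# ---------------------------------------------------------------------------

def pseudo_item_to_dict(item: PseudoItemParams, intercept_ids=None) -> dict:
    """JSON-ready dict: {K, processes: [...], intercept_ids or tau}."""
    d: dict = {
        "K": item.K,
        "name": item.name,
        "processes": [
            {
                "irf": p.kind,
                "trait": p.trait,
                "weights": p.weights.tolist(),
                "discrimination_id": p.discrimination,
                "location_id": p.location,
            }
            for p in item.processes
        ],
    }
    if intercept_ids is not None:
        d["intercept_ids"] = list(intercept_ids)
    else:
        d["tau"] = np.asarray(item.tau, float).tolist()
    return d


def pseudo_item_from_dict(d: dict, params: Mapping[str, float] | None = None) -> PseudoItemParams:
    procs = tuple(
        ProcessSpec(
            kind=p["irf"],
            trait=p["trait"],
            weights=np.asarray(p["weights"], float),
            discrimination=p["discrimination_id"],
            location=p.get("location_id"),
        )
        for p in d["processes"]
    )
    if "intercept_ids" in d:
        if params is None:
            raise ValueError("intercept_ids present but no parameter table supplied")
        tau = np.array([float(params[i]) for i in d["intercept_ids"]])
    else:
        tau = np.asarray(d["tau"], float)
    item = PseudoItemParams(processes=procs, tau=tau, name=d.get("name", "pseudo-item"))
    return item.resolve(params) if params is not None else item
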