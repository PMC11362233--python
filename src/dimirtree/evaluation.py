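"""Recovery and model-comparison metrics.

Parameter recovery is summarized by the mean absolute bias (MAB) of EAP
point estimates against the generating values; out-of-sample fit is
compared by PSIS-LOO (Pareto-smoothed importance-sampling approximation
of leave-one-out cross-validation), reported on the deviance scale
(-2 * elpd) so that *smaller values indicate better fit*.

MAB aggregation over a simulation grid averages within replication
(over persons or items) first, then over replications.  The recovery
report pivots results into (generating model, fitted model) rows with
parameter-family columns; the comparison report adds, per generating
condition, the proportion of replications in which each fitted model
attained the smallest LOO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .inference import PosteriorFit
from .synthesis import SimulatedDataset

__all__ = [
    "mean_absolute_bias",
    "loo_ic",
    "loo_compare",
    "dataset_recovery",
    "recovery_summary",
]

#: pareto-k value above which a pointwise PSIS estimate is unreliable
PARETO_K_WARN = 0.7


def mean_absolute_bias(estimates, truths) -> float:
    """Mean of |estimate - truth| over aligned parameter vectors."""
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if est.size != tru.size:
        raise ValueError(f"length mismatch: {est.size} estimates vs {tru.size} truths")
    return float(np.mean(np.abs(est - tru)))


@dataclass
class LooResult:
    """LOO information criterion (deviance scale) with standard error."""

    loo: float
    se: float
    p_loo: float
    n_high_pareto_k: int
    n_obs: int

    @property
    def reliable(self) -> bool:
        return self.n_high_pareto_k == 0


def loo_ic(fit: PosteriorFit, max_draws_per_chain: int = 250) -> LooResult:
    """PSIS-LOO of a fitted model on the deviance scale (-2 * elpd).

    A count of observations with Pareto-k above 0.7 is reported as
    warning metadata rather than raised, matching how practitioners
    treat PSIS diagnostics.
    """
    idata = fit.loo_inferencedata(max_draws_per_chain)
    # relative efficiency of the MCMC draws from the fit's own diagnostics
    # (arviz otherwise needs the full posterior group attached)
    if fit.diagnostics is not None and len(fit.diagnostics):
        total = np.prod(next(iter(fit.draws.values())).shape[:2])
        reff = float(min(1.0, fit.diagnostics["ess_bulk"].mean() / total))
    else:
        reff = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True, scale="deviance", reff=reff)
    k = np.asarray(res.pareto_k)
    return LooResult(
        loo=float(res.elpd_loo),
        se=float(res.se),
        p_loo=float(res.p_loo),
        n_high_pareto_k=int(np.sum(k > PARETO_K_WARN)),
        n_obs=k.size,
    )


def loo_compare(fits: dict[str, PosteriorFit]) -> pd.DataFrame:
    """Compare models fitted to the same observations by PSIS-LOO.

    Returns one row per model with columns ``loo`` (deviance scale),
    ``se``, ``p_loo``, ``n_high_pareto_k`` and ``best`` (smallest LOO).
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = None
    rows = {}
    for name, fit in fits.items():
        res = loo_ic(fit)
        if n_obs is None:
            n_obs = res.n_obs
        elif res.n_obs != n_obs:
            raise ValueError("fits cover different observation sets")
        rows[name] = res
    table = pd.DataFrame(
        {
            "loo": {k: r.loo for k, r in rows.items()},
            "se": {k: r.se for k, r in rows.items()},
            "p_loo": {k: r.p_loo for k, r in rows.items()},
            "n_high_pareto_k": {k: r.n_high_pareto_k for k, r in rows.items()},
        }
    )
    table["best"] = table["loo"] == table["loo"].min()
    table.attrs["scale"] = "deviance"
    return table


# mapping of draw names to generation-side item columns, per family
_ITEM_FAMILIES = {
    "log_lambda1": ("lambda1", np.exp),
    "log_alpha": ("alpha", np.exp),
    "log_lambda2": ("lambda2", np.exp),
    "log_alpha1": ("alpha1", np.exp),
    "log_alpha2": ("alpha2", np.exp),
    "log_alpha3": ("alpha3", np.exp),
    "log_alpha4": ("alpha4", np.exp),
    "log_lambda": ("lambda", np.exp),
    "delta": ("delta", None),
}


def dataset_recovery(fit: PosteriorFit, dataset: SimulatedDataset) -> dict[str, float]:
    """MAB per parameter family for one fitted simulated dataset.

    Person families are keyed by trait name (theta, eta, ...); the
    category intercepts of all pseudo-items pool into a single ``tau``
    entry, matching how recovery tables group them.
    """
    eap = fit.eap()
    out: dict[str, float] = {}
    for trait in dataset.persons.columns:
        if trait in eap:
            out[trait] = mean_absolute_bias(eap[trait], dataset.persons[trait])
    for name, (col, tf) in _ITEM_FAMILIES.items():
        if name in eap and col in dataset.items:
            est = eap[name]
            est = est[:, 0] if est.ndim == 2 else est
            if tf is not None:
                est = tf(est)
            out[col] = mean_absolute_bias(est, dataset.items[col])
    tau_est, tau_true = [], []
    for name in sorted(eap):
        if name.startswith("tau"):
            node = name[3:]
            est = np.atleast_2d(eap[name])
            for i in range(est.shape[0]):
                for k in range(est.shape[1]):
                    key = f"tau{node}[{i},{k + 1}]"
                    if key in dataset.params:
                        tau_est.append(est[i, k])
                        tau_true.append(dataset.params[key])
    if tau_est:
        out["tau"] = mean_absolute_bias(tau_est, tau_true)
    return out


def recovery_summary(
    grid_results: pd.DataFrame,
    mab_over: tuple[str, ...] = ("N",),
    loo_over: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a simulation grid into recovery and comparison tables.

    ``grid_results`` holds one row per (generating model, fitted model,
    replication, condition) with MAB columns (``mab_<family>``), ``loo``
    and ``loo_se``.  The recovery table averages MAB over replications
    and over the axes in ``mab_over`` (conditions keep the remaining
    axes as columns); the comparison table averages LOO within each
    condition and reports the proportion of replications in which each
    fitted model attained the smallest LOO.  Aggregation axes are
    recorded in ``DataFrame.attrs``.  Incomplete cells (a replication
    missing some fitted model) are dropped from the proportion with a
    warning.
    """
    df = grid_results.copy()
    required = {"generating", "fitted", "replication"}
    if not required.issubset(df.columns):
        raise ValueError(f"grid results need columns {sorted(required)}")
    cond_axes = [c for c in ("N", "I") if c in df.columns]

    mab_cols = [c for c in df.columns if c.startswith("mab_")]
    rec_axes = [c for c in cond_axes if c not in mab_over]
    recovery = (
        df.groupby(["generating", "fitted"] + rec_axes, sort=False)[mab_cols]
        .mean()
        .reset_index()
    )
    recovery.attrs["averaged_over"] = tuple(mab_over) + ("replication",)

    comparison = pd.DataFrame()
    if "loo" in df.columns:
        loo_axes = [c for c in cond_axes if c not in loo_over]
        group = ["generating"] + loo_axes
        counts = df.groupby(group + ["replication"])["fitted"].count()
        n_models = df.groupby(group)["fitted"].nunique()
        best_rows = []
        for key, sub in df.groupby(group + ["replication"]):
            if sub["fitted"].nunique() < n_models.loc[key[: len(group)] if len(group) > 1 else key[0]]:
                warnings.warn(f"incomplete grid cell {key}; skipped in proportions")
                continue
            b = sub.loc[sub["loo"].idxmin(), "fitted"]
            for f in sub["fitted"]:
                best_rows.append((*key, f, 1.0 if f == b else 0.0))
        best = pd.DataFrame(best_rows, columns=group + ["replication", "fitted", "is_best"])
        comparison = (
            df.merge(best, on=group + ["replication", "fitted"], how="left")
            .groupby(group + ["fitted"], sort=False)
            .agg(loo=("loo", "mean"), se=("loo_se", "mean"), prop_best=("is_best", "mean"))
            .reset_index()
        )
        comparison.attrs["averaged_over"] = tuple(loo_over) + ("replication",)
    return recovery, comparison
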