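"""Joint modeling of five-point responses and item-level response times.

Response times carry information about the response process: heuristic,
response-style-driven category choices tend to be fast, and a large
person-item distance on the latent continuum makes the agree/disagree
decision easy (speed-distance hypothesis).  The joint model couples the
midscale-family IRTree with a linear mixed model on log response times:

    log RT_vi = g000 + (g100 + g110 * eta1_v) * X1_vi
              + (g200 + g220 * eta2_v) * Xext_vi
              + g011 * |theta_v - beta2_i| + u_v + u_i + eps_vi

where X1 indicates a midscale response, Xext an extreme response on
either side (the two extreme pseudo-items share one coefficient), u_v
and u_i are random person and item intercepts, and |theta - beta2| is
the same person-item distance that drives the ideal-point process of
the midscale pseudo-item.  Estimation is one-step: a single posterior
covers IRTree and RT parameters, so the response-style levels entering
the RT slopes are never plug-in scores.  A two-step mode (RT model on
frozen EAPs) exists for diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    MidscaleFamily,
    PosteriorFit,
    PriorSpec,
    SamplerConfig,
    fit_tree_model,
)
from .tree import build_model_midscale

__all__ = [
    "RTCoefficients",
    "build_rt_design",
    "fit_joint_rt_model",
    "fit_rt_two_step",
    "rts_long_to_wide",
]

_GAMMA_NAMES = ("gamma_000", "gamma_100", "gamma_200", "gamma_110", "gamma_220", "gamma_011")
# sampled gamma layout is [intercept, X1, Xext, X1*eta1, Xext*eta2, dist]
_DRAW_COLUMN = {"gamma_000": 0, "gamma_100": 1, "gamma_200": 2,
                "gamma_110": 3, "gamma_220": 4, "gamma_011": 5}


def build_rt_design(responses) -> dict[str, np.ndarray]:
    """Manifest indicator matrices from five-point responses.

    ``x1`` flags the middle category (Y = 2); ``extreme`` flags the
    outermost category on either side (Y = 0 or Y = 4) — both extreme
    pseudo-items share one RT coefficient.  Respondent-missing responses
    (negative codes) yield zero indicators.
    """
    y = np.asarray(responses)
    if np.any(y >= 5):
        raise ValueError("the RT design is defined for five-point responses (0..4)")
    observed = y >= 0
    return {
        "x1": ((y == 2) & observed).astype(int),
        "extreme": (((y == 0) | (y == 4)) & observed).astype(int),
        "observed": observed,
    }


@dataclass
class RTCoefficients:
    """Fixed effects and variance components of the log-RT mixed model."""

    estimates: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    sd_person: float
    sd_item: float
    sd_residual: float

    def excludes_zero(self, name: str) -> bool:
        """True if the 95% credible interval of a fixed effect excludes 0."""
        return (self.ci_lower[name] > 0) or (self.ci_upper[name] < 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (n, self.estimates[n], self.ci_lower[n], self.ci_upper[n])
            for n in _GAMMA_NAMES
        ]
        return pd.DataFrame(rows, columns=["coefficient", "estimate", "ci_2.5", "ci_97.5"])


def _coefficients_from_fit(fit: PosteriorFit) -> RTCoefficients:
    g = fit.draws["gamma"].reshape(-1, 6)
    est, lo, hi = {}, {}, {}
    for name, col in _DRAW_COLUMN.items():
        est[name] = float(g[:, col].mean())
        lo[name], hi[name] = (float(q) for q in np.percentile(g[:, col], [2.5, 97.5]))
    sds = np.exp(fit.draws["log_sigma_rt"].reshape(-1, 3)).mean(axis=0)
    return RTCoefficients(
        estimates=est, ci_lower=lo, ci_upper=hi,
        sd_person=float(sds[0]), sd_item=float(sds[1]), sd_residual=float(sds[2]),
    )


def fit_joint_rt_model(
    responses,
    rts,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    warm_start: bool = True,
) -> tuple[PosteriorFit, RTCoefficients]:
    """One-step joint fit of the midscale IRTree and the log-RT mixed model.

    ``rts`` is a persons x items matrix of response times in seconds
    (NaN or nonpositive entries are treated as missing pairwise).  The
    midscale ideal-point location is tied to the agreement threshold, so
    the latent continuum needs no orientation template.  Returns the
    posterior fit plus the RT coefficient summary with 95% credible
    intervals.
    """
    y = np.asarray(responses)
    spec = build_model_midscale(y.shape[1])
    fit = fit_tree_model(y, spec, priors=priors, config=config, rts=np.asarray(rts, float),
                         warm_start=warm_start)
    return fit, _coefficients_from_fit(fit)


def fit_rt_two_step(
    responses,
    rts,
    response_fit: PosteriorFit,
    n_iter: int = 2000,
    seed: int = 0,
    priors: PriorSpec | None = None,
) -> RTCoefficients:
    """Diagnostic two-step fit: RT mixed model on frozen response EAPs.

    The IRTree person parameters and the person-item distance are fixed
    at the EAPs of a response-only fit; only the mixed-model blocks
    (coefficients, random intercepts, variance components) are sampled.
    This reproduces the classical plug-in approach the one-step model is
    designed to improve on, and is useful to quantify how much the
    plug-in step attenuates the response-style slopes.
    """
    family = MidscaleFamily(np.asarray(responses), rts=np.asarray(rts, float),
                            priors=priors or PriorSpec())
    params = family.init_params()
    eap = response_fit.eap()
    for k in ("theta", "eta1", "eta2", "log_alpha2", "tau2"):
        params[k] = np.asarray(eap[k], dtype=float)
    rng = np.random.default_rng(seed)
    keep = {"gamma": [], "log_sigma_rt": []}
    for t in range(n_iter):
        family.extra_updates(params, rng, {})
        if t >= n_iter // 2:
            keep["gamma"].append(params["gamma"].copy())
            keep["log_sigma_rt"].append(params["log_sigma_rt"].copy())
    draws = {k: np.asarray(v)[None] for k, v in keep.items()}
    pseudo = PosteriorFit(draws=draws, family=family, config=SamplerConfig(seed=seed))
    return _coefficients_from_fit(pseudo)


def rts_long_to_wide(long: pd.DataFrame, n_persons: int, n_items: int) -> np.ndarray:
    """(person_id, item_id, rt_seconds) long CSV rows -> persons x items matrix."""
    out = np.full((n_persons, n_items), np.nan)
    out[long["person_id"].to_numpy(int), long["item_id"].to_numpy(int)] = (
        long["rt_seconds"].to_numpy(float)
    )
    return out
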