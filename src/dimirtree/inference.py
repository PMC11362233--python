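"""Bayesian estimation of IRTree models with co-occurring-process nodes.

The estimation-facing parameterization is (discriminations, locations,
category intercepts tau): process-specific thresholds are not separately
identified and exist only on the data-generation side.  Trait scales are
fixed N(0, 1); discriminations get Gamma(1.5, 1.5) (shape-rate) priors;
intercepts get N(0, 5); ideal-point locations delta get a hierarchical
normal prior with N(0, 5) hyperprior on the mean and half-normal(5) on
the sd.

The sampling engine is an adaptive random-walk Metropolis-within-Gibbs
sampler, fully vectorized: person parameters are proposed jointly per
person and accepted in parallel (persons are conditionally independent
given item parameters), item-parameter coordinates are proposed and
accepted in parallel across items, and hyperparameters (plus, in the
joint response-time model, the mixed-model coefficients and random
effects) get Gibbs or scalar Metropolis updates.  Proposal scales are
tuned during warmup by Robbins-Monro stochastic approximation and frozen
afterwards.  Any engine producing tagged posterior draws plus
per-observation log-likelihood would satisfy the same interface.

Estimation protocol (see :func:`fit_tree_model`): a constrained model
with discriminations and intercepts shared across items is fitted first
(one chain, 500 warmup + 500 draws) and its EAP estimates, expanded
item-wise, initialize the full model.  Ideal-point models are only
identified up to a joint sign flip of (theta, delta); the orientation is
fixed through the initial values of delta (a user-supplied sign template,
``+/-1`` per item) and checked after fitting — a fit that converged to
the mirrored solution is re-fitted with a different seed.  Four chains
are run with 500 warmup + 1000 post-warmup draws; if any parameter has
R-hat > 1.05 or bulk/tail effective sample size < 100, sampling is
extended in steps of 500 up to 3000 post-warmup draws per chain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._kernels import agreement_intensity_ll, midscale_ll
from .tree import MISSING, TreeMapping, TreeModelSpec, build_model_ideal_ers, build_model_midscale

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "PosteriorFit",
    "fit_constrained_warmstart",
    "fix_orientation",
    "fit_model",
    "fit_tree_model",
    "eap_estimates",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters (Gamma is shape-rate; normals are mean-sd)."""

    disc_shape: float = 1.5
    disc_rate: float = 1.5
    tau_sd: float = 5.0
    delta_mean_sd: float = 5.0
    delta_sd_scale: float = 5.0
    rt_coef_sd: float = 5.0
    rt_sd_scale: float = 5.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if not np.isfinite(getattr(self, f.name)) or getattr(self, f.name) <= 0:
                raise ValueError(f"prior hyperparameter {f.name} must be positive and finite")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 500
    draws: int = 1000
    extend_step: int = 500
    max_draws: int = 3000
    rhat_threshold: float = 1.05
    min_ess: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_draws < self.draws:
            raise ValueError("max_draws must be >= draws")
        if min(self.chains, self.warmup, self.draws, self.extend_step) <= 0:
            raise ValueError("chains, warmup, draws and extend_step must be positive")


# ---------------------------------------------------------------------------
# model families: data layout + vectorized log-likelihood
# ---------------------------------------------------------------------------

def _decompose(responses: np.ndarray, mapping: TreeMapping) -> np.ndarray:
    """(N, I, H) pseudo-responses; respondent-missing responses become MISSING."""
    y = np.asarray(responses)
    out = np.full((*y.shape, mapping.n_nodes), MISSING, dtype=int)
    valid = (y >= 0) & (y < mapping.n_categories)
    out[valid] = mapping.table[y[valid]]
    return out


def _bc(arr: np.ndarray, n_items: int) -> np.ndarray:
    """Broadcast a (1, ...) constrained parameter array to all items."""
    arr = np.asarray(arr, dtype=float)
    shape = (n_items, *arr.shape[1:])
    return np.ascontiguousarray(np.broadcast_to(arr, shape))


class _Family:
    """Shared machinery: parameter bookkeeping for the MH sampler."""

    kind: str
    person_names: tuple[str, ...]
    #: (name, n_columns) of item-level parameter arrays, in update order
    item_families: tuple[tuple[str, int], ...]
    #: item families whose update changes the RT likelihood
    rt_sensitive: frozenset = frozenset()
    has_rt: bool = False
    #: item coordinates that get a dedicated slice move (slow mixers)
    slice_coord_names: tuple[str, ...] = ()

    def __init__(self, responses, mapping, priors, constrained=False, fixed=()):
        self.mapping = mapping
        self.priors = priors
        self.constrained = bool(constrained)
        self.fixed = frozenset(fixed)  # item families held at their initial values
        y = np.asarray(responses)
        if y.ndim != 2:
            raise ValueError("responses must be a persons x items matrix")
        self.N, self.I = y.shape
        self.X = _decompose(y, mapping)
        self.Xc = [np.ascontiguousarray(self.X[..., h]) for h in range(mapping.n_nodes)]
        self.observed = np.asarray(y) >= 0

    @property
    def item_dim(self) -> int:
        return 1 if self.constrained else self.I

    # subclasses define: init_params, response_loglik, item_logprior,
    # person_logprior, extra_updates

    def response_loglik(self, params) -> np.ndarray:
        raise NotImplementedError

    def rt_loglik(self, params) -> np.ndarray:
        raise NotImplementedError

    def loglik(self, params) -> np.ndarray:
        ll = self.response_loglik(params)
        if self.has_rt:
            ll = ll + self.rt_loglik(params)
        return ll

    def item_logprior(self, name: str, value: np.ndarray, params) -> np.ndarray:
        p = self.priors
        if name.startswith("log_"):
            x = value  # log of a Gamma(shape, rate) discrimination + Jacobian
            return p.disc_shape * x - p.disc_rate * np.exp(x)
        if name.startswith("tau"):
            return -0.5 * np.sum(value**2, axis=-1) / p.tau_sd**2
        if name == "delta":
            mu = params["mu_delta"][0]
            sd = np.exp(params["log_sigma_delta"][0])
            return -0.5 * ((value[:, 0] - mu) / sd) ** 2 - np.log(sd)
        raise KeyError(name)

    def person_logprior(self, persons: np.ndarray) -> np.ndarray:
        return -0.5 * np.sum(persons**2, axis=1)

    def extra_updates(self, params, rng, scales) -> bool:
        """Gibbs/MH updates outside the generic blocks; True if ll changed."""
        return False


class AgreementIntensityFamily(_Family):
    """Agreement + two intensity nodes on a 4- or 6-point scale.

    ``variant`` selects the intensity parameterization: ``co_occurring``
    (ERS dominance + trait ideal point), ``ers_only`` or ``trait_only``.
    """

    def __init__(self, responses, scale_points=6, variant="co_occurring",
                 priors=None, constrained=False, fixed=()):
        spec = build_model_ideal_ers(scale_points, 1, intensity=variant)
        super().__init__(responses, spec.mapping, priors or PriorSpec(), constrained, fixed)
        self.scale_points = scale_points
        self.variant = variant
        self.kind = f"ideal_ers_{variant}_{scale_points}pt"
        self.kh = scale_points // 2 - 1
        self.has_ers = variant in ("co_occurring", "ers_only")
        self.has_trait_intensity = variant in ("co_occurring", "trait_only")
        self.person_names = ("theta", "eta") if self.has_ers else ("theta",)
        fams = [("log_lambda1", 1)]
        if self.has_ers:
            fams.append(("log_alpha", 1))
        if self.has_trait_intensity:
            fams.append(("log_lambda2", 1))
        fams += [("delta", 1), ("tau1", 1), ("tau2", self.kh), ("tau3", self.kh)]
        self.item_families = tuple(fams)
        self.s_int = np.arange(self.kh + 1, dtype=float)
        self.m_int = 2 * self.kh + 1
        self.s_bin = np.array([0.0, 1.0])
        self.slice_coord_names = ("delta",)

    def init_params(self, sign_template=None) -> dict[str, np.ndarray]:
        d = self.item_dim
        params = {
            "theta": np.zeros(self.N),
            "log_lambda1": np.zeros(d),
            "delta": np.ones((self.I, 1)),
            "tau1": np.zeros((d, 1)),
            "tau2": np.zeros((d, self.kh)),
            "tau3": np.zeros((d, self.kh)),
            "mu_delta": np.zeros(1),
            "log_sigma_delta": np.zeros(1),
        }
        if self.has_ers:
            params["eta"] = np.zeros(self.N)
            params["log_alpha"] = np.zeros(d)
        if self.has_trait_intensity:
            params["log_lambda2"] = np.zeros(d)
        if sign_template is not None:
            params = fix_orientation(params, sign_template)
        return params

    def response_loglik(self, params) -> np.ndarray:
        zeros_i = np.zeros(self.I)
        zeros_n = np.zeros(self.N)
        out = np.empty((self.N, self.I))
        agreement_intensity_ll(
            np.ascontiguousarray(params["theta"]),
            np.ascontiguousarray(params["eta"]) if self.has_ers else zeros_n,
            _bc(np.exp(params["log_lambda1"]), self.I),
            _bc(np.exp(params["log_alpha"]), self.I) if self.has_ers else zeros_i,
            _bc(np.exp(params["log_lambda2"]), self.I) if self.has_trait_intensity else zeros_i,
            np.ascontiguousarray(params["delta"][:, 0]),
            _bc(params["tau1"], self.I),
            _bc(params["tau2"], self.I),
            _bc(params["tau3"], self.I),
            self.Xc[0], self.Xc[1], self.Xc[2], out,
        )
        return out

    def extra_updates(self, params, rng, scales) -> bool:
        if "delta" not in self.fixed:
            _update_delta_hyper(params, self.priors, rng, scales)
        return False


class MidscaleFamily(_Family):
    """Five-point midscale / agreement / extreme model, optionally joint with RTs.

    The ideal-point location of the midscale node is tied to the agreement
    threshold ``beta2 = tau2 / alpha2``, which is identified by the
    dominance modeling, so no orientation fixing is needed.
    """

    person_names = ("theta", "eta1", "eta2")

    def __init__(self, responses, rts=None, priors=None, constrained=False,
                 trait_midscale="ideal_point"):
        spec = build_model_midscale(1, trait_midscale=trait_midscale)
        super().__init__(responses, spec.mapping, priors or PriorSpec(), constrained)
        self.trait_midscale = trait_midscale
        self.kind = f"midscale_{trait_midscale}" + ("_rt" if rts is not None else "")
        self.item_families = tuple(
            (n, 1) for n in ("log_alpha1", "log_lambda", "log_alpha2",
                             "log_alpha3", "log_alpha4", "tau1", "tau2", "tau3", "tau4")
        )
        self.s_bin = np.array([0.0, 1.0])
        y = np.asarray(responses)
        self.x1 = (y == 2) & self.observed
        self.xext = ((y == 0) | (y == 4)) & self.observed
        self.rts = None
        if rts is not None:
            rts = np.asarray(rts, dtype=float)
            if rts.shape != y.shape:
                raise ValueError("RT matrix must align with the response matrix")
            self.rt_obs = self.observed & np.isfinite(rts) & (rts > 0)
            self.log_rt = np.where(self.rt_obs, np.log(np.where(self.rt_obs, rts, 1.0)), 0.0)
            self.rts = rts
            self.has_rt = True
            self.rt_sensitive = frozenset({"log_alpha2", "tau2"})

    def init_params(self, sign_template=None) -> dict[str, np.ndarray]:
        d = self.item_dim
        params = {
            "theta": np.zeros(self.N),
            "eta1": np.zeros(self.N),
            "eta2": np.zeros(self.N),
        }
        for n in ("log_alpha1", "log_lambda", "log_alpha2", "log_alpha3", "log_alpha4"):
            params[n] = np.zeros(d)
        for n in ("tau1", "tau2", "tau3", "tau4"):
            params[n] = np.zeros((d, 1))
        if self.rts is not None:
            lr = self.log_rt[self.rt_obs]
            params["gamma"] = np.array([lr.mean(), 0, 0, 0, 0, 0])
            params["u_person"] = np.zeros(self.N)
            params["u_item"] = np.zeros(self.I)
            params["log_sigma_rt"] = np.log([0.1, 0.1, max(lr.std(), 0.1)])
        return params

    def _beta2(self, params) -> np.ndarray:
        return _bc(params["tau2"], self.I)[:, 0] / _bc(np.exp(params["log_alpha2"]), self.I)

    def response_loglik(self, params) -> np.ndarray:
        out = np.empty((self.N, self.I))
        midscale_ll(
            np.ascontiguousarray(params["theta"]),
            np.ascontiguousarray(params["eta1"]),
            np.ascontiguousarray(params["eta2"]),
            _bc(np.exp(params["log_alpha1"]), self.I),
            _bc(np.exp(params["log_lambda"]), self.I),
            _bc(np.exp(params["log_alpha2"]), self.I),
            _bc(np.exp(params["log_alpha3"]), self.I),
            _bc(np.exp(params["log_alpha4"]), self.I),
            _bc(params["tau1"], self.I),
            _bc(params["tau2"], self.I),
            _bc(params["tau3"], self.I),
            _bc(params["tau4"], self.I),
            self.trait_midscale == "ideal_point",
            self.Xc[0], self.Xc[1], self.Xc[2], self.Xc[3], out,
        )
        return out

    # -- response-time block -------------------------------------------------

    def _rt_design(self, params) -> np.ndarray:
        """(N, I, 6) regressors: 1, X1, Xext, X1*eta1, Xext*eta2, |theta-beta2|."""
        dist = np.abs(params["theta"][:, None] - self._beta2(params)[None, :])
        x1 = self.x1.astype(float)
        xe = self.xext.astype(float)
        return np.stack(
            [np.ones_like(dist), x1, xe, x1 * params["eta1"][:, None],
             xe * params["eta2"][:, None], dist], axis=-1)

    def rt_loglik(self, params) -> np.ndarray:
        z = self._rt_design(params)
        mean = z @ params["gamma"] + params["u_person"][:, None] + params["u_item"][None, :]
        sd = np.exp(params["log_sigma_rt"][2])
        ll = -0.5 * ((self.log_rt - mean) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
        return np.where(self.rt_obs, ll, 0.0)

    def extra_updates(self, params, rng, scales) -> bool:
        if self.rts is None:
            return False
        p = self.priors
        obs = self.rt_obs
        z = self._rt_design(params)[obs]  # (n_obs, 6)
        y = self.log_rt[obs]
        sd_p, sd_i, sd_e = np.exp(params["log_sigma_rt"])
        rows, cols = np.nonzero(obs)

        # gamma | rest: conjugate normal regression
        resid = y - params["u_person"][rows] - params["u_item"][cols]
        prec = z.T @ z / sd_e**2 + np.eye(6) / p.rt_coef_sd**2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, z.T @ resid / sd_e**2)
        params["gamma"] = mean + np.linalg.solve(chol.T, rng.standard_normal(6))

        # random intercepts | rest: conjugate per person / item
        fitted = z @ params["gamma"]
        r = y - fitted
        for key, idx, size, sd_u in (("u_person", rows, self.N, sd_p),
                                     ("u_item", cols, self.I, sd_i)):
            other = params["u_item"][cols] if key == "u_person" else params["u_person"][rows]
            rr = r - other
            n_k = np.bincount(idx, minlength=size)
            s_k = np.bincount(idx, weights=rr, minlength=size)
            var = 1.0 / (n_k / sd_e**2 + 1.0 / sd_u**2)
            params[key] = var * s_k / sd_e**2 + np.sqrt(var) * rng.standard_normal(size)

        # variance components: scalar MH on the log scale, half-normal priors
        def halfn(s):
            return -0.5 * (s / p.rt_sd_scale) ** 2

        eps = r - params["u_person"][rows] - params["u_item"][cols]
        targets = [
            lambda s: np.sum(-0.5 * (params["u_person"] / s) ** 2 - np.log(s)) + halfn(s),
            lambda s: np.sum(-0.5 * (params["u_item"] / s) ** 2 - np.log(s)) + halfn(s),
            lambda s: np.sum(-0.5 * (eps / s) ** 2 - np.log(s)) + halfn(s),
        ]
        ls = params["log_sigma_rt"]
        for j, target in enumerate(targets):
            prop = ls[j] + scales.get(("log_sigma_rt", j), 0.3) * rng.standard_normal()
            # +x terms are the log-scale Jacobian
            delta = (target(np.exp(prop)) + prop) - (target(np.exp(ls[j])) + ls[j])
            if np.log(rng.random()) < delta:
                ls[j] = prop
        return True


def _update_delta_hyper(params, priors, rng, scales) -> None:
    """Gibbs for mu_delta, scalar MH for log_sigma_delta."""
    delta = params["delta"][:, 0]
    sd = np.exp(params["log_sigma_delta"][0])
    prec = delta.size / sd**2 + 1.0 / priors.delta_mean_sd**2
    mean = delta.sum() / sd**2 / prec
    params["mu_delta"][0] = mean + rng.standard_normal() / np.sqrt(prec)

    mu = params["mu_delta"][0]

    def target(ls):
        s = np.exp(ls)
        return (-delta.size * ls - 0.5 * np.sum((delta - mu) ** 2) / s**2
                - 0.5 * (s / priors.delta_sd_scale) ** 2 + ls)  # + Jacobian

    cur = params["log_sigma_delta"][0]
    prop = cur + scales.get(("log_sigma_delta", 0), 0.3) * rng.standard_normal()
    if np.log(rng.random()) < target(prop) - target(cur):
        params["log_sigma_delta"][0] = prop


# ---------------------------------------------------------------------------
# the adaptive Metropolis-within-Gibbs engine
# ---------------------------------------------------------------------------

class _ChainState:
    """One MCMC chain: person block, per-item block, and auxiliary updates.

    Item parameters are updated jointly per item with a multivariate
    random-walk proposal whose covariance is learned during warmup from
    the chain history (adaptive Metropolis); the global scale is tuned by
    Robbins-Monro toward a 0.23 acceptance rate and everything is frozen
    after warmup.  The constrained (item-homogeneous) model falls back to
    coordinate-wise updates, where blocking would couple the shared
    parameters with the item-specific locations.
    """

    def __init__(self, family: _Family, params: dict[str, np.ndarray], rng):
        self.family = family
        self.params = {k: np.array(v, dtype=float) for k, v in params.items()}
        self.rng = rng
        self.ll_resp = family.response_loglik(self.params)
        self.ll_rt = family.rt_loglik(self.params) if family.has_rt else None
        self.person_scale = np.full(family.N, 0.4)
        # layout of the per-item block: (family name, column within family)
        self.block_coords = [
            (name, j) for name, ncol in family.item_families
            for j in range(ncol) if name not in family.fixed
        ]
        d = len(self.block_coords)
        i_n = family.I
        self.block_dim = d
        self.block_logscale = np.zeros(i_n)
        self.block_mean = np.zeros((i_n, d))
        self.block_cov = np.zeros((i_n, d, d))
        self.block_chol = np.tile(0.15 * np.eye(d), (i_n, 1, 1))
        self.block_count = 0
        self.ridge_dir: list[np.ndarray] | None = None
        self.ridge_width: list[np.ndarray] | None = None
        # coordinate-wise scales for the constrained model
        self.item_scales = {
            (name, j): np.full(family.I if name == "delta" else family.item_dim, 0.25)
            for name, ncol in family.item_families
            for j in range(ncol)
        }
        self.misc_scales: dict = {}
        self.t = 0

    # -- helpers -----------------------------------------------------------

    def _gather_block(self) -> np.ndarray:
        cols = []
        for name, j in self.block_coords:
            arr = self.params[name]
            cols.append(arr[:, j] if arr.ndim == 2 else arr)
        return np.column_stack(cols)

    def _scatter_block(self, mat: np.ndarray, into: dict) -> None:
        for k, (name, j) in enumerate(self.block_coords):
            arr = np.array(into[name])
            if arr.ndim == 2:
                arr[:, j] = mat[:, k]
            else:
                arr = mat[:, k]
            into[name] = arr

    def _block_prior(self, mat: np.ndarray, params) -> np.ndarray:
        total = np.zeros(mat.shape[0])
        k = 0
        for name, ncol in self.family.item_families:
            if name in self.family.fixed:
                continue
            val = mat[:, k:k + ncol]
            if name == "delta" or name.startswith("tau"):
                total += np.asarray(self.family.item_logprior(name, val, params))
            else:
                total += np.asarray(self.family.item_logprior(name, val[:, 0], params))
            k += ncol
        return total

    def _person_update(self, lr: float) -> None:
        fam, params, rng = self.family, self.params, self.rng
        names = fam.person_names
        cur = np.column_stack([params[n] for n in names])
        prop = cur + self.person_scale[:, None] * rng.standard_normal(cur.shape)
        trial = dict(params)
        for j, n in enumerate(names):
            trial[n] = prop[:, j]
        resp_new = fam.response_loglik(trial)
        d_post = (resp_new.sum(axis=1) - self.ll_resp.sum(axis=1)
                  + fam.person_logprior(prop) - fam.person_logprior(cur))
        rt_new = None
        if fam.has_rt:
            rt_new = fam.rt_loglik(trial)
            d_post = d_post + rt_new.sum(axis=1) - self.ll_rt.sum(axis=1)
        acc = np.log(rng.random(fam.N)) < d_post
        for j, n in enumerate(names):
            params[n] = np.where(acc, prop[:, j], cur[:, j])
        self.ll_resp = np.where(acc[:, None], resp_new, self.ll_resp)
        if fam.has_rt:
            self.ll_rt = np.where(acc[:, None], rt_new, self.ll_rt)
        if lr:
            self.person_scale *= np.exp(lr * (acc - 0.30))

    def _item_block_update(self, lr: float) -> None:
        fam, params, rng = self.family, self.params, self.rng
        cur = self._gather_block()
        z = rng.standard_normal(cur.shape)
        step = np.einsum("idk,ik->id", self.block_chol, z)
        # 10 % of proposals are 3x wider: tail exploration for skewed
        # posteriors (boundary item locations)
        wide = np.where(rng.random(cur.shape[0]) < 0.1, 3.0, 1.0)
        prop = cur + (wide * np.exp(self.block_logscale))[:, None] * step
        trial = dict(params)
        self._scatter_block(prop, trial)
        resp_new = fam.response_loglik(trial)
        d_ll = (resp_new - self.ll_resp).sum(axis=0)
        rt_new = None
        if fam.has_rt:
            rt_new = fam.rt_loglik(trial)
            d_ll = d_ll + (rt_new - self.ll_rt).sum(axis=0)
        d_post = d_ll + self._block_prior(prop, params) - self._block_prior(cur, params)
        acc = np.log(rng.random(fam.I)) < d_post
        new = np.where(acc[:, None], prop, cur)
        self._scatter_block(new, params)
        self.ll_resp = np.where(acc[None, :], resp_new, self.ll_resp)
        if fam.has_rt:
            self.ll_rt = np.where(acc[None, :], rt_new, self.ll_rt)
        if lr:
            self.block_logscale += lr * (acc - 0.23)
            self.block_count += 1
            n = self.block_count
            delta_old = new - self.block_mean
            self.block_mean += delta_old / n
            delta_new = new - self.block_mean
            self.block_cov += (np.einsum("id,ie->ide", delta_old, delta_new)
                               - self.block_cov) / n
            if n >= 100 and n % 25 == 0:
                d = self.block_dim
                reg = self.block_cov + 1e-6 * np.eye(d)
                try:
                    self.block_chol = np.linalg.cholesky(2.38**2 / d * reg)
                except np.linalg.LinAlgError:
                    pass
                else:
                    vals, vecs = np.linalg.eigh(reg)
                    # widest posterior direction per item, plus the
                    # coordinate directions that need dedicated moves
                    dirs = [vecs[:, :, -1]]
                    widths = [2.0 * np.sqrt(vals[:, -1])]
                    diag = np.sqrt(np.maximum(
                        reg[:, np.arange(d), np.arange(d)], 1e-12))
                    for name in self.family.slice_coord_names:
                        if (name, 0) in self.block_coords:
                            k = self.block_coords.index((name, 0))
                            e = np.zeros((self.family.I, d))
                            e[:, k] = 1.0
                            dirs.append(e)
                            widths.append(2.0 * diag[:, k])
                    self.ridge_dir = dirs
                    self.ridge_width = widths

    def _item_logpost_cols(self, mat: np.ndarray) -> np.ndarray:
        """Per-item log posterior (likelihood column sums + block prior)."""
        trial = dict(self.params)
        self._scatter_block(mat, trial)
        total = self.family.response_loglik(trial).sum(axis=0)
        if self.family.has_rt:
            total = total + self.family.rt_loglik(trial).sum(axis=0)
        return total + self._block_prior(mat, self.params)

    def _item_ridge_slice(self) -> None:
        """Slice sampling along the dominant eigendirection of each item's
        adapted posterior covariance.

        Random-walk proposals mix slowly along the long, curved ridge that
        couples an ideal-point item's location with its intercepts (most
        visible for items located near the edge of the trait range); a
        slice move along that direction always lands inside the slice, so
        the ridge is traversed in O(1) moves per draw.
        """
        if self.ridge_dir is None:
            return
        for v, w in zip(self.ridge_dir, self.ridge_width):
            self._slice_along(v, w)

    def _slice_along(self, v: np.ndarray, w: np.ndarray) -> None:
        fam, rng = self.family, self.rng
        n_items = fam.I
        x0 = self._gather_block()
        f0 = self._item_logpost_cols(x0)
        height = f0 + np.log(rng.random(n_items))
        u = rng.random(n_items)
        left = -u * w
        right = left + w
        for _ in range(5):
            grow = self._item_logpost_cols(x0 + left[:, None] * v) > height
            if not grow.any():
                break
            left = np.where(grow, left - w, left)
        for _ in range(5):
            grow = self._item_logpost_cols(x0 + right[:, None] * v) > height
            if not grow.any():
                break
            right = np.where(grow, right + w, right)
        t = np.zeros(n_items)
        done = np.zeros(n_items, dtype=bool)
        # items that exhaust the shrink budget keep their current state
        for _ in range(30):
            prop = np.where(done, t, left + rng.random(n_items) * (right - left))
            ok = self._item_logpost_cols(x0 + prop[:, None] * v) > height
            t = np.where(ok & ~done, prop, t)
            shrink = ~(done | ok)
            left = np.where(shrink & (prop < 0), prop, left)
            right = np.where(shrink & (prop >= 0), prop, right)
            done |= ok
            if done.all():
                break
        new = x0 + t[:, None] * v
        self._scatter_block(new, self.params)
        self.ll_resp = self.family.response_loglik(self.params)
        if fam.has_rt:
            self.ll_rt = fam.rt_loglik(self.params)

    def _item_coordinate_update(self, lr: float) -> None:
        fam, params, rng = self.family, self.params, self.rng
        for name, ncol in fam.item_families:
            if name in fam.fixed:
                continue
            for j in range(ncol):
                scale = self.item_scales[(name, j)]
                cur_arr = params[name]
                prop_arr = cur_arr.copy()
                if prop_arr.ndim == 2:
                    prop_arr[:, j] = prop_arr[:, j] + scale * rng.standard_normal(len(scale))
                else:
                    prop_arr = prop_arr + scale * rng.standard_normal(len(scale))
                trial = dict(params)
                trial[name] = prop_arr
                resp_new = fam.response_loglik(trial)
                d_ll = (resp_new - self.ll_resp).sum(axis=0)
                touches_rt = fam.has_rt and name in fam.rt_sensitive
                rt_new = None
                if touches_rt:
                    rt_new = fam.rt_loglik(trial)
                    d_ll = d_ll + (rt_new - self.ll_rt).sum(axis=0)
                d_prior = (fam.item_logprior(name, prop_arr, params)
                           - fam.item_logprior(name, cur_arr, params))
                if fam.constrained and name != "delta":
                    d_post = np.atleast_1d(d_ll.sum() + np.sum(d_prior))
                    acc = np.log(rng.random(1)) < d_post
                    acc_items = np.repeat(acc, fam.I)
                else:
                    d_post = d_ll + np.asarray(d_prior)
                    acc = np.log(rng.random(len(d_post))) < d_post
                    acc_items = acc
                if np.any(acc):
                    params[name] = np.where(
                        (acc[:, None] if cur_arr.ndim == 2 else acc), prop_arr, cur_arr)
                    self.ll_resp = np.where(acc_items[None, :], resp_new, self.ll_resp)
                    if touches_rt:
                        self.ll_rt = np.where(acc_items[None, :], rt_new, self.ll_rt)
                if lr:
                    self.item_scales[(name, j)] = scale * np.exp(lr * (acc - 0.44))

    def step(self, adapt: bool = True) -> None:
        """One sweep: persons, item blocks, item coordinates, auxiliaries.

        Adaptation (proposal scales and block covariances) continues for
        the whole run with a learning rate decaying as t^-0.6 —
        diminishing adaptation, which preserves the stationary
        distribution while letting long runs keep refining the proposals.
        """
        fam, params, rng = self.family, self.params, self.rng
        self.t += 1
        lr = 1.0 / (self.t + 10.0) ** 0.6

        self._person_update(lr)
        if fam.constrained:
            self._item_coordinate_update(lr)
        else:
            for _ in range(4):
                self._item_block_update(lr)
            self._item_ridge_slice()
            self._item_coordinate_update(lr)
        self._person_update(lr)

        if fam.extra_updates(params, rng, self.misc_scales):
            self.ll_rt = fam.rt_loglik(params)


def _run_chain(family, inits, rng, warmup, draws, store=None, state=None):
    """Run one chain; returns (draws dict of (draws, ...), final state)."""
    if state is None:
        state = _ChainState(family, inits, rng)
        for _ in range(warmup):
            state.step(adapt=True)
    sampled = {k: np.empty((draws, *np.shape(v)), dtype=np.float64)
               for k, v in state.params.items()}
    for t in range(draws):
        state.step(adapt=False)
        for k, v in state.params.items():
            sampled[k][t] = v
    return sampled, state


def _stack_chains(chain_draws: list[dict]) -> dict[str, np.ndarray]:
    return {k: np.stack([c[k] for c in chain_draws]) for k in chain_draws[0]}


def _concat_draws(a: dict, b: dict) -> dict:
    return {k: np.concatenate([a[k], b[k]], axis=1) for k in a}


@dataclass
class PosteriorFit:
    """Tagged posterior draws plus diagnostics and bookkeeping.

    ``draws`` maps parameter names to arrays of shape (chains, draws, ...).
    """

    draws: dict[str, np.ndarray]
    family: _Family
    config: SamplerConfig
    diagnostics: pd.DataFrame | None = None
    converged: bool | None = None
    extensions: list[int] = field(default_factory=list)
    orientation_ok: bool | None = None
    warm_start: dict | None = None
    seed_used: int | None = None

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def eap(self) -> dict[str, np.ndarray]:
        """Posterior means over pooled post-warmup draws."""
        return {k: v.mean(axis=(0, 1)) for k, v in self.draws.items()}

    def to_inferencedata(self) -> az.InferenceData:
        return az.from_dict(posterior=self.draws)

    def pointwise_loglik(self, max_draws_per_chain: int = 250) -> np.ndarray:
        """(chains, draws, N, I) response log-likelihood on observed responses."""
        chains, total = next(iter(self.draws.values())).shape[:2]
        step = max(1, int(np.ceil(total / max_draws_per_chain)))
        idx = np.arange(total - 1, -1, -step)[::-1]
        out = np.empty((chains, idx.size, self.family.N, self.family.I), dtype=np.float64)
        for c in range(chains):
            for t, d in enumerate(idx):
                params = {k: v[c, d] for k, v in self.draws.items()}
                ll = self.family.response_loglik(params)
                out[c, t] = np.where(self.family.observed, ll, np.nan)
        return out

    def loo_inferencedata(self, max_draws_per_chain: int = 250) -> az.InferenceData:
        ll = self.pointwise_loglik(max_draws_per_chain)
        chains, d = ll.shape[:2]
        flat = ll.reshape(chains, d, -1)
        keep = ~np.isnan(flat[0, 0])
        return az.from_dict(log_likelihood={"y": flat[..., keep]})


def eap_estimates(fit: PosteriorFit) -> dict[str, np.ndarray]:
    """EAP point estimates: posterior mean per parameter across pooled draws."""
    return fit.eap()


def fix_orientation(inits: dict, sign_template) -> dict:
    """Impose the latent-continuum orientation on the initial values.

    ``sign_template`` holds one nonzero number per item (signs of the item
    locations, or reference delta estimates).  Fresh initial values get
    ``delta = +/-1``; if the supplied inits already carry delta estimates
    whose majority sign disagrees with the template, the (delta, theta)
    solution is flipped jointly, which leaves the likelihood unchanged.
    """
    template = np.sign(np.asarray(sign_template, dtype=float)).ravel()
    if np.any(template == 0):
        raise ValueError("sign template must not contain zeros")
    out = {k: np.array(v, dtype=float) for k, v in inits.items()}
    if "delta" not in out:
        raise KeyError("inits carry no delta to orient")
    delta = out["delta"]
    if delta.shape[0] != template.size:
        raise ValueError("sign template length must equal the item count")
    cur = delta[:, 0] if delta.ndim == 2 else delta
    if np.allclose(cur, cur[0]) and np.allclose(np.abs(cur), 1.0) or np.all(cur == 0):
        out["delta"] = template.reshape(delta.shape) * 1.0
    else:
        agree = np.mean(np.sign(cur) == template)
        if agree < 0.5:
            out["delta"] = -delta
            if "theta" in out:
                out["theta"] = -out["theta"]
    return out


def _family_for(spec: TreeModelSpec, responses, rts=None, priors=None, constrained=False):
    kind = spec.kind
    if kind.startswith("ideal_ers_"):
        variant = kind[len("ideal_ers_"):].rsplit("_", 1)[0]
        scale_points = int(kind.rsplit("_", 1)[1].rstrip("pt"))
        return AgreementIntensityFamily(responses, scale_points, variant, priors, constrained)
    if kind.startswith("midscale"):
        trait_midscale = kind.split("_", 1)[1]
        return MidscaleFamily(responses, rts=rts, priors=priors, constrained=constrained,
                              trait_midscale=trait_midscale)
    raise ValueError(f"no estimation family registered for tree kind {kind!r}")


def _diagnose(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    idata = az.from_dict(posterior=draws)
    rhat = az.rhat(idata)
    bulk = az.ess(idata, method="bulk")
    tail = az.ess(idata, method="tail")
    rows = []
    for name in draws:
        r = np.asarray(rhat[name]).ravel()
        b = np.asarray(bulk[name]).ravel()
        t = np.asarray(tail[name]).ravel()
        for j in range(r.size):
            rows.append((name if r.size == 1 else f"{name}[{j}]", r[j], b[j], t[j]))
    return pd.DataFrame(rows, columns=["param", "rhat", "ess_bulk", "ess_tail"])


def fit_constrained_warmstart(responses, spec: TreeModelSpec, config=None,
                              priors=None, sign_template=None, rts=None):
    """Fit the item-homogeneous model and expand its EAPs into full-model inits.

    Discriminations and category intercepts are shared across items
    (item locations delta stay item-specific); one chain with 500 warmup
    and 500 post-warmup iterations yields approximate EAP estimates that
    are broadcast item-wise as initial values for the full model.
    """
    config = config or SamplerConfig()
    family = _family_for(spec, responses, rts=rts, priors=priors, constrained=True)
    inits = family.init_params(sign_template=sign_template)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    sampled, _ = _run_chain(family, inits, rng, warmup=500, draws=500)
    eap = {k: v.mean(axis=0) for k, v in sampled.items()}

    full = _family_for(spec, responses, rts=rts, priors=priors, constrained=False)
    expanded = {}
    for k, v in eap.items():
        if k in dict(full.item_families).keys() and v.shape[0] == 1:
            expanded[k] = np.repeat(v, full.I, axis=0)
        else:
            expanded[k] = v
    record = {"constrained_eap": eap, "chains": 1, "warmup": 500, "draws": 500}
    return expanded, record


def fit_model(responses, spec: TreeModelSpec, priors=None, inits=None,
              config=None, rts=None) -> PosteriorFit:
    """Sample the full model, extending until convergence or ``max_draws``.

    Sampling continues in steps of ``extend_step`` until every parameter
    has R-hat <= threshold and bulk/tail ESS >= ``min_ess``, or the draw
    budget is exhausted (then ``converged`` is False).
    """
    config = config or SamplerConfig()
    family = _family_for(spec, responses, rts=rts, priors=priors)
    if inits is None:
        inits = family.init_params()
    rngs = [np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(c + 1,)))
            for c in range(config.chains)]

    chain_draws, states = [], []
    for c, rng in enumerate(rngs):
        jit = {k: np.asarray(v, float) + 0.05 * rng.standard_normal(np.shape(v))
               for k, v in inits.items()}
        sampled, state = _run_chain(family, jit, rng, config.warmup, config.draws)
        chain_draws.append(sampled)
        states.append(state)
    draws = _stack_chains(chain_draws)

    extensions: list[int] = []
    while True:
        if config.chains >= 2:
            diag = _diagnose(draws)
            ok = (diag["rhat"].max() <= config.rhat_threshold
                  and diag[["ess_bulk", "ess_tail"]].min().min() >= config.min_ess)
        else:
            diag, ok = None, True
        total = next(iter(draws.values())).shape[1]
        if ok or total + config.extend_step > config.max_draws:
            break
        more = [
            _run_chain(family, None, rng, 0, config.extend_step, state=state)[0]
            for state, rng in zip(states, rngs)
        ]
        draws = _concat_draws(draws, _stack_chains(more))
        extensions.append(config.extend_step)

    return PosteriorFit(draws=draws, family=family, config=config, diagnostics=diag,
                        converged=bool(ok) if diag is not None else None,
                        extensions=extensions, seed_used=config.seed)


def fit_tree_model(responses, spec: TreeModelSpec, sign_template=None, priors=None,
                   config=None, rts=None, warm_start=True,
                   max_orientation_refits: int = 2) -> PosteriorFit:
    """Full estimation protocol: warm start, orientation fixing, refit-on-flip."""
    config = config or SamplerConfig()
    needs_orientation = sign_template is not None
    seed = config.seed
    attempt = 0
    while True:
        cfg = dataclasses.replace(config, seed=seed)
        if warm_start:
            inits, record = fit_constrained_warmstart(
                responses, spec, cfg, priors, sign_template=sign_template, rts=rts)
            if needs_orientation:
                inits = fix_orientation(inits, sign_template)
        else:
            family = _family_for(spec, responses, rts=rts, priors=priors)
            inits = family.init_params(sign_template=sign_template)
            record = None
        fit = fit_model(responses, spec, priors=priors, inits=inits, config=cfg, rts=rts)
        fit.warm_start = record
        if not needs_orientation:
            fit.orientation_ok = None
            return fit
        delta_eap = fit.eap()["delta"].ravel()
        agree = np.mean(np.sign(delta_eap) == np.sign(np.asarray(sign_template, float)))
        fit.orientation_ok = bool(agree >= 0.5)
        if fit.orientation_ok or attempt >= max_orientation_refits:
            return fit
        attempt += 1
        seed = seed + 1000 + attempt  # re-fit with a different seed
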