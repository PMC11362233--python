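"""Synthetic persons, items, responses and response times.

The generator reproduces the statistical structure of the simulation
design used to study the co-occurring-process IRTree models:

* person parameters (trait theta, response styles eta) are independent
  standard normal;
* discriminations are log-normal, ``LogN(0, 0.25)`` with 0.25 read as the
  *sd* of the log — the same second-argument convention as the normal
  threshold draws (configurable via :data:`DISC_SDLOG`);
* ideal-point item locations delta are uniform on (-3, 3);
* ideal-point thresholds are normal with sds 0.2 around means
  (-2.2, -1.3) for intense disagreement, -1.0 for agreement, and
  (-0.8, -0.2) for intense agreement (ordered across ordinal categories);
* dominance thresholds decompose as ``beta_ik = beta_i + zeta_ik`` with
  ``beta_i ~ U(-1, 1)`` and deviations ``zeta ~ N(-0.5, 0.2)`` and
  ``N(0.5, 0.2)`` (second arguments read as sds).

Responses are drawn from the model-implied tree probabilities.  Response
times follow a log-normal linear mixed model whose predictors are the
manifest midscale/extreme indicators, the person-item distance
``|theta - beta2|``, random person and item intercepts, and random slopes
of the indicators in the response styles.

One seed sequence per replication is sub-streamed by purpose (persons /
items / responses / response times) so that, e.g., adding response times
never perturbs the simulated responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tree import TreeModelSpec, build_model_ideal_ers, build_model_midscale, category_log_probs

__all__ = [
    "PopulationDesign",
    "SimulatedDataset",
    "RTGenerationParams",
    "draw_population",
    "simulate_responses",
    "simulate_response_times",
    "simulate_dataset",
    "condition_grid",
]

MODEL_KINDS = ("I-DI", "I-D", "I-I", "midscale")

#: intensity parameterization per generating model of the six-point family
_INTENSITY = {"I-DI": "co_occurring", "I-D": "ers_only", "I-I": "trait_only"}

#: ordered ideal-point threshold means for the six-point design:
#: (intense disagree x2, agreement, intense agree x2), each with sd 0.2
XI_MEANS_6PT = {
    "intensity_disagree": (-2.2, -1.3),
    "agreement": (-1.0,),
    "intensity_agree": (-0.8, -0.2),
}
#: scaled-down analogue for four-point scales (binary intensity nodes)
XI_MEANS_4PT = {
    "intensity_disagree": (-1.3,),
    "agreement": (-1.0,),
    "intensity_agree": (-0.8,),
}
XI_SD = 0.2
ZETA_MEANS = (-0.5, 0.5)
ZETA_SD = 0.2
#: sd of the log of discrimination draws, LogN(0, DISC_SDLOG).  The second
#: lognormal argument follows the same convention as the normal-threshold
#: draws (an sd, as in R's rlnorm), hence 0.25.
DISC_SDLOG = 0.25


@dataclass(frozen=True)
class PopulationDesign:
    """One cell of the simulation design."""

    N: int
    I: int
    model_kind: str = "I-DI"
    seed: int = 0
    replication: int = 0
    scale_points: int = 6

    def __post_init__(self) -> None:
        if self.N < 2 or self.I < 2:
            raise ValueError("need at least 2 persons and 2 items")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}; choose from {MODEL_KINDS}")


@dataclass
class RTGenerationParams:
    """Coefficients and variance components of the log-RT mixed model.

    Fixed-effect defaults are realistic magnitudes for rating-scale
    responding: a ~2.7 s baseline, slightly slower midscale and faster
    extreme responses, and negative response-style and distance slopes.
    Variance components are the sds of the person intercept, item
    intercept and residual on the log-seconds scale.
    """

    gamma_000: float = 1.0
    gamma_100: float = 0.041
    gamma_200: float = -0.068
    gamma_110: float = -0.116
    gamma_220: float = -0.127
    gamma_011: float = -0.086
    sd_person: float = 0.3
    sd_item: float = 0.1
    sd_residual: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sd_person", "sd_item", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be nonnegative")


@dataclass
class SimulatedDataset:
    """Responses plus the generating truth, for recovery experiments."""

    design: PopulationDesign
    spec: TreeModelSpec
    persons: pd.DataFrame
    items: pd.DataFrame
    params: dict[str, float]
    responses: np.ndarray | None = None
    rts: np.ndarray | None = None
    rt_params: RTGenerationParams | None = None

    @property
    def traits(self) -> dict[str, np.ndarray]:
        return {c: self.persons[c].to_numpy() for c in self.persons.columns}

    def save(self, outdir) -> None:
        """Write responses.csv (wide), persons.csv, items.csv, meta.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.responses is not None:
            pd.DataFrame(
                self.responses,
                columns=[f"item{i}" for i in range(self.responses.shape[1])],
            ).to_csv(outdir / "responses.csv", index_label="person")
        self.persons.to_csv(outdir / "persons.csv", index_label="person")
        self.items.to_csv(outdir / "items.csv", index_label="item")
        if self.rts is not None:
            n, i = self.rts.shape
            long = pd.DataFrame(
                {
                    "person_id": np.repeat(np.arange(n), i),
                    "item_id": np.tile(np.arange(i), n),
                    "rt_seconds": self.rts.ravel(),
                }
            )
            long.to_csv(outdir / "rts.csv", index=False)
        meta = {
            "model_kind": self.design.model_kind,
            "N": self.design.N,
            "I": self.design.I,
            "seed": self.design.seed,
            "replication": self.design.replication,
            "scale_points": self.design.scale_points,
            "tree_kind": self.spec.kind,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))


def _rngs(design: PopulationDesign) -> dict[str, np.random.Generator]:
    keys = ("persons", "items", "responses", "rts")
    seq = np.random.SeedSequence(entropy=design.seed, spawn_key=(design.replication,))
    return dict(zip(keys, map(np.random.default_rng, seq.spawn(len(keys)))))


def _draw_ideal_ers(design: PopulationDesign, rng: np.random.Generator):
    """Item parameters and identified intercepts of the six/four-point family."""
    I = design.I
    kind = design.model_kind
    xi_means = XI_MEANS_6PT if design.scale_points == 6 else XI_MEANS_4PT
    kh = design.scale_points // 2 - 1

    cols: dict[str, np.ndarray] = {}
    cols["lambda1"] = rng.lognormal(mean=0.0, sigma=DISC_SDLOG, size=I)
    cols["delta"] = rng.uniform(-3, 3, size=I)
    if kind in ("I-DI", "I-D"):
        cols["alpha"] = rng.lognormal(mean=0.0, sigma=DISC_SDLOG, size=I)
    if kind in ("I-DI", "I-I"):
        cols["lambda2"] = rng.lognormal(mean=0.0, sigma=DISC_SDLOG, size=I)

    for k, m in enumerate(xi_means["agreement"], start=1):
        cols[f"xi1_{k}"] = rng.normal(m, XI_SD, size=I)
    if kind in ("I-DI", "I-I"):
        for k, m in enumerate(xi_means["intensity_agree"], start=1):
            cols[f"xi2_{k}"] = rng.normal(m, XI_SD, size=I)
        for k, m in enumerate(xi_means["intensity_disagree"], start=1):
            cols[f"xi3_{k}"] = rng.normal(m, XI_SD, size=I)
    if kind in ("I-DI", "I-D"):
        beta_loc = rng.uniform(-1, 1, size=I)
        cols["beta_loc"] = beta_loc
        for node in (1, 2):
            for k in range(1, kh + 1):
                mean = ZETA_MEANS[k - 1] if kh > 1 else 0.0
                cols[f"beta{node}_{k}"] = beta_loc + rng.normal(mean, ZETA_SD, size=I)

    items = pd.DataFrame(cols)

    params: dict[str, float] = {}
    for i in range(I):
        params[f"lambda1[{i}]"] = items["lambda1"][i]
        params[f"delta[{i}]"] = items["delta"][i]
        if kind in ("I-DI", "I-D"):
            params[f"alpha[{i}]"] = items["alpha"][i]
        if kind in ("I-DI", "I-I"):
            params[f"lambda2[{i}]"] = items["lambda2"][i]
        params[f"tau1[{i},1]"] = items["lambda1"][i] * items["xi1_1"][i]
        for node, beta_vec, xi_vec in ((2, "beta1", "xi2"), (3, "beta2", "xi3")):
            for k in range(1, kh + 1):
                tau = 0.0
                if kind in ("I-DI", "I-D"):
                    tau += items["alpha"][i] * items[f"{beta_vec}_{k}"][i]
                if kind in ("I-DI", "I-I"):
                    tau += items["lambda2"][i] * items[f"{xi_vec}_{k}"][i]
                params[f"tau{node}[{i},{k}]"] = tau
    for i in range(I):
        for node in (1, 2, 3):
            for k in range(1, (1 if node == 1 else kh) + 1):
                items.loc[i, f"tau{node}_{k}"] = params[f"tau{node}[{i},{k}]"]

    spec = build_model_ideal_ers(design.scale_points, I, intensity=_INTENSITY[kind])
    return spec, items, params


# generation-side threshold distributions of the midscale family; the
# agreement threshold doubles as the tied ideal-point location
_MIDSCALE_DRAWS = {
    "beta1": ("normal", 1.0, 0.3),   # MRS threshold (midscale well below 50 %)
    "beta2": ("uniform", -1.5, 1.5),  # agreement threshold == delta
    "xi": ("normal", -1.0, 0.2),      # midscale ideal-point threshold
    "beta3": ("normal", 0.5, 0.3),    # ERS threshold, extreme | agree
    "beta4": ("normal", 0.0, 0.3),    # trait threshold, extreme | agree
    "beta5": ("normal", 0.5, 0.3),    # ERS threshold, extreme | disagree
    "beta6": ("normal", 0.0, 0.3),    # trait threshold, extreme | disagree
}


def _draw_midscale(design: PopulationDesign, rng: np.random.Generator):
    I = design.I
    cols: dict[str, np.ndarray] = {}
    for name in ("alpha1", "alpha2", "alpha3", "alpha4", "lambda"):
        cols[name] = rng.lognormal(mean=0.0, sigma=DISC_SDLOG, size=I)
    for name, (dist, a, b) in _MIDSCALE_DRAWS.items():
        cols[name] = rng.normal(a, b, size=I) if dist == "normal" else rng.uniform(a, b, size=I)
    items = pd.DataFrame(cols)

    params: dict[str, float] = {}
    for i in range(I):
        for name in ("alpha1", "alpha2", "alpha3", "alpha4", "lambda", "beta2"):
            params[f"{name}[{i}]"] = items[name][i]
        params[f"tau1[{i},1]"] = (
            items["alpha1"][i] * items["beta1"][i] + items["lambda"][i] * items["xi"][i]
        )
        params[f"tau2[{i},1]"] = items["alpha2"][i] * items["beta2"][i]
        params[f"tau3[{i},1]"] = (
            items["alpha3"][i] * items["beta3"][i] + items["alpha4"][i] * items["beta4"][i]
        )
        params[f"tau4[{i},1]"] = (
            items["alpha3"][i] * items["beta5"][i] + items["alpha4"][i] * items["beta6"][i]
        )
        for node in (1, 2, 3, 4):
            items.loc[i, f"tau{node}_1"] = params[f"tau{node}[{i},1]"]

    spec = build_model_midscale(I)
    return spec, items, params


def draw_population(design: PopulationDesign) -> SimulatedDataset:
    """Draw person and item parameters for one replication (no responses yet)."""
    rngs = _rngs(design)
    if design.model_kind == "midscale":
        spec, items, params = _draw_midscale(design, rngs["items"])
    else:
        if design.scale_points not in (4, 6):
            raise ValueError("the agreement/intensity family supports 4- or 6-point scales")
        spec, items, params = _draw_ideal_ers(design, rngs["items"])
    prng = rngs["persons"]
    trait_names = sorted(spec.traits)
    persons = pd.DataFrame(
        {t: prng.standard_normal(design.N) for t in trait_names}
    )
    return SimulatedDataset(design=design, spec=spec, persons=persons, items=items, params=params)


def simulate_responses(dataset: SimulatedDataset) -> np.ndarray:
    """Sample the response matrix from the model-implied tree probabilities."""
    rng = _rngs(dataset.design)["responses"]
    N, I = dataset.design.N, dataset.design.I
    traits = dataset.traits
    out = np.empty((N, I), dtype=int)
    for i in range(I):
        nodes = dataset.spec.resolve_item(i, dataset.params)
        probs = np.exp(category_log_probs(traits, nodes, dataset.spec.mapping))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(N)
        out[:, i] = (u[:, None] > cum).sum(axis=1)
    dataset.responses = out
    return out


def simulate_response_times(
    dataset: SimulatedDataset, rt_params: RTGenerationParams | None = None
) -> np.ndarray:
    """Sample response times from the log-normal mixed model.

    ``log RT = g000 + (g100 + g110*eta1) X1 + (g200 + g220*eta2) Xext
    + g011 |theta - beta2| + u_person + u_item + eps``, exponentiated.
    Requires five-point midscale-family responses.
    """
    if dataset.responses is None:
        raise ValueError("simulate responses before response times")
    if dataset.design.model_kind != "midscale":
        raise ValueError("response times are defined for the five-point midscale family")
    g = rt_params or RTGenerationParams()
    rng = _rngs(dataset.design)["rts"]
    N, I = dataset.responses.shape
    y = dataset.responses
    x1 = (y == 2).astype(float)
    xext = ((y == 0) | (y == 4)).astype(float)
    theta = dataset.persons["theta"].to_numpy()
    eta1 = dataset.persons["eta1"].to_numpy()
    eta2 = dataset.persons["eta2"].to_numpy()
    beta2 = dataset.items["beta2"].to_numpy()
    dist = np.abs(theta[:, None] - beta2[None, :])
    u_p = rng.normal(0.0, g.sd_person, size=N)
    u_i = rng.normal(0.0, g.sd_item, size=I)
    eps = rng.normal(0.0, g.sd_residual, size=(N, I))
    log_rt = (
        g.gamma_000
        + (g.gamma_100 + g.gamma_110 * eta1[:, None]) * x1
        + (g.gamma_200 + g.gamma_220 * eta2[:, None]) * xext
        + g.gamma_011 * dist
        + u_p[:, None]
        + u_i[None, :]
        + eps
    )
    dataset.rts = np.exp(log_rt)
    dataset.rt_params = g
    return dataset.rts


def simulate_dataset(
    design: PopulationDesign, with_rts: bool = False,
    rt_params: RTGenerationParams | None = None,
) -> SimulatedDataset:
    """Draw parameters and responses (and optionally RTs) in one call."""
    ds = draw_population(design)
    simulate_responses(ds)
    if with_rts:
        simulate_response_times(ds, rt_params)
    return ds


def condition_grid(
    seed: int,
    replications: int = 100,
    sample_sizes: tuple[int, ...] = (500, 1000),
    test_lengths: tuple[int, ...] = (10, 20),
    model_kinds: tuple[str, ...] = ("I-DI", "I-D", "I-I"),
) -> list[PopulationDesign]:
    """The full 2(N) x 2(I) x 3(model) x replications simulation grid."""
    return [
        PopulationDesign(N=n, I=i, model_kind=m, seed=seed, replication=r)
        for m in model_kinds
        for n in sample_sizes
        for i in test_lengths
        for r in range(replications)
    ]
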