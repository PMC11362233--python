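"""IRTree composition: ordinal responses as products of pseudo-item responses.

An IRTree model decomposes each ordinal rating category into a path of
sub-decisions (pseudo-items).  Cells a category's path never reaches are
*missing by design* and contribute nothing to the likelihood; this
sentinel (:data:`MISSING`) is distinct from a respondent-level missing
response, which simply drops the whole item for that person.

Two named builders construct the models used throughout the package:

* :func:`build_model_ideal_ers` — agreement + two intensity sub-decisions
  for 4- or 6-point ideal-point items, with a co-occurring extreme
  response style (ERS) dominance process and trait ideal-point process in
  the intensity nodes.  Sequential special cases (ERS-only or trait-only
  intensity) are available for model comparison.
* :func:`build_model_midscale` — midscale + agreement + two extreme
  sub-decisions for 5-point dominance items, where trait-based midscale
  responding is an ideal-point process whose location is *tied* to the
  agreement threshold.

Intensity pseudo-item categories are ordered inner to outer (least to
most intense); on the disagreement side the trait enters with reversed
scoring weights, implementing direction without reordering categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dimirt import ProcessSpec, PseudoItemParams, dimirt_log_probs

__all__ = [
    "MISSING",
    "TreeMapping",
    "NodeSpec",
    "TreeModelSpec",
    "decompose_response",
    "tree_response_probability",
    "category_log_probs",
    "build_model_ideal_ers",
    "build_model_midscale",
]

#: sentinel for pseudo-item cells that are missing by design
MISSING = -1


@dataclass(frozen=True)
class TreeMapping:
    """Ordinal-category -> pseudo-item response table.

    ``table`` has shape (K_scale+1, H); entry (y, h) is the pseudo-item
    response X_h implied by ordinal category y, or :data:`MISSING`.
    """

    table: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=int)
        if t.ndim != 2:
            raise ValueError("mapping table must be 2-d (categories x pseudo-items)")
        if t.shape[1] != len(self.node_names):
            raise ValueError("node_names length must match table columns")
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "node_names", tuple(self.node_names))

    @property
    def n_categories(self) -> int:
        return self.table.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.table.shape[1]

    @property
    def node_n_categories(self) -> tuple[int, ...]:
        """K_h + 1 for each pseudo-item, inferred from the table."""
        return tuple(int(self.table[:, h].max()) + 1 for h in range(self.n_nodes))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.table.T,
            index=list(self.node_names),
            columns=[str(y) for y in range(self.n_categories)],
        )
        return df.astype(object).where(df.values != MISSING, "-")

    def to_csv(self, path) -> None:
        """Rows = pseudo-items, columns = ordinal categories, '-' for missing."""
        self.to_frame().to_csv(path, index_label="pseudo_item")

    @classmethod
    def from_csv(cls, path) -> "TreeMapping":
        df = pd.read_csv(path, index_col=0)
        raw = df.to_numpy(dtype=object)
        table = np.where(np.isin(raw, ["-", "–"]), MISSING, raw).astype(int).T
        return cls(table=table, node_names=tuple(df.index))


def decompose_response(y: int, mapping: TreeMapping) -> np.ndarray:
    """Pseudo-item response vector for ordinal category ``y`` (MISSING kept)."""
    if not 0 <= y < mapping.n_categories:
        raise ValueError(
            f"ordinal category {y} out of range 0..{mapping.n_categories - 1}"
        )
    return mapping.table[int(y)].copy()


@dataclass(frozen=True)
class NodeSpec:
    """A pseudo-item template: processes plus named intercept references."""

    processes: tuple[ProcessSpec, ...]
    intercept_ids: tuple[str, ...]
    name: str

    def resolve(self, params: Mapping[str, float]) -> PseudoItemParams:
        try:
            tau = np.array([float(params[i]) for i in self.intercept_ids])
            procs = tuple(p.resolve(params) for p in self.processes)
        except KeyError as exc:
            raise KeyError(
                f"unresolved parameter reference {exc.args[0]!r} in node {self.name!r}"
            ) from None
        return PseudoItemParams(processes=procs, tau=tau, name=self.name)


@dataclass(frozen=True)
class TreeModelSpec:
    """An IRTree model: mapping plus per-item pseudo-item specifications."""

    mapping: TreeMapping
    nodes: tuple[tuple[NodeSpec, ...], ...]  # [item][node]
    traits: frozenset[str]
    kind: str = "custom"

    def __post_init__(self) -> None:
        for item_nodes in self.nodes:
            if len(item_nodes) != self.mapping.n_nodes:
                raise ValueError("each item needs one NodeSpec per pseudo-item")
            for node in item_nodes:
                for p in node.processes:
                    if p.trait not in self.traits:
                        raise ValueError(
                            f"trait {p.trait!r} used by {node.name!r} is not registered"
                        )

    @property
    def n_items(self) -> int:
        return len(self.nodes)

    @property
    def n_categories(self) -> int:
        return self.mapping.n_categories

    def param_names(self) -> list[str]:
        """All parameter references used by any node, in first-use order."""
        seen: dict[str, None] = {}
        for item_nodes in self.nodes:
            for node in item_nodes:
                for p in node.processes:
                    if isinstance(p.discrimination, str):
                        seen.setdefault(p.discrimination)
                    if isinstance(p.location, str):
                        seen.setdefault(p.location)
                for i in node.intercept_ids:
                    seen.setdefault(i)
        return list(seen)

    def resolve_item(
        self, item_index: int, params: Mapping[str, float]
    ) -> list[PseudoItemParams]:
        return [node.resolve(params) for node in self.nodes[item_index]]


def category_log_probs(
    traits: Mapping[str, np.ndarray],
    nodes: Sequence[PseudoItemParams],
    mapping: TreeMapping,
) -> np.ndarray:
    """Log probability of every ordinal category, vectorized over persons.

    The tree probability of category y is the product of the conditional
    pseudo-item probabilities along y's path; missing-by-design cells are
    skipped.  Returns shape ``(*trait_shape, K_scale+1)``.
    """
    node_logp = [dimirt_log_probs(traits, node) for node in nodes]
    cats = []
    for y in range(mapping.n_categories):
        total = 0.0
        for h in range(mapping.n_nodes):
            x = mapping.table[y, h]
            if x != MISSING:
                total = total + node_logp[h][..., x]
        cats.append(total)
    return np.stack(np.broadcast_arrays(*cats), axis=-1)


def tree_response_probability(
    y: int,
    traits: Mapping[str, float],
    spec: TreeModelSpec,
    item_index: int,
    params: Mapping[str, float] | None = None,
) -> float:
    """Probability of ordinal response ``y`` to one item under the tree model."""
    if params is None:
        params = {}
    nodes = spec.resolve_item(item_index, params)
    logp = category_log_probs(
        {k: np.asarray(v, float) for k, v in traits.items()}, nodes, spec.mapping
    )
    if not 0 <= y < spec.mapping.n_categories:
        raise ValueError(f"ordinal category {y} out of range")
    return float(np.exp(logp[..., int(y)]))


# ---------------------------------------------------------------------------
# Named model builders
# ---------------------------------------------------------------------------

def _ideal_ers_mapping(scale_points: int) -> TreeMapping:
    half = scale_points // 2
    rows = []
    for y in range(scale_points):
        if y >= half:  # agreement side, intensity inner -> outer
            rows.append([1, y - half, MISSING])
        else:  # disagreement side, intensity inner -> outer
            rows.append([0, MISSING, half - 1 - y])
    return TreeMapping(
        table=np.array(rows),
        node_names=("agreement", "intensity_agree", "intensity_disagree"),
    )


def build_model_ideal_ers(
    scale_points: int,
    item_count: int,
    intensity: str = "co_occurring",
) -> TreeModelSpec:
    """Agreement/intensity IRTree for 4- or 6-point ideal-point items.

    The agreement node is a binary trait ideal-point process.  The two
    intensity nodes combine an ERS dominance process (weights 0..K_h) and
    a trait ideal-point process (weights 0..K_h on the agreement side,
    reversed K_h..0 on the disagreement side); the ERS discrimination and
    the trait intensity discrimination are shared across the two intensity
    nodes, and the item location is shared with the agreement node.

    ``intensity`` selects the pseudo-item parameterization:
    ``"co_occurring"`` (both processes), ``"ers_only"`` (sequential
    trait-ERS model) or ``"trait_only"`` (sequential trait-trait model).
    """
    if scale_points % 2 != 0:
        raise ValueError("the agreement split requires an even number of scale points")
    if intensity not in ("co_occurring", "ers_only", "trait_only"):
        raise ValueError(f"unknown intensity parameterization: {intensity!r}")
    mapping = _ideal_ers_mapping(scale_points)
    kh = scale_points // 2 - 1  # categories per intensity node minus 1
    up = np.arange(kh + 1, dtype=float)
    traits = {"theta"} if intensity == "trait_only" else {"theta", "eta"}

    items = []
    for i in range(item_count):
        lam1, alpha, lam2, delta = (
            f"lambda1[{i}]", f"alpha[{i}]", f"lambda2[{i}]", f"delta[{i}]",
        )
        agree = NodeSpec(
            processes=(
                ProcessSpec("ideal_point", "theta", np.array([0.0, 1.0]), lam1, delta),
            ),
            intercept_ids=(f"tau1[{i},1]",),
            name=f"agreement[{i}]",
        )
        intensity_nodes = []
        for side, w_trait in (("agree", up), ("disagree", up[::-1])):
            procs = []
            if intensity in ("co_occurring", "ers_only"):
                procs.append(ProcessSpec("dominance", "eta", up, alpha))
            if intensity in ("co_occurring", "trait_only"):
                procs.append(ProcessSpec("ideal_point", "theta", w_trait, lam2, delta))
            tag = 2 if side == "agree" else 3
            intensity_nodes.append(
                NodeSpec(
                    processes=tuple(procs),
                    intercept_ids=tuple(f"tau{tag}[{i},{k}]" for k in range(1, kh + 1)),
                    name=f"intensity_{side}[{i}]",
                )
            )
        items.append((agree, *intensity_nodes))
    return TreeModelSpec(
        mapping=mapping,
        nodes=tuple(items),
        traits=frozenset(traits),
        kind=f"ideal_ers_{intensity}_{scale_points}pt",
    )


_MIDSCALE_TABLE = np.array(
    [
        # X1 midscale, X2 agreement, X3 extreme|agree, X4 extreme|disagree
        [0, 0, MISSING, 1],  # Y=0 strong disagree
        [0, 0, MISSING, 0],  # Y=1
        [1, MISSING, MISSING, MISSING],  # Y=2 middle
        [0, 1, 0, MISSING],  # Y=3
        [0, 1, 1, MISSING],  # Y=4 strong agree
    ]
)


def build_model_midscale(item_count: int, trait_midscale: str = "ideal_point") -> TreeModelSpec:
    """Midscale/agreement/extreme IRTree for 5-point dominance items.

    Node X1 (midscale) combines a midscale response style (MRS) dominance
    process with a trait ideal-point process whose location is tied to the
    agreement threshold ``beta2`` (maximal midscale probability where the
    agreement decision is maximally ambiguous).  Node X2 (agreement) is a
    trait dominance process.  Nodes X3/X4 (extreme given agree/disagree)
    combine an ERS dominance process with a trait dominance process whose
    weights are reversed on the disagreement side; the ERS and trait
    extreme discriminations are shared across X3/X4.

    ``trait_midscale="dominance"`` builds the all-dominance alternative in
    which trait-based midscale responding is a dominance process as well.
    """
    if trait_midscale not in ("ideal_point", "dominance"):
        raise ValueError(f"unknown midscale trait IRF: {trait_midscale!r}")
    mapping = TreeMapping(
        table=_MIDSCALE_TABLE,
        node_names=("midscale", "agreement", "extreme_agree", "extreme_disagree"),
    )
    b01 = np.array([0.0, 1.0])
    items = []
    for i in range(item_count):
        a1, lam, a2, a3, a4 = (
            f"alpha1[{i}]", f"lambda[{i}]", f"alpha2[{i}]", f"alpha3[{i}]", f"alpha4[{i}]",
        )
        if trait_midscale == "ideal_point":
            trait_mid = ProcessSpec("ideal_point", "theta", b01, lam, f"beta2[{i}]")
        else:
            trait_mid = ProcessSpec("dominance", "theta", b01, lam)
        items.append(
            (
                NodeSpec(
                    processes=(ProcessSpec("dominance", "eta1", b01, a1), trait_mid),
                    intercept_ids=(f"tau1[{i},1]",),
                    name=f"midscale[{i}]",
                ),
                NodeSpec(
                    processes=(ProcessSpec("dominance", "theta", b01, a2),),
                    intercept_ids=(f"tau2[{i},1]",),
                    name=f"agreement[{i}]",
                ),
                NodeSpec(
                    processes=(
                        ProcessSpec("dominance", "eta2", b01, a3),
                        ProcessSpec("dominance", "theta", b01, a4),
                    ),
                    intercept_ids=(f"tau3[{i},1]",),
                    name=f"extreme_agree[{i}]",
                ),
                NodeSpec(
                    processes=(
                        ProcessSpec("dominance", "eta2", b01, a3),
                        ProcessSpec("dominance", "theta", b01[::-1].copy(), a4),
                    ),
                    intercept_ids=(f"tau4[{i},1]",),
                    name=f"extreme_disagree[{i}]",
                ),
            )
        )
    return TreeModelSpec(
        mapping=mapping,
        nodes=tuple(items),
        traits=frozenset({"theta", "eta1", "eta2"}),
        kind=f"midscale_{trait_midscale}",
    )
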