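import numpy as np
import pytest

from dimirtree import synthesis


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_idi_dataset():
    """A small six-point co-occurring dataset with known truth."""
    return synthesis.simulate_dataset(
        synthesis.PopulationDesign(N=60, I=5, model_kind="I-DI", seed=7)
    )


@pytest.fixture(scope="session")
def small_midscale_dataset():
    """A small five-point midscale dataset with responses and RTs."""
    return synthesis.simulate_dataset(
        synthesis.PopulationDesign(N=60, I=5, model_kind="midscale", seed=9),
        with_rts=True,
    )


def random_pseudo_item(rng, n_processes=2, K=2, ideal_indices=(1,)):
    """A random DI-MIRT pseudo-item plus its generation-side thresholds."""
    from dimirtree.dimirt import ProcessSpec, PseudoItemParams, category_intercepts

    procs, thresholds = [], []
    for r in range(n_processes):
        kind = "ideal_point" if r in ideal_indices else "dominance"
        weights = np.sort(rng.normal(size=K + 1)) if rng.random() < 0.3 else np.arange(K + 1.0)
        procs.append(
            ProcessSpec(
                kind=kind,
                trait=f"t{r}",
                weights=weights,
                discrimination=float(rng.lognormal(0, 0.3)),
                location=float(rng.normal(0, 1.5)) if kind == "ideal_point" else None,
            )
        )
        thresholds.append(rng.normal(0, 1, size=K))
    tau = category_intercepts(list(zip(procs, thresholds)))
    item = PseudoItemParams(processes=tuple(procs), tau=tau[1:])
    return item, procs, thresholds
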