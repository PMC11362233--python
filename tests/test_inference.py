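"""Estimation machinery: orientation handling, warm starts, EAPs, and a
quadrature cross-check of the sampler on a one-item toy model."""

import numpy as np
import pytest

from dimirtree import inference as inf
from dimirtree import synthesis as sy
from dimirtree import tree as tr


class TestFixOrientation:
    def test_fresh_inits_get_template_signs(self):
        fam_inits = {"delta": np.ones((3, 1)), "theta": np.zeros(4)}
        out = inf.fix_orientation(fam_inits, [2.0, -0.5, 1.1])
        np.testing.assert_array_equal(out["delta"][:, 0], [1.0, -1.0, 1.0])

    def test_inverted_reference_solution_is_flipped_jointly(self):
        inits = {"delta": np.array([[-1.2], [0.8], [-2.0]]), "theta": np.array([0.5, -0.3])}
        out = inf.fix_orientation(inits, [1.0, -1.0, 1.0])
        np.testing.assert_allclose(out["delta"][:, 0], [1.2, -0.8, 2.0])
        np.testing.assert_allclose(out["theta"], [-0.5, 0.3])

    def test_aligned_reference_solution_is_kept(self):
        inits = {"delta": np.array([[-1.2], [0.8], [-2.0]]), "theta": np.array([0.5, -0.3])}
        out = inf.fix_orientation(inits, [-1.0, 1.0, -1.0])
        np.testing.assert_allclose(out["delta"][:, 0], [-1.2, 0.8, -2.0])

    def test_zero_sign_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            inf.fix_orientation({"delta": np.ones((2, 1))}, [1.0, 0.0])


def test_likelihood_invariant_under_joint_sign_flip(small_idi_dataset):
    """(theta, delta) -> (-theta, -delta) leaves the tree likelihood
    unchanged: the motivation for fixing the orientation."""
    ds = small_idi_dataset
    fam = inf.AgreementIntensityFamily(ds.responses, 6, "co_occurring")
    params = fam.init_params()
    rng = np.random.default_rng(0)
    params["theta"] = rng.normal(size=fam.N)
    params["eta"] = rng.normal(size=fam.N)
    params["delta"] = rng.normal(size=(fam.I, 1))
    params["tau2"] = rng.normal(size=(fam.I, 2))
    base = fam.response_loglik(params).sum()
    flipped = dict(params)
    flipped["theta"] = -params["theta"]
    flipped["delta"] = -params["delta"]
    assert fam.response_loglik(flipped).sum() == pytest.approx(base, rel=1e-12)


class TestWarmStart:
    def test_constrained_eaps_expand_item_wise(self, small_idi_dataset):
        ds = small_idi_dataset
        signs = np.sign(ds.items["delta"].to_numpy())
        config = inf.SamplerConfig(seed=1, chains=1, warmup=50, draws=50, max_draws=50)
        inits, record = inf.fit_constrained_warmstart(
            ds.responses, ds.spec, config, sign_template=signs)
        # per-item discrimination inits all equal (the constraint definition)
        assert np.ptp(inits["log_alpha"]) == 0.0
        assert inits["log_alpha"].shape == (ds.design.I,)
        assert record["constrained_eap"]["log_alpha"].shape == (1,)
        # delta stays item-specific in the constrained model
        assert inits["delta"].shape == (ds.design.I, 1)

    def test_constrained_model_has_fewer_free_values(self, small_idi_dataset):
        ds = small_idi_dataset
        full = inf.AgreementIntensityFamily(ds.responses, 6, "co_occurring")
        con = inf.AgreementIntensityFamily(ds.responses, 6, "co_occurring", constrained=True)
        def n_item_values(fam):
            return sum(fam.item_dim * ncol if name != "delta" else fam.I
                       for name, ncol in fam.item_families)
        assert n_item_values(con) < n_item_values(full)

    def test_warm_start_improves_initial_posterior_density(self, small_idi_dataset):
        """The constrained-model EAPs start the full sampler at a higher
        joint density than the default cold inits."""
        ds = small_idi_dataset
        signs = np.sign(ds.items["delta"].to_numpy())
        config = inf.SamplerConfig(seed=3, chains=1, warmup=200, draws=200, max_draws=200)
        warm, _ = inf.fit_constrained_warmstart(ds.responses, ds.spec, config,
                                                sign_template=signs)
        fam = inf.AgreementIntensityFamily(ds.responses, 6, "co_occurring")
        cold = fam.init_params(sign_template=signs)
        assert fam.response_loglik(warm).sum() > fam.response_loglik(cold).sum()


class TestEap:
    def test_constant_draws(self):
        draws = {"x": np.full((2, 10, 3), 1.7)}
        fit = inf.PosteriorFit(draws=draws, family=None, config=inf.SamplerConfig())
        np.testing.assert_allclose(inf.eap_estimates(fit)["x"], 1.7)

    def test_symmetric_two_point_draws(self):
        a = np.array([2.5, -1.0])
        draws = {"x": np.stack([np.tile(a, (6, 1)), np.tile(-a, (6, 1))])}
        fit = inf.PosteriorFit(draws=draws, family=None, config=inf.SamplerConfig())
        np.testing.assert_allclose(inf.eap_estimates(fit)["x"], 0.0, atol=1e-15)


class TestSamplerAgainstQuadrature:
    def test_tau_eaps_match_grid_posterior(self):
        """One four-point trait-only item with known discriminations and
        location: the sampled tau EAPs must match a dense grid posterior
        (Gauss-Hermite over theta, 3-d grid over tau) within MC error."""
        design = sy.PopulationDesign(N=120, I=2, model_kind="I-I", seed=17, scale_points=4)
        ds = sy.draw_population(design)
        # single-item data: copy item 0 into item 1 so the family machinery
        # (which needs I >= 2) sees two identical items
        for k in ("lambda1[1]", "lambda2[1]", "delta[1]"):
            ds.params[k] = ds.params[k.replace("[1]", "[0]")]
        for t in (1, 2, 3):
            ds.params[f"tau{t}[1,1]"] = ds.params[f"tau{t}[0,1]"]
        responses = sy.simulate_responses(ds)[:, :1]
        y = np.repeat(responses, 2, axis=1)
        y[:, 1] = -1  # second column missing: the toy model is one item

        lam1 = ds.params["lambda1[0]"]
        lam2 = ds.params["lambda2[0]"]
        delta = ds.params["delta[0]"]
        fam = inf.AgreementIntensityFamily(
            y, 4, "trait_only", fixed=("log_lambda1", "log_lambda2", "delta"))
        params = fam.init_params()
        params["log_lambda1"] = np.full(2, np.log(lam1))
        params["log_lambda2"] = np.full(2, np.log(lam2))
        params["delta"] = np.full((2, 1), delta)
        rng = np.random.default_rng(5)
        sampled, _ = inf._run_chain(fam, params, rng, warmup=800, draws=4000)
        eap = {k: v.mean(axis=0) for k, v in sampled.items()}

        # --- independent grid posterior --------------------------------
        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        prior_w = weights / weights.sum()
        spec = tr.build_model_ideal_ers(4, 1, intensity="trait_only")
        counts = np.bincount(responses[:, 0], minlength=4)
        grids = [np.linspace(ds.params[f"tau{t}[0,1]"] - 3.0,
                             ds.params[f"tau{t}[0,1]"] + 3.0, 41) for t in (1, 2, 3)]
        G1, G2, G3 = np.meshgrid(*grids, indexing="ij")
        logpost = np.zeros(G1.shape)
        flat = [G1.ravel(), G2.ravel(), G3.ravel()]
        marg = np.zeros((G1.size, 4))
        for g in range(G1.size):
            p = {"lambda1[0]": lam1, "lambda2[0]": lam2, "delta[0]": delta,
                 "tau1[0,1]": flat[0][g], "tau2[0,1]": flat[1][g], "tau3[0,1]": flat[2][g]}
            item_nodes = spec.resolve_item(0, p)
            lp = tr.category_log_probs({"theta": nodes}, item_nodes, spec.mapping)
            marg[g] = prior_w @ np.exp(lp)
        loglik = counts @ np.log(marg.T)
        logprior = sum(-0.5 * (f / 5.0) ** 2 for f in flat)
        w = np.exp(loglik + logprior - (loglik + logprior).max())
        w /= w.sum()
        expected = [w @ f for f in flat]

        for t, exp_val in zip((1, 2, 3), expected):
            got = eap[f"tau{t}"][0, 0]
            assert got == pytest.approx(exp_val, abs=0.1), f"tau{t}"


class TestFitModel:
    @pytest.fixture(scope="class")
    def tiny_fit(self, small_idi_dataset):
        ds = small_idi_dataset
        signs = np.sign(ds.items["delta"].to_numpy())
        config = inf.SamplerConfig(seed=2, chains=2, warmup=150, draws=150,
                                   extend_step=100, max_draws=350)
        return ds, inf.fit_tree_model(ds.responses, ds.spec, sign_template=signs,
                                      config=config)

    def test_diagnostics_cover_every_parameter(self, tiny_fit):
        ds, fit = tiny_fit
        names = set(fit.diagnostics["param"].str.replace(r"\[\d+\]", "", regex=True))
        assert {"theta", "eta", "delta", "tau1", "tau2", "tau3",
                "log_lambda1", "log_alpha", "log_lambda2"} <= names
        assert fit.diagnostics[["rhat", "ess_bulk", "ess_tail"]].notna().all().all()

    def test_extension_bookkeeping_within_budget(self, tiny_fit):
        _, fit = tiny_fit
        assert sum(fit.extensions) <= 350 - 150
        assert fit.n_draws <= 350
        assert fit.converged in (True, False)

    def test_pointwise_loglik_shape_and_mask(self, tiny_fit):
        ds, fit = tiny_fit
        ll = fit.pointwise_loglik(max_draws_per_chain=20)
        assert ll.shape[0] == 2 and ll.shape[2:] == (ds.design.N, ds.design.I)
        assert np.isfinite(ll).all()

    def test_orientation_flag_set(self, tiny_fit):
        _, fit = tiny_fit
        assert fit.orientation_ok is True
        assert fit.warm_start is not None


class TestKernelAgainstTreeOracle:
    """The compiled likelihood kernels must reproduce the generic tree
    evaluation (independent pure-python path through the resolved
    pseudo-items) for both model families."""

    def test_agreement_intensity_kernel(self, small_idi_dataset, rng):
        ds = small_idi_dataset
        fam = inf.AgreementIntensityFamily(ds.responses, 6, "co_occurring")
        params = _params_from_truth_idi(ds)
        ll = fam.response_loglik(params)
        for v in rng.integers(0, ds.design.N, size=8):
            tv = {k: w[v] for k, w in ds.traits.items()}
            for i in range(ds.design.I):
                p = tr.tree_response_probability(
                    int(ds.responses[v, i]), tv, ds.spec, i, ds.params)
                assert ll[v, i] == pytest.approx(np.log(p), abs=1e-10)

    def test_midscale_kernel(self, small_midscale_dataset, rng):
        ds = small_midscale_dataset
        fam = inf.MidscaleFamily(ds.responses)
        params = fam.init_params()
        for n, src in (("log_alpha1", "alpha1"), ("log_lambda", "lambda"),
                       ("log_alpha2", "alpha2"), ("log_alpha3", "alpha3"),
                       ("log_alpha4", "alpha4")):
            params[n] = np.log(ds.items[src].to_numpy())
        for t in (1, 2, 3, 4):
            params[f"tau{t}"] = np.array(
                [[ds.params[f"tau{t}[{i},1]"]] for i in range(ds.design.I)])
        for k in ("theta", "eta1", "eta2"):
            params[k] = ds.persons[k].to_numpy()
        ll = fam.response_loglik(params)
        for v in rng.integers(0, ds.design.N, size=8):
            tv = {k: w[v] for k, w in ds.traits.items()}
            for i in range(ds.design.I):
                p = tr.tree_response_probability(
                    int(ds.responses[v, i]), tv, ds.spec, i, ds.params)
                assert ll[v, i] == pytest.approx(np.log(p), abs=1e-10)


def _params_from_truth_idi(ds):
    I = ds.design.I
    return {
        "theta": ds.persons["theta"].to_numpy(),
        "eta": ds.persons["eta"].to_numpy(),
        "log_lambda1": np.log([ds.params[f"lambda1[{i}]"] for i in range(I)]),
        "log_alpha": np.log([ds.params[f"alpha[{i}]"] for i in range(I)]),
        "log_lambda2": np.log([ds.params[f"lambda2[{i}]"] for i in range(I)]),
        "delta": np.array([[ds.params[f"delta[{i}]"]] for i in range(I)]),
        "tau1": np.array([[ds.params[f"tau1[{i},1]"]] for i in range(I)]),
        "tau2": np.array([[ds.params[f"tau2[{i},{k}]"] for k in (1, 2)] for i in range(I)]),
        "tau3": np.array([[ds.params[f"tau3[{i},{k}]"] for k in (1, 2)] for i in range(I)]),
        "mu_delta": np.zeros(1),
        "log_sigma_delta": np.zeros(1),
    }
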