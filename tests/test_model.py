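"""NB multilevel model: fitting, diagnostics, prediction, relative flux."""

import math

import arviz as az
import numpy as np
import pandas as pd
import pytest

from aquagate.errors import ConfigurationError, FitError
from aquagate.model import (
    ModelSpec,
    Posterior,
    check_convergence,
    fit,
    predict_state_flux,
    relative_flux,
)
from aquagate.permeation import FluxSeries, PermeationEvent


def posterior_from_draws(draws_by_chain):
    """Posterior wrapper around hand-made alpha draws (chains, draws)."""
    idata = az.from_dict(posterior={"alpha": np.asarray(draws_by_chain)})
    return Posterior(
        idata=idata,
        predictor_names=[],
        group_names=[],
        x_mean=np.empty(0),
        spec=ModelSpec(),
        sampler_meta={},
    )


class TestFit:
    def test_intercept_only_recovers_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5.0, 1500)
        df = pd.DataFrame({"flux_count": y, "pore_id": "p0"})
        post = fit(df, chains=2, iterations=600, warmup=300, seed=1)
        rate = np.exp(post.draws("alpha"))
        lo, hi = np.percentile(rate, [2.5, 97.5])
        assert lo <= y.mean() <= hi
        assert rate.mean() == pytest.approx(y.mean(), rel=0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"flux_count": rng.poisson(4.0, 400), "pore_id": "p0"})
        a = fit(df, chains=1, iterations=200, warmup=100, seed=7)
        b = fit(df, chains=1, iterations=200, warmup=100, seed=7)
        np.testing.assert_array_equal(a.draws("alpha"), b.draws("alpha"))

    def test_degenerate_data_is_fit_error(self):
        df = pd.DataFrame({"flux_count": np.zeros(50, dtype=int), "pore_id": "p0"})
        with pytest.raises(FitError):
            fit(df)

    def test_empty_dataset_is_fit_error(self):
        with pytest.raises(FitError):
            fit(pd.DataFrame())

    def test_varying_intercept_shrinks_to_group_means(self):
        rng = np.random.default_rng(3)
        rows = []
        offsets = {"p0": 0.3, "p1": -0.3}
        for pore, off in offsets.items():
            rows.append(
                pd.DataFrame(
                    {
                        "flux_count": rng.poisson(4.0 * math.exp(off), 500),
                        "pore_id": pore,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        post = fit(df, chains=2, iterations=600, warmup=300, seed=4)
        u = post.draws("u").mean(axis=0)
        assert u[0] > u[1]
        assert u[0] - u[1] == pytest.approx(0.6, abs=0.15)


class TestConvergence:
    def test_identical_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(2, 4000))
        rep = check_convergence(posterior_from_draws(draws), ess_min=400)
        assert rep.passed
        assert rep.rhat["alpha"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chain_means_fail(self):
        rng = np.random.default_rng(0)
        draws = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        rep = check_convergence(posterior_from_draws(draws))
        assert not rep.passed
        assert rep.rhat["alpha"] > 1.01

    def test_constant_chains_fail_on_ess(self):
        draws = np.ones((2, 2000))
        rep = check_convergence(posterior_from_draws(draws))
        assert not rep.passed

    def test_single_chain_is_error(self):
        with pytest.raises(ConfigurationError):
            check_convergence(posterior_from_draws(np.random.default_rng(0).normal(size=(1, 100))))


class TestPrediction:
    def _null_posterior(self):
        # degenerate posterior: beta exactly 0, alpha = log 5
        chains, draws, p = 2, 200, 2
        alpha = np.full((chains, draws), math.log(5.0))
        beta = np.zeros((chains, draws, p))
        idata = az.from_dict(
            posterior={"alpha": alpha, "beta": beta},
            coords={"predictor": ["gate.blocked", "other.in_pore"]},
            dims={"beta": ["predictor"]},
        )
        spec = ModelSpec(
            state_space={
                "gate": (("blocked", "open"), "open"),
                "other": (("in_pore", "out"), "out"),
            }
        )
        return Posterior(
            idata=idata,
            predictor_names=["gate.blocked", "other.in_pore"],
            group_names=["p0"],
            x_mean=np.array([0.25, 0.4]),
            spec=spec,
            sampler_meta={},
        )

    def test_null_effects_predict_exp_alpha_everywhere(self):
        post = self._null_posterior()
        for state in ("blocked", "open"):
            pred = predict_state_flux(post, "gate", state)
            assert pred.mean == pytest.approx(5.0, rel=1e-9)
            assert pred.lo95 <= pred.mean <= pred.hi95

    def test_reference_state_equals_zeroed_predictors(self):
        post = self._null_posterior()
        ref = predict_state_flux(post, "gate", "open", covariate_policy="reference")
        assert ref.mean == pytest.approx(5.0, rel=1e-9)

    def test_unknown_state_is_lookup_error(self):
        post = self._null_posterior()
        with pytest.raises(KeyError):
            predict_state_flux(post, "gate", "nope")
        with pytest.raises(KeyError):
            predict_state_flux(post, "missing", "open")


class TestRelativeFlux:
    def _series(self, variant, n_events, n_pores=2):
        out = []
        for p in range(n_pores):
            events = [
                PermeationEvent(i, 1, 0.0, 10.0 + i * (80.0 / max(n_events, 1)), 0.1)
                for i in range(n_events)
            ]
            out.append(FluxSeries(pore_id=(variant, 1, chr(65 + p)), events=events))
        return out

    def test_ratio_arithmetic(self):
        res = relative_flux(
            {"wt": self._series("wt", 100), "mut": self._series("mut", 137)},
            analysis_range=(0.0, 100.0),
        )
        ratio = res.set_index("variant").loc["mut", "ratio_to_reference"]
        assert ratio == pytest.approx(1.37)

    def test_reduction_ratio(self):
        res = relative_flux(
            {"wt": self._series("wt", 100), "mut": self._series("mut", 64)},
            analysis_range=(0.0, 100.0),
        )
        assert res.set_index("variant").loc["mut", "ratio_to_reference"] == pytest.approx(0.64)

    def test_identical_variants_ratio_one(self):
        res = relative_flux(
            {"wt": self._series("wt", 80), "twin": self._series("twin", 80)},
            analysis_range=(0.0, 100.0),
        )
        row = res.set_index("variant").loc["twin"]
        assert row["ratio_to_reference"] == pytest.approx(1.0)

    def test_missing_reference_is_error(self):
        with pytest.raises(ConfigurationError):
            relative_flux({"mut": self._series("mut", 10)}, analysis_range=(0.0, 100.0))
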