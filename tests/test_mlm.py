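"""Multilevel model: linear-reduction exactness, shrinkage, recovery, covariates."""

import numpy as np
import pandas as pd
import pytest

from corticurve.curve import GammaKernelParams, ResponseCurveParams, evaluate_curve, gamma_density
from corticurve.errors import ValidationError
from corticurve.mlm import (
    DEFAULT_COVARIATES,
    MultilevelGammaModel,
    MultilevelSpec,
    covariate_frame,
    evaluate_covariate,
    retention_decision,
)
from .conftest import hierarchical_cohort, make_series, series_from_curve


class TestLinearReduction:
    """With only a random amplitude on the identity scale the model is a
    linear mixed model, and the estimator must match closed-form ML."""

    def test_matches_mixedlm_ml(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        kern = GammaKernelParams(3.0, 0.1)
        t = np.array([0.0, 10.0, 20.0, 30.0, 45.0, 60.0])
        f = gamma_density(t, kern)
        series, rows = [], []
        for i in range(40):
            y = np.maximum(5.0 + rng.normal(150, 40) * f + rng.normal(0, 0.8, t.size), 0)
            series.append(make_series(t, y, participant_id=f"p{i}"))
            rows += [{"id": i, "y": yy, "f": ff} for yy, ff in zip(y, f)]
        df = pd.DataFrame(rows)

        mm = MultilevelGammaModel(
            parameters=("A", "b0"), random_effects=("A",),
            families={"A": "identity"}, fixed_values={"alpha": 3.0, "beta": 0.1},
            mc_samples=0, max_iter=5000, tol=1e-13,
        ).fit(series)

        md = sm.MixedLM.from_formula("y ~ f", df, groups="id", re_formula="0 + f")
        res = md.fit(reml=False, method="lbfgs", maxiter=2000)
        res = md.fit(reml=False, method="cg", start_params=res.params_object,
                     maxiter=2000)

        assert mm.fixed_effects_natural_["A"] == pytest.approx(
            float(res.params["f"]), abs=1e-3
        )
        assert mm.fixed_effects_natural_["b0"] == pytest.approx(
            float(res.params["Intercept"]), abs=1e-3
        )
        # the likelihood is nearly flat in the variance component, so the
        # two optimizers can sit 'far' apart in omega while agreeing on the
        # likelihood itself; require likelihood agreement and no worse an
        # optimum than the reference
        assert mm.omega_["A"] == pytest.approx(float(res.cov_re.iloc[0, 0]), rel=1e-2)
        assert mm.sigma_**2 == pytest.approx(float(res.scale), rel=1e-3)
        assert mm.loglik_ == pytest.approx(float(res.llf), abs=1e-3)
        assert mm.loglik_ >= float(res.llf) - 1e-3


class TestShrinkage:
    def test_sparse_participant_shrinks_more(self):
        """Same off-center truth, 2 vs 13 samples: the sparse participant's
        EB estimate sits closer to the population mean."""
        rng = np.random.default_rng(0)
        probe = ResponseCurveParams(GammaKernelParams(4.5, 0.14), 600.0, 8.5)
        t_sparse = (0.0, 60.0)
        t_dense = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 75.0, 80.0)
        series = [
            series_from_curve(probe, t_sparse, 0.8, rng, participant_id="sparse"),
            series_from_curve(probe, t_dense, 0.8, rng, participant_id="dense"),
        ]
        background, _ = hierarchical_cohort(seed=1, n=38)
        series += background
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=40
        ).fit(series)
        ip = mm.individual_params_.set_index("participant_id")
        mu, om = mm.fixed_effects_, mm.omega_

        def weighted_distance(pid):
            z = [
                (np.log(ip.loc[pid, "alpha"]) - mu["alpha"]) / np.sqrt(om["alpha"]),
                (np.log(ip.loc[pid, "beta"]) - mu["beta"]) / np.sqrt(om["beta"]),
                (np.log(ip.loc[pid, "A"]) - mu["A"]) / np.sqrt(om["A"]),
                (ip.loc[pid, "b0"] - mu["b0"]) / np.sqrt(om["b0"]),
            ]
            return float(np.linalg.norm(z))

        assert weighted_distance("sparse") < weighted_distance("dense")

    def test_zero_heterogeneity_estimates_collapse_to_mean(self):
        shared = ResponseCurveParams(GammaKernelParams(3.0, 0.09), 250.0, 5.5)
        rng = np.random.default_rng(5)
        series = [
            series_from_curve(shared, (0, 10, 20, 30, 45, 60, 80), 0.3, rng,
                              participant_id=f"p{i}")
            for i in range(30)
        ]
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=60
        ).fit(series)
        ip = mm.individual_params_
        assert ip["A"].std() / ip["A"].mean() < 0.05
        assert ip["alpha"].std() / ip["alpha"].mean() < 0.05


class TestPrediction:
    def test_noise_free_dense_participant_recovered(self):
        truth = ResponseCurveParams(GammaKernelParams(3.2, 0.10), 300.0, 6.0)
        rng = np.random.default_rng(2)
        series = [series_from_curve(truth, np.arange(0, 81, 5.0), participant_id="target")]
        background, _ = hierarchical_cohort(seed=3, n=30)
        series += background
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=60
        ).fit(series)
        params = mm.predict_individual("target")
        t = np.arange(0, 81, 1.0)
        pred = evaluate_curve(params, t)
        true_vals = evaluate_curve(truth, t)
        assert np.max(np.abs(pred - true_vals)) / true_vals.max() < 0.02

    def test_unknown_participant_errors(self, responder_training_data):
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=10, mc_samples=0
        ).fit(responder_training_data[:30])
        with pytest.raises(ValidationError):
            mm.predict_individual("nobody")

    def test_eb_beats_population_mean_in_sample(self):
        series, _ = hierarchical_cohort(seed=9, n=50)
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=40
        ).fit(series)
        nat = mm.fixed_effects_natural_
        pop_curve = ResponseCurveParams(
            GammaKernelParams(nat["alpha"], nat["beta"]), nat["A"], nat["b0"]
        )
        pop_mae = np.mean([
            np.abs(s.cortisol_array() - evaluate_curve(pop_curve, s.times_array())).mean()
            for s in series
        ])
        assert mm.diagnostics_["mae"].mean() < pop_mae

    def test_estimate_individuals_on_new_data(self):
        train, _ = hierarchical_cohort(seed=11, n=40)
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=30
        ).fit(train)
        new, truths = hierarchical_cohort(seed=12, n=10)
        est = mm.estimate_individuals(new)
        assert len(est) == 10
        # amplitudes track the true per-individual amplitudes in rank
        from corticurve.evaluate import spearman
        assert spearman(est["A"], [p.A for p in truths]) > 0.7


class TestMultilevelShapeOrdering:
    def test_mlm_fits_tighter_than_asm(self, responder_training_data):
        """The flexible multilevel fit must have lower per-participant MAE
        than the shared-shape amplitude model on the same data."""
        from corticurve.asm import AmplitudeScalingModel, fit_individual_amplitude
        from corticurve.preprocess import classify_responder
        from corticurve.errors import UnclassifiableResponderError

        responders = []
        for s in responder_training_data:
            try:
                if classify_responder(s):
                    responders.append(s)
            except UnclassifiableResponderError:
                pass
        asm = AmplitudeScalingModel(select_by_bic=False).fit(responders)
        asm_mae = np.mean([
            np.abs(
                s.cortisol_array()
                - evaluate_curve(
                    fit_individual_amplitude(s, asm.population_curve_).curve,
                    s.times_array(),
                )
            ).mean()
            for s in responders
        ])
        mm = MultilevelGammaModel(
            parameters=("alpha", "beta", "A", "b0"), max_iter=30
        ).fit(responders)
        assert mm.diagnostics_["mae"].mean() < asm_mae


class TestCovariates:
    def test_dummy_coding(self):
        series = [
            make_series([0, 30], [5, 7], participant_id="a", condition="stress",
                        gender="F", test_type="TSST"),
            make_series([0, 30], [5, 7], participant_id="b", condition="control",
                        gender="M", test_type="control"),
            make_series([0, 30], [5, 7], participant_id="c", condition="stress",
                        gender="M", test_type="MAST"),
        ]
        frame = covariate_frame(series).set_index("participant_id")
        assert frame.loc["a"].tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]
        assert frame.loc["b", "control"] == 1.0 and frame.loc["b", "female"] == 0.0
        assert frame.loc["c", "mast"] == 1.0 and frame.loc["c", "control"] == 0.0

    def test_default_spec_carries_final_effect_map(self):
        spec = MultilevelSpec()
        assert spec.covariates == DEFAULT_COVARIATES
        assert "mast" in spec.covariates["beta"]

    @pytest.mark.parametrize(
        "p,cv,dbic,expected",
        [
            (0.01, 10.0, -8.0, True),
            (0.01, 40.0, -8.0, False),
            (0.20, 10.0, -8.0, False),
            (0.01, 10.0, +3.0, False),
        ],
    )
    def test_retention_rule(self, p, cv, dbic, expected):
        assert retention_decision(p, cv, dbic)["retain"] is expected

    def test_covariate_effect_detected_and_evaluated(self):
        rng = np.random.default_rng(21)
        series = []
        for i in range(80):
            female = i % 2 == 0
            logA = np.log(250.0) + (0.5 if female else 0.0) + rng.normal(0, 0.2)
            p = ResponseCurveParams(
                GammaKernelParams(np.exp(np.log(3.0) + rng.normal(0, 0.15)),
                                  np.exp(np.log(0.09) + rng.normal(0, 0.1))),
                float(np.exp(logA)), float(rng.normal(5.5, 0.8)),
            )
            series.append(
                series_from_curve(p, (0, 10, 20, 30, 45, 60, 80), 0.5, rng,
                                  participant_id=f"p{i}",
                                  gender="F" if female else "M")
            )
        kwargs = dict(parameters=("alpha", "beta", "A", "b0"), max_iter=30)
        with_cov = MultilevelGammaModel(
            covariates={"A": ("female",)}, **kwargs
        ).fit(series)
        without = MultilevelGammaModel(**kwargs).fit(series)
        row = with_cov.covariate_coefs_.iloc[0]
        assert row["parameter"] == "A" and row["covariate"] == "female"
        assert row["estimate"] == pytest.approx(0.5, abs=0.15)
        decision = evaluate_covariate(with_cov, without, ("A", "female"))
        assert decision["retain"] is True

    def test_non_nested_fits_rejected(self):
        series, _ = hierarchical_cohort(seed=30, n=10)
        a = MultilevelGammaModel(parameters=("alpha", "beta", "A", "b0"),
                                 max_iter=5, mc_samples=0).fit(series)
        b = MultilevelGammaModel(parameters=("alpha", "beta", "A", "b0"),
                                 max_iter=5, mc_samples=0).fit(series[:5])
        with pytest.raises(ValidationError):
            evaluate_covariate(a, b, ("A", "female"))


class TestValidation:
    def test_needs_two_participants(self):
        series, _ = hierarchical_cohort(seed=0, n=1)
        with pytest.raises(ValidationError):
            MultilevelGammaModel().fit(series)

    def test_needs_two_samples_each(self):
        bad = [make_series([0], [5.0], participant_id="solo"),
               make_series([0, 30], [5.0, 8.0], participant_id="ok")]
        with pytest.raises(ValidationError):
            MultilevelGammaModel().fit(bad)
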