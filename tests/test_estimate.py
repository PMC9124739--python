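"""Laplace marginal likelihood, model discrimination, profiling, GOF."""

import math

import numpy as np
import pytest
from scipy import optimize
from scipy.integrate import quad

import vancosorb.estimate as est
from vancosorb.cohort import CohortConfig, generate_cohort
from vancosorb.dataset import EventRecord, StudyDataset
from vancosorb.estimate import (
    ModelSpec,
    SpecError,
    fit,
    gof_table,
    lrt,
    neg2_loglik,
    profile_ci,
    shrinkage_from_etas,
)
from vancosorb.model import build_segments, predict_concentrations
from vancosorb.params import PKParameters

from conftest import make_subject_events


def one_obs_dataset(t=48.0, dv=22.0, sid="A"):
    events = make_subject_events(sid=sid, maintenance=(100.0, 0.0, t),
                                 loading=(1500.0, 750.0), obs=((t, dv),))
    events = [e for e in events if not (e.evid == 1 and e.amt == 1500.0)]
    return StudyDataset({sid: events})


class TestLaplaceOFV:
    def test_linear_in_eta_model_matches_conjugate_closed_form(self, monkeypatch):
        """With a prediction linear in eta the Laplace approximation is the
        exact Gaussian marginal: OFV = r^2/(sigma^2 + b^2 omega^2)
        + log(sigma^2 + b^2 omega^2) (2*pi constant dropped)."""
        a, b = 18.0, -7.0
        monkeypatch.setattr(
            est, "predict_concentrations",
            lambda params, eta, seg, obs_t, dt=0.02: np.full(len(obs_t), a + b * eta),
        )
        ds = one_obs_dataset(dv=22.0)
        spec = ModelSpec(adsorption_model="none", effluent_covariate=False)
        for omega, sigma in ((0.3, 2.0), (0.05, 3.0), (1.0, 0.5)):
            vals = {"cl_typical": 2.0, "v": 80.0, "omega_cl": omega, "sigma_add": sigma}
            ofv = neg2_loglik(spec, vals, ds)
            s2 = sigma**2 + b**2 * omega**2
            closed = (22.0 - a) ** 2 / s2 + math.log(s2)
            assert ofv == pytest.approx(closed, abs=1e-6)

    def test_matches_adaptive_quadrature_on_nonlinear_model(self):
        """Against brute-force numerical integration of the marginal."""
        ds = one_obs_dataset(dv=22.0)
        spec = ModelSpec(adsorption_model="none", effluent_covariate=False)
        omega, sigma = 0.3, 2.0
        vals = {"cl_typical": 2.0, "v": 80.0, "omega_cl": omega, "sigma_add": sigma}
        ofv = neg2_loglik(spec, vals, ds)
        p = PKParameters(cl_typical=2.0, v=80.0, omega_cl=omega, sigma_add=sigma)
        seg = build_segments(ds.events_for("A"), horizon=48.0)

        def integrand(eta):
            f = predict_concentrations(p, eta, seg, np.array([48.0]))[0]
            return (
                math.exp(-0.5 * ((22.0 - f) / sigma) ** 2) / sigma
                * math.exp(-0.5 * (eta / omega) ** 2) / (omega * math.sqrt(2 * math.pi))
            )

        L, _ = quad(integrand, -4.0, 4.0, limit=200)
        assert ofv == pytest.approx(-2.0 * math.log(L), abs=0.02)

    def test_omega_zero_limit_is_fixed_effects_wls(self):
        obs = ((6.0, 18.0), (12.0, 25.0), (24.0, 30.0))
        events = make_subject_events(sid="A", maintenance=(100.0, 0.0, 24.0),
                                     obs=obs)
        events = [e for e in events if not (e.evid == 1 and e.amt == 1500.0)]
        ds = StudyDataset({"A": events})
        spec = ModelSpec(adsorption_model="none", effluent_covariate=False)
        vals = {"cl_typical": 2.5, "v": 90.0, "omega_cl": 1e-8, "sigma_add": 3.0}
        ofv = neg2_loglik(spec, vals, ds)
        p = PKParameters(cl_typical=2.5, v=90.0, sigma_add=3.0)
        seg = build_segments(ds.events_for("A"), horizon=24.0)
        t = np.array([o[0] for o in obs])
        y = np.array([o[1] for o in obs])
        f = predict_concentrations(p, 0.0, seg, t)
        wls = float(np.sum((y - f) ** 2 / 9.0) + len(y) * math.log(9.0))
        assert ofv == pytest.approx(wls, abs=1e-4)

    def test_likelihood_factorizes_over_subjects(self):
        ds1 = one_obs_dataset(sid="A")
        both = StudyDataset({"A": ds1.events_for("A"),
                             "B": [EventRecord("B", e.time, e.evid, e.amt, e.rate,
                                               e.dv, e.mdv, e.effluent, e.cyto,
                                               e.filter_id)
                                   for e in ds1.events_for("A")]})
        spec = ModelSpec(adsorption_model="none", effluent_covariate=False)
        vals = {"cl_typical": 2.0, "v": 80.0, "omega_cl": 0.2, "sigma_add": 3.0}
        assert neg2_loglik(spec, vals, both) == pytest.approx(
            2.0 * neg2_loglik(spec, vals, ds1), rel=1e-12
        )


class TestLRT:
    def test_boundary_drop_is_not_significant(self):
        r = lrt(100.0, 100.0 - 3.84, df=1)
        assert not r.significant  # strict "<" at the 3.84 threshold

    def test_large_drop_two_df(self):
        r = lrt(100.0, 100.0 - 32.9, df=2)
        assert r.significant
        assert r.p_value < 1e-4

    def test_no_drop_gives_p_one(self):
        assert lrt(50.0, 50.0, df=1).p_value == pytest.approx(1.0)

    def test_just_past_threshold_significant(self):
        assert lrt(100.0, 100.0 - 3.8415, df=1).significant

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError):
            lrt(1.0, 0.0, df=0)


@pytest.fixture(scope="module")
def rich_cohort():
    cfg = CohortConfig(seed=31, n_subjects=8, horizon_h=120.0, obs_per_day=4,
                       sessions_per_subject=1, extra_obs_per_session=2,
                       simulate_method="fast")
    ds, truth = generate_cohort(cfg)
    return ds, truth


class TestFitAndProfile:
    def test_profile_ci_against_direct_rootfinding(self, rich_cohort):
        """With one free parameter the profile bound solves
        OFV(cl) = OFV_min + chi2(0.90); compare bisection machinery with an
        independent brentq root of the same curve, and with the Wald
        interval from the local curvature."""
        ds, truth = rich_cohort
        spec = ModelSpec(
            adsorption_model="linear_saturable",
            fixed={"v": 98.1, "cov_effluent": 0.0003, "k_max": 0.068,
                   "a_max": 572.0, "omega_cl": 0.144, "sigma_add": 3.55},
        )
        fr = fit(spec, ds)
        lo, hi = profile_ci(spec, ds, fr, "cl_typical", level=0.90)
        target = fr.ofv + 2.7055434540100098
        f = lambda c: neg2_loglik(spec, {"cl_typical": c}, ds) - target
        lo_ref = optimize.brentq(f, fr.values["cl_typical"] * 0.5,
                                 fr.values["cl_typical"])
        hi_ref = optimize.brentq(f, fr.values["cl_typical"],
                                 fr.values["cl_typical"] * 2.0)
        assert lo == pytest.approx(lo_ref, rel=5e-3)
        assert hi == pytest.approx(hi_ref, rel=5e-3)
        # near-quadratic OFV: profile ~ Wald from finite-difference curvature
        c0 = fr.values["cl_typical"]
        h = 1e-3 * c0
        d2 = (f(c0 + h) - 2 * f(c0) + f(c0 - h)) / h**2
        half = math.sqrt(2.0 * 2.7055434540100098 / d2)
        assert hi - lo == pytest.approx(2 * half, rel=0.15)
        assert lo < c0 < hi

    def test_level_zero_degenerates_to_estimate(self, rich_cohort):
        ds, _ = rich_cohort
        spec = ModelSpec(
            adsorption_model="linear_saturable",
            fixed={"v": 98.1, "cov_effluent": 0.0003, "k_max": 0.068,
                   "a_max": 572.0, "omega_cl": 0.144, "sigma_add": 3.55},
        )
        fr = fit(spec, ds)
        lo, hi = profile_ci(spec, ds, fr, "cl_typical", level=0.0)
        assert lo == hi == fr.values["cl_typical"]

    def test_start_at_truth_stays_at_truth_on_low_noise_data(self):
        p = PKParameters(cl_typical=2.29, v=98.1, cov_effluent=0.0003,
                         k_max=0.068, a_max=572.0, omega_cl=0.0,
                         sigma_add=0.05, adsorption_model="linear_saturable")
        cfg = CohortConfig(seed=41, n_subjects=6, horizon_h=96.0, obs_per_day=4,
                           sessions_per_subject=1, true_params=p,
                           simulate_method="fast")
        ds, _ = generate_cohort(cfg)
        spec = ModelSpec(
            adsorption_model="linear_saturable",
            fixed={"v": 98.1, "cov_effluent": 0.0003, "omega_cl": 1e-4,
                   "sigma_add": 0.05},
        )
        fr = fit(spec, ds, start={"cl_typical": 2.29, "k_max": 0.068,
                                  "a_max": 572.0})
        assert fr.values["cl_typical"] == pytest.approx(2.29, rel=0.005)
        assert fr.values["k_max"] == pytest.approx(0.068, rel=0.05)
        assert fr.values["a_max"] == pytest.approx(572.0, rel=0.05)

    def test_nested_model_never_fits_worse(self, rich_cohort):
        """Adding the adsorption term can only lower (or tie) the OFV."""
        ds, _ = rich_cohort
        fixed = {"v": 98.1, "cov_effluent": 0.0003}
        red = fit(ModelSpec(adsorption_model="none", fixed=fixed), ds)
        full = fit(ModelSpec(adsorption_model="linear_saturable", fixed=fixed), ds,
                   start={k: red.values[k] for k in ("cl_typical", "omega_cl",
                                                     "sigma_add")})
        assert full.ofv <= red.ofv + 1e-3

    def test_unidentifiable_spec_rejected(self):
        ds = one_obs_dataset()
        spec = ModelSpec(adsorption_model="linear_saturable",
                         fixed={"v": 98.1, "cov_effluent": 0.0003})
        with pytest.raises(SpecError):
            fit(spec, ds)

    def test_all_fixed_rejected(self, rich_cohort):
        ds, _ = rich_cohort
        spec = ModelSpec(adsorption_model="none", effluent_covariate=False,
                         fixed={"cl_typical": 2.29, "v": 98.1,
                                "omega_cl": 0.1, "sigma_add": 3.0})
        with pytest.raises(SpecError):
            fit(spec, ds)


class TestShrinkageAndGOF:
    def test_shrinkage_extremes(self):
        assert shrinkage_from_etas([0.0, 0.0, 0.0], 0.2) == pytest.approx(100.0)
        etas = [-0.2, 0.2]  # sample SD exactly omega
        omega = np.std(etas, ddof=1)
        assert shrinkage_from_etas(etas, omega) == pytest.approx(0.0)

    def test_shrinkage_undefined_at_zero_omega(self):
        with pytest.raises(ValueError):
            shrinkage_from_etas([0.1, -0.1], 0.0)

    def test_gof_on_noiseless_data_reproduces_observations(self):
        p = PKParameters(cl_typical=2.29, v=98.1, cov_effluent=0.0003,
                         k_max=0.068, a_max=572.0, omega_cl=0.144,
                         sigma_add=1e-6, adsorption_model="linear_saturable")
        cfg = CohortConfig(seed=43, n_subjects=4, horizon_h=96.0, obs_per_day=3,
                           sessions_per_subject=1, true_params=p,
                           simulate_method="fast")
        ds, truth = generate_cohort(cfg)
        spec = ModelSpec(adsorption_model="linear_saturable",
                         fixed={"v": 98.1, "cov_effluent": 0.0003,
                                "cl_typical": 2.29, "k_max": 0.068,
                                "a_max": 572.0, "omega_cl": 0.144,
                                "sigma_add": 1e-6})
        ofv, etas = neg2_loglik(spec, {}, ds, return_etas=True)
        fr = est.FitResult(spec=spec, estimates=spec.build_params({}),
                           values=dict(spec.fixed), ofv=ofv, etas=etas,
                           eta_shrinkage=None, converged=True, n_obs=0)
        g = gof_table(fr, ds)
        assert np.allclose(g["ipred"], g["dv"], atol=1e-4)
        # population predictions deviate from individual ones only through eta
        sub = g[np.abs(g["eta"]) > 0.05]
        if len(sub):
            assert (np.abs(sub["pred"] - sub["ipred"]) > 1e-6).any()

    def test_residuals_calibrated_at_truth(self):
        cfg = CohortConfig(seed=47, n_subjects=20, horizon_h=120.0, obs_per_day=4,
                           sessions_per_subject=1, simulate_method="fast")
        ds, truth = generate_cohort(cfg)
        spec = ModelSpec(adsorption_model="linear_saturable",
                         fixed={"v": 98.1, "cov_effluent": 0.0003,
                                "cl_typical": 2.29, "k_max": 0.068,
                                "a_max": 572.0, "omega_cl": 0.144,
                                "sigma_add": 3.55})
        ofv, etas = neg2_loglik(spec, {}, ds, return_etas=True)
        fr = est.FitResult(spec=spec, estimates=spec.build_params({}),
                           values=dict(spec.fixed), ofv=ofv, etas=etas,
                           eta_shrinkage=None, converged=True, n_obs=0)
        g = gof_table(fr, ds)
        n = len(g)
        assert abs(g["ires"].mean()) < 3 * 3.55 / math.sqrt(n)
        assert g["ires"].std(ddof=1) == pytest.approx(3.55, abs=3 * 3.55 / math.sqrt(2 * n))
        assert abs(g["iwres"].mean()) < 3 / math.sqrt(n)
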