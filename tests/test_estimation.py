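"""Metabolism-model fitting: generative recovery, uncertainty routes,
bootstrap behaviour and identifiability guards."""

import numpy as np
import pytest

import meshivive as mi
from meshivive.exceptions import (DomainError, IdentifiabilityError,
                                  InsufficientDataError)

TRUTH = {
    "parent_a_max": 0.0631,
    "metabolite_a_max": 0.0299,
    "cl_per_cell": 4.7e-6,
    "metabolite_fraction": 0.015,
    "scaling_exponent": 0.643,
}


class TestPercentRse:
    def test_arithmetic(self):
        assert mi.percent_rse(2.0, 0.2) == pytest.approx(10.0)
        assert mi.percent_rse(0.643, 0.0083) == pytest.approx(1.29, abs=0.01)
        assert mi.percent_rse(5.0, 0.0) == 0.0
        assert mi.percent_rse(-2.0, 0.2) == pytest.approx(10.0)

    def test_zero_estimate_undefined(self):
        with pytest.raises(DomainError):
            mi.percent_rse(0.0, 0.1)


class TestPointFit:
    def test_noiseless_data_recovered_exactly(self, diclofenac_fitspec,
                                              geometry):
        data = mi.generate_metabolism_dataset(
            mi.diclofenac_design(noise_cv=0.0), seed=1)
        res = mi.fit_metabolism(data, diclofenac_fitspec, geometry,
                                multistart=2, seed=0)
        for name, value in TRUTH.items():
            assert res.estimates[name] == pytest.approx(value, rel=1e-3)
        assert res.objective < 1e-6

    def test_noisy_recovery_of_identifiable_parameters(
            self, noisy_diclofenac_fit):
        """At 10% noise the well-identified parameters come back within
        15%; the metabolite transfer maximum is structurally
        near-unidentifiable (its escape rate is negligible over the
        sampling window) and is checked only for its huge %RSE flag."""
        res = noisy_diclofenac_fit
        for name in ("parent_a_max", "cl_per_cell", "metabolite_fraction",
                     "scaling_exponent"):
            assert res.estimates[name] == pytest.approx(TRUTH[name],
                                                        rel=0.15)
            assert res.pct_rse[name] < 25.0
        assert res.pct_rse["metabolite_a_max"] > 100.0

    def test_all_fixed_spec_evaluates_objective_only(self, geometry,
                                                     diclofenac_fitspec):
        data = mi.generate_metabolism_dataset(
            mi.diclofenac_design(noise_cv=0.0), seed=1)
        spec = mi.FitSpec(free=(), fixed={**TRUTH, "alpha": 1.56,
                                          "beta": -3.3})
        res = mi.fit_metabolism(data, spec, geometry)
        assert res.estimates["cl_per_cell"] == TRUTH["cl_per_cell"]
        assert res.objective < 1e-8
        assert res.pct_rse == {}

    def test_objective_invariant_under_row_order(self, geometry,
                                                 diclofenac_fitspec,
                                                 noisy_diclofenac_data):
        spec = mi.FitSpec(free=(), fixed={**TRUTH, "alpha": 1.56,
                                          "beta": -3.3})
        a = mi.fit_metabolism(noisy_diclofenac_data, spec, geometry)
        shuffled = noisy_diclofenac_data.sample(frac=1.0, random_state=5)
        b = mi.fit_metabolism(shuffled, spec, geometry)
        assert a.objective == pytest.approx(b.objective, rel=1e-12)

    def test_metabolite_parameters_need_metabolite_data(self, geometry):
        data = mi.generate_metabolism_dataset(
            mi.testosterone_design(noise_cv=0.0), seed=1)
        spec = mi.FitSpec(free=("metabolite_fraction",),
                          fixed={**{k: v for k, v in TRUTH.items()
                                    if k != "metabolite_fraction"},
                                 "alpha": 1.565, "beta": -3.3})
        with pytest.raises(IdentifiabilityError):
            mi.fit_metabolism(data, spec, geometry)

    def test_too_few_time_points_rejected(self, geometry,
                                          diclofenac_fitspec,
                                          noisy_diclofenac_data):
        short = noisy_diclofenac_data[
            noisy_diclofenac_data.time_h <= 0.5]
        with pytest.raises(InsufficientDataError):
            mi.fit_metabolism(short, diclofenac_fitspec, geometry)

    def test_mesh_workflow_recovers_transfer_maximum(self, geometry,
                                                     weibull_regressions):
        """Fixing the Weibull scale/shape at their regression-predicted
        508-mesh values and re-estimating only the transfer maximum on
        synthetic 508-mesh data recovers the generating value."""
        wp = mi.predict_weibull_params(weibull_regressions, 400.0)
        mp = mi.MetabolismParams.with_shared_shape(
            mi.WeibullParams(0.0631, wp.alpha, wp.beta),
            metabolite_a_max=0.0299, cl_per_cell=4.7e-6,
            metabolite_fraction=0.015, scaling_exponent=0.643)
        data = mi.generate_metabolism_dataset(
            mi.diclofenac_design(noise_cv=0.10), mp=mp, seed=11)
        spec = mi.FitSpec(
            free=("parent_a_max",),
            fixed={"metabolite_a_max": 0.0299, "cl_per_cell": 4.7e-6,
                   "metabolite_fraction": 0.015,
                   "scaling_exponent": 0.643,
                   "alpha": wp.alpha, "beta": wp.beta})
        res = mi.fit_metabolism(data, spec, geometry, multistart=2, seed=0)
        assert res.estimates["parent_a_max"] == pytest.approx(0.0631,
                                                              rel=0.10)


class TestBootstrap:
    def test_noiseless_bootstrap_is_point_mass(self, geometry,
                                               diclofenac_fitspec):
        data = mi.generate_metabolism_dataset(
            mi.diclofenac_design(noise_cv=0.0), seed=1)
        point = mi.fit_metabolism(data, diclofenac_fitspec, geometry,
                                  multistart=2, seed=0)
        boot = mi.bootstrap_fit(data, diclofenac_fitspec, geometry, n=10,
                                seed=2, point=point)
        for name in diclofenac_fitspec.free:
            assert boot.median[name] == pytest.approx(
                point.estimates[name], rel=0.01)
            assert boot.pct_rse[name] < 0.5

    def test_seed_reproducibility(self, geometry, diclofenac_fitspec,
                                  noisy_diclofenac_data,
                                  noisy_diclofenac_fit):
        kwargs = dict(n=5, seed=9, point=noisy_diclofenac_fit)
        b1 = mi.bootstrap_fit(noisy_diclofenac_data, diclofenac_fitspec,
                              geometry, **kwargs)
        b2 = mi.bootstrap_fit(noisy_diclofenac_data, diclofenac_fitspec,
                              geometry, **kwargs)
        assert b1.median == b2.median

    def test_bootstrap_tames_pathological_jacobian_rse(
            self, geometry, diclofenac_fitspec, noisy_diclofenac_data,
            noisy_diclofenac_fit):
        """For the near-unidentifiable metabolite transfer maximum the
        Jacobian %RSE explodes; the bootstrap distribution gives a far
        smaller, more honest spread."""
        boot = mi.bootstrap_fit(noisy_diclofenac_data, diclofenac_fitspec,
                                geometry, n=30, seed=4,
                                point=noisy_diclofenac_fit)
        jac_rse = noisy_diclofenac_fit.pct_rse["metabolite_a_max"]
        assert jac_rse > 300.0
        assert boot.pct_rse["metabolite_a_max"] < jac_rse / 2.0
        # identifiable parameters keep tight bootstrap spreads
        assert boot.pct_rse["cl_per_cell"] < 10.0
        assert boot.pct_rse["scaling_exponent"] < 10.0

    def test_requires_multiple_units(self, geometry, diclofenac_fitspec,
                                     noisy_diclofenac_data):
        one_curve = noisy_diclofenac_data[
            (noisy_diclofenac_data.replicate == 1)
            & (noisy_diclofenac_data.cells == 1e5)]
        with pytest.raises(InsufficientDataError):
            mi.bootstrap_fit(one_curve, diclofenac_fitspec, geometry,
                             n=5, seed=0)


class TestFitSpecValidation:
    def test_free_fixed_overlap_rejected(self):
        with pytest.raises(DomainError):
            mi.FitSpec(free=("cl_per_cell",),
                       fixed={"cl_per_cell": 1e-6, "alpha": 1.56,
                              "beta": -3.3})

    def test_missing_shape_parameters_rejected(self):
        with pytest.raises(DomainError):
            mi.FitSpec(free=("cl_per_cell",), fixed={"alpha": 1.56})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(DomainError):
            mi.FitSpec(free=("volume_of_distribution",),
                       fixed={"alpha": 1.56, "beta": -3.3})
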