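"""Simulation of the insert system: Weibull rate law, diffusion and
four-compartment metabolism, conservation and solver-oracle checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import meshivive as mi
from meshivive import reference as ref
from meshivive.exceptions import DomainError
from meshivive.kinetics import integrate_metabolism_amounts
from conftest import rk4_states

W508 = ref.WEIBULL_508

positive = st.floats(1e-4, 10.0, allow_nan=False)


def series(df, analyte, compartment, col="conc_uM"):
    sel = df[(df.analyte == analyte) & (df.compartment == compartment)]
    return sel.sort_values("time_h")[col].to_numpy()


class TestWeibullRate:
    @pytest.mark.parametrize("beta", [-12.1, -3.3, -0.5, 0.7, 2.0])
    def test_rate_at_scale_time_is_63_percent(self, beta):
        p = mi.WeibullParams(a_max=0.01, alpha=2.0, beta=beta)
        expected = 0.01 * (1 - np.exp(-1))
        assert mi.weibull_rate(2.0, p) == pytest.approx(expected, rel=1e-12)

    def test_508_mesh_rate_decays_to_trickle(self):
        # frozen from direct evaluation of the rate law
        assert mi.weibull_rate(10.0, W508) == pytest.approx(2.195e-6,
                                                            rel=1e-3)

    def test_time_zero_limits(self):
        neg = mi.WeibullParams(0.01, 1.0, -3.0)
        pos = mi.WeibullParams(0.01, 1.0, 3.0)
        assert mi.weibull_rate(0.0, neg) == pytest.approx(0.01)
        assert mi.weibull_rate(0.0, pos) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            mi.weibull_rate(-0.1, W508)

    @given(a_max=positive, alpha=positive,
           beta=st.floats(-15, 15).filter(lambda b: abs(b) > 1e-3))
    def test_rate_monotone_in_time(self, a_max, alpha, beta):
        p = mi.WeibullParams(a_max, alpha, beta)
        t = np.linspace(0, 50, 200)
        k = mi.weibull_rate(t, p)
        assert np.all(k >= 0) and np.all(k <= a_max * (1 + 1e-12))
        diffs = np.diff(k)
        if beta < 0:
            assert np.all(diffs <= 1e-12)    # decaying transfer
        else:
            assert np.all(diffs >= -1e-12)   # saturating transfer


class TestDiffusion:
    times = [0.17, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0]

    def test_zero_rate_means_no_transfer(self, geometry):
        p = mi.WeibullParams(0.0, 1.0, -3.0)
        sim = mi.simulate_diffusion(geometry, p, 0.1, self.times)
        assert np.allclose(series(sim, "parent", "insert"), 0.0)
        assert np.allclose(series(sim, "parent", "media"),
                           0.1 * 1e3 / geometry.v_media)

    @given(a_max=st.floats(1e-4, 0.5), alpha=st.floats(0.05, 5.0),
           beta=st.floats(-13.0, -0.3))
    def test_mass_conserved(self, geometry, a_max, alpha, beta):
        p = mi.WeibullParams(a_max, alpha, beta)
        sim = mi.simulate_diffusion(geometry, p, 0.1, self.times)
        total = sim.groupby("time_h").amount_nmol.sum().to_numpy()
        assert np.max(np.abs(total / 100.0 - 1.0)) < 1e-8

    def test_insert_profile_monotone_and_plateaus(self, geometry):
        sim = mi.simulate_diffusion(geometry, ref.WEIBULL_BY_MESH[125],
                                    0.1, self.times)
        ins = series(sim, "parent", "insert")
        assert np.all(np.diff(ins) >= -1e-12)

    def test_coarser_mesh_equilibrates_faster(self, geometry):
        """Time to 95% of the final plateau is strictly shorter for the
        125 mesh (large pores) than the 686 mesh (small pores)."""
        t = np.linspace(0.01, 72.0, 400)

        def t95(wp):
            sim = mi.simulate_diffusion(geometry, wp, 0.1, t)
            ins = series(sim, "parent", "insert")
            return t[np.argmax(ins >= 0.95 * ins[-1])]

        assert t95(ref.WEIBULL_BY_MESH[125]) < t95(ref.WEIBULL_BY_MESH[686])

    def test_unsorted_times_rejected(self, geometry):
        with pytest.raises(DomainError):
            mi.simulate_diffusion(geometry, W508, 0.1, [1.0, 0.5])


class TestMetabolism:
    times = [0.17, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0]

    def test_no_cells_reduces_to_diffusion(self, geometry,
                                           diclofenac_params):
        import dataclasses
        mp = dataclasses.replace(diclofenac_params, cl_per_cell=0.0)
        geom = geometry.with_cells(5e5)
        met = mi.simulate_metabolism(geom, mp, 0.08, self.times)
        diff = mi.simulate_diffusion(geom, mp.parent_release, 0.08,
                                     self.times)
        for comp in ("media", "insert"):
            assert series(met, "parent", comp) == pytest.approx(
                series(diff, "parent", comp), rel=1e-7)
        assert np.allclose(series(met, "metabolite", "insert"), 0.0)

    def test_closed_funnel_traps_all_eliminated_parent(self, geometry):
        """With full conversion and no metabolite escape, the insert
        metabolite amount equals the cumulative eliminated parent."""
        parent = mi.WeibullParams(0.05, 1.56, -3.3)
        mp = mi.MetabolismParams.with_shared_shape(
            parent, metabolite_a_max=0.0, cl_per_cell=4.7e-6,
            metabolite_fraction=1.0, scaling_exponent=0.643)
        sim = mi.simulate_metabolism(geometry.with_cells(5e5), mp, 0.08,
                                     self.times)
        met_ins = series(sim, "metabolite", "insert", col="amount_nmol")
        eliminated = sim.attrs["eliminated_nmol"]
        assert met_ins == pytest.approx(eliminated, abs=1e-6 * 80)

    def test_parent_mass_balance_closes(self, geometry, diclofenac_params):
        sim = mi.simulate_metabolism(geometry.with_cells(5e5),
                                     diclofenac_params, 0.08, self.times)
        parent = (series(sim, "parent", "media", col="amount_nmol")
                  + series(sim, "parent", "insert", col="amount_nmol"))
        closure = parent + sim.attrs["eliminated_nmol"]
        assert np.max(np.abs(closure / 80.0 - 1.0)) < 1e-8
        # metabolite never exceeds its share of eliminated parent
        met = (series(sim, "metabolite", "media", col="amount_nmol")
               + series(sim, "metabolite", "insert", col="amount_nmol"))
        cap = diclofenac_params.metabolite_fraction
        assert np.all(met <= cap * sim.attrs["eliminated_nmol"] + 1e-9)

    def test_media_metabolite_monotone(self, geometry, diclofenac_params):
        sim = mi.simulate_metabolism(geometry.with_cells(5e5),
                                     diclofenac_params, 0.08, self.times)
        assert np.all(np.diff(series(sim, "metabolite", "media")) >= -1e-12)

    @pytest.mark.parametrize("n_cells,fold", [(2e5, 1.56), (5e5, 2.81)])
    def test_per_cell_clearance_folds(self, n_cells, fold):
        """With scaling exponent 0.643 the per-cell clearance is 1.56x
        at 2e5 cells and 2.81x at 5e5 cells relative to 1e5 cells."""
        geom_ref = mi.SystemGeometry(n_cells=1e5)
        geom = mi.SystemGeometry(n_cells=n_cells)
        per_cell_ref = mi.cell_clearance_rate(geom_ref, 4.7e-6, 0.643) / 1e5
        per_cell = mi.cell_clearance_rate(geom, 4.7e-6, 0.643) / n_cells
        assert per_cell / per_cell_ref == pytest.approx(fold, abs=5e-3)

    def test_adaptive_solver_matches_rk4_oracle(self, geometry,
                                                diclofenac_params):
        mp = diclofenac_params
        geom = geometry.with_cells(5e5)
        times = [0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0]
        y_adaptive = integrate_metabolism_amounts(geom, mp, 0.08, times,
                                                  rtol=1e-10, atol=1e-12)
        k_e = mi.cell_clearance_rate(geom, mp.cl_per_cell,
                                     mp.scaling_exponent)
        frac = mp.metabolite_fraction
        from meshivive.kinetics import _rate_scalar

        def rhs(t, y):
            kp = _rate_scalar(t, mp.parent_release)
            km = _rate_scalar(t, mp.metabolite_release)
            return np.array([
                -kp * y[0],
                kp * y[0] - k_e * y[1],
                frac * k_e * y[1] - km * y[2],
                km * y[2]])

        y_rk4 = rk4_states(rhs, [80.0, 0.0, 0.0, 0.0], 72.0, 1e-3, times)
        scale = np.abs(y_rk4).max(axis=0)
        err = np.abs(y_adaptive[:, :4] - y_rk4) / scale
        assert err.max() < 1e-5


class TestMonteCarlo:
    times = [1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0]

    def test_zero_cv_collapses_to_point_trajectory(self, geometry,
                                                   diclofenac_params):
        geom = geometry.with_cells(5e5)
        bands = mi.monte_carlo_interval(geom, diclofenac_params, 0.08,
                                        self.times, variability_cv=0.0,
                                        n=10, seed=1)
        point = mi.simulate_metabolism(geom, diclofenac_params, 0.08,
                                       self.times)
        for analyte, comp in [("parent", "insert"),
                              ("metabolite", "insert")]:
            b = bands[(bands.analyte == analyte)
                      & (bands.compartment == comp)]
            expected = series(point, analyte, comp)
            assert b.lo_uM.to_numpy() == pytest.approx(expected, rel=1e-4)
            assert b.hi_uM.to_numpy() == pytest.approx(expected, rel=1e-4)

    def test_seed_reproducibility(self, geometry, diclofenac_params):
        geom = geometry.with_cells(5e5)
        kwargs = dict(variability_cv=0.3, n=50, seed=42)
        b1 = mi.monte_carlo_interval(geom, diclofenac_params, 0.08,
                                     self.times, **kwargs)
        b2 = mi.monte_carlo_interval(geom, diclofenac_params, 0.08,
                                     self.times, **kwargs)
        pd.testing.assert_frame_equal(b1, b2)

    def test_band_coverage_near_nominal(self, geometry, diclofenac_params):
        """A fresh parameter draw's trajectory falls inside the 90% band
        about 90% of the time (pointwise, averaged over draws)."""
        from meshivive.kinetics import (perturb_metabolism_params,
                                        integrate_metabolism_amounts)
        geom = geometry.with_cells(5e5)
        bands = mi.monte_carlo_interval(geom, diclofenac_params, 0.08,
                                        self.times, variability_cv=0.3,
                                        n=500, seed=0)
        sel = bands[(bands.analyte == "parent")
                    & (bands.compartment == "insert")]
        lo, hi = sel.lo_uM.to_numpy(), sel.hi_uM.to_numpy()
        rng = np.random.default_rng(123)
        fresh = perturb_metabolism_params(diclofenac_params, 0.3, rng, 200)
        inside = []
        for mp in fresh:
            y = integrate_metabolism_amounts(geom, mp, 0.08, self.times)
            conc = y[:, 1] / geom.v_insert
            inside.append(np.mean((conc >= lo) & (conc <= hi)))
        assert np.mean(inside) == pytest.approx(0.90, abs=0.04)

    def test_invalid_arguments(self, geometry, diclofenac_params):
        with pytest.raises(DomainError):
            mi.monte_carlo_interval(geometry, diclofenac_params, 0.08,
                                    self.times, n=1)
        with pytest.raises(DomainError):
            mi.monte_carlo_interval(geometry, diclofenac_params, 0.08,
                                    self.times, level=1.5)
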