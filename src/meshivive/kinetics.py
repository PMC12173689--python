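"""Simulation of the mesh-insert culture system.

Two models are provided:

* **Diffusion** — drug in the stirred medium crosses the mesh into the
  insert with a time-varying first-order rate coefficient
  ``k(t) = a_max * (1 - exp(-(t/alpha)**beta))``.  With negative ``beta``
  the coefficient starts at ``a_max`` and decays to zero, so the insert
  concentration rises to a plateau (the observed equilibrium).

* **Metabolism** — a four-compartment extension (parent and metabolite in
  medium and insert).  Parent transfers medium→insert, is eliminated inside
  the insert by the seeded cells at a cell-number-scaled first-order rate,
  a fraction of the eliminated parent appears as metabolite in the insert,
  and the metabolite transfers insert→medium with its own Weibull law.
  The remainder of eliminated parent is tracked as a sink so the mass
  balance closes exactly.

Amounts are integrated in nmol; concentrations are reported in µM
(nmol/mL).  Both simulators return tidy DataFrames with columns
``analyte``, ``compartment``, ``time_h``, ``conc_uM``, ``amount_nmol``.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .exceptions import DomainError, IntegrationError
from .params import (MetabolismParams, SystemGeometry, WeibullParams,
                     cell_clearance_rate)

__all__ = [
    "weibull_rate",
    "simulate_diffusion",
    "simulate_metabolism",
    "monte_carlo_interval",
]

# exponent clamp: exp(±700) is the float64 limit
_EXP_CLAMP = 700.0


def weibull_rate(t, p: WeibullParams):
    """Instantaneous transfer-rate coefficient k(t), 1/h.

    ``k(t) = a_max * (1 - exp(-(t/alpha)**beta))``.  For ``beta < 0`` the
    t→0⁺ limit is ``a_max`` (taken as the value at t=0) and k decays to 0
    as t→∞; for ``beta > 0`` the rate starts at 0 and rises to ``a_max``.
    Accepts scalars or arrays; negative times raise :class:`DomainError`.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    with np.errstate(divide="ignore", over="ignore"):
        x = (t_arr / p.alpha) ** p.beta
    x = np.clip(x, 0.0, _EXP_CLAMP)          # t=0, beta<0 -> inf -> clamp
    out = p.a_max * (-np.expm1(-x))
    if np.ndim(t) == 0:
        return float(out)
    return out


def _check_times(times: Sequence[float]) -> np.ndarray:
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise DomainError("need at least one output time")
    if np.any(times < 0):
        raise DomainError("output times must be >= 0")
    if np.any(np.diff(times) <= 0):
        raise DomainError("output times must be strictly increasing")
    return times


def _rate_scalar(t: float, p: WeibullParams) -> float:
    # scalar fast path for ODE right-hand sides
    if t <= 0.0:
        return p.a_max if p.beta < 0 else 0.0
    x = (t / p.alpha) ** p.beta
    if x > _EXP_CLAMP:
        x = _EXP_CLAMP
    return p.a_max * -math.expm1(-x)


def _integrate(rhs: Callable, y0: Sequence[float], times: np.ndarray,
               rtol: float, atol: float) -> np.ndarray:
    """LSODA integration from t=0 through the requested output times."""
    if times[0] > 0.0:
        t_solve = np.concatenate(([0.0], times))
        skip = 1
    else:
        t_solve = times
        skip = 0
    y, info = odeint(rhs, np.asarray(y0, dtype=float), t_solve,
                     rtol=rtol, atol=atol, tfirst=True, full_output=True,
                     mxstep=50000)
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"ODE solver failed: {info['message']}")
    return y[skip:]


def _tidy(times: np.ndarray, series: Iterable[Tuple[str, str, np.ndarray, float]],
          compound: Optional[str]) -> pd.DataFrame:
    frames = []
    for analyte, compartment, amount, volume in series:
        frames.append(pd.DataFrame({
            "compound": compound,
            "analyte": analyte,
            "compartment": compartment,
            "time_h": times,
            "conc_uM": amount / volume,       # nmol/mL == µM
            "amount_nmol": amount,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_diffusion(geom: SystemGeometry, p: WeibullParams,
                       dose_umol: float, times: Sequence[float],
                       compound: Optional[str] = None,
                       rtol: float = 1e-10, atol: float = 1e-12
                       ) -> pd.DataFrame:
    """Simulate drug equilibration from medium into a cell-free insert.

    The dose (µmol) is placed in the medium at t=0 and transfers one-way at
    the Weibull rate:  dA_med/dt = −k(t)·A_med,  dA_ins/dt = +k(t)·A_med.
    Total mass is conserved and the insert profile is non-decreasing,
    plateauing as k→0.

    Returns a tidy frame with two series (parent in ``media``/``insert``).
    """
    if dose_umol < 0:
        raise DomainError("dose must be >= 0")
    times = _check_times(times)
    dose_nmol = dose_umol * 1e3

    def rhs(t, y):
        k = _rate_scalar(t, p)
        flux = k * y[0]
        return (-flux, flux)

    y = _integrate(rhs, (dose_nmol, 0.0), times, rtol, atol)
    return _tidy(times, [
        ("parent", "media", y[:, 0], geom.v_media),
        ("parent", "insert", y[:, 1], geom.v_insert),
    ], compound)


def simulate_metabolism(geom: SystemGeometry, mp: MetabolismParams,
                        dose_umol: float, times: Sequence[float],
                        compound: Optional[str] = None,
                        metabolite_name: Optional[str] = None,
                        rtol: float = 1e-10, atol: float = 1e-12
                        ) -> pd.DataFrame:
    """Simulate the four-compartment parent/metabolite system.

    States (nmol): parent in medium, parent in insert, metabolite in
    insert, metabolite in medium, other-pathway sink, and cumulative
    eliminated parent.  Elimination applies the cell-number-scaled rate
    constant from :func:`meshivive.params.cell_clearance_rate` to the
    insert parent amount; a fraction ``metabolite_fraction`` of eliminated
    parent enters the insert metabolite pool (1:1 molar stoichiometry).

    Returns a tidy frame with four series; the sink and cumulative
    elimination trajectories are attached as ``df.attrs["sink_nmol"]`` and
    ``df.attrs["eliminated_nmol"]`` for mass-balance checks.
    """
    if dose_umol < 0:
        raise DomainError("dose must be >= 0")
    times = _check_times(times)
    dose_nmol = dose_umol * 1e3
    k_e = cell_clearance_rate(geom, mp.cl_per_cell, mp.scaling_exponent)
    frac = mp.metabolite_fraction
    pw, mw = mp.parent_release, mp.metabolite_release

    def rhs(t, y):
        kp = _rate_scalar(t, pw)
        km = _rate_scalar(t, mw)
        uptake = kp * y[0]
        elim = k_e * y[1]
        release = km * y[2]
        return (-uptake,
                uptake - elim,
                frac * elim - release,
                release,
                (1.0 - frac) * elim,
                elim)

    y = _integrate(rhs, (dose_nmol, 0.0, 0.0, 0.0, 0.0, 0.0), times,
                   rtol, atol)
    met = metabolite_name or (f"{compound}-metabolite" if compound else None)
    df = _tidy(times, [
        ("parent", "media", y[:, 0], geom.v_media),
        ("parent", "insert", y[:, 1], geom.v_insert),
    ], compound)
    df_met = _tidy(times, [
        ("metabolite", "insert", y[:, 2], geom.v_insert),
        ("metabolite", "media", y[:, 3], geom.v_media),
    ], met)
    df = pd.concat([df, df_met], ignore_index=True)
    df.attrs["sink_nmol"] = y[:, 4].copy()
    df.attrs["eliminated_nmol"] = y[:, 5].copy()
    df.attrs["dose_nmol"] = dose_nmol
    return df


def integrate_metabolism_amounts(geom: SystemGeometry, mp: MetabolismParams,
                                 dose_umol: float, times: Sequence[float],
                                 rtol: float = 1e-8, atol: float = 1e-10
                                 ) -> np.ndarray:
    """Raw state matrix (n_times × 6, nmol) for fitting hot paths.

    Column order: media parent, insert parent, insert metabolite, media
    metabolite, sink, cumulative eliminated parent.
    """
    times = _check_times(times)
    dose_nmol = dose_umol * 1e3
    k_e = cell_clearance_rate(geom, mp.cl_per_cell, mp.scaling_exponent)
    frac = mp.metabolite_fraction
    pw, mw = mp.parent_release, mp.metabolite_release

    def rhs(t, y):
        kp = _rate_scalar(t, pw)
        km = _rate_scalar(t, mw)
        uptake = kp * y[0]
        elim = k_e * y[1]
        release = km * y[2]
        return (-uptake, uptake - elim, frac * elim - release, release,
                (1.0 - frac) * elim, elim)

    return _integrate(rhs, (dose_nmol, 0.0, 0.0, 0.0, 0.0, 0.0), times,
                      rtol, atol)


def _lognormal_draws(rng: np.random.Generator, point: float, cv: float,
                     n: int) -> np.ndarray:
    """Mean-preserving lognormal draws about a point estimate."""
    if point == 0.0 or cv == 0.0:
        return np.full(n, point)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(point) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def perturb_metabolism_params(mp: MetabolismParams, cv: float,
                              rng: np.random.Generator,
                              n: int) -> list:
    """Draw ``n`` metabolism-parameter sets with lognormal CV about the
    point estimates (per-cell clearance, metabolite fraction, metabolite
    release rate); the fraction is capped at 1."""
    cl = _lognormal_draws(rng, mp.cl_per_cell, cv, n)
    frac = np.minimum(_lognormal_draws(rng, mp.metabolite_fraction, cv, n), 1.0)
    vm = _lognormal_draws(rng, mp.metabolite_release.a_max, cv, n)
    out = []
    for i in range(n):
        met = WeibullParams(float(vm[i]), mp.metabolite_release.alpha,
                            mp.metabolite_release.beta)
        out.append(MetabolismParams(
            parent_release=mp.parent_release, metabolite_release=met,
            cl_per_cell=float(cl[i]), metabolite_fraction=float(frac[i]),
            scaling_exponent=mp.scaling_exponent))
    return out


def monte_carlo_interval(geom: SystemGeometry, mp: MetabolismParams,
                         dose_umol: float, times: Sequence[float],
                         variability_cv: float = 0.30, n: int = 500,
                         level: float = 0.90, seed: Optional[int] = None,
                         compound: Optional[str] = None) -> pd.DataFrame:
    """Monte-Carlo prediction bands for the metabolism model.

    Draws ``n`` metabolism-parameter sets from a lognormal distribution
    with coefficient of variation ``variability_cv`` about the point
    estimates, simulates each, and returns per-time central quantile bands
    (5th–95th percentile for ``level=0.90``) together with the mean
    trajectory, per (analyte, compartment) series.  Reproducible under a
    fixed seed; with ``variability_cv=0`` the band collapses onto the
    point trajectory.
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    if not 0.0 < level < 1.0:
        raise DomainError("level must be in (0, 1)")
    if variability_cv < 0:
        raise DomainError("variability_cv must be >= 0")
    times = _check_times(times)
    rng = np.random.default_rng(seed)
    draws = perturb_metabolism_params(mp, variability_cv, rng, n)
    # state trajectories: (n, n_times, 4 observable series)
    sims = np.empty((n, len(times), 4))
    for i, mpi in enumerate(draws):
        y = integrate_metabolism_amounts(geom, mpi, dose_umol, times)
        sims[i] = y[:, :4]
    vols = np.array([geom.v_media, geom.v_insert, geom.v_insert,
                     geom.v_media])
    conc = sims / vols                      # nmol/mL -> µM
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    labels = [("parent", "media"), ("parent", "insert"),
              ("metabolite", "insert"), ("metabolite", "media")]
    frames = []
    for j, (analyte, compartment) in enumerate(labels):
        frames.append(pd.DataFrame({
            "compound": compound,
            "analyte": analyte,
            "compartment": compartment,
            "time_h": times,
            "mean_uM": conc[:, :, j].mean(axis=0),
            "lo_uM": np.quantile(conc[:, :, j], lo_q, axis=0),
            "hi_uM": np.quantile(conc[:, :, j], hi_q, axis=0),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["level"] = level
    out.attrs["n"] = n
    return out
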