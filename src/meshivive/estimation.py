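"""Fitting the metabolism model to concentration–time data.

The diffusion shape parameters (Weibull scale and shape) are fixed at
their mesh-regression values; the transfer maxima, the per-cell
clearance, the metabolite fraction and the cell-count scaling exponent
are estimated by least squares on log concentrations (a proportional
error model, matching how such data are assayed and displayed).  All
experimental conditions — dose levels and cell densities — are fitted
jointly with shared parameters; joint fitting across cell densities is
what identifies the scaling exponent.

Point estimates carry a Jacobian-based %RSE; a nonparametric bootstrap
that resamples replicate curves within each condition provides the more
robust uncertainty route when the Jacobian is near-singular (the
metabolite transfer maximum is the classic offender).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (DomainError, FitConvergenceError,
                         IdentifiabilityError, InsufficientDataError)
from .kinetics import integrate_metabolism_amounts
from .params import MetabolismParams, SystemGeometry, WeibullParams

__all__ = ["FitSpec", "FitResult", "BootstrapResult", "fit_metabolism",
           "bootstrap_fit", "percent_rse"]

#: estimable parameters and their box bounds
PARAMETER_BOUNDS: Dict[str, Tuple[float, float]] = {
    "parent_a_max": (1e-8, 10.0),
    "metabolite_a_max": (0.0, 10.0),
    "cl_per_cell": (0.0, 1e-2),
    "metabolite_fraction": (0.0, 1.0),
    "scaling_exponent": (0.0, 3.0),
}

_DEFAULT_INIT = {
    "parent_a_max": 0.01,
    "metabolite_a_max": 0.01,
    "cl_per_cell": 1e-6,
    "metabolite_fraction": 0.1,
    "scaling_exponent": 0.5,
}

_STATE_COLUMN = {("parent", "media"): 0, ("parent", "insert"): 1,
                 ("metabolite", "insert"): 2, ("metabolite", "media"): 3}


def percent_rse(estimate: float, se: float) -> float:
    """Percent relative standard error, 100·SE/|estimate|."""
    if estimate == 0:
        raise DomainError("%RSE undefined for a zero estimate")
    if se < 0:
        raise DomainError("standard error must be >= 0")
    return 100.0 * se / abs(estimate)


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and what to hold fixed.

    ``free`` names a subset of :data:`PARAMETER_BOUNDS`; ``fixed`` must
    supply the Weibull scale/shape (keys ``alpha``, ``beta``, optionally
    ``metabolite_alpha``/``metabolite_beta``) plus any estimable parameter
    not listed as free.  ``observed`` maps data series (analyte,
    compartment) onto model states.  Concentrations are floored at
    ``conc_floor`` µM before taking logs.
    """

    free: Tuple[str, ...]
    fixed: Dict[str, float]
    observed: Tuple[Tuple[str, str], ...] = (("parent", "insert"),
                                             ("metabolite", "insert"))
    conc_floor: float = 1e-6
    init: Optional[Dict[str, float]] = None

    def __post_init__(self):
        unknown = set(self.free) - set(PARAMETER_BOUNDS)
        if unknown:
            raise DomainError(f"unknown free parameters: {sorted(unknown)}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise DomainError(f"parameters both free and fixed: "
                              f"{sorted(overlap)}")
        for key in ("alpha", "beta"):
            if key not in self.fixed:
                raise DomainError(f"fixed must supply {key!r}")
        for series in self.observed:
            if tuple(series) not in _STATE_COLUMN:
                raise DomainError(f"unknown observed series {series}")

    def full_values(self, free_values: Sequence[float]) -> Dict[str, float]:
        vals = {name: 0.0 for name in PARAMETER_BOUNDS}
        vals.update(self.fixed)
        vals.update(dict(zip(self.free, free_values)))
        return vals


def _build_params(vals: Dict[str, float]) -> MetabolismParams:
    parent = WeibullParams(max(vals["parent_a_max"], 0.0), vals["alpha"],
                           vals["beta"])
    met = WeibullParams(max(vals["metabolite_a_max"], 0.0),
                        vals.get("metabolite_alpha", vals["alpha"]),
                        vals.get("metabolite_beta", vals["beta"]))
    return MetabolismParams(
        parent_release=parent, metabolite_release=met,
        cl_per_cell=max(vals["cl_per_cell"], 0.0),
        metabolite_fraction=min(max(vals["metabolite_fraction"], 0.0), 1.0),
        scaling_exponent=max(vals["scaling_exponent"], 0.0))


@dataclass(frozen=True)
class FitResult:
    """Point estimates with Jacobian-based uncertainty."""

    estimates: Dict[str, float]          # free + fixed parameters
    pct_rse: Dict[str, float]            # free parameters, %
    se: Dict[str, float]                 # free parameters, same units
    objective: float                     # SSE on the log scale
    converged: bool
    n_obs: int
    free: Tuple[str, ...]


@dataclass(frozen=True)
class BootstrapResult:
    """Nonparametric bootstrap summary.

    ``pct_rse`` is 100·SD/|median| of the resample distribution (the
    bootstrap analogue of %RSE).  ``samples`` holds one row of estimates
    per successful resample.
    """

    n_resamples: int
    n_failed: int
    median: Dict[str, float]
    pct_rse: Dict[str, float]
    samples: pd.DataFrame


class _Problem:
    """Pre-indexed observations + simulator for the joint residual."""

    def __init__(self, data: pd.DataFrame, spec: FitSpec,
                 geom: SystemGeometry, rtol: float = 1e-8):
        self.spec = spec
        self.geom = geom
        self.rtol = rtol
        observed = {tuple(s) for s in spec.observed}
        df = data[data[["analyte", "compartment"]].apply(tuple, axis=1)
                  .isin(observed)].copy()
        if df.empty:
            raise InsufficientDataError("no rows match the observed series")
        if "dose_uM" not in df.columns:
            raise InsufficientDataError("data must carry a dose_uM column")
        df = df.sort_values(["dose_uM", "cells", "analyte", "compartment",
                             "time_h", "replicate"], kind="mergesort")
        self.conditions = []
        for (dose, cells), grp in df.groupby(["dose_uM", "cells"],
                                             sort=True):
            times = np.asarray(sorted(grp.time_h.unique()))
            t_index = {t: i for i, t in enumerate(times)}
            rows_idx = np.array([t_index[t] for t in grp.time_h])
            cols = np.array([_STATE_COLUMN[(a, c)] for a, c in
                             zip(grp.analyte, grp.compartment)])
            vols = np.where(cols % 3 == 0, geom.v_media, geom.v_insert)
            obs = np.log(np.maximum(grp.conc_uM.to_numpy(),
                                    spec.conc_floor))
            self.conditions.append({
                "dose_umol": float(dose) * geom.v_media / 1000.0,
                "geom": geom.with_cells(float(cells)),
                "times": times, "row_idx": rows_idx, "col_idx": cols,
                "vols": vols, "log_obs": obs,
            })
        self.n_obs = int(sum(len(c["log_obs"]) for c in self.conditions))
        n_series = df.groupby(["dose_uM", "cells", "analyte"]).time_h.nunique()
        if (n_series < 3).any():
            raise InsufficientDataError(
                "every fitted series needs >= 3 distinct time points")
        self._validate_identifiability(df)

    def _validate_identifiability(self, df: pd.DataFrame) -> None:
        spec = self.spec
        has_metabolite = (df.analyte == "metabolite").any()
        needs_met = {"metabolite_a_max", "metabolite_fraction"} & set(spec.free)
        if needs_met and not has_metabolite:
            raise IdentifiabilityError(
                f"{sorted(needs_met)} free but no metabolite observations")
        n_densities = df.cells.nunique()
        if ("scaling_exponent" in spec.free
                and "cl_per_cell" in spec.free and n_densities < 2):
            warnings.warn(
                "scaling_exponent and cl_per_cell are jointly free with a "
                "single cell density; they are not separately identifiable",
                stacklevel=3)

    def residuals(self, free_values: Sequence[float]) -> np.ndarray:
        mp = _build_params(self.spec.full_values(free_values))
        parts = []
        for c in self.conditions:
            y = integrate_metabolism_amounts(
                c["geom"], mp, c["dose_umol"], c["times"], rtol=self.rtol)
            conc = y[c["row_idx"], c["col_idx"]] / c["vols"]
            pred = np.log(np.maximum(conc, self.spec.conc_floor))
            parts.append(pred - c["log_obs"])
        return np.concatenate(parts)

    def sse(self, free_values: Sequence[float]) -> float:
        r = self.residuals(free_values)
        return float(r @ r)


def _multistart_points(spec: FitSpec, n_starts: int,
                       rng: np.random.Generator) -> list:
    init = dict(_DEFAULT_INIT)
    if spec.init:
        init.update(spec.init)
    starts = [np.array([init[name] for name in spec.free])]
    log_ranges = {"parent_a_max": (-4, 0), "metabolite_a_max": (-4, 0),
                  "cl_per_cell": (-8, -4), "metabolite_fraction": (-3, 0)}
    for _ in range(n_starts - 1):
        pt = []
        for name in spec.free:
            if name in log_ranges:
                lo, hi = log_ranges[name]
                pt.append(10.0 ** rng.uniform(lo, hi))
            else:
                pt.append(rng.uniform(0.0, 2.0))
        starts.append(np.array(pt))
    return starts


def _polish(problem: _Problem, x0: np.ndarray,
            max_nfev: Optional[int] = None):
    lb = np.array([PARAMETER_BOUNDS[n][0] for n in problem.spec.free])
    ub = np.array([PARAMETER_BOUNDS[n][1] for n in problem.spec.free])
    x0 = np.clip(x0, lb, ub)
    return optimize.least_squares(
        problem.residuals, x0, bounds=(lb, ub), method="trf",
        x_scale="jac", ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=max_nfev)


def _nelder_mead(problem: _Problem, x0: np.ndarray,
                 maxiter: int = 150) -> np.ndarray:
    lb = np.array([PARAMETER_BOUNDS[n][0] for n in problem.spec.free])
    ub = np.array([PARAMETER_BOUNDS[n][1] for n in problem.spec.free])

    def obj(x):
        return problem.sse(np.clip(x, lb, ub))

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-8,
                                     "fatol": 1e-10})
    return np.clip(res.x, lb, ub)


def fit_metabolism(data: pd.DataFrame, spec: FitSpec, geom: SystemGeometry,
                   multistart: int = 5, seed: int = 0,
                   nelder_mead_prestart: bool = True,
                   rtol: float = 1e-8) -> FitResult:
    """Estimate the free metabolism parameters from tidy observations.

    Minimises the sum of squared residuals on ln(concentration) across
    every mapped series, replicate and condition.  ``multistart`` starting
    points (the configured initial values plus log-uniform draws) each run
    an optional capped Nelder–Mead pre-search followed by a bounded
    trust-region least-squares polish; the best SSE wins.  %RSE comes from
    the Jacobian covariance at the optimum: 100·SE/|estimate|.

    Raises :class:`FitConvergenceError` if no start converges and
    :class:`IdentifiabilityError` for specs the data cannot identify.
    """
    problem = _Problem(data, spec, geom, rtol=rtol)
    if not spec.free:
        # evaluation-only: echo the fixed values with their objective
        sse = problem.sse(np.empty(0))
        return FitResult(estimates=spec.full_values(()), pct_rse={}, se={},
                         objective=sse, converged=True,
                         n_obs=problem.n_obs, free=())
    rng = np.random.default_rng(seed)
    best = None
    last_x = None
    for x0 in _multistart_points(spec, multistart, rng):
        try:
            if nelder_mead_prestart:
                x0 = _nelder_mead(problem, x0)
            res = _polish(problem, x0)
            last_x = res.x
        except (ValueError, RuntimeError):
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitConvergenceError("no optimisation start converged",
                                  last_iterate=last_x)

    sse = float(2.0 * best.cost)
    m, k = problem.n_obs, len(spec.free)
    jac = best.jac
    if m > k:
        s2 = sse / (m - k)
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    else:
        se_vec = np.full(k, np.nan)
    estimates = problem.spec.full_values(best.x)
    se = dict(zip(spec.free, (float(s) for s in se_vec)))
    rse = {name: (percent_rse(estimates[name], se[name])
                  if estimates[name] != 0 and np.isfinite(se[name])
                  else float("inf"))
           for name in spec.free}
    return FitResult(estimates=estimates, pct_rse=rse, se=se,
                     objective=sse, converged=True, n_obs=m,
                     free=tuple(spec.free))


def _resample(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample replicate curves with replacement within each condition.

    The resampling unit is one replicate's full curve (all analytes and
    times) within a (dose, cells) condition, preserving within-curve
    correlation.  Duplicated draws get fresh replicate labels.
    """
    pieces = []
    for (dose, cells), grp in data.groupby(["dose_uM", "cells"], sort=True):
        reps = sorted(grp.replicate.unique())
        draws = rng.choice(reps, size=len(reps), replace=True)
        for new_id, rep in enumerate(draws, start=1):
            piece = grp[grp.replicate == rep].copy()
            piece["replicate"] = new_id
            pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def bootstrap_fit(data: pd.DataFrame, spec: FitSpec, geom: SystemGeometry,
                  n: int = 500, seed: Optional[int] = None,
                  point: Optional[FitResult] = None,
                  max_failure_fraction: float = 0.20,
                  rtol: float = 1e-8) -> BootstrapResult:
    """Nonparametric bootstrap of the metabolism fit.

    ``n`` resampled datasets (replicate curves drawn with replacement
    within condition) are each refitted by a single bounded least-squares
    run warm-started at the point estimate.  Returns per-parameter median
    and bootstrap %RSE (100·SD/|median|).  Resamples whose refit fails
    are recorded and excluded; more than ``max_failure_fraction`` failures
    raises :class:`FitConvergenceError`.  Reproducible under ``seed``.
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    n_units = data.groupby(["dose_uM", "cells"]).replicate.nunique().sum()
    if n_units < 2:
        raise InsufficientDataError("need >= 2 resampling units")
    if point is None:
        point = fit_metabolism(data, spec, geom, seed=0)
    x_point = np.array([point.estimates[name] for name in spec.free])
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n):
        sample = _resample(data, rng)
        try:
            problem = _Problem(sample, spec, geom, rtol=rtol)
            res = _polish(problem, x_point, max_nfev=200)
            if not res.success:
                raise FitConvergenceError("resample fit did not converge")
            rows.append(dict(zip(spec.free, res.x)))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_fraction * n:
        raise FitConvergenceError(
            f"{n_failed}/{n} bootstrap refits failed")
    samples = pd.DataFrame(rows)
    median = {name: float(samples[name].median()) for name in spec.free}
    rse = {}
    for name in spec.free:
        sd = float(samples[name].std(ddof=1))
        rse[name] = (percent_rse(median[name], sd)
                     if median[name] != 0 else float("inf"))
    return BootstrapResult(n_resamples=n, n_failed=n_failed, median=median,
                           pct_rse=rse, samples=samples)
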