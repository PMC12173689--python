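"""Synthetic concentration–time datasets for the three benchmark studies.

Real observations from the insert system are not published, so every fit
and round-trip in this package runs against data generated here.  The
generators reproduce the experimental designs exactly — compound, dose
levels, mesh, cell densities, sampling schedules, triplicates — and add
multiplicative lognormal observation noise with a configurable CV
(default 10%).  Each (condition, replicate, analyte) series draws from its
own seeded substream, so row order never changes the values.

Designs:

* rosiglitazone diffusion — 50 µM in the medium, cell-free inserts with
  125/230/686 meshes (the diffusion-characterisation study);
* diclofenac metabolism — 40 µM, 508 mesh, 1/2/5 × 1e5 cells, parent
  sampled at 9 times and 4-hydroxydiclofenac at 6 times in the insert;
* testosterone metabolism — 1/5/20 µM, 508 mesh, 5 × 1e5 cells, parent
  only at 8 times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import reference
from .exceptions import ValidationError
from .kinetics import simulate_diffusion, simulate_metabolism
from .params import MetabolismParams, SystemGeometry, WeibullParams

__all__ = [
    "ExperimentDesign",
    "rosiglitazone_design",
    "diclofenac_design",
    "testosterone_design",
    "default_metabolism_params",
    "generate_diffusion_dataset",
    "generate_metabolism_dataset",
    "to_ng_per_ml",
]

#: parent sampling schedule of the diclofenac study, h
DICLOFENAC_PARENT_TIMES = (0.17, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0)
#: metabolite sampling schedule of the diclofenac study, h
DICLOFENAC_METABOLITE_TIMES = (3.0, 6.0, 12.0, 24.0, 48.0, 72.0)
#: testosterone sampling schedule, h
TESTOSTERONE_TIMES = (1.0, 3.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0)
#: diffusion sampling grid (the published study does not print one;
#: chosen to resolve both the fast early phase and the plateau)
DIFFUSION_TIMES = (0.08, 0.17, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """One experiment: compound, doses, mesh, cells, schedules, noise."""

    compound: str
    molar_mass: float
    doses_uM: Tuple[float, ...]
    mesh_count: int
    cell_densities: Tuple[float, ...] = (0.0,)
    times_parent: Tuple[float, ...] = DIFFUSION_TIMES
    times_metabolite: Tuple[float, ...] = ()
    metabolite_name: Optional[str] = None
    replicates: int = 3
    noise_cv: float = 0.10
    compartments: Tuple[str, ...] = ("insert",)

    def __post_init__(self):
        for ts in (self.times_parent, self.times_metabolite):
            if list(ts) != sorted(ts):
                raise ValidationError("sampling times must be sorted")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not self.doses_uM:
            raise ValidationError("need at least one dose level")


def rosiglitazone_design(noise_cv: float = 0.10) -> ExperimentDesign:
    """50 µM rosiglitazone diffusion across 125/230/686 meshes (the mesh
    key is carried per-series; ``mesh_count`` holds the first)."""
    return ExperimentDesign(
        compound="rosiglitazone",
        molar_mass=reference.MOLAR_MASS["rosiglitazone"],
        doses_uM=(50.0,), mesh_count=125, noise_cv=noise_cv)


def diclofenac_design(noise_cv: float = 0.10) -> ExperimentDesign:
    """40 µM diclofenac, 508 mesh, 1/2/5 × 1e5 cells, metabolite tracked."""
    return ExperimentDesign(
        compound="diclofenac",
        molar_mass=reference.MOLAR_MASS["diclofenac"],
        doses_uM=(40.0,), mesh_count=508,
        cell_densities=(1e5, 2e5, 5e5),
        times_parent=DICLOFENAC_PARENT_TIMES,
        times_metabolite=DICLOFENAC_METABOLITE_TIMES,
        metabolite_name="4-hydroxydiclofenac",
        noise_cv=noise_cv)


def testosterone_design(noise_cv: float = 0.10) -> ExperimentDesign:
    """1/5/20 µM testosterone, 508 mesh, 5 × 1e5 cells, parent only."""
    return ExperimentDesign(
        compound="testosterone",
        molar_mass=reference.MOLAR_MASS["testosterone"],
        doses_uM=(1.0, 5.0, 20.0), mesh_count=508,
        cell_densities=(5e5,),
        times_parent=TESTOSTERONE_TIMES,
        noise_cv=noise_cv)


def default_metabolism_params(compound: str) -> MetabolismParams:
    """Benchmark point estimates as generating parameters."""
    if compound == "diclofenac":
        e = reference.DICLOFENAC_ESTIMATES
        return MetabolismParams.with_shared_shape(
            WeibullParams(e["parent_a_max"], e["alpha"], e["beta"]),
            metabolite_a_max=e["metabolite_a_max"],
            cl_per_cell=e["cl_per_cell"],
            metabolite_fraction=e["metabolite_fraction"],
            scaling_exponent=e["scaling_exponent"])
    if compound == "testosterone":
        e = reference.TESTOSTERONE_ESTIMATES
        return MetabolismParams.with_shared_shape(
            WeibullParams(e["parent_a_max"], e["alpha"], e["beta"]),
            metabolite_a_max=0.0,
            cl_per_cell=e["cl_per_cell"],
            metabolite_fraction=0.0,
            scaling_exponent=e["scaling_exponent"])
    raise ValidationError(f"no default metabolism parameters for {compound!r}")


def _series_rng(seed: int, index: int) -> np.random.Generator:
    # one independent substream per observed series
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _noisy(conc: np.ndarray, cv: float,
           rng: np.random.Generator) -> np.ndarray:
    if cv == 0.0:
        return conc.copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    return conc * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                size=conc.shape)


_COLUMNS = ["compound", "analyte", "compartment", "time_h", "conc_uM",
            "replicate", "cells", "mesh", "dose_uM"]


def generate_diffusion_dataset(
    design: ExperimentDesign,
    weibull_by_mesh: Optional[Dict[int, WeibullParams]] = None,
    seed: int = 0,
    geom: Optional[SystemGeometry] = None,
) -> pd.DataFrame:
    """Noisy insert cumulative-concentration profiles per mesh.

    Simulates the cell-free diffusion model for each mesh and replicate
    and applies multiplicative lognormal noise.  Row count is
    ``len(meshes) * replicates * len(times)``.
    """
    weibull_by_mesh = weibull_by_mesh or reference.WEIBULL_BY_MESH
    geom = geom or SystemGeometry()
    dose_umol = design.doses_uM[0] * geom.v_media / 1000.0
    times = np.asarray(design.times_parent)
    rows = []
    series_index = 0
    for mesh, wp in weibull_by_mesh.items():
        sim = simulate_diffusion(geom, wp, dose_umol, times)
        ins = sim[(sim.analyte == "parent")
                  & (sim.compartment == "insert")].conc_uM.to_numpy()
        for rep in range(1, design.replicates + 1):
            rng = _series_rng(seed, series_index)
            series_index += 1
            conc = _noisy(ins, design.noise_cv, rng)
            rows.append(pd.DataFrame({
                "compound": design.compound, "analyte": "parent",
                "compartment": "insert", "time_h": times, "conc_uM": conc,
                "replicate": rep, "cells": 0.0, "mesh": mesh,
                "dose_uM": design.doses_uM[0]}))
    return pd.concat(rows, ignore_index=True)[_COLUMNS]


def generate_metabolism_dataset(
    design: ExperimentDesign,
    mp: Optional[MetabolismParams] = None,
    seed: int = 0,
    geom: Optional[SystemGeometry] = None,
) -> pd.DataFrame:
    """Noisy insert observations of the four-compartment model.

    One simulated system per (dose, cell density); observations are
    emitted for the insert parent at ``times_parent`` and, when a
    metabolite is tracked, the insert metabolite at ``times_metabolite``.
    The diclofenac design yields 81 parent + 54 metabolite rows; the
    testosterone design 72 parent rows.
    """
    mp = mp or default_metabolism_params(design.compound)
    geom = geom or SystemGeometry()
    track_metabolite = (design.metabolite_name is not None
                        and len(design.times_metabolite) > 0)
    all_times = np.asarray(sorted(set(design.times_parent)
                                  | set(design.times_metabolite)))
    rows = []
    series_index = 0
    for dose_uM in design.doses_uM:
        dose_umol = dose_uM * geom.v_media / 1000.0
        for n_cells in design.cell_densities:
            g = geom.with_cells(n_cells)
            sim = simulate_metabolism(g, mp, dose_umol, all_times)
            specs = [("parent", design.compound, design.times_parent)]
            if track_metabolite:
                specs.append(("metabolite", design.metabolite_name,
                              design.times_metabolite))
            for compartment in design.compartments:
                for analyte, label, times in specs:
                    sel = sim[(sim.analyte == analyte)
                              & (sim.compartment == compartment)]
                    sel = sel.set_index("time_h").loc[list(times)]
                    clean = sel.conc_uM.to_numpy()
                    for rep in range(1, design.replicates + 1):
                        rng = _series_rng(seed, series_index)
                        series_index += 1
                        conc = _noisy(clean, design.noise_cv, rng)
                        rows.append(pd.DataFrame({
                            "compound": label, "analyte": analyte,
                            "compartment": compartment,
                            "time_h": np.asarray(times), "conc_uM": conc,
                            "replicate": rep, "cells": n_cells,
                            "mesh": design.mesh_count, "dose_uM": dose_uM}))
    return pd.concat(rows, ignore_index=True)[_COLUMNS]


def to_ng_per_ml(df: pd.DataFrame,
                 molar_mass: Optional[Dict[str, float]] = None
                 ) -> pd.DataFrame:
    """Add a ``conc_ng_mL`` column (µM × g/mol = ng/mL) for format
    realism when exporting assay-style tables."""
    molar_mass = molar_mass or reference.MOLAR_MASS
    out = df.copy()
    masses = out["compound"].map(molar_mass)
    if masses.isna().any():
        missing = sorted(out.loc[masses.isna(), "compound"].unique())
        raise ValidationError(f"no molar mass for compounds: {missing}")
    out["conc_ng_mL"] = out["conc_uM"] * masses
    return out
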