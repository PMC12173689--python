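"""Published reference values for the characterised mesh-insert system.

These constants are the benchmark characterisation of the biomimetic
system and its two probe compounds: measured mesh pore areas, per-mesh
Weibull transfer parameters fitted to rosiglitazone diffusion, the fitted
metabolism parameters for diclofenac (CYP2C9 probe) and testosterone
(CYP3A4 probe), and the physiological constants of the hepatic-clearance
scaling chain.  They serve as inputs for worked examples, regression tests
and the default synthetic-data designs.
"""

from __future__ import annotations

from .params import MeshSpec, WeibullParams

# ---------------------------------------------------------------------------
# Mesh characterisation
# ---------------------------------------------------------------------------

#: SEM-measured pore areas (µm²) by mesh count; the 686 mesh is too dense to
#: measure directly and its pore area is predicted by regression.
MEASURED_PORE_AREAS = {125: 13033.0, 230: 4259.0, 508: 400.0}

#: regression-estimated pore area of the 686 mesh, µm²
PORE_AREA_686 = 211.05

MESHES = {
    125: MeshSpec(125, 13033.0, measured=True, source="SEM"),
    230: MeshSpec(230, 4259.0, measured=True, source="SEM"),
    508: MeshSpec(508, 400.0, measured=True, source="SEM"),
    686: MeshSpec(686, PORE_AREA_686, measured=False, source="regression"),
}

#: Weibull transfer parameters fitted per mesh from 50 µM rosiglitazone
#: diffusion (training rows of the pore→parameter regressions; the 686-mesh
#: row uses the regression-estimated pore area 211 µm²).
WEIBULL_BY_MESH = {
    125: WeibullParams(a_max=0.011, alpha=0.15, beta=-12.1),
    230: WeibullParams(a_max=0.0024, alpha=0.49, beta=-8.05),
    686: WeibullParams(a_max=0.00064, alpha=1.66, beta=-2.61),
}

#: pore areas (µm²) paired with WEIBULL_BY_MESH for regression training
WEIBULL_TRAINING_PORES = {125: 13033.0, 230: 4259.0, 686: 211.0}

#: 508-mesh Weibull parameters obtained from the pore→parameter regressions
#: at the measured 400 µm² pore area (used for both metabolism studies)
WEIBULL_508 = WeibullParams(a_max=0.001, alpha=1.565, beta=-3.3)

# ---------------------------------------------------------------------------
# Fitted metabolism-model parameters (point estimates)
# ---------------------------------------------------------------------------

#: diclofenac (40 µM, 508 mesh, 1/2/5 × 1e5 HepaRG cells per insert)
DICLOFENAC_ESTIMATES = {
    "parent_a_max": 0.0631,       # 1/h
    "metabolite_a_max": 0.0299,   # 1/h
    "alpha": 1.56,                # h (fixed from the mesh regression)
    "beta": -3.3,                 # fixed from the mesh regression
    "cl_per_cell": 4.7e-6,        # 1/h/cell
    "metabolite_fraction": 0.015,
    "scaling_exponent": 0.643,
}

#: testosterone (1/5/20 µM, 508 mesh, 5 × 1e5 HepaRG cells per insert)
TESTOSTERONE_ESTIMATES = {
    "parent_a_max": 0.253,        # 1/h
    "alpha": 1.565,               # h (fixed from the mesh regression)
    "beta": -3.3,                 # fixed
    "cl_per_cell": 9.56e-6,       # 1/h/cell
    "scaling_exponent": 0.589,
}

# ---------------------------------------------------------------------------
# Physiological & compound constants of the clearance-scaling chain
# ---------------------------------------------------------------------------

#: hepatocytes per gram of liver, 1e6 cells/g
HPGL = 99.0
#: liver weight scaling for a 70 kg adult, g liver / kg body weight
LIVER_PER_KG = 25.7
#: hepatic blood flow, mL/min/kg
Q_HEPATIC = 20.7

#: HepaRG/hepatocyte metabolic activity ratios (compound-specific CYPs)
ACTIVITY_RATIO = {"diclofenac": 0.3, "testosterone": 0.7}

#: unbound fraction in blood
F_U = {"diclofenac": 0.005, "testosterone": (0.01, 0.04)}

#: unbound fraction in the cell incubation (nonspecific-binding correction)
F_U_INC = {"diclofenac": 0.963, "testosterone": 0.872}

#: lipophilicity (logP/logD7.4) used by the incubation-binding relationship;
#: reproduces the tabulated unbound incubation fractions at V_R = 0.0025
LOG_PD = {"diclofenac": 1.3, "testosterone": 2.9}

#: hepatocyte:medium volume ratio at 5e5 cells in 1 mL
V_R_DEFAULT = 0.0025

MOLAR_MASS = {
    "rosiglitazone": 357.43,
    "diclofenac": 296.15,
    "4-hydroxydiclofenac": 312.15,
    "testosterone": 288.42,
}
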