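"""Domain types shared across the package.

The biomimetic culture system is a single well containing a porous-mesh
insert.  Drug placed in the stirred medium equilibrates into the insert at a
rate controlled by the mesh pore area; hepatic cells seeded inside the insert
metabolise the drug.  These dataclasses describe the mesh, the Weibull
transfer-rate law, the well geometry, and the cellular metabolism parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .exceptions import DomainError

#: reference cell count for the cell-number scaling law (cells per insert)
DEFAULT_REFERENCE_CELLS = 1e5


@dataclass(frozen=True)
class MeshSpec:
    """A woven mesh insert.

    Parameters
    ----------
    mesh_count : float
        Mesh fineness (threads per inch), > 0.
    pore_area : float
        Open pore cross-section in µm², > 0.  Either measured from
        electron-microscopy images or predicted by the pore-size regression.
    measured : bool
        True when the pore area is a direct measurement.
    source : str, optional
        Annotation for measured meshes (e.g. "SEM").
    """

    mesh_count: float
    pore_area: float
    measured: bool = True
    source: Optional[str] = None

    def __post_init__(self):
        if self.mesh_count <= 0:
            raise DomainError(f"mesh_count must be > 0, got {self.mesh_count}")
        if self.pore_area <= 0:
            raise DomainError(f"pore_area must be > 0, got {self.pore_area}")


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the Weibull transfer-rate law.

    The instantaneous transfer-rate coefficient is

        k(t) = a_max * (1 - exp(-(t / alpha) ** beta))

    With negative ``beta`` (every fitted mesh) the rate starts at ``a_max``
    at t=0 and decays towards zero, freezing the system at its equilibrium.

    Attributes
    ----------
    a_max : float
        Maximum transfer rate, 1/h (> 0).
    alpha : float
        Weibull scale, hours (> 0).
    beta : float
        Weibull shape, dimensionless (non-zero; negative in all fitted
        meshes).
    """

    a_max: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.a_max < 0:
            raise DomainError(f"a_max must be >= 0, got {self.a_max}")
        if self.alpha <= 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if self.beta == 0:
            raise DomainError("beta must be non-zero")


@dataclass(frozen=True)
class SystemGeometry:
    """Volumes and cell loading of one well + insert.

    ``v_insert`` defaults to 1.0 mL and ``v_media`` to 2.0 mL; ``n_ref`` is
    the reference cell count of the cell-number scaling law.
    """

    v_media: float = 2.0
    v_insert: float = 1.0
    n_cells: float = 0.0
    n_ref: float = DEFAULT_REFERENCE_CELLS
    mesh: Optional[MeshSpec] = None

    def __post_init__(self):
        if self.v_media <= 0 or self.v_insert <= 0:
            raise DomainError("compartment volumes must be > 0")
        if self.n_cells < 0:
            raise DomainError("n_cells must be >= 0")
        if self.n_ref <= 0:
            raise DomainError("n_ref must be > 0")

    def with_cells(self, n_cells: float) -> "SystemGeometry":
        return replace(self, n_cells=n_cells)


def cell_clearance_rate(geom: SystemGeometry, cl_per_cell: float,
                        scaling_exponent: float) -> float:
    """Total cellular elimination rate constant, 1/h.

    The per-cell clearance scales sub- (or supra-) proportionally with the
    seeded cell number N:

        CL_cells = cl_per_cell * N * (N / n_ref) ** scaling_exponent

    so the *per-cell* rate at N relative to n_ref is (N/n_ref)**SF; with
    SF = 0.643 the per-cell fold is 2**0.643 = 1.56 at 2e5 cells and
    5**0.643 = 2.81 at 5e5 cells.  Divided by the insert volume this gives
    the first-order elimination rate applied to the insert amount.
    """
    if cl_per_cell < 0:
        raise DomainError("cl_per_cell must be >= 0")
    if scaling_exponent < 0:
        raise DomainError("scaling_exponent must be >= 0")
    if geom.n_cells == 0:
        return 0.0
    n = geom.n_cells
    return cl_per_cell * n * (n / geom.n_ref) ** scaling_exponent / geom.v_insert


@dataclass(frozen=True)
class MetabolismParams:
    """Cellular metabolism and transfer parameters of the four-compartment
    model.

    Attributes
    ----------
    parent_release : WeibullParams
        Medium→insert transfer law for the parent drug.
    metabolite_release : WeibullParams
        Insert→medium transfer law for the metabolite.  Only its maximum
        rate is usually identifiable; scale/shape default to the parent's.
    cl_per_cell : float
        Per-cell elimination rate, 1/h/cell (convertible to mL/min/1e6
        cells via :func:`meshivive.ivive.cl_per_cell_to_clint`).
    metabolite_fraction : float
        Fraction of eliminated parent converted to the measured metabolite,
        in [0, 1]; the remainder leaves through other pathways.
    scaling_exponent : float
        Exponent of the cell-number scaling law (>= 0).
    """

    parent_release: WeibullParams
    metabolite_release: WeibullParams
    cl_per_cell: float = 0.0
    metabolite_fraction: float = 0.0
    scaling_exponent: float = 0.0

    def __post_init__(self):
        if self.cl_per_cell < 0:
            raise DomainError("cl_per_cell must be >= 0")
        if not 0.0 <= self.metabolite_fraction <= 1.0:
            raise DomainError("metabolite_fraction must be in [0, 1]")
        if self.scaling_exponent < 0:
            raise DomainError("scaling_exponent must be >= 0")

    @classmethod
    def with_shared_shape(cls, parent_release: WeibullParams,
                          metabolite_a_max: float = 0.0, **kwargs
                          ) -> "MetabolismParams":
        """Build params whose metabolite transfer shares the parent's
        scale/shape (the usual identifiable parameterisation)."""
        met = WeibullParams(metabolite_a_max, parent_release.alpha,
                            parent_release.beta)
        return cls(parent_release=parent_release, metabolite_release=met,
                   **kwargs)
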