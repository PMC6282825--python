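"""Spherical-harmonic shim basis, design matrices, residual projection.

Scanner shim coils generate fields shaped like the real solid harmonics of
first and second order: X, Y, Z, Z2 = 2z^2 - x^2 - y^2, ZX = zx, ZY = zy,
X2-Y2 = x^2 - y^2, XY = xy.  Coefficients are expressed in "Hz at the
reference radius": each term is scaled so that a unit coefficient produces
``scale`` Hz at ``reference_radius`` on the term's principal axis (the
direction maximizing |term| on the reference sphere).  Conversion to coil
amperes is an external calibration and is out of scope.

The constant (center-frequency) term is excluded from the basis: scanners
apply it as a transmitter frequency offset, which the solvers report as the
post-shim mean over the brain ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fieldmap import FieldMap, RegionMask
from .grid import Grid

SH_TERMS = ("X", "Y", "Z", "Z2", "ZX", "ZY", "X2-Y2", "XY")
N_TERMS = len(SH_TERMS)


@dataclass(frozen=True)
class ShimBasis:
    """First- plus second-order shim terms in field units.

    reference_radius : mm; scale : Hz produced at the reference radius per
    unit coefficient, for every term.
    """

    terms: tuple[str, ...] = SH_TERMS
    reference_radius: float = 200.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.terms != SH_TERMS:
            raise ValueError(f"basis terms must be {SH_TERMS}")
        if self.reference_radius <= 0 or self.scale <= 0:
            raise ValueError("reference radius and scale must be positive")

    @property
    def n_terms(self) -> int:
        return N_TERMS


@dataclass(frozen=True)
class ShimLimits:
    """Per-term hardware coefficient bounds (same units as coefficients).

    The defaults are placeholders; real systems must supply their own.
    """

    lb: np.ndarray = field(default_factory=lambda: np.full(N_TERMS, -2000.0))
    ub: np.ndarray = field(default_factory=lambda: np.full(N_TERMS, 2000.0))

    def __post_init__(self) -> None:
        lb = np.asarray(self.lb, dtype=float)
        ub = np.asarray(self.ub, dtype=float)
        if lb.shape != (N_TERMS,) or ub.shape != (N_TERMS,):
            raise ValueError(f"bounds must have {N_TERMS} entries")
        if np.any(lb > ub):
            raise ValueError("lower bounds exceed upper bounds")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)


@dataclass
class DesignMatrix:
    """Shim-term values per mask voxel: rows follow the mask's deterministic
    voxel order (x fastest), columns follow SH_TERMS."""

    values: np.ndarray      # (N_voxels, 8), Hz per unit coefficient
    voxel_index: np.ndarray  # (N_voxels, 3) int grid indices
    region: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != N_TERMS:
            raise ValueError(f"design matrix must have {N_TERMS} columns")
        if self.values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("row count must match voxel index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite design-matrix entries")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def _raw_terms(x, y, z):
    return (x, y, z, 2 * z**2 - x**2 - y**2, z * x, z * y, x**2 - y**2, x * y)


def _term_norms(radius: float) -> np.ndarray:
    """max |term| over the sphere of the given radius, per term."""
    r = radius
    return np.array([r, r, r, 2 * r**2, r**2 / 2, r**2 / 2, r**2, r**2 / 2])


def evaluate_basis(coords: np.ndarray, basis: ShimBasis = ShimBasis()) -> np.ndarray:
    """Evaluate all 8 shim terms at physical points (mm).

    Parameters
    ----------
    coords : (N, 3) array of points in mm (isocenter origin).

    Returns
    -------
    (N, 8) array in Hz per unit coefficient.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 3 or not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite (N, 3) points in mm")
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    raw = np.stack(_raw_terms(x, y, z), axis=1)
    return raw * (basis.scale / _term_norms(basis.reference_radius))


def build_design_matrix(
    mask: RegionMask, basis: ShimBasis = ShimBasis()
) -> DesignMatrix:
    """Design matrix over a region: one row per mask voxel (voxel-center
    coordinates), deterministic x-fastest order."""
    if mask.count == 0:
        if mask.label == "brain":
            raise ValueError("empty brain mask: nothing to shim")
        warnings.warn(
            f"empty {mask.label} mask: constraints will be vacuous", stacklevel=2
        )
    idx = mask.index()
    coords = mask.grid.coords(idx)
    values = (
        evaluate_basis(coords, basis) if len(idx) else np.zeros((0, N_TERMS))
    )
    return DesignMatrix(values=values, voxel_index=idx, region=mask.label)


def evaluate_basis_on_grid(grid: Grid, basis: ShimBasis = ShimBasis()) -> np.ndarray:
    """All 8 term fields on the full grid, shape (*grid.shape, 8)."""
    X, Y, Z = grid.meshgrid()
    raw = np.stack(_raw_terms(X, Y, Z), axis=-1)
    return raw * (basis.scale / _term_norms(basis.reference_radius))


def project_shim(
    fieldmap: FieldMap,
    basis: ShimBasis,
    s: np.ndarray,
    limits: ShimLimits | None = None,
) -> FieldMap:
    """Residual field after applying shim coefficients ``s``.

    residual = field - sum_j s_j * term_j on the whole grid; the valid mask
    is unchanged.  Out-of-bounds coefficients only raise a warning, since
    projecting hypothetical settings is a legitimate simulation.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (N_TERMS,):
        raise ValueError(f"expected {N_TERMS} coefficients, got shape {s.shape}")
    if limits is not None and (np.any(s < limits.lb) or np.any(s > limits.ub)):
        warnings.warn("shim coefficients outside hardware bounds", stacklevel=2)
    shim_field = evaluate_basis_on_grid(fieldmap.grid, basis) @ s
    return FieldMap(
        freq=fieldmap.freq - shim_field, grid=fieldmap.grid, valid=fieldmap.valid
    )
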