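"""Synthetic maternal-abdomen phantom.

Generates the complete set of inputs the shimming pipeline consumes — dual
echo field-map images, a three-point Dixon triplet, ground-truth field map
and masks — from a parametric description: an elliptic torso cross-section
carrying water signal, a subcutaneous fat ring on its boundary carrying the
-430 Hz chemical-shift species, an ellipsoidal fetal-brain target, a smooth
background field expressed in the shim spherical-harmonic basis (so it is
exactly correctable), optional gas pockets adding analytic sphere-dipole
field perturbations (not in the harmonic span, hence never fully
correctable), and Gaussian noise.  Every draw is fixed by the spec's seed.

The default geometry mirrors a maternal-abdomen field-map acquisition:
350 x 350 x 100 mm field of view at 5 x 5 x 10 mm acquired resolution
(70 x 70 x 10 voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fieldmap import (
    FAT_SHIFT_HZ,
    EchoImage,
    EllipsoidROI,
    FieldMap,
    RegionMask,
    make_ellipsoid_roi,
)
from .grid import Grid
from .shim_model import ShimBasis, evaluate_basis_on_grid


@dataclass(frozen=True)
class GasPocket:
    """Spherical susceptibility perturber (intestinal gas).

    The external field is the analytic sphere dipole
    df = strength * (3 cos^2 theta - 1) / r^3  (theta from the B0/z axis,
    r in mm from the center); the field inside the sphere is set to zero
    and the sphere carries no signal.  ``strength`` is in Hz * mm^3.
    """

    center: tuple[float, float, float]
    radius: float
    strength: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (70, 70, 10)
    spacing: tuple[float, float, float] = (5.0, 5.0, 10.0)
    torso_semiaxes: tuple[float, float] = (160.0, 120.0)   # mm, x/y
    fat_ring_thickness: float = 15.0                        # mm
    brain: EllipsoidROI = EllipsoidROI(
        center=(25.0, 15.0, 0.0), semiaxes=(40.0, 40.0, 35.0)
    )
    background_coeffs: tuple[float, ...] = (
        300.0, -200.0, 100.0, 150.0, -100.0, 80.0, 120.0, -60.0
    )  # Hz at the 200 mm reference radius; ~36 Hz SD over the brain ROI
    gas_pockets: tuple[GasPocket, ...] = ()
    noise_sd: float = 0.0             # Hz, per-voxel field perturbation
    snr: float = float("inf")         # magnitude SNR; inf = noise-free echoes
    seed: int = 0
    chemical_shift: float = FAT_SHIFT_HZ
    te_fieldmap: tuple[float, float] = (4.6, 6.9)           # ms
    te_dixon: tuple[float, float, float] = (4.6, 5.6, 6.6)  # ms
    fat_fraction_ring: float = 0.95
    basis: ShimBasis = ShimBasis()

    @property
    def grid(self) -> Grid:
        return Grid.centered(self.shape, self.spacing)


@dataclass
class PhantomData:
    """Everything the pipeline needs, plus the ground truth behind it."""

    echo1: EchoImage
    echo2: EchoImage
    dixon_echoes: tuple[EchoImage, EchoImage, EchoImage]
    field_truth: FieldMap          # noiseless field (SH + dipoles), Hz
    brain_mask: RegionMask
    fat_mask: RegionMask           # ground-truth fat ring
    coeffs: np.ndarray             # ground-truth SH coefficients
    water_amp: np.ndarray
    fat_amp: np.ndarray
    spec: PhantomSpec


def _torso_rho(grid: Grid, semiaxes: tuple[float, float]) -> np.ndarray:
    X, Y, _ = grid.meshgrid()
    return np.sqrt((X / semiaxes[0]) ** 2 + (Y / semiaxes[1]) ** 2)


def _dipole_field(grid: Grid, pocket: GasPocket) -> tuple[np.ndarray, np.ndarray]:
    X, Y, Z = grid.meshgrid()
    dx, dy, dz = X - pocket.center[0], Y - pocket.center[1], Z - pocket.center[2]
    r2 = dx**2 + dy**2 + dz**2
    inside = r2 <= pocket.radius**2
    r2 = np.maximum(r2, 1e-9)
    cos2 = dz**2 / r2
    df = pocket.strength * (3.0 * cos2 - 1.0) / r2**1.5
    df[inside] = 0.0
    return df, inside


def generate_phantom(spec: PhantomSpec) -> PhantomData:
    """Forward-simulate the phantom described by ``spec``.

    The simulated field is  SH(background_coeffs) + dipoles + N(0, noise_sd);
    the returned ``field_truth`` excludes the noise term (it is what a
    perfect, noise-free measurement would see).  Echo images follow the
    two-species model  s(te) = (W + F exp(i 2 pi shift te)) exp(i 2 pi f te)
    with complex Gaussian receiver noise at the requested SNR.
    """
    grid = spec.grid
    a, b = spec.torso_semiaxes
    t = spec.fat_ring_thickness
    if t <= 0 or t >= min(a, b):
        raise ValueError("fat ring thickness must be positive and thinner than the torso")
    rho_out = _torso_rho(grid, (a, b))
    rho_in = _torso_rho(grid, (a - t, b - t))
    torso = rho_out <= 1.0
    ring = torso & (rho_in > 1.0)

    brain_mask = make_ellipsoid_roi(spec.brain, grid)
    c = np.asarray(spec.brain.center)
    ax = np.asarray(spec.brain.semiaxes)
    # brain must sit strictly inside the water compartment
    corners = c[None, :2] + np.array([[1, 0], [-1, 0], [0, 1], [0, -1]]) * ax[:2].max()
    if np.any((corners[:, 0] / (a - t)) ** 2 + (corners[:, 1] / (b - t)) ** 2 > 1.0):
        raise ValueError("brain ellipsoid extends into or beyond the fat ring")

    sh = evaluate_basis_on_grid(grid, spec.basis)
    coeffs = np.asarray(spec.background_coeffs, dtype=float)
    if coeffs.shape != (spec.basis.n_terms,):
        raise ValueError("background_coeffs must match the basis size")
    field_true = sh @ coeffs
    signal_free = ~torso
    for pocket in spec.gas_pockets:
        df, inside = _dipole_field(grid, pocket)
        if not np.all(torso[inside]):
            raise ValueError("gas pocket extends outside the torso")
        field_true = field_true + df
        signal_free = signal_free | inside

    rng = np.random.default_rng(spec.seed)
    field_sim = field_true + rng.normal(0.0, spec.noise_sd, grid.shape) \
        if spec.noise_sd > 0 else field_true

    water = np.where(torso & ~ring & ~signal_free, 1.0, 0.0)
    ff = spec.fat_fraction_ring
    water = np.where(ring, 1.0 - ff, water)
    fat = np.where(ring, ff, 0.0)

    def echo(te_ms: float) -> EchoImage:
        te_s = te_ms * 1e-3
        s = (water + fat * np.exp(2j * np.pi * spec.chemical_shift * te_s)) * np.exp(
            2j * np.pi * field_sim * te_s
        )
        if np.isfinite(spec.snr) and spec.snr > 0:
            sd = 1.0 / spec.snr
            s = s + rng.normal(0.0, sd, grid.shape) + 1j * rng.normal(
                0.0, sd, grid.shape
            )
        return EchoImage(data=s, te=te_ms, grid=grid)

    e1, e2 = (echo(te) for te in spec.te_fieldmap)
    dixon = tuple(echo(te) for te in spec.te_dixon)

    return PhantomData(
        echo1=e1,
        echo2=e2,
        dixon_echoes=dixon,
        field_truth=FieldMap(freq=field_true, grid=grid, valid=~signal_free),
        brain_mask=brain_mask,
        fat_mask=RegionMask(mask=ring, grid=grid, label="fat"),
        coeffs=coeffs,
        water_amp=water,
        fat_amp=fat,
        spec=spec,
    )


def best_sh_fit_floor(data: PhantomData) -> float:
    """Standard deviation (Hz) of the brain-ROI residual after the best
    unconstrained SH fit to the true field — the floor any solver can reach."""
    idx = data.brain_mask.index()
    A = evaluate_basis_on_grid(data.field_truth.grid, data.spec.basis)[
        tuple(idx.T)
    ]
    b = data.field_truth.freq[tuple(idx.T)]
    s, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = b - A @ s
    return float(np.std(r))


def scenario_library() -> dict[str, PhantomSpec]:
    """Named phantom presets covering the study's regimes.

    - ``pure-sh``: background exactly in the shim span; both solvers recover
      the ground truth and the fat constraints stay inactive.
    - ``fat-conflict``: a gas pocket beside an off-center fetal brain makes
      the localized fit extrapolate badly to the fat ring, pushing fat
      residuals outside the [-350, 100] Hz saturation band; the constrained
      solve pulls them back at a small brain-homogeneity cost.
    - ``gas``: a strong dipole overlapping the brain ROI that no first- plus
      second-order field can correct, leaving a large residual either way.
    """
    base = PhantomSpec()
    fat_conflict = replace(
        base,
        brain=EllipsoidROI(center=(45.0, 40.0, 0.0), semiaxes=(30.0, 30.0, 25.0)),
        gas_pockets=(
            GasPocket(center=(-15.0, 35.0, 0.0), radius=18.0, strength=2.0e6),
        ),
        seed=7,
    )
    gas = replace(
        base,
        gas_pockets=(
            GasPocket(center=(-40.0, 0.0, 0.0), radius=20.0, strength=3.0e6),
        ),
        seed=11,
    )
    return {"pure-sh": base, "fat-conflict": fat_conflict, "gas": gas}
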