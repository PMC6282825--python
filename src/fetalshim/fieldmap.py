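"""Field maps, Dixon fat-water separation, fat masks and ellipsoidal ROIs.

The B0 field map is estimated from two gradient-echo images whose echo
times are chosen so that water and fat are in phase (at 3 T the water-fat
shift is about -430 Hz, one in-phase period per 1000/|shift| ms), so the
subcutaneous fat ring does not alias into an apparent off-resonance.
Fat regions are segmented from a three-point Dixon acquisition, and the
shim target region is an ellipsoid circumscribing the fetal brain, drawn
in one slice and propagated through the stack.

Conventions: field maps are stored in Hz (deviation from the water center
frequency); the fat chemical shift defaults to -430 Hz, configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .grid import GeometryError, Grid, mask_index
from .unwrap import goldstein_unwrap_2d  # noqa: F401  (re-exported pipeline step)

FAT_SHIFT_HZ = -430.0  # water-fat shift at 3 T; -434 Hz for 3.4 ppm purists

#: validity threshold: fraction of the robust (99th-percentile) magnitude
DEFAULT_MAG_THRESHOLD = 0.05


class ParameterError(ValueError):
    """Raised for invalid acquisition or algorithm parameters."""


@dataclass(frozen=True)
class EchoImage:
    """One complex gradient-echo image.

    data : complex 3-D array (arbitrary units); te : echo time in ms.
    """

    data: np.ndarray
    te: float
    grid: Grid

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape != self.grid.shape:
            raise GeometryError(
                f"echo data shape {d.shape} does not match grid {self.grid.shape}"
            )
        if self.te <= 0:
            raise ParameterError(f"echo time must be positive, got {self.te} ms")
        object.__setattr__(self, "data", np.asarray(d, dtype=complex))


@dataclass
class FieldMap:
    """Scalar off-resonance map in Hz with a validity mask."""

    freq: np.ndarray
    grid: Grid
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.freq.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise GeometryError("field map arrays must match grid shape")
        if not np.all(np.isfinite(self.freq[self.valid])):
            raise ValueError("non-finite frequency on valid voxels")


@dataclass
class RegionMask:
    """Boolean mask over a grid with a semantic label (brain / fat / other)."""

    mask: np.ndarray
    grid: Grid
    label: str = "other"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GeometryError("mask shape must match grid shape")
        if self.label not in ("brain", "fat", "other"):
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def index(self) -> np.ndarray:
        return mask_index(self.mask)


@dataclass(frozen=True)
class EllipsoidROI:
    """Ellipsoid circumscribing the fetal brain; propagated over slices.

    center/semiaxes in mm (scanner coordinates); ``slice_range`` is an
    inclusive (z_first, z_last) index pair, or None for all slices.
    """

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    slice_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise ParameterError(f"semiaxes must be positive, got {self.semiaxes}")


class DixonResult(NamedTuple):
    water: np.ndarray
    fat: np.ndarray
    f0: np.ndarray


def in_phase_te2(te1: float, chemical_shift: float) -> float:
    """Second echo time (ms) putting water and fat back in phase.

    One chemical-shift beat period after te1, reported at 0.1 ms precision.
    """
    if chemical_shift == 0:
        raise ParameterError("chemical shift must be non-zero")
    return round(te1 + 1000.0 / abs(chemical_shift), 1)


def compute_fieldmap(
    echo1: EchoImage,
    echo2: EchoImage,
    mag_threshold: float = DEFAULT_MAG_THRESHOLD,
) -> FieldMap:
    """Wrapped field map from the inter-echo phase difference.

    freq = angle(echo2 * conj(echo1)) / (2*pi*dTE); values therefore lie in
    (-1/(2 dTE), +1/(2 dTE)].  Validity is a magnitude threshold at a
    fraction of the robust (99th percentile) maximum of the mean echo
    magnitude, which excludes background air without clipping fetal tissue.
    """
    echo1.grid.require_match(echo2.grid, "echoes")
    dte_s = (echo2.te - echo1.te) * 1e-3
    if dte_s <= 0:
        raise ParameterError("echo2 must be acquired later than echo1")
    phasor = echo2.data * np.conj(echo1.data)
    freq = np.angle(phasor) / (2.0 * np.pi * dte_s)
    mag = 0.5 * (np.abs(echo1.data) + np.abs(echo2.data))
    robust_max = np.percentile(mag, 99)
    valid = mag > mag_threshold * robust_max
    return FieldMap(freq=freq, grid=echo1.grid, valid=valid)


def unwrap_fieldmap(fmap: FieldMap, dte_ms: float) -> FieldMap:
    """Goldstein-unwrap a wrapped field map, slice by slice.

    The wrapped frequency is converted back to inter-echo phase
    (phase = 2*pi*freq*dTE, which lies in (-pi, pi] by construction),
    unwrapped, and converted to Hz again; voxels that could not be
    unwrapped are dropped from the valid mask.

    Unwrapping leaves one 2*pi freedom per connected component; it is
    resolved by assuming bulk tissue lies near the water resonance: each
    component is shifted by the multiple of 1/dTE that brings its median
    frequency into the Nyquist band (-1/(2 dTE), +1/(2 dTE)].  A region
    whose true median exceeds that band cannot be anchored correctly from
    this acquisition alone.
    """
    from scipy import ndimage

    if dte_ms <= 0:
        raise ParameterError("echo-time difference must be positive")
    scale = 2.0 * np.pi * dte_ms * 1e-3  # rad per Hz
    res = goldstein_unwrap_2d(fmap.freq * scale, fmap.valid)
    freq = res.phase / scale
    reliable = fmap.valid & res.reliable
    f_period = 1000.0 / dte_ms
    labels, n = ndimage.label(reliable)
    for lab in range(1, n + 1):
        sel = labels == lab
        k = np.rint(np.median(freq[sel]) / f_period)
        if k:
            freq[sel] -= k * f_period
    return FieldMap(freq=freq, grid=fmap.grid, valid=reliable)


def _fat_phasor(chemical_shift: float, te_ms: np.ndarray) -> np.ndarray:
    return np.exp(2j * np.pi * chemical_shift * te_ms * 1e-3)


def dixon_fat_water(
    echoes: Sequence[EchoImage],
    chemical_shift: float = FAT_SHIFT_HZ,
    f0_step: float = 4.0,
    mag_threshold: float = DEFAULT_MAG_THRESHOLD,
    f0_prior: np.ndarray | None = None,
) -> DixonResult:
    """Three-point Dixon separation with a single-peak fat model.

    Per voxel the model  s(te) = (W + F exp(i 2 pi shift te)) exp(i 2 pi f0 te)
    is inverted by variable projection: a coarse grid over the local
    off-resonance f0 (|f0| < 1/(2 dTE)) followed by Gauss-Newton refinement
    of f0, with the complex amplitudes solved linearly at each step.
    W and F are returned as non-negative magnitudes.

    The two-species model has an exact alias that swaps water and fat while
    shifting f0; among near-degenerate minima the solution whose f0 is
    closest to ``f0_prior`` (per-voxel expected off-resonance in Hz, e.g.
    the separately measured B0 map; default 0) is returned.  Without a
    prior the rule is safe only while the true |f0| stays below roughly
    half the alias spacing.
    """
    if len(echoes) != 3:
        raise ParameterError("three-point Dixon needs exactly three echoes")
    g = echoes[0].grid
    for e in echoes[1:]:
        g.require_match(e.grid, "Dixon echoes")
    tes = np.array([e.te for e in echoes], dtype=float)
    dte = np.diff(tes)
    if not np.allclose(dte, dte[0], rtol=1e-6) or dte[0] <= 0:
        raise ParameterError("Dixon echoes must be uniformly spaced in time")
    v = _fat_phasor(chemical_shift, tes)
    if np.allclose(v, v[0], atol=1e-9):
        raise ParameterError(
            "degenerate echo spacing: fat phasor identical at all echoes"
        )

    s = np.stack([e.data.reshape(-1) for e in echoes])  # (3, N)
    mag = np.abs(s).mean(axis=0)
    floor = mag_threshold * np.percentile(mag, 99)
    live = mag > floor

    f_nyq = 1000.0 / (2.0 * dte[0])
    cand = np.arange(-f_nyq, f_nyq, f0_step)

    if f0_prior is None:
        prior = np.zeros(int(live.sum()))
    else:
        prior = np.asarray(f0_prior, dtype=float).reshape(-1)[live]

    sl = s[:, live]
    n_live = sl.shape[1]
    f0 = np.zeros(n_live)
    if n_live:
        res_grid = np.empty((cand.size, n_live))
        for k, f in enumerate(cand):
            res_grid[k] = _vp_residual(sl, tes, v, f)
        f0a = _refine_f0(sl, tes, v, cand[np.argmin(res_grid, axis=0)])
        # the aliased (water-fat swapped) minimum sits exactly at
        # wrap(f0 - shift); both fit the data identically, so the prior
        # decides between them per voxel
        partner = f0a - chemical_shift
        partner = (partner + f_nyq) % (2.0 * f_nyq) - f_nyq
        f0b = _refine_f0(sl, tes, v, partner)
        f0 = np.where(np.abs(f0a - prior) <= np.abs(f0b - prior), f0a, f0b)

    Wl, Fl = _vp_amplitudes(sl, tes, v, f0)
    water = np.zeros(s.shape[1])
    fat = np.zeros(s.shape[1])
    f0_full = np.zeros(s.shape[1])
    water[live] = np.abs(Wl)
    fat[live] = np.abs(Fl)
    f0_full[live] = f0
    shape = g.shape
    return DixonResult(water.reshape(shape), fat.reshape(shape), f0_full.reshape(shape))


def _vp_design(tes: np.ndarray, v: np.ndarray, f0: np.ndarray):
    """Demodulation phasors, shape (3,) or (3, N)."""
    return np.exp(-2j * np.pi * np.multiply.outer(tes * 1e-3, f0))


def _vp_solve(sl: np.ndarray, v: np.ndarray, demod: np.ndarray):
    """Least-squares (W, F) complex amplitudes for demodulated signals."""
    d = sl * demod  # (3, N)
    # Gram matrix of [1, v] is constant across voxels
    g11 = 3.0
    g12 = np.sum(np.conj(v))
    g22 = 3.0
    p1 = d.sum(axis=0)
    p2 = (np.conj(v)[:, None] * d).sum(axis=0)
    det = g11 * g22 - np.abs(g12) ** 2
    W = (g22 * p1 - np.conj(g12) * p2) / det
    F = (g11 * p2 - g12 * p1) / det
    return W, F


def _vp_residual(sl: np.ndarray, tes: np.ndarray, v: np.ndarray, f0) -> np.ndarray:
    f0 = np.broadcast_to(np.asarray(f0, dtype=float), (sl.shape[1],))
    demod = _vp_design(tes, v, f0)
    W, F = _vp_solve(sl, v, demod)
    model = (W[None, :] + F[None, :] * v[:, None]) / demod
    return (np.abs(sl - model) ** 2).sum(axis=0)


def _vp_amplitudes(sl: np.ndarray, tes: np.ndarray, v: np.ndarray, f0: np.ndarray):
    demod = _vp_design(tes, v, np.broadcast_to(f0, (sl.shape[1],)))
    return _vp_solve(sl, v, demod)


def _refine_f0(sl: np.ndarray, tes: np.ndarray, v: np.ndarray,
               f0: np.ndarray, iters: int = 40) -> np.ndarray:
    """Gauss-Newton refinement of the per-voxel off-resonance.

    Fits the slope of the residual phase (signal vs current model) against
    echo time, weighted by model magnitude; converges quadratically near
    the optimum of the variable-projection objective.
    """
    te_s = tes * 1e-3
    f0 = f0.astype(float).copy()
    for _ in range(iters):
        demod = _vp_design(tes, v, f0)
        W, F = _vp_solve(sl, v, demod)
        model = (W[None, :] + F[None, :] * v[:, None]) / demod
        amp = np.abs(model)
        small = amp < 1e-12 * np.abs(sl).max()
        phase_err = np.angle(np.where(small, 1.0, sl * np.conj(model)))
        wgt = amp**2
        tbar = (wgt * te_s[:, None]).sum(axis=0) / np.maximum(wgt.sum(axis=0), 1e-30)
        tc = te_s[:, None] - tbar[None, :]
        denom = (wgt * tc**2).sum(axis=0)
        slope = (wgt * tc * phase_err).sum(axis=0) / np.maximum(denom, 1e-30)
        df = slope / (2.0 * np.pi)
        f0 += df
        if np.max(np.abs(df)) < 1e-10:
            break
    return f0


def segment_fat(
    fat: np.ndarray,
    water: np.ndarray,
    grid: Grid,
    threshold: float = 0.5,
    mag_threshold: float = DEFAULT_MAG_THRESHOLD,
) -> RegionMask:
    """Fat mask by thresholding the Dixon fat fraction F/(W+F).

    Voxels below the magnitude noise floor are excluded.  An empty mask is
    returned with a warning (constraints become vacuous downstream).
    """
    if not 0 < threshold < 1:
        raise ParameterError("fat-fraction threshold must be in (0, 1)")
    fat = np.asarray(fat, dtype=float)
    water = np.asarray(water, dtype=float)
    total = fat + water
    floor = mag_threshold * np.percentile(total, 99)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, fat / np.maximum(total, 1e-30), 0.0)
    mask = (frac > threshold) & (total > floor)
    if not mask.any():
        warnings.warn("fat segmentation produced an empty mask", stacklevel=2)
    return RegionMask(mask=mask, grid=grid, label="fat")


def make_ellipsoid_roi(roi: EllipsoidROI, grid: Grid) -> RegionMask:
    """Rasterize an ellipsoid ROI: voxel centers with
    sum(((x_i - c_i)/a_i)^2) <= 1, restricted to the ROI's slice range."""
    X, Y, Z = grid.meshgrid()
    c, a = roi.center, roi.semiaxes
    q = ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2
    mask = q <= 1.0
    if roi.slice_range is not None:
        z0, z1 = roi.slice_range
        keep = np.zeros(grid.shape[2], dtype=bool)
        keep[z0 : z1 + 1] = True
        mask &= keep[None, None, :]
    if not mask.any():
        raise ValueError("ellipsoid ROI does not intersect the grid (unshimmable)")
    return RegionMask(mask=mask, grid=grid, label="brain")
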