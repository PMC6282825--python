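"""Goldstein branch-cut phase unwrapping (2-D, applied slice by slice).

The field map is reconstructed from a wrapped phase difference, so every
value is only known modulo 2*pi.  On a residue-free slice, summing wrapped
phase gradients along any path gives a path-independent result; residues
(non-zero loop integrals around 2x2 pixel cells) break that independence.
The Goldstein approach pairs residues of opposite sign (or connects them to
the image border) with branch cuts, then integrates along paths that never
cross a cut, which restores path independence outside the cuts.

Implementation notes
--------------------
* Residues are computed on 2x2 cells whose four pixels are all valid; the
  charge is the loop integral of wrapped gradients divided by 2*pi.
* Cuts are rasterized as blocked pixels along the straight segment between
  the paired residue cell corners (8-connected Bresenham lines, which block
  the 4-connected integration front).  Blocked pixels are unwrapped last,
  from an already-unwrapped neighbour, and flagged as less reliable.
* Each 4-connected component of valid pixels is integrated independently,
  so the output is correct up to one additive multiple of 2*pi per
  component.  For 3-D input the per-slice 2*pi offsets are reconciled by
  shifting each slice so the median difference to the previous slice,
  inside the joint valid mask, is as close to zero as a 2*pi multiple
  allows.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

TWO_PI = 2.0 * np.pi


class UnwrapResult(NamedTuple):
    phase: np.ndarray
    reliable: np.ndarray  # voxels actually unwrapped (valid, reached)
    residue_count: int


def wrap_to_pi(phase: np.ndarray) -> np.ndarray:
    """Map phase into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, dtype=float), TWO_PI)


def residue_map(wrapped: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Integer residue charge per 2x2 cell of a 2-D wrapped-phase slice.

    Cell (i, j) covers pixels (i, j), (i+1, j), (i, j+1), (i+1, j+1); cells
    touching an invalid pixel carry charge 0.
    """
    w = np.asarray(wrapped, dtype=float)
    if w.ndim != 2:
        raise ValueError("residue_map expects a 2-D slice")
    d10 = wrap_to_pi(w[1:, :-1] - w[:-1, :-1])   # down left edge
    d11 = wrap_to_pi(w[1:, 1:] - w[1:, :-1])     # right along bottom
    d01 = wrap_to_pi(w[:-1, 1:] - w[1:, 1:])     # up right edge
    d00 = wrap_to_pi(w[:-1, :-1] - w[:-1, 1:])   # left along top
    q = d10 + d11 + d01 + d00
    charge = np.rint(q / TWO_PI).astype(int)
    if valid is not None:
        v = np.asarray(valid, dtype=bool)
        cell_ok = v[:-1, :-1] & v[1:, :-1] & v[:-1, 1:] & v[1:, 1:]
        charge = np.where(cell_ok, charge, 0)
    return charge


def _bresenham(i0: int, j0: int, i1: int, j1: int) -> list[tuple[int, int]]:
    pts = []
    di, dj = abs(i1 - i0), abs(j1 - j0)
    si = 1 if i1 > i0 else -1
    sj = 1 if j1 > j0 else -1
    err = di - dj
    i, j = i0, j0
    while True:
        pts.append((i, j))
        if i == i1 and j == j1:
            break
        e2 = 2 * err
        if e2 > -dj:
            err -= dj
            i += si
        if e2 < di:
            err += di
            j += sj
    return pts


def _place_cuts(charge: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Blocked-pixel mask from greedy residue pairing.

    Opposite charges are paired nearest-first; a residue closer to the image
    border than to any unpaired partner is cut to the border instead.
    """
    cut = np.zeros(shape, dtype=bool)
    pos = [tuple(p) for p in np.argwhere(charge > 0)]
    neg = [tuple(p) for p in np.argwhere(charge < 0)]
    ni, nj = shape

    def border_dist(p):
        return min(p[0] + 1, p[1] + 1, ni - 1 - p[0], nj - 1 - p[1])

    def border_target(p):
        i, j = p
        cands = [(0, j), (ni - 1, j), (i, 0), (i, nj - 1)]
        return min(cands, key=lambda q: abs(q[0] - i) + abs(q[1] - j))

    def mark(p, q):
        for i, j in _bresenham(p[0], p[1], q[0], q[1]):
            cut[i, j] = True

    while pos and neg:
        p = pos.pop()
        dists = [abs(p[0] - q[0]) + abs(p[1] - q[1]) for q in neg]
        k = int(np.argmin(dists))
        if border_dist(p) < dists[k]:
            mark(p, border_target(p))
        else:
            mark(p, neg.pop(k))
    for p in pos + neg:  # unbalanced leftovers go to the border
        mark(p, border_target(p))
    return cut


def _integrate(wrapped: np.ndarray, seedable: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flood-fill integration of wrapped gradients over ``seedable`` pixels,
    then a second pass pulling in the remaining valid (cut) pixels."""
    out = wrapped.astype(float).copy()
    done = np.zeros(wrapped.shape, dtype=bool)

    def grow(allowed: np.ndarray) -> None:
        # wave-front expansion with 4-connectivity, vectorized per wave
        while True:
            grew = False
            for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
                src = np.roll(done, shift, axis=axis)
                src_val = np.roll(out, shift, axis=axis)
                ref = np.roll(wrapped, shift, axis=axis)
                if shift == 1:
                    if axis == 0:
                        src[0, :] = False
                    else:
                        src[:, 0] = False
                else:
                    if axis == 0:
                        src[-1, :] = False
                    else:
                        src[:, -1] = False
                new = src & allowed & ~done
                if np.any(new):
                    step = wrap_to_pi(wrapped[new] - ref[new])
                    out[new] = src_val[new] + step
                    done[new] = True
                    grew = True
            if not grew:
                break

    remaining = seedable & ~done
    while np.any(remaining):
        seed = tuple(np.argwhere(remaining)[0])
        done[seed] = True
        grow(seedable)
        remaining = seedable & ~done
    # cut pixels: attach to the integrated solution from any neighbour
    grow(valid)
    # isolated valid pixels with no unwrapped neighbour keep wrapped values
    return out, done


def goldstein_unwrap_2d(wrapped: np.ndarray, valid: np.ndarray | None = None) -> UnwrapResult:
    """Unwrap a 2-D slice (or 3-D stack, slice by slice) of wrapped phase.

    Parameters
    ----------
    wrapped:
        Phase in radians, values in (-pi, pi].  2-D ``(nx, ny)`` or 3-D
        ``(nx, ny, nz)``.
    valid:
        Boolean mask of reliable pixels; invalid pixels are left untouched
        and flagged unreliable.  An all-invalid slice yields an empty result
        (reliable all False), not an exception.

    Returns
    -------
    UnwrapResult with the unwrapped phase, the reliability mask and the
    total number of residues detected.
    """
    w = np.asarray(wrapped, dtype=float)
    if valid is None:
        valid = np.ones(w.shape, dtype=bool)
    v = np.asarray(valid, dtype=bool)
    if v.shape != w.shape:
        raise ValueError("valid mask shape must match the phase array")

    if w.ndim == 2:
        phase, rel, nres = _unwrap_slice(w, v)
        return UnwrapResult(phase, rel, nres)
    if w.ndim != 3:
        raise ValueError("expected a 2-D slice or 3-D stack")

    out = w.copy()
    rel = np.zeros(w.shape, dtype=bool)
    nres = 0
    for z in range(w.shape[2]):
        out[:, :, z], rel[:, :, z], n = _unwrap_slice(w[:, :, z], v[:, :, z])
        nres += n
    # reconcile the per-slice 2*pi freedoms
    for z in range(1, w.shape[2]):
        joint = rel[:, :, z] & rel[:, :, z - 1]
        if not np.any(joint):
            continue
        med = np.median(out[:, :, z][joint] - out[:, :, z - 1][joint])
        out[:, :, z] -= TWO_PI * np.rint(med / TWO_PI)
    return UnwrapResult(out, rel, nres)


def _unwrap_slice(w: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    if not np.any(v):
        return w.copy(), np.zeros(w.shape, dtype=bool), 0
    charge = residue_map(w, v)
    nres = int(np.sum(np.abs(charge)))
    cut = _place_cuts(charge, w.shape) if nres else np.zeros(w.shape, dtype=bool)
    seedable = v & ~cut
    if not np.any(seedable):
        seedable = v  # fully cut slice: integrate anyway, flag as usual
    out, done = _integrate(w, seedable, v)
    out = np.where(v, out, w)
    return out, done & v, nres
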