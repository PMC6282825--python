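"""Field-map arithmetic, Dixon separation, fat masks and ellipsoid ROIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalshim import (
    EchoImage,
    EllipsoidROI,
    Grid,
    ParameterError,
    GeometryError,
    compute_fieldmap,
    dixon_fat_water,
    in_phase_te2,
    make_ellipsoid_roi,
    segment_fat,
)


def _echo_pair(field_hz, grid, te1=4.6, te2=6.9, water=1.0, fat=0.0,
               shift=-430.0):
    """Forward-simulate the two-species signal at two echo times."""
    def sig(te):
        te_s = te * 1e-3
        s = (water + fat * np.exp(2j * np.pi * shift * te_s)) * np.exp(
            2j * np.pi * field_hz * te_s
        )
        return EchoImage(np.broadcast_to(s, grid.shape).copy(), te, grid)

    return sig(te1), sig(te2)


class TestComputeFieldmap:
    def test_zero_phase_difference_gives_zero_hz(self, small_grid):
        e1, e2 = _echo_pair(np.zeros(small_grid.shape), small_grid)
        fmap = compute_fieldmap(e1, e2)
        assert np.allclose(fmap.freq, 0.0)
        assert fmap.valid.all()

    def test_quarter_turn_phase_closed_form(self, small_grid):
        # pi/2 phase over dTE = 2.3 ms -> 1/(4*2.3e-3) = 108.70 Hz
        f = 1.0 / (4 * 2.3e-3)
        e1, e2 = _echo_pair(np.full(small_grid.shape, f), small_grid)
        fmap = compute_fieldmap(e1, e2)
        assert np.allclose(fmap.freq, 108.70, atol=0.005)

    def test_fat_wraps_to_zero_at_in_phase_echoes(self, small_grid):
        """A pure-fat voxel at the chemical shift accrues ~ -2*pi between
        in-phase echoes, so it aliases to ~0 Hz: the echo-time choice hides
        fat from the field map."""
        e1, e2 = _echo_pair(np.zeros(small_grid.shape), small_grid,
                            water=0.0, fat=1.0, shift=-434.0)
        fmap = compute_fieldmap(e1, e2)
        assert np.all(np.abs(fmap.freq) < 1.0)

    @pytest.mark.parametrize("field", [-210.0, -50.0, 0.0, 37.5, 216.0])
    def test_constant_field_round_trip_exact(self, small_grid, field):
        e1, e2 = _echo_pair(np.full(small_grid.shape, field), small_grid)
        fmap = compute_fieldmap(e1, e2)
        assert np.allclose(fmap.freq, field, atol=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=-217.0, max_value=217.0, allow_nan=False))
    def test_any_in_band_constant_field_recovered(self, field):
        grid = Grid.centered((3, 3, 1), (5, 5, 10))
        e1, e2 = _echo_pair(np.full(grid.shape, field), grid)
        fmap = compute_fieldmap(e1, e2)
        assert np.allclose(fmap.freq, field, atol=1e-9)

    def test_geometry_mismatch_raises(self, small_grid):
        other = Grid.centered(small_grid.shape, (4.0, 5.0, 10.0))
        e1, _ = _echo_pair(np.zeros(small_grid.shape), small_grid)
        e2 = EchoImage(np.ones(other.shape, complex), 6.9, other)
        with pytest.raises(GeometryError):
            compute_fieldmap(e1, e2)

    def test_non_positive_dte_raises(self, small_grid):
        e1, _ = _echo_pair(np.zeros(small_grid.shape), small_grid)
        e2 = EchoImage(e1.data, 4.6, small_grid)
        with pytest.raises(ParameterError):
            compute_fieldmap(e1, e2)


class TestInPhaseTe2:
    @pytest.mark.parametrize(
        "te1, shift, expected",
        [(4.6, 434.0, 6.9), (0.0, 434.0, 2.3), (4.6, 868.0, 5.8),
         (4.6, -434.0, 6.9)],
    )
    def test_closed_form(self, te1, shift, expected):
        assert in_phase_te2(te1, shift) == pytest.approx(expected)

    def test_zero_shift_rejected(self):
        with pytest.raises(ParameterError):
            in_phase_te2(4.6, 0.0)


def _dixon_triplet(grid, water, fat, f0, tes=(4.6, 5.6, 6.6), shift=-430.0):
    echoes = []
    for te in tes:
        te_s = te * 1e-3
        s = (water + fat * np.exp(2j * np.pi * shift * te_s)) * np.exp(
            2j * np.pi * f0 * te_s
        )
        echoes.append(EchoImage(np.asarray(s, complex), te, grid))
    return echoes


class TestDixon:
    def test_pure_water_voxel(self, small_grid):
        shp = small_grid.shape
        ech = _dixon_triplet(small_grid, np.full(shp, 0.8), np.zeros(shp),
                             np.full(shp, 33.0))
        res = dixon_fat_water(ech)
        assert np.allclose(res.fat, 0.0, atol=1e-8)
        assert np.allclose(res.water, 0.8, atol=1e-8)

    def test_known_voxel_recovered_to_1e6(self):
        grid = Grid.centered((2, 1, 1), (5, 5, 10))
        W, F, f0 = 0.3, 0.7, 20.0
        ech = _dixon_triplet(grid, np.full((2, 1, 1), W), np.full((2, 1, 1), F),
                             np.full((2, 1, 1), f0))
        res = dixon_fat_water(ech)
        assert res.water == pytest.approx(W, abs=1e-6)
        assert res.fat == pytest.approx(F, abs=1e-6)
        assert res.f0 == pytest.approx(f0, abs=1e-4)

    def test_inversion_grid_noise_free(self):
        """Exact inversion across (W, F, f0); |f0| kept below the alias
        midpoint so the zero prior resolves the water-fat swap correctly."""
        Ws = [1.0, 0.6, 0.2, 0.0]
        Fs = [0.0, 0.4, 0.8]
        f0s = [-200.0, -75.0, 0.0, 120.0, 200.0]
        combos = [(w, f, f0) for w in Ws for f in Fs for f0 in f0s
                  if w + f > 0]
        grid = Grid.centered((len(combos), 1, 1), (5, 5, 10))
        W = np.array([c[0] for c in combos]).reshape(-1, 1, 1)
        F = np.array([c[1] for c in combos]).reshape(-1, 1, 1)
        f0 = np.array([c[2] for c in combos]).reshape(-1, 1, 1)
        res = dixon_fat_water(_dixon_triplet(grid, W, F, f0))
        assert np.abs(res.water - W).max() < 1e-6
        assert np.abs(res.fat - F).max() < 1e-6

    def test_prior_resolves_alias_beyond_midpoint(self):
        """At large |f0| the swapped branch is closer to zero; the per-voxel
        prior recovers the true decomposition anyway."""
        grid = Grid.centered((1, 1, 1), (5, 5, 10))
        W, F, f0 = 0.7, 0.3, 400.0
        ech = _dixon_triplet(grid, np.full((1, 1, 1), W), np.full((1, 1, 1), F),
                             np.full((1, 1, 1), f0))
        res = dixon_fat_water(ech, f0_prior=np.full((1, 1, 1), 390.0))
        assert res.water == pytest.approx(W, abs=1e-6)
        assert res.fat == pytest.approx(F, abs=1e-6)

    def test_degenerate_spacing_rejected(self):
        grid = Grid.centered((2, 1, 1), (5, 5, 10))
        shp = (2, 1, 1)
        # dTE such that the fat phasor is identical at all echoes
        period = 1000.0 / 430.0
        ech = _dixon_triplet(grid, np.ones(shp), np.ones(shp), np.zeros(shp),
                             tes=(4.6, 4.6 + period, 4.6 + 2 * period))
        with pytest.raises(ParameterError):
            dixon_fat_water(ech)

    def test_phantom_fat_ring_fraction(self, pure_sh_phantom, pure_sh_fieldmap):
        d = pure_sh_phantom
        prior = np.where(pure_sh_fieldmap.valid, pure_sh_fieldmap.freq, 0.0)
        res = dixon_fat_water(d.dixon_echoes, f0_prior=prior)
        total = res.water + res.fat
        live = total > 0.1
        frac = np.where(live, res.fat / np.maximum(total, 1e-30), 0.0)
        ring = d.fat_mask.mask
        assert np.all(frac[ring & live] > 0.9)
        assert np.all(frac[~ring & live] < 0.1)


class TestSegmentFat:
    def test_all_water_empty_mask_warns(self, small_grid):
        with pytest.warns(UserWarning, match="empty"):
            m = segment_fat(np.zeros(small_grid.shape),
                            np.ones(small_grid.shape), small_grid)
        assert m.count == 0

    def test_threshold_monotone(self, small_grid, rng):
        fat = rng.uniform(0, 1, small_grid.shape)
        water = rng.uniform(0, 1, small_grid.shape)
        m_lo = segment_fat(fat, water, small_grid, threshold=0.3)
        m_hi = segment_fat(fat, water, small_grid, threshold=0.7)
        assert np.all(m_lo.mask | ~m_hi.mask)  # mask(0.3) superset of mask(0.7)

    def test_phantom_ring_count_within_5_percent(self, pure_sh_phantom,
                                                 pure_sh_fieldmap):
        d = pure_sh_phantom
        prior = np.where(pure_sh_fieldmap.valid, pure_sh_fieldmap.freq, 0.0)
        res = dixon_fat_water(d.dixon_echoes, f0_prior=prior)
        m = segment_fat(res.fat, res.water, d.spec.grid, threshold=0.5)
        n_true = d.fat_mask.count
        assert abs(m.count - n_true) <= 0.05 * n_true

    def test_bad_threshold_rejected(self, small_grid):
        with pytest.raises(ParameterError):
            segment_fat(np.ones(small_grid.shape), np.ones(small_grid.shape),
                        small_grid, threshold=0.0)


class TestEllipsoidROI:
    def test_matches_brute_force_enumeration(self):
        grid = Grid.centered((21, 21, 11), (5, 5, 10))
        roi = EllipsoidROI(center=(0.0, 0.0, 0.0), semiaxes=(25.0, 25.0, 25.0))
        mask = make_ellipsoid_roi(roi, grid).mask
        X, Y, Z = grid.meshgrid()
        expect = np.zeros(grid.shape, bool)
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                for k in range(grid.shape[2]):
                    q = (X[i, j, k] / 25) ** 2 + (Y[i, j, k] / 25) ** 2 + (
                        Z[i, j, k] / 25) ** 2
                    expect[i, j, k] = q <= 1
        assert np.array_equal(mask, expect)

    def test_tiny_ellipsoid_selects_single_voxel(self):
        grid = Grid.centered((11, 11, 5), (5, 5, 10))
        roi = EllipsoidROI(center=(0.0, 0.0, 0.0), semiaxes=(1.0, 1.0, 1.0))
        assert make_ellipsoid_roi(roi, grid).count == 1

    def test_translation_by_one_pitch_shifts_mask(self):
        grid = Grid.centered((15, 15, 5), (5, 5, 10))
        roi0 = EllipsoidROI(center=(0.0, 0.0, 0.0), semiaxes=(12.0, 9.0, 15.0))
        roi1 = EllipsoidROI(center=(5.0, 0.0, 0.0), semiaxes=(12.0, 9.0, 15.0))
        m0 = make_ellipsoid_roi(roi0, grid).mask
        m1 = make_ellipsoid_roi(roi1, grid).mask
        assert np.array_equal(np.roll(m0, 1, axis=0)[1:], m1[1:])

    def test_slice_range_restricts(self):
        grid = Grid.centered((15, 15, 6), (5, 5, 10))
        roi = EllipsoidROI(center=(0.0, 0.0, 0.0), semiaxes=(30.0, 30.0, 60.0),
                           slice_range=(2, 3))
        m = make_ellipsoid_roi(roi, grid).mask
        assert m[:, :, [0, 1, 4, 5]].sum() == 0 and m[:, :, 2:4].sum() > 0

    def test_empty_intersection_raises(self):
        grid = Grid.centered((5, 5, 3), (5, 5, 10))
        roi = EllipsoidROI(center=(500.0, 0.0, 0.0), semiaxes=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            make_ellipsoid_roi(roi, grid)
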