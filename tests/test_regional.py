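"""Tile grid construction and regional/zonal percent density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbd.phantom import PhantomSpec, generate_phantom
from mbd.regional import (
    GridError,
    default_zones,
    make_grid,
    regional_pd,
    zonal_pd,
)


class TestMakeGrid:
    def test_divisible_case_gives_equal_tiles(self):
        g = make_grid(480, 360)
        assert np.all(np.diff(g.row_edges) == 60)
        assert np.all(np.diff(g.col_edges) == 60)

    def test_remainder_goes_to_last_tiles(self):
        g = make_grid(10, 7)
        assert tuple(np.diff(g.row_edges)) == (1, 1, 1, 1, 1, 1, 2, 2)
        assert tuple(np.diff(g.col_edges)) == (1, 1, 1, 1, 1, 2)

    def test_too_small_image_rejected(self):
        with pytest.raises(GridError):
            make_grid(5, 100)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(h=st.integers(8, 500), w=st.integers(6, 400))
    def test_partition_property(self, h, w):
        g = make_grid(h, w)
        rh, cw = np.diff(g.row_edges), np.diff(g.col_edges)
        # exact cover, near-equal tiles
        assert g.row_edges[0] == 0 and g.row_edges[-1] == h
        assert g.col_edges[0] == 0 and g.col_edges[-1] == w
        assert rh.max() - rh.min() <= 1 and cw.max() - cw.min() <= 1
        assert g.tile_areas().sum() == h * w


class TestRegionalPD:
    def test_all_dense_tile_mode_is_100_everywhere(self):
        mask = np.ones((96, 72), bool)
        dg = regional_pd(mask, mask, make_grid(96, 72), denominator="tile")
        assert np.all(dg.pd == 100.0)

    def test_breast_free_tile_is_zero_in_both_modes(self):
        mask = np.zeros((96, 72), bool)
        mask[:12, :12] = True  # only the first tile holds breast
        dense = np.zeros((96, 72), bool)
        for mode in ("tile", "mask"):
            dg = regional_pd(dense, mask, make_grid(96, 72), denominator=mode)
            assert dg.pd[1:, 1:].sum() == 0.0

    def test_mask_mode_records_zero_denominator(self):
        mask = np.zeros((96, 72), bool)
        mask[:12, :12] = True
        dg = regional_pd(mask, mask, make_grid(96, 72), denominator="mask")
        assert dg.denominators[0, 0] == 144
        assert dg.denominators[7, 5] == 0
        assert dg.pd[7, 5] == 0.0

    def test_tile_mode_conservation(self, noisy_phantom):
        # equal tiles: mean regional PD equals the frame-level dense share
        ph = noisy_phantom
        dense = ph.true_dense_mask[:192, :144]
        g = make_grid(192, 144)
        dg = regional_pd(dense, ph.breast_mask, g, denominator="tile")
        frame_pd = 100.0 * dense.sum() / dense.size
        assert dg.pd.mean() == pytest.approx(frame_pd)

    def test_single_blob_tile_geometry(self):
        # a fully dense tile reports exactly 100 x (tile ∩ dense)/area
        dense = np.zeros((96, 72), bool)
        dense[12:24, 12:24] = True  # tile (1,1) exactly
        mask = np.ones((96, 72), bool)
        dg = regional_pd(dense, mask, make_grid(96, 72))
        assert dg.pd[1, 1] == 100.0
        assert dg.pd.sum() == 100.0


class TestZones:
    def test_left_chest_wall_band_assignment(self):
        z = default_zones("left")
        assert z.zone_columns("posterior") == (0, 1)
        assert z.zone_columns("middle") == (2, 3)
        assert z.zone_columns("anterior") == (4, 5)

    def test_right_chest_wall_mirrors(self):
        z = default_zones("right")
        assert z.zone_columns("posterior") == (4, 5)
        assert z.zone_columns("anterior") == (0, 1)

    def test_every_column_in_exactly_one_zone(self):
        z = default_zones("left")
        cols = sorted(
            sum((z.zone_columns(zone) for zone in ("posterior", "middle", "anterior")), ())
        )
        assert cols == list(range(6))


class TestZonalPD:
    def _dgrid(self, pd_matrix):
        mask = np.ones((96, 72), bool)
        g = make_grid(96, 72)
        dg = regional_pd(mask, mask, g)
        object.__setattr__(dg, "pd", np.asarray(pd_matrix, float))
        return dg

    def test_constant_grid_gives_constant_zones(self):
        z = zonal_pd(self._dgrid(np.full((8, 6), 10.0)), default_zones("left"))
        assert (z.posterior, z.middle, z.anterior) == (10.0, 10.0, 10.0)

    def test_posterior_band_only(self):
        m = np.zeros((8, 6))
        m[:, :2] = 100.0
        z = zonal_pd(self._dgrid(m), default_zones("left"))
        assert (z.posterior, z.middle, z.anterior) == (100.0, 0.0, 0.0)

    def test_zone_mean_is_over_16_tiles(self):
        m = np.zeros((8, 6))
        m[:, :2] = 20.0  # posterior band sums to 320 over 16 tiles
        z = zonal_pd(self._dgrid(m), default_zones("left"))
        assert z.posterior == pytest.approx(320 / 16)


def test_planted_blob_regional_geometry():
    # a noiseless phantom's regional PDs are reproducible by direct pixel
    # counting of the emitted ground-truth mask
    ph = generate_phantom(
        PhantomSpec(image_height=96, image_width=72, dense_fraction=0.2,
                    noise_sd=0.0, seed=4, placement="middle")
    )
    g = make_grid(96, 72)
    dg = regional_pd(ph.true_dense_mask, ph.breast_mask, g)
    i, j = 3, 2
    r0, r1 = g.row_edges[i], g.row_edges[i + 1]
    c0, c1 = g.col_edges[j], g.col_edges[j + 1]
    expected = 100.0 * ph.true_dense_mask[r0:r1, c0:c1].sum() / ((r1 - r0) * (c1 - c0))
    assert dg.pd[i, j] == pytest.approx(expected)
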