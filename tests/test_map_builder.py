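"""Map construction, alignment, projections and peak quantization."""

import numpy as np
import pytest

from scracm.geometry import PIXEL_SIZE_UM
from scracm.map_builder import (InputMap, align_and_average, build_map,
                                horizontal_bias, horizontal_profile,
                                normalize_map, peak_location, round_half_up,
                                vertical_profile)
from scracm.trace_analysis import SpotResponse


def _responses(charges, significant=None):
    significant = significant if significant is not None else [q > 0 for q in charges]
    return [SpotResponse(i, 10.0, q, 0.1, s, 5.0)
            for i, (q, s) in enumerate(zip(charges, significant))]


def _session(n_rows=24, n_cols=12, soma_row=24, soma_col=12):
    from types import SimpleNamespace
    return SimpleNamespace(n_rows=n_rows, n_cols=n_cols, n_spots=n_rows * n_cols,
                           soma_row=soma_row, soma_col=soma_col, pia_row=0,
                           medial_sign=1)


class TestBuildMap:
    def test_all_zero_responses_give_zero_map(self):
        m = build_map(_responses([0.0] * 288), _session())
        assert m.total == 0.0

    def test_one_spot_splits_into_four_quadrants(self):
        charges = [0.0] * 288
        charges[13] = 1.0
        m = build_map(_responses(charges), _session())
        assert (m.grid > 0).sum() == 4
        assert set(np.round(m.grid[m.grid > 0], 12)) == {0.25}
        assert m.total == pytest.approx(1.0)

    def test_total_equals_sum_of_significant_charges(self):
        rng = np.random.default_rng(1)
        charges = rng.uniform(0, 1, 288)
        sig = rng.random(288) < 0.5
        m = build_map(_responses(charges, sig), _session())
        assert m.total == pytest.approx(charges[sig].sum(), rel=1e-12)

    def test_wrong_response_count_rejected(self):
        with pytest.raises(ValueError, match="288"):
            build_map(_responses([1.0] * 10), _session())


class TestNormalize:
    def test_uniform_map_becomes_ones(self):
        m = InputMap(np.full((4, 4), 3.0))
        assert (normalize_map(m).grid == 1.0).all()

    def test_ratios_preserved(self):
        m = InputMap(np.array([[4.0, 2.0], [1.0, 0.0]]))
        out = normalize_map(m).grid
        np.testing.assert_allclose(out, [[1.0, 0.5], [0.25, 0.0]])

    def test_all_zero_passes_with_warning(self):
        m = InputMap(np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_map(m)
        assert out.total == 0.0


class TestAlignAndAverage:
    def test_single_map_is_identity(self):
        grid = np.arange(12.0).reshape(3, 4)
        m = InputMap(grid, soma_anchor=(1, 2))
        avg, counts = align_and_average([m], mode="pia")
        np.testing.assert_allclose(avg.grid, grid)
        assert (counts == 1).all()

    def test_known_shift_realigned(self):
        """Two identical maps with offset anchors average to one aligned map."""
        grid = np.zeros((6, 6))
        grid[2, 3] = 1.0
        a = InputMap(grid, soma_anchor=(2, 3), pia_row=0)
        shifted = np.zeros((6, 6))
        shifted[4, 1] = 1.0
        b = InputMap(shifted, soma_anchor=(4, 1), pia_row=2)
        avg, counts = align_and_average([a, b], mode="pia")
        peak_cells = np.argwhere(avg.grid == avg.grid.max())
        assert len(peak_cells) == 1
        r, c = peak_cells[0]
        assert avg.grid[r, c] == pytest.approx(1.0)

    def test_average_of_normalized_maps_bounded_by_one(self):
        rng = np.random.default_rng(3)
        maps = [normalize_map(InputMap(rng.uniform(0, 2, (8, 8)),
                                       soma_anchor=(4, 4))) for _ in range(5)]
        avg, _ = align_and_average(maps, mode="soma")
        assert avg.grid.max() <= 1.0 + 1e-12

    def test_alignment_idempotent(self):
        rng = np.random.default_rng(5)
        maps = [InputMap(rng.uniform(0, 1, (6, 6)), soma_anchor=(3, 3))
                for _ in range(3)]
        avg1, _ = align_and_average(maps, mode="pia")
        avg2, _ = align_and_average([avg1], mode="pia")
        np.testing.assert_allclose(avg2.grid, avg1.grid)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            align_and_average([], mode="pia")


class TestProfiles:
    def test_single_pixel_gives_delta_profiles(self):
        grid = np.zeros((10, 8))
        grid[6, 2] = 2.0
        m = InputMap(grid, soma_anchor=(4, 4))
        v = vertical_profile(m, align="pia")
        h = horizontal_profile(m)
        assert (v.values > 0).sum() == 1 and v.values[6] == 2.0
        assert (h.values > 0).sum() == 1 and h.values[2] == 2.0

    def test_projection_conserves_total(self):
        rng = np.random.default_rng(11)
        m = InputMap(rng.uniform(0, 1, (12, 10)), soma_anchor=(6, 5))
        assert vertical_profile(m).values.sum() == pytest.approx(m.total)
        assert horizontal_profile(m).values.sum() == pytest.approx(m.total)

    def test_uniform_map_flat_profile(self):
        m = InputMap(np.ones((5, 4)), soma_anchor=(2, 2))
        assert np.ptp(vertical_profile(m).values) == 0

    def test_soma_axis_positive_toward_pia(self):
        grid = np.zeros((10, 4))
        grid[2, 1] = 1.0  # above the soma row
        m = InputMap(grid, soma_anchor=(6, 2))
        v = vertical_profile(m, align="soma")
        pk = peak_location(v)
        assert pk.raw_um == pytest.approx((6 - 2) * PIXEL_SIZE_UM)


class TestPeakLocation:
    def test_ninth_bin_below_pia_reports_188(self):
        """A peak 9 quadrant bins below the pia reads 187.5 -> 188 µm."""
        values = np.zeros(48)
        values[9] = 1.0
        m = InputMap(values[:, None], soma_anchor=(20, 0))
        pk = peak_location(vertical_profile(m, align="pia"))
        assert pk.raw_um == pytest.approx(187.5)
        assert pk.rounded_um == 188

    def test_peak_at_soma_is_zero(self):
        values = np.zeros(48)
        values[20] = 1.0
        m = InputMap(values[:, None], soma_anchor=(20, 0))
        assert peak_location(vertical_profile(m, align="soma")).rounded_um == 0

    def test_ties_break_toward_anchor(self):
        values = np.zeros(48)
        values[[10, 30]] = 1.0
        m = InputMap(values[:, None], soma_anchor=(25, 0))
        pk = peak_location(vertical_profile(m, align="soma"))
        assert pk.raw_um == pytest.approx((25 - 30) * PIXEL_SIZE_UM)

    def test_all_zero_profile_reports_no_peak(self):
        m = InputMap(np.zeros((48, 1)), soma_anchor=(20, 0))
        assert peak_location(vertical_profile(m)).found is False

    def test_raw_locations_live_on_pixel_lattice(self):
        """All peak locations are integer multiples of 1000/48 µm pre-rounding."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            grid = rng.uniform(0, 1, (48, 24)) * (rng.random((48, 24)) < 0.2)
            if grid.max() == 0:
                continue
            m = InputMap(grid, soma_anchor=(int(rng.integers(48)),
                                            int(rng.integers(24))),
                         medial_sign=int(rng.choice([-1, 1])))
            for prof in (vertical_profile(m, "pia"), vertical_profile(m, "soma")):
                pk = peak_location(prof)
                assert pk.raw_um / PIXEL_SIZE_UM == pytest.approx(
                    round(pk.raw_um / PIXEL_SIZE_UM), abs=1e-9)
            hb = horizontal_bias(horizontal_profile(m))
            assert hb.raw_um / PIXEL_SIZE_UM == pytest.approx(
                round(hb.raw_um / PIXEL_SIZE_UM), abs=1e-9)


class TestHorizontalBias:
    def test_symmetric_profile_zero_bias(self):
        grid = np.zeros((4, 9))
        grid[2, 4] = 1.0
        m = InputMap(grid, soma_anchor=(2, 4))
        assert horizontal_bias(horizontal_profile(m)).rounded_um == 0

    def test_one_quadrant_medial_is_21(self):
        grid = np.zeros((4, 9))
        grid[2, 5] = 1.0
        m = InputMap(grid, soma_anchor=(2, 4), medial_sign=1)
        assert horizontal_bias(horizontal_profile(m)).rounded_um == 21

    def test_three_quadrants_lateral_is_minus_63(self):
        grid = np.zeros((4, 9))
        grid[2, 1] = 1.0
        m = InputMap(grid, soma_anchor=(2, 4), medial_sign=1)
        assert horizontal_bias(horizontal_profile(m)).rounded_um == -63


@pytest.mark.parametrize("x,expected", [(62.5, 63), (-62.5, -63), (20.83, 21),
                                        (187.5, 188), (0.0, 0), (-104.17, -104)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected


def test_soma_translation_equivariance():
    """Shifting the soma anchor by k quadrants shifts soma-aligned peaks by k bins."""
    grid = np.zeros((48, 24))
    grid[30, 10] = 1.0
    for k in (0, 2, 5):
        m = InputMap(grid, soma_anchor=(24 + k, 12))
        pk = peak_location(vertical_profile(m, align="soma"))
        assert pk.raw_um == pytest.approx((24 + k - 30) * PIXEL_SIZE_UM)
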