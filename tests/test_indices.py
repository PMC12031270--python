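"""Browning/Yellowing Index arithmetic, inversion, and per-slice maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pearbrowning.indices import (
    browning_index,
    index_maps_for_slice,
    lab_from_indices,
    yellowing_index,
)
from pearbrowning.segmentation import extract_slices


@pytest.mark.parametrize(
    "L,a,b,expected",
    [
        (100.0, 0.0, 0.0, 100 * (175.0 / 564.5 - 0.31) / 0.17),  # ≈ 0.0052
        (50.0, 10.0, 20.0, 100 * (97.5 / 232.01 - 0.31) / 0.17),  # ≈ 64.85
    ],
)
def test_browning_index_worked_examples(L, a, b, expected):
    assert browning_index(L, a, b) == pytest.approx(expected, rel=1e-12)
    assert browning_index(50.0, 10.0, 20.0) == pytest.approx(64.85, abs=0.01)


def test_browning_index_zero_at_chromatic_balance():
    # (L, a, b) with X = 0.31 exactly: L=50, b=0 ⇒ a solves a+87.5 = 0.31(282.25+a)
    a = (0.31 * 282.25 - 87.5) / (1 - 0.31)
    assert browning_index(50.0, a, 0.0) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize(
    "L,b,expected", [(50.0, 0.0, 0.0), (50.0, 20.0, 57.144), (100.0, 70.0, 100.002)]
)
def test_yellowing_index_worked_examples(L, b, expected):
    assert yellowing_index(L, b) == pytest.approx(expected, rel=1e-9)


def test_degenerate_pixels_are_nan_not_raises():
    # denominator 5.645 L + a - 3.012 b = 0
    assert np.isnan(browning_index(10.0, -56.45, 0.0))
    assert np.isnan(yellowing_index(0.0, 10.0))


def test_browning_depends_only_on_ratio():
    """Scaling numerator and denominator together leaves BI unchanged."""
    L, a, b = 50.0, 10.0, 20.0
    bi = browning_index(L, a, b)
    # triple every Lab coordinate: both affine forms scale by 3
    assert browning_index(3 * L, 3 * a, 3 * b) == pytest.approx(bi, rel=1e-12)


def test_yellowing_linear_in_b():
    assert yellowing_index(60.0, 30.0) == pytest.approx(2 * yellowing_index(60.0, 15.0))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    bi=st.floats(-50, 300),
    yi=st.floats(-50, 200),
    L=st.floats(5, 100),
)
def test_index_inversion_round_trips(bi, yi, L):
    a, b = lab_from_indices(bi, yi, L)
    assert browning_index(L, a, b) == pytest.approx(bi, abs=1e-9)
    assert yellowing_index(L, b) == pytest.approx(yi, abs=1e-9)


def test_inversion_of_worked_example():
    bi = browning_index(50.0, 10.0, 20.0)
    yi = yellowing_index(50.0, 20.0)
    a, b = lab_from_indices(bi, yi, 50.0)
    assert a == pytest.approx(10.0, abs=1e-9)
    assert b == pytest.approx(20.0, abs=1e-9)


def test_inversion_zero_case_and_singularity():
    a, b = lab_from_indices(0.0, 0.0, 100.0)
    assert b == 0.0
    assert browning_index(100.0, a, b) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        lab_from_indices((1 - 0.31) / 0.17 * 100, 0.0, 50.0)  # X = 1
    with pytest.raises(ValueError):
        lab_from_indices(0.0, 0.0, 0.0)  # L = 0


def _disc_lab(value, shape=(40, 40), center=(20, 20), radius=10, bg=(61.0, 98.0, -61.0)):
    lab = np.empty(shape + (3,))
    lab[:] = bg
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    lab[mask] = value
    return lab, mask


def test_uniform_disc_gives_constant_samples():
    lab, _ = _disc_lab((50.0, 10.0, 20.0))
    from pearbrowning.segmentation import segment_foreground

    comp = extract_slices(segment_foreground(lab), min_size=10)[0]
    maps = index_maps_for_slice(lab, comp, "u")
    assert np.allclose(maps.bi_sample, browning_index(50.0, 10.0, 20.0))
    assert np.allclose(maps.yi_sample, yellowing_index(50.0, 20.0))
    assert maps.bi_sample.size == comp.pixel_count


def test_sample_mean_matches_pixel_loop():
    rng = np.random.default_rng(3)
    lab, mask = _disc_lab((50.0, 10.0, 20.0))
    lab[mask] = np.column_stack(
        [rng.uniform(40, 80, mask.sum()), rng.uniform(-5, 25, mask.sum()),
         rng.uniform(0, 30, mask.sum())]
    )
    from pearbrowning.segmentation import segment_foreground

    comp = extract_slices(segment_foreground(lab), min_size=10)[0]
    maps = index_maps_for_slice(lab, comp, "r")
    # independent per-pixel loop
    vals = [
        browning_index(*lab[r, c])
        for r in range(40) for c in range(40) if comp.mask[r, c]
    ]
    assert maps.bi_sample.mean() == pytest.approx(np.mean(vals), rel=1e-12)


def test_index_map_export_round_trip(tmp_path):
    import imageio.v3 as iio

    from pearbrowning.indices import export_index_map
    from pearbrowning.segmentation import segment_foreground

    lab, _ = _disc_lab((50.0, 10.0, 20.0))
    comp = extract_slices(segment_foreground(lab), min_size=10)[0]
    maps = index_maps_for_slice(lab, comp, "slice0")
    paths = export_index_map(maps, tmp_path)
    assert len(paths) == 5
    tif = iio.imread(tmp_path / "slice0_bi.tiff")
    finite = tif[np.isfinite(tif)]
    assert finite.size == comp.pixel_count
    assert np.allclose(finite, browning_index(50.0, 10.0, 20.0), atol=1e-4)


def test_degenerate_pixels_excluded_and_counted():
    lab, mask = _disc_lab((50.0, 10.0, 20.0))
    idx = np.argwhere(mask)[:3]
    for r, c in idx:
        lab[r, c] = (10.0, -56.45, 0.0)  # BI denominator exactly zero
    from pearbrowning.segmentation import segment_foreground

    comp = extract_slices(segment_foreground(lab), min_size=10)[0]
    maps = index_maps_for_slice(lab, comp, "d")
    assert maps.n_degenerate_bi == 3
    assert maps.bi_sample.size == comp.pixel_count - 3
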