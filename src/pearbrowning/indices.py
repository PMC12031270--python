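"""Browning Index (BI) and Yellowing Index (YI) maps over Lab rasters.

BI is the purity-of-brown metric

    BI = 100 (X - 0.31) / 0.17,   X = (a* + 1.75 L*) / (5.645 L* + a* - 3.012 b*),

and YI the yellowness ratio

    YI = 142.86 b* / L*.

Both are dimensionless.  Pixels with a near-zero denominator are marked
undefined and excluded from index samples — counted, never imputed.  The
algebraic inversion (BI, YI, L*) → (a*, b*) is what the synthetic generator
uses to paint pixels with prescribed index values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pearbrowning.segmentation import SliceComponent

__all__ = [
    "DEGENERATE_EPS",
    "IndexMaps",
    "browning_index",
    "yellowing_index",
    "lab_from_indices",
    "index_maps_for_slice",
]

#: |denominator| below this marks a pixel undefined rather than raising.
DEGENERATE_EPS = 1e-6


def browning_index(L, a, b, *, eps: float = DEGENERATE_EPS):
    """Element-wise Browning Index; NaN where 5.645 L + a - 3.012 b ≈ 0."""
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = 5.645 * L + a - 3.012 * b
    with np.errstate(divide="ignore", invalid="ignore"):
        X = (a + 1.75 * L) / denom
        bi = 100.0 * (X - 0.31) / 0.17
    return np.where(np.abs(denom) < eps, np.nan, bi)[()]


def yellowing_index(L, b, *, eps: float = DEGENERATE_EPS):
    """Element-wise Yellowing Index 142.86 b/L; NaN where L ≤ eps."""
    L = np.asarray(L, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        yi = 142.86 * b / L
    return np.where(L <= eps, np.nan, yi)[()]


def lab_from_indices(BI, YI, L):
    """Invert (BI, YI, L*) to (a*, b*), exactly, for the synthetic generator.

    From YI: b = YI·L/142.86.  From BI: X = 0.31 + 0.17·BI/100 and
    a = [X·(5.645 L − 3.012 b) − 1.75 L] / (1 − X), which round-trips through
    the forward index formulas to machine precision.  X = 1 is singular.
    """
    BI = np.asarray(BI, dtype=float)
    YI = np.asarray(YI, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L* must be strictly positive to invert the indices")
    X = 0.31 + 0.17 * BI / 100.0
    if np.any(np.abs(1.0 - X) < 1e-12):
        raise ValueError("X = 1 (BI ≈ 405.88) is singular; cannot invert")
    b = YI * L / 142.86
    a = (X * (5.645 * L - 3.012 * b) - 1.75 * L) / (1.0 - X)
    return a[()], b[()]


@dataclass(frozen=True)
class IndexMaps:
    """Per-pixel BI and YI maps for one slice plus their flattened samples.

    Maps carry NaN off the component and at degenerate pixels; samples hold
    the finite values only.
    """

    slice_id: str
    bi_map: np.ndarray = field(repr=False)
    yi_map: np.ndarray = field(repr=False)
    bi_sample: np.ndarray = field(repr=False)
    yi_sample: np.ndarray = field(repr=False)
    n_degenerate_bi: int = 0
    n_degenerate_yi: int = 0


def export_index_map(maps: "IndexMaps", directory, *, summary: bool = True) -> list:
    """Write BI/YI maps as single-channel float32 TIFFs plus per-pixel CSVs
    (row, col, value) and an optional per-slice summary CSV; returns paths."""
    import pathlib

    import imageio.v3 as iio
    import pandas as pd

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, arr, sample in (
        ("bi", maps.bi_map, maps.bi_sample),
        ("yi", maps.yi_map, maps.yi_sample),
    ):
        tif = directory / f"{maps.slice_id}_{kind}.tiff"
        iio.imwrite(tif, arr.astype(np.float32))
        rows, cols = np.nonzero(np.isfinite(arr))
        csv = directory / f"{maps.slice_id}_{kind}.csv"
        pd.DataFrame({"row": rows, "col": cols, "value": arr[rows, cols]}).to_csv(
            csv, index=False
        )
        written += [tif, csv]
    if summary:
        path = directory / f"{maps.slice_id}_summary.csv"
        pd.DataFrame(
            [
                {"index": k.upper(), "n": s.size, "mean": s.mean(),
                 "sd": s.std(ddof=1), "min": s.min(), "max": s.max()}
                for k, s in (("bi", maps.bi_sample), ("yi", maps.yi_sample))
            ]
        ).to_csv(path, index=False)
        written.append(path)
    return written


def index_maps_for_slice(
    lab: np.ndarray, comp: SliceComponent, slice_id: str = ""
) -> IndexMaps:
    """BI/YI maps restricted to one component, with flattened finite samples."""
    lab = np.asarray(lab, dtype=float)
    if comp.mask.shape != lab.shape[:2]:
        raise ValueError("component mask does not match image shape")
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    bi = np.where(comp.mask, browning_index(L, a, b), np.nan)
    yi = np.where(comp.mask, yellowing_index(L, b), np.nan)
    bi_sample = bi[comp.mask]
    yi_sample = yi[comp.mask]
    n_deg_bi = int(np.isnan(bi_sample).sum())
    n_deg_yi = int(np.isnan(yi_sample).sum())
    bi_sample = bi_sample[np.isfinite(bi_sample)]
    yi_sample = yi_sample[np.isfinite(yi_sample)]
    if bi_sample.size == 0 or yi_sample.size == 0:
        raise ValueError(
            f"slice {slice_id or comp.component_id}: no defined index pixels"
        )
    return IndexMaps(
        slice_id=slice_id or str(comp.component_id),
        bi_map=bi,
        yi_map=yi,
        bi_sample=bi_sample,
        yi_sample=yi_sample,
        n_degenerate_bi=n_deg_bi,
        n_degenerate_yi=n_deg_yi,
    )
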