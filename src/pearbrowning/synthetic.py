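"""Seeded synthetic image sets with the statistical structure the analysis assumes.

The generator emulates the browning study design: two treatment groups
(control, antioxidant-treated), slices photographed on a magenta chroma-key
background every 30 min over 9 h.  Each slice's true Weibull shape factors
for BI and YI drift linearly in exposure time with group-specific intercepts
and a common slope, plus Gaussian slice-to-slice noise; per-pixel BI/YI
values are drawn from the corresponding three-parameter Weibull distributions
(coupled through a Gaussian copula), inverted to Lab via the index algebra,
and encoded to 8-bit sRGB discs on the magenta canvas.  Regeneration under
the same (config, seed) is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pearbrowning.colorspace import D65_10, WhitePoint, lab_to_srgb, srgb_to_lab, write_rgb
from pearbrowning.indices import lab_from_indices
from pearbrowning.segmentation import ThresholdRanges

__all__ = [
    "GroupLine",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_shape_trajectories",
    "render_slice_image",
    "generate_dataset",
    "background_rgb",
]

#: shape factors are truncated below at this value.
BETA_FLOOR = 0.05


@dataclass(frozen=True)
class GroupLine:
    """Linear drift of a shape factor: intercept_group + slope · t(min)."""

    control_intercept: float
    treated_intercept: float
    slope: float

    def value(self, group: str, t: float) -> float:
        a = self.control_intercept if group == "control" else self.treated_intercept
        return a + self.slope * t


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic browning dataset.

    Defaults reproduce the study conditions: 0–540 min in 30-min steps,
    108 slices per group, YI shape lines 1.280 / 0.885 + 0.00125·t with noise
    sd 0.18, BI shape lines 2.380 / 1.721 + 0.00076·t with noise sd 0.54,
    magenta background at Lab (61, 98, −61).  The pixel-level Weibull scale
    (10) and location (0.5) keep index values in realistic ranges and are a
    modelling choice, as is the 0.3 copula correlation between per-pixel BI
    and YI.
    """

    seed: int = 0
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 541, 30))
    n_per_group: int = 108
    replicates_per_timepoint: int | None = None  # overrides n_per_group if set
    image_size: tuple[int, int] = (112, 112)
    disc_radius: int = 45
    discs_per_image: int = 1
    background_lab: tuple[float, float, float] = (61.0, 98.0, -61.0)
    yi_line: GroupLine = GroupLine(1.280, 0.885, 0.00125)
    bi_line: GroupLine = GroupLine(2.380, 1.721, 0.00076)
    yi_noise_sd: float = 0.18
    bi_noise_sd: float = 0.54
    pixel_alpha: float = 10.0
    pixel_gamma: float = 0.5
    index_correlation: float = 0.3
    index_cap: float = 60.0      # gamut guard: index draws truncated here
    l_max: float = 72.0          # L* of a hypothetical zero-BI slice
    l_per_bi: float = 1.2        # linear darkening: L* drop per unit mean BI

    def __post_init__(self) -> None:
        if self.pixel_alpha <= 0:
            raise ValueError("pixel Weibull scale must be positive")
        if any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.yi_noise_sd < 0 or self.bi_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class SyntheticDataset:
    root: Path
    truth: pd.DataFrame
    image_paths: list[Path]
    manifest: dict


def _replicate_counts(cfg: GeneratorConfig) -> list[int]:
    """Slices per timepoint for one group, distributed as evenly as possible."""
    T = len(cfg.timepoints)
    if cfg.replicates_per_timepoint is not None:
        return [cfg.replicates_per_timepoint] * T
    base, rem = divmod(cfg.n_per_group, T)
    return [base + (1 if i < rem else 0) for i in range(T)]


def generate_shape_trajectories(cfg: GeneratorConfig) -> pd.DataFrame:
    """Truth table of per-slice shape factors drawn around the group lines.

    Each slice gets β = intercept_group + slope·t + N(0, sd), truncated below
    at 0.05, independently for BI and YI.  Deterministic per (config, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7261]))
    counts = _replicate_counts(cfg)
    rows = []
    for group in ("control", "treated"):
        for t, c in zip(cfg.timepoints, counts):
            for r in range(c):
                beta_yi = cfg.yi_line.value(group, t) + rng.normal(0, cfg.yi_noise_sd)
                beta_bi = cfg.bi_line.value(group, t) + rng.normal(0, cfg.bi_noise_sd)
                rows.append(
                    {
                        "slice_id": f"{group}_t{int(t):03d}_r{r}",
                        "group": group,
                        "time_min": t,
                        "beta_bi_true": max(BETA_FLOOR, beta_bi),
                        "beta_yi_true": max(BETA_FLOOR, beta_yi),
                        "alpha_true": cfg.pixel_alpha,
                        "gamma_true": cfg.pixel_gamma,
                    }
                )
    return pd.DataFrame(rows)


def _disc_centers(cfg: GeneratorConfig) -> list[tuple[int, int]]:
    """Deterministic grid placement of discs on the canvas, row-major."""
    H, W = cfg.image_size
    k = cfg.discs_per_image
    nr = max(1, int(math.floor(math.sqrt(k))))
    nc = math.ceil(k / nr)
    cell_h, cell_w = H / nr, W / nc
    if min(cell_h, cell_w) < 2 * cfg.disc_radius + 4:
        raise ValueError(
            f"{k} discs of radius {cfg.disc_radius} do not fit a {H}×{W} canvas"
        )
    centers = []
    for i in range(nr):
        for j in range(nc):
            if len(centers) == k:
                break
            centers.append(
                (int((i + 0.5) * cell_h), int((j + 0.5) * cell_w))
            )
    return centers


def background_rgb(
    bg_lab: tuple[float, float, float] = (61.0, 98.0, -61.0),
    thr: ThresholdRanges = ThresholdRanges(),
    white: WhitePoint = D65_10,
) -> np.ndarray:
    """8-bit magenta whose round-tripped Lab sits inside the background intervals.

    The nominal background Lab is marginally out of the sRGB gamut, so the
    naive inverse followed by clipping can land a* below the threshold window.
    A small neighbourhood search picks the quantised RGB closest to the target
    whose Lab classifies as background.
    """
    naive = lab_to_srgb(np.array([[bg_lab]], dtype=float), white)[0, 0]
    target = np.array(bg_lab, dtype=float)
    best, best_d = None, np.inf
    span = 20
    cand = [
        np.clip(naive.astype(int) + np.array([dr, dg, db]), 0, 255)
        for dr in range(-span, span + 1, 2)
        for dg in range(-span, span + 1, 2)
        for db in range(-span, span + 1, 2)
    ]
    cand = np.unique(np.array(cand, dtype=np.uint8), axis=0)
    labs = srgb_to_lab(cand[None, :, :], white)[0]
    inside = (
        (labs[:, 0] >= thr.L_range[0]) & (labs[:, 0] <= thr.L_range[1])
        & (labs[:, 1] >= thr.a_range[0]) & (labs[:, 1] <= thr.a_range[1])
        & (labs[:, 2] >= thr.b_range[0]) & (labs[:, 2] <= thr.b_range[1])
    )
    if not inside.any():
        return naive  # degenerate thresholds: fall back to the plain inverse
    d = np.linalg.norm(labs[inside] - target, axis=1)
    return cand[inside][int(np.argmin(d))]


def _disc_mask(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_slice_image(
    beta_bi: float,
    beta_yi: float,
    alpha: float,
    gamma: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    canvas: np.ndarray | None = None,
    center: tuple[int, int] | None = None,
    white: WhitePoint = D65_10,
) -> tuple[np.ndarray, int]:
    """Render one disc whose pixels carry Weibull-distributed BI/YI values.

    Per-pixel (BI, YI) pairs are drawn through a Gaussian copula with the
    configured correlation, inverted to (a*, b*) at a slice-level L* set by
    the linear darkening map, and encoded to sRGB.  Returns the canvas and
    the out-of-gamut clip count for the disc pixels.
    """
    H, W = cfg.image_size
    if canvas is None:
        canvas = np.empty((H, W, 3), dtype=np.uint8)
        canvas[:] = background_rgb(cfg.background_lab, white=white)
    if center is None:
        center = (H // 2, W // 2)
    mask = _disc_mask((H, W), center, cfg.disc_radius)
    npix = int(mask.sum())
    rho = cfg.index_correlation
    z = rng.standard_normal((npix, 2))
    z2 = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
    u_bi = np.clip(stats.norm.cdf(z[:, 0]), 1e-12, 1 - 1e-9)
    u_yi = np.clip(stats.norm.cdf(z2), 1e-12, 1 - 1e-9)
    # right-truncate at the gamut guard: extreme Weibull tails (low shapes)
    # would otherwise leave the sRGB gamut and corrupt the rendered indices
    bi = np.minimum(stats.weibull_min.ppf(u_bi, beta_bi, loc=gamma, scale=alpha),
                    cfg.index_cap)
    yi = np.minimum(stats.weibull_min.ppf(u_yi, beta_yi, loc=gamma, scale=alpha),
                    cfg.index_cap)
    mean_bi = gamma + alpha * math.gamma(1 + 1 / beta_bi)
    L = float(np.clip(cfg.l_max - cfg.l_per_bi * mean_bi, 20.0, 95.0))
    a, b = lab_from_indices(bi, yi, np.full(npix, L))
    lab_px = np.stack([np.full(npix, L), a, b], axis=-1)
    rgb_px, n_clip = lab_to_srgb(lab_px[None, :, :], white, return_clip_count=True)
    canvas[mask] = rgb_px[0]
    return canvas, n_clip


def generate_dataset(cfg: GeneratorConfig, outdir: str | Path) -> SyntheticDataset:
    """Write the full synthetic image set, truth table and manifest.

    Produces one PNG per ``discs_per_image`` slices (default: one slice per
    image), a ``truth.csv`` holding per-slice group, exposure time, true
    Weibull parameters, image path and component index, and a
    ``manifest.json`` recording the seed, config hash and file list.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    truth = generate_shape_trajectories(cfg)
    centers = _disc_centers(cfg)
    k = cfg.discs_per_image
    ss = np.random.SeedSequence([cfg.seed, 0x6d67])
    child = ss.spawn(math.ceil(len(truth) / k))
    image_paths: list[Path] = []
    img_col: list[str] = []
    comp_col: list[int] = []
    clip_counts: list[int] = []
    for img_idx in range(math.ceil(len(truth) / k)):
        block = truth.iloc[img_idx * k : (img_idx + 1) * k]
        rng = np.random.default_rng(child[img_idx])
        canvas = None
        nclip_img = 0
        for ci, (_, row) in enumerate(block.iterrows()):
            canvas, nclip = render_slice_image(
                row.beta_bi_true, row.beta_yi_true,
                row.alpha_true, row.gamma_true,
                cfg, rng, canvas=canvas, center=centers[ci],
            )
            nclip_img += nclip
        name = f"img_{img_idx:04d}.png"
        path = outdir / "images" / name
        write_rgb(path, canvas)
        image_paths.append(path)
        clip_counts.append(nclip_img)
        img_col.extend([f"images/{name}"] * len(block))
        comp_col.extend(range(len(block)))
    truth = truth.assign(image_path=img_col, component_index=comp_col)
    truth.to_csv(outdir / "truth.csv", index=False)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "n_slices": int(len(truth)),
        "n_images": len(image_paths),
        "clipped_pixels": clip_counts,
        "files": ["truth.csv"] + [f"images/{p.name}" for p in image_paths],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return SyntheticDataset(
        root=outdir, truth=truth, image_paths=image_paths, manifest=manifest
    )
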