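"""Synthetic two-channel cell images with known localization ground truth.

Emulates the image structure the granule quantification consumes: an
elongated (trypanosome-like) cell mask with uniform cytoplasmic signal, a
Gaussian-profile spot at one pole of the cell, optional disk-shaped stress
granules in the marker channel, an additive constant background, and
Gaussian camera noise.

The generator's ``pp_fraction`` parameter is defined operationally: it is
the fraction of the channel's total (pre-noise) signal contained in the
standard measuring circle at the pole — the pole spot plus the diffuse
cytoplasm beneath it. The spot mass is calibrated so the circle holds
exactly the requested percentage, which makes quantification of a noise-free
image return the parameter itself (round-trip closure). At ``pp_fraction 0``
no spot is planted and the measured value is simply the circle's share of
the uniform signal; a requested fraction below that diffuse share is
infeasible and raises an error. Granule shares are calibrated the same way
over the planted granule pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .granules import PP_RADIUS_PX, CellImage, circle_mask

__all__ = ["ImageTruth", "simulate_cell", "save_cell", "load_cell"]


@dataclass
class ImageTruth:
    """Ground truth for one synthetic cell."""

    pp_fraction: dict[str, float]
    pp_center: tuple[int, int]
    pp_radius_px: float
    granule_share: dict[str, float]
    granule_mask: np.ndarray | None
    background: float
    noise_sd: float
    cell_mask: np.ndarray = field(repr=False, default=None)


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi_axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a_row, a_col = semi_axes
    return ((rr - center[0]) / a_row) ** 2 + ((cc - center[1]) / a_col) ** 2 <= 1.0


def simulate_cell(
    shape: tuple[int, int] = (80, 340),
    semi_axes: tuple[float, float] = (20.0, 150.0),
    pp_fraction: Mapping[str, float] | None = None,
    n_granules: int = 0,
    granule_share: Mapping[str, float] | None = None,
    granule_radius: float = 3.0,
    background: float = 10.0,
    noise_sd: float = 5.0,
    cyto_level: float = 100.0,
    pp_radius_px: float = PP_RADIUS_PX,
    channels: Sequence[str] = ("bait", "marker"),
    n_slices: int = 1,
    seed: int | None = None,
) -> tuple[CellImage, ImageTruth]:
    """Simulate one two-channel cell.

    ``pp_fraction`` maps channel name to the percentage of that channel's
    total signal inside the pole circle (see module docstring for the
    calibration); ``granule_share`` likewise for the stress-granule pixels.
    The pole spot has a truncated Gaussian profile (sigma = circle radius/2)
    restricted to circle-and-mask pixels; granules are disks of
    ``granule_radius`` planted in the cell interior away from the pole.
    With ``n_slices > 1`` each channel is emitted as a Z-stack whose
    sum-slice projection carries the configured signal.
    """
    rng = np.random.default_rng(seed)
    pp_fraction = dict(pp_fraction or {})
    granule_share = dict(granule_share or {})
    for name, f in {**pp_fraction, **granule_share}.items():
        if not 0 <= f < 100:
            raise ValueError(f"fraction for channel {name!r} must be in [0, 100)")

    center = (shape[0] / 2.0 - 0.5, shape[1] / 2.0 - 0.5)
    cell_mask = _ellipse_mask(shape, center, semi_axes)
    area = int(cell_mask.sum())
    total_cyto = cyto_level * area

    # pole of the mask: extreme point along the long (column) axis
    cols_in = np.argwhere(cell_mask)
    pole = tuple(int(v) for v in cols_in[np.argmax(cols_in[:, 1])])

    circle = circle_mask(shape, pole, pp_radius_px)
    spot_region = circle & cell_mask
    if not spot_region.any():
        raise ValueError("pole circle does not intersect the cell mask")
    cyto_in_circle = cyto_level * int(spot_region.sum())

    # Gaussian spot profile, truncated to circle-and-mask pixels
    rr, cc = np.indices(shape)
    sigma = pp_radius_px / 2.0
    profile = np.exp(-(((rr - pole[0]) ** 2 + (cc - pole[1]) ** 2) / (2 * sigma**2)))
    profile = np.where(spot_region, profile, 0.0)
    profile /= profile.sum()

    # granule disks in the marker channel's interior, away from the pole circle
    gmask = None
    if n_granules > 0:
        gmask = np.zeros(shape, dtype=bool)
        placed = 0
        for _ in range(10000):
            if placed == n_granules:
                break
            r = rng.uniform(shape[0] * 0.25, shape[0] * 0.75)
            c = rng.uniform(shape[1] * 0.15, shape[1] * 0.7)
            disk = circle_mask(shape, (r, c), granule_radius)
            if (disk & ~cell_mask).any() or (disk & circle).any() or (disk & gmask).any():
                continue
            gmask |= disk
            placed += 1
        if placed < n_granules:
            raise ValueError("could not place the requested number of granules")

    images: dict[str, np.ndarray] = {}
    truth_pp: dict[str, float] = {}
    truth_gr: dict[str, float] = {}
    for name in channels:
        cyto = np.where(cell_mask, cyto_level, 0.0)
        f = pp_fraction.get(name, 0.0) / 100.0
        s = granule_share.get(name, 0.0) / 100.0 if gmask is not None else 0.0
        cyto_in_granules = cyto_level * int(gmask.sum()) if gmask is not None else 0.0

        # solve for spot mass S and granule mass G such that the circle holds
        # exactly f and the granule pixels exactly s of the channel total
        #   S + cyto_in_circle  = f * (T0 + S + G)
        #   G + cyto_in_granule = s * (T0 + S + G)
        a = np.array([[1 - f, -f], [-s, 1 - s]])
        b = np.array([f * total_cyto - cyto_in_circle,
                      s * total_cyto - cyto_in_granules])
        spot_mass, granule_mass = np.linalg.solve(a, b)
        if f > 0 and spot_mass < 0:
            raise ValueError(
                f"requested pp_fraction {100*f:.3g}% for channel {name!r} is below "
                "the diffuse circle share; enlarge the cell or raise the fraction"
            )
        if f == 0:
            spot_mass = 0.0
        if s == 0:
            granule_mass = 0.0
        if granule_mass < 0:
            raise ValueError(
                f"requested granule_share {100*s:.3g}% for channel {name!r} is below "
                "the diffuse granule-pixel share"
            )

        image = cyto + spot_mass * profile
        if gmask is not None and granule_mass > 0:
            image = image + granule_mass * (gmask / gmask.sum())
        total = image.sum()
        truth_pp[name] = 100.0 * image[spot_region].sum() / total
        truth_gr[name] = 100.0 * image[gmask].sum() / total if gmask is not None else 0.0

        image = image + background
        if n_slices > 1:
            stack = np.repeat(image[None, :, :] / n_slices, n_slices, axis=0)
            stack += rng.normal(0.0, noise_sd / np.sqrt(n_slices), size=stack.shape)
            images[name] = np.clip(stack, 0.0, None)
        else:
            noisy = image + rng.normal(0.0, noise_sd, size=image.shape)
            images[name] = np.clip(noisy, 0.0, None)

    cell = CellImage(channels=images, cell_mask=cell_mask)
    truth = ImageTruth(
        pp_fraction=truth_pp,
        pp_center=pole,
        pp_radius_px=pp_radius_px,
        granule_share=truth_gr,
        granule_mask=gmask,
        background=background,
        noise_sd=noise_sd,
        cell_mask=cell_mask,
    )
    return cell, truth


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------

def save_cell(cell: CellImage, truth: ImageTruth, directory: str | Path, stem: str) -> None:
    """Write channels as one multi-channel TIFF plus mask TIFF and truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = list(cell.channels)
    stack = np.stack([cell.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(directory / f"{stem}.tif", stack,
                     metadata={"axes": "CYX" if stack.ndim == 3 else "CZYX",
                               "channels": ",".join(names)})
    tifffile.imwrite(directory / f"{stem}_mask.tif",
                     cell.cell_mask.astype(np.uint8))
    rows = {
        "channel": names,
        "pp_fraction": [truth.pp_fraction.get(n, 0.0) for n in names],
        "granule_share": [truth.granule_share.get(n, 0.0) for n in names],
    }
    df = pd.DataFrame(rows)
    df["pp_center_row"] = truth.pp_center[0]
    df["pp_center_col"] = truth.pp_center[1]
    df["pp_radius_px"] = truth.pp_radius_px
    df["background"] = truth.background
    df["noise_sd"] = truth.noise_sd
    df.to_csv(directory / f"{stem}_truth.tsv", sep="\t", index=False)


def load_cell(directory: str | Path, stem: str) -> tuple[CellImage, ImageTruth]:
    """Read back a cell written by :func:`save_cell`."""
    directory = Path(directory)
    with tifffile.TiffFile(directory / f"{stem}.tif") as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("channels", "").split(",") if meta.get("channels") else [
        f"ch{i}" for i in range(stack.shape[0])
    ]
    mask = tifffile.imread(directory / f"{stem}_mask.tif").astype(bool)
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    df = pd.read_csv(directory / f"{stem}_truth.tsv", sep="\t")
    truth = ImageTruth(
        pp_fraction=dict(zip(df["channel"], df["pp_fraction"])),
        pp_center=(int(df["pp_center_row"].iloc[0]), int(df["pp_center_col"].iloc[0])),
        pp_radius_px=float(df["pp_radius_px"].iloc[0]),
        granule_share=dict(zip(df["channel"], df["granule_share"])),
        granule_mask=None,
        background=float(df["background"].iloc[0]),
        noise_sd=float(df["noise_sd"].iloc[0]),
        cell_mask=mask,
    )
    return CellImage(channels=channels, cell_mask=mask), truth
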