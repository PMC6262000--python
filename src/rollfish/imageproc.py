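"""Raw image stacks to labeled spot tables.

The spot-calling chain mirrors the classical amplified-FISH workflow:
maximum-intensity projection over focal planes, grid stitching of tile
scans, white top-hat background suppression, and watershed labeling of
thresholded foreground seeded at local intensity maxima, so that each
rolling-circle product receives a unique label. A robust per-spot
signal-to-noise ratio is measured against a local background annulus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat as _sk_white_tophat
from skimage.segmentation import watershed

from .errors import InvalidInputError, InvalidParameterError
from .simgen import ImageStack

__all__ = [
    "max_project",
    "stitch_tiles",
    "white_tophat",
    "detect_spots",
    "spot_snr",
]

#: Columns of a spot table as produced by :func:`detect_spots`.
SPOT_COLUMNS = ["label", "x_um", "y_um", "peak", "integrated", "area_px", "channel", "gene"]


def max_project(stack: ImageStack | np.ndarray, channel: str | None = None) -> np.ndarray:
    """Maximum-intensity projection over z.

    Accepts either an :class:`~rollfish.simgen.ImageStack` (with ``channel``
    naming the channel to project) or a raw ``(z, H, W)`` array.
    """
    if isinstance(stack, ImageStack):
        if channel is None or channel not in stack.channels:
            raise InvalidInputError(f"channel {channel!r} not in stack")
        planes = stack.channels[channel]
    else:
        planes = np.asarray(stack)
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise InvalidInputError("expected a non-empty (z, H, W) stack")
    return planes.max(axis=0)


def stitch_tiles(tiles: np.ndarray, overlap: float) -> np.ndarray:
    """Stitch a tile grid with known placement and fractional overlap.

    ``tiles`` is a ``(rows, cols, H, W)`` array; neighboring tiles overlap
    by ``overlap`` of their width/height (e.g. 0.10 for a 10% overlap scan).
    Placement is deterministic from the grid — no registration search —
    and pixels claimed by several tiles keep the per-pixel maximum.
    """
    tiles = np.asarray(tiles)
    if tiles.ndim != 4:
        raise InvalidInputError("tiles must have shape (rows, cols, H, W)")
    if not 0.0 <= overlap < 1.0:
        raise InvalidParameterError("overlap fraction must lie in [0, 1)")
    rows, cols, h, w = tiles.shape
    step_r = h - int(round(h * overlap))
    step_c = w - int(round(w * overlap))
    out = np.full(((rows - 1) * step_r + h, (cols - 1) * step_c + w), -np.inf)
    for r in range(rows):
        for c in range(cols):
            sl = np.s_[r * step_r : r * step_r + h, c * step_c : c * step_c + w]
            out[sl] = np.maximum(out[sl], tiles[r, c])
    return out


def white_tophat(image: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat: image minus its morphological opening by a disk.

    Suppresses background structure larger than the disk while preserving
    bright peaks smaller than it; the result is non-negative and bounded
    above by the input.
    """
    image = np.asarray(image)
    if radius < 1:
        raise InvalidParameterError("radius must be >= 1")
    if 2 * radius + 1 > min(image.shape):
        raise InvalidParameterError("structuring element larger than image")
    return _sk_white_tophat(image, footprint=disk(radius))


def _mad_threshold(values: np.ndarray, k: float) -> float:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return float(med + k * 1.4826 * mad)


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    tophat_radius: int = 5,
    threshold: float | None = None,
    k_mad: float = 5.0,
    min_separation_px: int = 3,
    channel: str = "spots",
    gene: str = "HER2",
) -> pd.DataFrame:
    """Call amplified-probe spots and label each one uniquely.

    Pipeline: white top-hat (disk of ``tophat_radius``) → foreground
    threshold → local maxima at least ``min_separation_px`` apart as seeds
    → watershed of the inverted top-hat image restricted to the foreground,
    so touching spots are split and every foreground pixel belongs to at
    most one label.

    By default the threshold is relative, ``median + k_mad·1.4826·MAD`` of
    the top-hat image, which makes the caller invariant to multiplicative
    intensity scaling; pass ``threshold`` for an absolute cutoff.

    Returns a DataFrame with one row per spot: ``label``, intensity-weighted
    centroid ``x_um``/``y_um``, ``peak`` and ``integrated`` intensity
    (measured on the background-suppressed image), ``area_px``, ``channel``
    and ``gene``. A blank image yields an empty table.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidInputError("empty image")
    if pixel_size_um <= 0:
        raise InvalidParameterError("pixel_size_um must be > 0")

    th = white_tophat(image, tophat_radius)
    cutoff = _mad_threshold(th, k_mad) if threshold is None else float(threshold)
    fg = th > cutoff
    if not fg.any():
        return pd.DataFrame(columns=SPOT_COLUMNS)

    peaks = peak_local_max(
        th, min_distance=min_separation_px, threshold_abs=cutoff, exclude_border=False
    )
    if peaks.shape[0] == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    # deterministic seed labels: row-major order of peak coordinates
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    markers = np.zeros(image.shape, dtype=np.int32)
    markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, peaks.shape[0] + 1)

    labels = watershed(-th, markers=markers, mask=fg)

    rows = []
    for rp in regionprops(labels, intensity_image=th):
        cy, cx = rp.centroid_weighted
        rows.append(
            dict(
                label=rp.label,
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                peak=float(rp.intensity_max),
                integrated=float(rp.image_intensity.sum()),
                area_px=int(rp.area),
                channel=channel,
                gene=gene,
            )
        )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def spot_snr(
    image: np.ndarray,
    spots: pd.DataFrame,
    pixel_size_um: float,
    *,
    annulus_px: tuple[int, int] = (5, 10),
) -> pd.Series:
    """Per-spot signal-to-noise ratio against a local background annulus.

    ``SNR = (peak − median(annulus)) / (1.4826 · MAD(annulus))``, the MAD
    scaled to estimate a Gaussian sd robustly. The peak is the maximum
    image value within 1 px of the spot centroid. Degenerate cases follow
    the flagging contract: a constant annulus (robust sd 0) gives ``inf``
    (or 0/0 → ``nan``); a spot whose annulus lies fully outside the image
    gives ``nan``.
    """
    r_in, r_out = annulus_px
    if not 0 < r_in < r_out:
        raise InvalidParameterError("need 0 < inner < outer annulus radius")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    out = np.empty(len(spots))
    for i, (_, s) in enumerate(spots.iterrows()):
        row = int(round(s.y_um / pixel_size_um))
        col = int(round(s.x_um / pixel_size_um))
        rr = np.arange(max(row - r_out, 0), min(row + r_out + 1, h))
        cc = np.arange(max(col - r_out, 0), min(col + r_out + 1, w))
        if rr.size == 0 or cc.size == 0:
            out[i] = np.nan
            continue
        d2 = (rr[:, None] - row) ** 2 + (cc[None, :] - col) ** 2
        ann = image[np.ix_(rr, cc)][(d2 > r_in**2) & (d2 <= r_out**2)]
        if ann.size == 0:
            out[i] = np.nan
            continue
        peak = image[
            max(row - 1, 0) : min(row + 2, h), max(col - 1, 0) : min(col + 2, w)
        ].max()
        med = np.median(ann)
        sd = 1.4826 * np.median(np.abs(ann - med))
        with np.errstate(divide="ignore", invalid="ignore"):
            out[i] = (peak - med) / sd
    return pd.Series(out, index=spots.index, name="snr")
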