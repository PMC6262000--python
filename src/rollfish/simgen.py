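"""Synthetic data generators with known ground truth.

Everything downstream (spot calling, segmentation, quantification, ROC
screening) is exercised against output of this module, because the raw
microscopy data the pipeline was designed for are not publicly deposited.
Each generator records the parameters it actually used in a
:class:`GroundTruth` object so tests can compare recovered quantities
against the truth.

Conventions
-----------
* Physical coordinates are in µm; images use 0-based row/col pixel indices
  with ``x_um = col * pixel_size``, ``y_um = row * pixel_size``
  (pixel-center convention).
* All generators are deterministic given ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "ImageStack",
    "GroundTruth",
    "IHC_SCORES",
    "DEFAULT_GROUP_MEANS",
    "TUMOR_SHAPE_PARAMS",
    "STROMAL_SHAPE_PARAMS",
    "generate_tissue_image",
    "generate_spot_field",
    "generate_two_color_dataset",
    "generate_tma_counts",
    "generate_shape_measurements",
]

#: Allowed immunohistochemistry score labels, from normal tissue to strongly
#: positive tumors.
IHC_SCORES = ("norm", "0", "1+", "2+", "3+")

#: Default mean spots per cell by IHC group for the tissue-microarray count
#: simulator. High expression in the 2+/3+ groups, near-background elsewhere.
DEFAULT_GROUP_MEANS: Mapping[str, float] = {
    "norm": 0.1,
    "0": 0.1,
    "1+": 0.3,
    "2+": 1.5,
    "3+": 4.0,
}

#: Default nucleus shape-descriptor distributions (ratio in µm, roundness
#: dimensionless) used by :func:`generate_shape_measurements`. The tumor
#: means/sds mimic manual measurements of large round tumor nuclei; the
#: stromal class is smaller (low area/perimeter ratio) and more elongated.
TUMOR_SHAPE_PARAMS = {
    "ratio_mean": 5.0,
    "ratio_sd": 0.3,
    "roundness_mean": 0.7,
    "roundness_sd": 0.08,
}
STROMAL_SHAPE_PARAMS = {
    "ratio_mean": 2.0,
    "ratio_sd": 0.5,
    "roundness_mean": 0.55,
    "roundness_sd": 0.12,
}


@dataclass
class ImageStack:
    """Multichannel image stack with physical pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name to a ``(z, H, W)`` float array.
    pixel_size_um
        Lateral pixel size in µm per pixel; must be positive.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be > 0")
        shapes = {c: a.shape[-2:] for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise InvalidParameterError(f"channel planes differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape[-2:]


@dataclass
class GroundTruth:
    """Ground truth attached to a simulated dataset.

    ``molecules`` has one row per simulated molecule with columns
    ``x_um, y_um, gene`` plus, where applicable, ``detected_a``,
    ``detected_b`` (boolean per-channel detection flags) and ``cell_id``
    (0 = outside any cell). ``true_params`` records every generator
    parameter needed to predict downstream measurements analytically.
    """

    molecules: pd.DataFrame
    true_params: dict = field(default_factory=dict)
    cells: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# helpers


def _render_gaussian_spots(image, positions_px, amplitude, sigma_px):
    """Add isotropic 2-D Gaussians (peak = amplitude) at subpixel positions."""
    h, w = image.shape
    r = max(1, int(np.ceil(4 * sigma_px)))
    for row, col in positions_px:
        r0, r1 = int(np.floor(row)) - r, int(np.floor(row)) + r + 1
        c0, c1 = int(np.floor(col)) - r, int(np.floor(col)) + r + 1
        rr = np.arange(max(r0, 0), min(r1, h))
        cc = np.arange(max(c0, 0), min(c1, w))
        if rr.size == 0 or cc.size == 0:
            continue
        dy = rr[:, None] - row
        dx = cc[None, :] - col
        image[np.ix_(rr, cc)] += amplitude * np.exp(
            -(dx**2 + dy**2) / (2.0 * sigma_px**2)
        )
    return image


def _sample_separated_points(rng, n, low, high, min_sep, max_tries=500):
    """Rejection-sample n points in [low, high]^2 with pairwise min separation.

    ``min_sep`` may be a scalar or a per-point sequence of collision radii
    (two points i, j must then be at least ``r_i + r_j`` apart).
    """
    radii = np.broadcast_to(np.asarray(min_sep, dtype=float) / 2.0, (n,))
    pts: list[np.ndarray] = []
    for i in range(n):
        for _attempt in range(max_tries):
            p = rng.uniform(low, high, size=2)
            if all(
                np.hypot(*(p - q)) >= radii[i] + radii[j]
                for j, q in enumerate(pts)
            ):
                pts.append(p)
                break
        else:
            raise InvalidParameterError(
                f"could not place {n} points in [{low}, {high}]; lower the density"
            )
    return np.array(pts).reshape(n, 2)


def _ellipse_mask_indices(shape, center_rc, a_px, b_px, theta):
    """Row/col indices of pixels inside an ellipse (semi-axes in px)."""
    h, w = shape
    r = int(np.ceil(max(a_px, b_px))) + 1
    rr = np.arange(max(int(center_rc[0]) - r, 0), min(int(center_rc[0]) + r + 1, h))
    cc = np.arange(max(int(center_rc[1]) - r, 0), min(int(center_rc[1]) + r + 1, w))
    dy = rr[:, None] - center_rc[0]
    dx = cc[None, :] - center_rc[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    ri, ci = np.nonzero(inside)
    return rr[ri], cc[ci]


# ---------------------------------------------------------------------------
# generators


def generate_tissue_image(
    field_size_um: float = 150.0,
    pixel_size_um: float = 0.325,
    n_tumor: int = 8,
    n_stromal: int = 12,
    spots_per_tumor_cell: float = 8.0,
    spots_per_stromal_cell: float = 0.5,
    psf_sigma_px: float = 1.3,
    amplitude: float = 500.0,
    background: float = 100.0,
    noise_sd: float = 10.0,
    *,
    tumor_diameter_um: tuple[float, float] = (18.0, 2.0),
    tumor_axis_ratio: tuple[float, float] = (0.7, 1.0),
    stromal_diameter_um: tuple[float, float] = (7.0, 1.5),
    stromal_axis_ratio: tuple[float, float] = (0.2, 0.5),
    cytoplasm_radius_um: float = 4.0,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a tissue field: nuclei, autofluorescent cytoplasm, RCP spots.

    Emulates an FFPE tissue scan: a DAPI-like nucleus channel, a cytoplasmic
    autofluorescence channel, and one spot channel in which each amplified
    probe product is a diffraction-limited isotropic Gaussian of peak
    ``amplitude`` over a constant autofluorescent ``background`` with
    additive Gaussian read noise. Tumor nuclei are larger and rounder
    (axis ratio near 1) than stromal nuclei.

    Per-cell spot counts are Poisson with the class mean; spot positions are
    uniform within the cell's cytoplasmic disk (nucleus equivalent radius +
    ``cytoplasm_radius_um``).

    Returns
    -------
    (ImageStack, GroundTruth)
        Channels ``nuclei``, ``autofluorescence``, ``spots`` each of shape
        ``(1, H, W)``. Ground-truth molecules carry ``cell_id`` (1-based,
        0 = none); ``GroundTruth.cells`` lists nucleus centers, class and
        ellipse axes.
    """
    if field_size_um <= 0 or pixel_size_um <= 0:
        raise InvalidParameterError("field and pixel size must be > 0")
    if min(spots_per_tumor_cell, spots_per_stromal_cell) < 0:
        raise InvalidParameterError("spot densities must be >= 0")
    if n_tumor < 0 or n_stromal < 0:
        raise InvalidParameterError("nucleus counts must be >= 0")

    rng = np.random.default_rng(seed)
    npx = int(round(field_size_um / pixel_size_um))
    shape = (npx, npx)

    n_cells = n_tumor + n_stromal
    cells = []
    shapes_drawn = []
    for i in range(n_cells):
        is_tumor = i < n_tumor
        dmu, dsd = tumor_diameter_um if is_tumor else stromal_diameter_um
        ar_lo, ar_hi = tumor_axis_ratio if is_tumor else stromal_axis_ratio
        d_eq = max(rng.normal(dmu, dsd), 2.0)
        ar = rng.uniform(ar_lo, ar_hi)
        theta = rng.uniform(0, np.pi)
        # preserve area: a*b = (d_eq/2)^2 with b/a = ar
        a_um = (d_eq / 2.0) / np.sqrt(ar)
        b_um = (d_eq / 2.0) * np.sqrt(ar)
        shapes_drawn.append((is_tumor, d_eq, ar, theta, a_um, b_um))
    if n_cells:
        margin = max(s[4] for s in shapes_drawn) + 1.0
        if 2 * margin >= field_size_um:
            raise InvalidParameterError("field too small for the requested nuclei")
        # collision diameter per cell = semi-major axis * 2 + clearance
        centers = _sample_separated_points(
            rng,
            n_cells,
            margin,
            field_size_um - margin,
            [2.0 * s[4] + 1.0 for s in shapes_drawn],
        )
    nuclei = np.zeros(shape)
    cell_id_map = np.zeros(shape, dtype=np.int32)
    for i in range(n_cells):
        is_tumor, d_eq, ar, theta, a_um, b_um = shapes_drawn[i]
        center_rc = centers[i][::-1] / pixel_size_um  # (y, x) -> (row, col)
        ri, ci = _ellipse_mask_indices(
            shape, center_rc, a_um / pixel_size_um, b_um / pixel_size_um, theta
        )
        nuclei[ri, ci] = 300.0
        cells.append(
            dict(
                cell_id=i + 1,
                x_um=centers[i][0],
                y_um=centers[i][1],
                true_class="tumor" if is_tumor else "stromal",
                equivalent_diameter_um=d_eq,
                axis_ratio=ar,
                theta=theta,
            )
        )

    # cytoplasmic autofluorescence: disk around each nucleus; nearest cell wins
    af = np.zeros(shape)
    molecules = []
    for c in cells:
        r_cyto_um = c["equivalent_diameter_um"] / 2.0 + cytoplasm_radius_um
        center_rc = np.array([c["y_um"], c["x_um"]]) / pixel_size_um
        ri, ci = _ellipse_mask_indices(
            shape, center_rc, r_cyto_um / pixel_size_um, r_cyto_um / pixel_size_um, 0.0
        )
        af[ri, ci] = np.maximum(af[ri, ci], 180.0)
        unclaimed = cell_id_map[ri, ci] == 0
        cell_id_map[ri[unclaimed], ci[unclaimed]] = c["cell_id"]

        mean = spots_per_tumor_cell if c["true_class"] == "tumor" else spots_per_stromal_cell
        k = rng.poisson(mean)
        # uniform in the cytoplasmic disk
        rr = r_cyto_um * np.sqrt(rng.uniform(size=k))
        phi = rng.uniform(0, 2 * np.pi, size=k)
        xs = np.clip(c["x_um"] + rr * np.cos(phi), 0, field_size_um - pixel_size_um)
        ys = np.clip(c["y_um"] + rr * np.sin(phi), 0, field_size_um - pixel_size_um)
        for x, y in zip(xs, ys):
            molecules.append(dict(x_um=x, y_um=y, gene="HER2", cell_id=c["cell_id"]))

    spot_img = np.zeros(shape)
    if molecules:
        pos_px = np.array(
            [[m["y_um"] / pixel_size_um, m["x_um"] / pixel_size_um] for m in molecules]
        )
        _render_gaussian_spots(spot_img, pos_px, amplitude, psf_sigma_px)

    def _finish(img, bg):
        return img + bg + rng.normal(0.0, noise_sd, size=shape)

    stack = ImageStack(
        channels={
            "nuclei": _finish(nuclei, 50.0)[None],
            "autofluorescence": _finish(af, 80.0)[None],
            "spots": _finish(spot_img, background)[None],
        },
        pixel_size_um=pixel_size_um,
    )
    gt = GroundTruth(
        molecules=pd.DataFrame(
            molecules, columns=["x_um", "y_um", "gene", "cell_id"]
        ),
        cells=pd.DataFrame(
            cells,
            columns=[
                "cell_id", "x_um", "y_um", "true_class",
                "equivalent_diameter_um", "axis_ratio", "theta",
            ],
        ),
        true_params=dict(
            amplitude=amplitude,
            background=background,
            noise_sd=noise_sd,
            psf_sigma_px=psf_sigma_px,
            pixel_size_um=pixel_size_um,
            field_size_um=field_size_um,
        ),
    )
    return stack, gt


def generate_spot_field(
    n_spots: int,
    field_size_um: float = 166.0,
    pixel_size_um: float = 0.325,
    psf_sigma_px: float = 1.3,
    amplitude: float = 500.0,
    background: float = 100.0,
    noise_sd: float = 10.0,
    min_separation_um: float | None = None,
    *,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render isolated Gaussian spots on a flat noisy background.

    A stripped-down single-channel variant of :func:`generate_tissue_image`
    for benchmarking the spot caller: ``n_spots`` molecules at random
    positions with a guaranteed pairwise separation (default 6·σ) and a
    3·σ clearance from the field edge.
    """
    if n_spots < 0:
        raise InvalidParameterError("n_spots must be >= 0")
    if field_size_um <= 0 or pixel_size_um <= 0:
        raise InvalidParameterError("field and pixel size must be > 0")
    rng = np.random.default_rng(seed)
    npx = int(round(field_size_um / pixel_size_um))
    if min_separation_um is None:
        min_separation_um = 6.0 * psf_sigma_px * pixel_size_um
    margin = 3.0 * psf_sigma_px * pixel_size_um
    img = np.zeros((npx, npx))
    if n_spots:
        pts = _sample_separated_points(
            rng, n_spots, margin, field_size_um - margin, min_separation_um
        )
        pos_px = pts[:, ::-1] / pixel_size_um  # (x, y) -> (row, col)
        _render_gaussian_spots(img, pos_px, amplitude, psf_sigma_px)
        mols = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1], "gene": "HER2"})
    else:
        mols = pd.DataFrame(columns=["x_um", "y_um", "gene"])
    img = img + background + rng.normal(0.0, noise_sd, size=img.shape)
    gt = GroundTruth(
        molecules=mols,
        true_params=dict(
            amplitude=amplitude,
            background=background,
            noise_sd=noise_sd,
            psf_sigma_px=psf_sigma_px,
            pixel_size_um=pixel_size_um,
        ),
    )
    return img, gt


def generate_two_color_dataset(
    n_molecules: int,
    q: float,
    jitter_sd_um: float = 0.2,
    *,
    field_size_um: float = 1000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the two-color colocalization assay.

    Each of ``n_molecules`` molecules (uniform in a square field) is
    detected independently in channel A and in channel B, each with
    probability ``q`` — the model in which two spectrally distinct padlock
    probes read out the same docking sequence. Observed spot positions are
    the true positions plus isotropic Gaussian localization jitter.

    Returns two spot tables (columns ``x_um, y_um, channel``) and the
    ground truth with per-molecule ``detected_a`` / ``detected_b`` flags.
    """
    if n_molecules < 0:
        raise InvalidParameterError("n_molecules must be >= 0")
    if not 0.0 <= q <= 1.0:
        raise InvalidParameterError(f"q must lie in [0, 1], got {q}")
    if jitter_sd_um < 0:
        raise InvalidParameterError("jitter_sd_um must be >= 0")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, field_size_um, size=(n_molecules, 2))
    det_a = rng.uniform(size=n_molecules) < q
    det_b = rng.uniform(size=n_molecules) < q

    def _observe(mask, channel):
        pos = xy[mask] + rng.normal(0.0, jitter_sd_um, size=(int(mask.sum()), 2))
        return pd.DataFrame(
            {"x_um": pos[:, 0], "y_um": pos[:, 1], "channel": channel}
        )

    spots_a = _observe(det_a, "A")
    spots_b = _observe(det_b, "B")
    gt = GroundTruth(
        molecules=pd.DataFrame(
            {
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "gene": "HER2",
                "detected_a": det_a,
                "detected_b": det_b,
            }
        ),
        true_params=dict(q=q, jitter_sd_um=jitter_sd_um, field_size_um=field_size_um),
    )
    return spots_a, spots_b, gt


def generate_tma_counts(
    n_samples_per_group: Mapping[str, int],
    mean_spots_per_cell: Mapping[str, float] = DEFAULT_GROUP_MEANS,
    dispersion: float = 2.0,
    cells_per_sample: int = 200,
    *,
    n_replicates: int = 1,
    sample_effect_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell transcript counts for a tissue microarray.

    Per-cell counts are negative-binomial with the IHC group's mean and a
    shared ``dispersion`` (shape) parameter; large dispersion approaches
    Poisson. Biological sample-to-sample variability is modelled by a
    lognormal multiplier on the group mean (``sample_effect_sd`` on the log
    scale) shared across replicate sections of the same sample, so
    replicate experiments correlate.

    Returns
    -------
    (sample_table, cell_counts)
        ``sample_table`` columns: ``sample_id, ihc_score, replicate_id,
        mean_spots_per_cell``. ``cell_counts`` columns: ``sample_id,
        replicate_id, cell_id, count``.
    """
    for g in list(n_samples_per_group) + list(mean_spots_per_cell):
        if g not in IHC_SCORES:
            raise InvalidParameterError(
                f"unknown IHC group {g!r}; allowed: {IHC_SCORES}"
            )
    if any(m < 0 for m in mean_spots_per_cell.values()):
        raise InvalidParameterError("group means must be >= 0")
    if cells_per_sample < 1:
        raise InvalidParameterError("cells_per_sample must be >= 1")
    if dispersion <= 0:
        raise InvalidParameterError("dispersion must be > 0")

    rng = np.random.default_rng(seed)
    sample_rows, cell_rows = [], []
    sid = 0
    for group in IHC_SCORES:
        n = n_samples_per_group.get(group, 0)
        mu_group = mean_spots_per_cell.get(group, 0.0)
        for _ in range(n):
            sid += 1
            mu = mu_group * np.exp(rng.normal(0.0, sample_effect_sd)) if mu_group else 0.0
            for rep in range(1, n_replicates + 1):
                if mu > 0:
                    p = dispersion / (dispersion + mu)
                    counts = rng.negative_binomial(dispersion, p, size=cells_per_sample)
                else:
                    counts = np.zeros(cells_per_sample, dtype=int)
                sample_rows.append(
                    dict(
                        sample_id=sid,
                        ihc_score=group,
                        replicate_id=rep,
                        mean_spots_per_cell=float(counts.mean()),
                    )
                )
                cell_rows.extend(
                    dict(sample_id=sid, replicate_id=rep, cell_id=i + 1, count=int(c))
                    for i, c in enumerate(counts)
                )
    sample_table = pd.DataFrame(
        sample_rows, columns=["sample_id", "ihc_score", "replicate_id", "mean_spots_per_cell"]
    )
    cell_counts = pd.DataFrame(
        cell_rows, columns=["sample_id", "replicate_id", "cell_id", "count"]
    )
    return sample_table, cell_counts


def generate_shape_measurements(
    n: int,
    ratio_mean: float = TUMOR_SHAPE_PARAMS["ratio_mean"],
    ratio_sd: float = TUMOR_SHAPE_PARAMS["ratio_sd"],
    roundness_mean: float = TUMOR_SHAPE_PARAMS["roundness_mean"],
    roundness_sd: float = TUMOR_SHAPE_PARAMS["roundness_sd"],
    true_class: str = "tumor",
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw nucleus shape descriptors (area/perimeter ratio, roundness).

    Emulates manual measurement of putative tumor (or stromal) nuclei used
    to calibrate classification cutoffs. Both descriptors are normal;
    roundness is clipped to [0, 1], ratio to > 0.

    Returns a DataFrame with columns ``ratio, roundness, true_class``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if ratio_sd < 0 or roundness_sd < 0:
        raise InvalidParameterError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    ratio = np.maximum(rng.normal(ratio_mean, ratio_sd, size=n), 1e-6)
    roundness = np.clip(rng.normal(roundness_mean, roundness_sd, size=n), 0.0, 1.0)
    return pd.DataFrame(
        {"ratio": ratio, "roundness": roundness, "true_class": true_class}
    )
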