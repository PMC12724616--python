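"""Nucleus segmentation, FISH spot detection, assignment and registration.

Segmentation is a transparent classical stand-in (Otsu threshold, hole
filling, distance-transform watershed) adequate for the smooth synthetic
nuclei this package simulates; it shares the I/O contract of the learned
segmenters used on real screens but is not a re-implementation of them.

Spot detection is a Laplacian-of-Gaussian blob detector with a robust
(MAD-based) background threshold and intensity-weighted subpixel centroids.

Channel registration aligns the DAPI images of two acquisitions by phase
cross-correlation with subpixel upsampling; the recovered shift is then
applied to the spot table of the moving acquisition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # cell_id of spots outside every nucleus

SPOT_COLUMNS = ["channel", "cell_id", "y_px", "x_px", "z_px",
                "x_um", "y_um", "z_um", "peak_intensity", "quality",
                "registered"]


@dataclass
class RegistrationResult:
    """Measured displacement of a moving image relative to a reference.

    ``shift_px`` is (dy, dx): the moving image content sits ``shift_px`` away
    from the reference, so subtracting it from moving-frame coordinates maps
    them into the reference frame.
    """

    shift_px: tuple[float, float]
    peak_correlation: float


def segment_nuclei(dapi_2d: np.ndarray, min_area_px: int = 200,
                   border_policy: str = "exclude"
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment nuclei in a 2D DAPI image.

    Otsu threshold -> hole filling -> distance-transform watershed to split
    touching nuclei; regions smaller than ``min_area_px`` are dropped.
    Border-touching nuclei are flagged and, under the default ``"exclude"``
    policy, removed from both the record table and the label image (distance
    measurements near crops are unreliable); ``border_policy="keep"`` retains
    them flagged.

    Returns a (records, label_image) pair; records columns are label,
    centroid_y_px, centroid_x_px, area_px, bbox coordinates and
    touches_border.  A blank image yields zero nuclei.
    """
    if border_policy not in ("exclude", "keep"):
        raise ValueError("border_policy must be 'exclude' or 'keep'")
    img = np.asarray(dapi_2d, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a 2D image")
    empty = pd.DataFrame(columns=["label", "centroid_y_px", "centroid_x_px",
                                  "area_px", "min_y", "min_x", "max_y",
                                  "max_x", "touches_border"])
    if img.size == 0 or np.ptp(img) == 0:
        logger.info("blank DAPI image: no nuclei")
        return empty, np.zeros(img.shape, dtype=np.int32)

    mask = img > threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    min_sep = max(3, int(round(math.sqrt(min_area_px / math.pi))))
    coords = peak_local_max(distance, min_distance=min_sep, labels=mask)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(coords, start=1):
        markers[y, x] = i
    labels = watershed(-distance, markers, mask=mask).astype(np.int32)

    ny, nx = labels.shape
    rows = []
    drop = []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            drop.append(rp.label)
            continue
        min_y, min_x, max_y, max_x = rp.bbox
        touches = min_y == 0 or min_x == 0 or max_y == ny or max_x == nx
        if touches and border_policy == "exclude":
            drop.append(rp.label)
            logger.info("nucleus %d touches the border: excluded", rp.label)
            continue
        cy, cx = rp.centroid
        rows.append((rp.label, cy, cx, int(rp.area),
                     min_y, min_x, max_y, max_x, touches))
    if drop:
        labels[np.isin(labels, drop)] = 0
    records = pd.DataFrame(rows, columns=empty.columns.tolist())
    if not rows:
        return empty, labels
    return records, labels


def _mad_spread(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * np.median(np.abs(values - med))


def detect_spots(image: np.ndarray, channel: str = "",
                 sigma_px: float = 1.3, min_snr: float = 8.0,
                 pixel_xy_um: Optional[float] = None,
                 z_step_um: Optional[float] = None) -> pd.DataFrame:
    """Detect diffraction-limited spots in a 2D image or 3D (Z, Y, X) stack.

    The scale-normalized negative LoG response at ``sigma_px`` is computed;
    local maxima whose response exceeds ``min_snr`` times the robust
    background spread (median absolute deviation x 1.4826) are kept.  For a
    3D stack the filter sigma in Z is compressed by the voxel anisotropy
    (``sigma_px * pixel_xy_um / z_step_um``).  Subpixel centroids are
    intensity-weighted means of the positive response in a window of
    half-width ceil(sigma); plateau ties resolve to the lexicographically
    lowest coordinate.  ``quality`` is response over background spread.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    img = np.asarray(image, dtype=float)
    is3d = img.ndim == 3
    if img.ndim not in (2, 3):
        raise ValueError("detect_spots expects a 2D image or 3D stack")
    if is3d:
        if not (pixel_xy_um and z_step_um):
            raise ValueError("3D detection needs pixel_xy_um and z_step_um "
                             "for the anisotropic filter")
        sigma = (sigma_px * pixel_xy_um / z_step_um, sigma_px, sigma_px)
    else:
        sigma = sigma_px

    response = -ndi.gaussian_laplace(img, sigma) * sigma_px ** 2
    spread = _mad_spread(response)
    if spread == 0:
        spread = max(np.std(response), np.finfo(float).tiny)
    threshold = min_snr * spread

    w = int(math.ceil(sigma_px))
    foot = np.ones((2 * w + 1,) * img.ndim, dtype=bool)
    local_max = (response == ndi.maximum_filter(response, footprint=foot))
    candidates = local_max & (response > threshold)
    # a flat plateau yields a connected candidate component; keep its
    # lexicographically lowest coordinate
    lab, n = ndi.label(candidates)
    rows = []
    pos_resp = np.clip(response, 0, None)
    for comp in range(1, n + 1):
        pts = np.argwhere(lab == comp)
        peak = pts[np.lexsort(pts.T[::-1])][0]
        sl = tuple(slice(max(0, c - w), min(s, c + w + 1))
                   for c, s in zip(peak, img.shape))
        window = pos_resp[sl]
        total = window.sum()
        if total == 0:
            centroid = peak.astype(float)
        else:
            grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl],
                                indexing="ij")
            centroid = np.array([(g * window).sum() / total for g in grids])
        peak_val = response[tuple(peak)]
        inten = img[tuple(peak)]
        if is3d:
            z, y, x = centroid
        else:
            y, x = centroid
            z = np.nan
        rows.append((channel, UNASSIGNED, y, x, z, np.nan, np.nan, np.nan,
                     inten, peak_val / spread, False))

    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    if pixel_xy_um:
        spots["x_um"] = spots["x_px"] * pixel_xy_um
        spots["y_um"] = spots["y_px"] * pixel_xy_um
    if z_step_um:
        spots["z_um"] = spots["z_px"] * z_step_um
    return spots


def register_translation(ref_dapi: np.ndarray, moving_dapi: np.ndarray,
                         upsample: int = 20) -> RegistrationResult:
    """Estimate the rigid (dy, dx) shift between two DAPI images.

    Phase cross-correlation with subpixel refinement at ``upsample``; the
    returned shift is the displacement of ``moving_dapi`` relative to
    ``ref_dapi`` (inverse-consistent to ~1/upsample px).
    """
    ref = np.asarray(ref_dapi, dtype=float)
    mov = np.asarray(moving_dapi, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must share a shape")
    for name, im in (("reference", ref), ("moving", mov)):
        if np.ptp(im) == 0:
            raise ValueError(f"{name} DAPI image is constant; cannot register")
    neg_shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample, normalization=None)
    shift = tuple(-float(s) for s in neg_shift)
    # correlation after undoing the integer part of the shift
    back = np.roll(mov, tuple(-int(round(s)) for s in shift), axis=(0, 1))
    corr = float(np.corrcoef(ref.ravel(), back.ravel())[0, 1])
    return RegistrationResult(shift_px=shift, peak_correlation=corr)


def apply_registration(spots: pd.DataFrame, result: RegistrationResult,
                       pixel_xy_um: Optional[float] = None) -> pd.DataFrame:
    """Map moving-acquisition spot centroids into the reference frame.

    Subtracts ``result.shift_px`` from the pixel centroids and recomputes the
    physical coordinates.  Registration is recorded per spot; applying it a
    second time raises (the operation is not idempotent).
    """
    if "registered" in spots.columns and spots["registered"].any():
        raise ValueError("spots already registered; refusing a second "
                         "application of the shift")
    out = spots.copy()
    dy, dx = result.shift_px
    out["y_px"] = out["y_px"] - dy
    out["x_px"] = out["x_px"] - dx
    if pixel_xy_um:
        out["x_um"] = out["x_px"] * pixel_xy_um
        out["y_um"] = out["y_px"] * pixel_xy_um
    elif {"x_um", "y_um"}.issubset(out.columns) and len(out):
        # preserve whatever calibration the table already used
        with np.errstate(invalid="ignore", divide="ignore"):
            cal = np.nanmedian(out["x_um"] / (out["x_px"] + dx))
        if np.isfinite(cal):
            out["x_um"] = out["x_px"] * cal
            out["y_um"] = out["y_px"] * cal
    out["registered"] = True
    return out


def assign_spots_to_nuclei(spots: pd.DataFrame,
                           label_image: np.ndarray) -> pd.DataFrame:
    """Set each spot's cell_id to the nucleus label under its centroid.

    Uses the rounded (y, x) position; label 0 (background) and out-of-field
    centroids map to ``UNASSIGNED``.
    """
    ny, nx = label_image.shape
    out = spots.copy()
    ids = np.full(len(out), UNASSIGNED, dtype=int)
    ys = np.round(out["y_px"].to_numpy()).astype(int)
    xs = np.round(out["x_px"].to_numpy()).astype(int)
    inside = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
    ids[inside] = label_image[ys[inside], xs[inside]]
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d spot centroid(s) outside the field: unassigned", n_out)
    out["cell_id"] = ids
    return out
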