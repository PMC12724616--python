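"""Ground-truthed synthetic scenes for allele-level DNA/RNA FISH.

The generator emulates the geometry the downstream analysis assumes: nuclei
scattered in a field of view, each carrying ``ploidy`` alleles of a genomic
domain whose 5' and 3' boundary loci are labelled in separate DNA FISH
channels, plus a nascent-RNA FISH channel that lights up only at
transcriptionally active alleles.

The 5'-to-3' boundary displacement follows a two-state mixture: with
probability ``p_pair`` the boundaries are *paired* and the displacement is an
isotropic Gaussian with small per-axis sd ``paired_scale_um``; otherwise the
*unpaired* sd ``unpaired_scale_um`` applies.  The 3D boundary distance is then
``scale * chi(3 df)``, which gives closed-form oracles for medians and for the
fraction of alleles below an interaction threshold.

Three levels of output are available:

``simulate_ground_truth``
    exact allele geometry and state labels (no imaging at all);
``degrade_to_spot_table``
    a detected-spot table with per-channel detection efficiency, localization
    noise and an unregistered RNA-channel shift — the state of the data after
    spot detection but before registration;
``render_stack``
    a 4-channel 3D image stack (DAPI + two DNA FISH + RNA FISH) with Gaussian
    spots, spherical nuclei and Poisson shot noise, for exercising the image
    analysis front end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .imageio import ImageStack, DEFAULT_CHANNEL_NAMES

logger = logging.getLogger(__name__)

#: FISH channels that carry point signals (DAPI is handled separately).
SPOT_CHANNELS = ("dna5", "dna3", "rna")

# sub-stream tags for the root seed; fixed so that adding a stage never
# reshuffles another stage's draws
_STREAM_PACK = 0
_STREAM_CELL = 1
_STREAM_DETECT = 2
_STREAM_RENDER = 3


class PackingError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be placed in the field."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic HiFISH scene.

    Defaults encode the imaging geometry of the spinning-disk acquisition the
    analysis targets (152 nm XY pixels, 1 um Z steps over a 7 um stack) and a
    boundary-distance mixture whose 2D-projected population median (~0.41 um)
    and 250 nm interaction fraction (~0.30) sit in the range reported for
    human TAD boundaries.
    """

    n_cells: int = 2000
    ploidy: int = 2
    nucleus_radius_um: float = 3.0
    field_size_px: tuple[int, int] = (4096, 4096)  # (x, y)
    z_planes: int = 8
    pixel_xy_um: float = 0.152
    z_step_um: float = 1.0
    p_pair: float = 0.15
    paired_scale_um: float = 0.08
    unpaired_scale_um: float = 0.40
    p_active: float = 0.3
    #: pairing probability for active alleles; None = same as inactive
    #: (activity and boundary pairing independent, the uncoupled null)
    p_pair_active: Optional[float] = None
    rna_offset_scale_um: float = 0.2
    #: per-channel detection probability; scalar applies to all spot channels
    detect_eff: float | Mapping[str, float] = 0.99
    loc_noise_um: float = 0.02
    channel_shift_px: tuple[float, float] = (0.0, 0.0)  # (dx, dy) of RNA acq.
    spot_sigma_px: float = 1.3
    #: axial PSF sd in um (confocal axial extent ~3x lateral)
    spot_sigma_z_um: float = 0.6
    spot_amplitude: float = 200.0
    background: float = 25.0
    min_allele_separation_um: float = 1.5
    seed: int = 0

    # -- derived geometry -------------------------------------------------
    @property
    def field_size_um(self) -> tuple[float, float]:
        return (self.field_size_px[0] * self.pixel_xy_um,
                self.field_size_px[1] * self.pixel_xy_um)

    @property
    def z_extent_um(self) -> float:
        return (self.z_planes - 1) * self.z_step_um

    def efficiency(self, channel: str) -> float:
        if isinstance(self.detect_eff, Mapping):
            return float(self.detect_eff.get(channel, 1.0))
        return float(self.detect_eff)

    def validate(self) -> "SimulationConfig":
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 (diploid) or 3 (triploid)")
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")
        for name in ("nucleus_radius_um", "pixel_xy_um", "z_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("paired_scale_um", "unpaired_scale_um",
                     "rna_offset_scale_um", "loc_noise_um",
                     "spot_sigma_px", "spot_sigma_z_um",
                     "spot_amplitude", "background",
                     "min_allele_separation_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = {"p_pair": self.p_pair, "p_active": self.p_active}
        if self.p_pair_active is not None:
            probs["p_pair_active"] = self.p_pair_active
        if isinstance(self.detect_eff, Mapping):
            probs.update({f"detect_eff[{k}]": v
                          for k, v in self.detect_eff.items()})
        else:
            probs["detect_eff"] = self.detect_eff
        for name, p in probs.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        fx, fy = self.field_size_um
        if min(fx, fy) < 2 * self.nucleus_radius_um:
            raise ValueError("field too small for a single nucleus")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_size_px"] = list(self.field_size_px)
        d["channel_shift_px"] = list(self.channel_shift_px)
        if isinstance(self.detect_eff, Mapping):
            d["detect_eff"] = dict(self.detect_eff)
        return d


@dataclass
class SceneGroundTruth:
    """True per-allele geometry and state for a simulated field.

    ``alleles`` columns: cell_id, allele_id, x5_um..z5_um, x3_um..z3_um,
    true_distance_um, paired_state, active, rna_x_um..rna_z_um (NaN when
    inactive).  ``nuclei`` columns: cell_id, cx_um, cy_um, cz_um, radius_um.
    Coordinates are physical (um) in the frame of the DNA acquisition.
    """

    alleles: pd.DataFrame
    nuclei: pd.DataFrame
    config: SimulationConfig


def _pack_nuclei(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Place n_cells non-overlapping nuclear spheres by rejection sampling.

    Spheres share a common z (mid-stack) so non-overlap is a 2D condition.
    """
    r = config.nucleus_radius_um
    fx, fy = config.field_size_um
    lo = np.array([r, r])
    hi = np.array([fx - r, fy - r])
    if np.any(hi <= lo):
        raise PackingError("field too small for nucleus radius")
    centers = np.empty((config.n_cells, 2))
    n_placed = 0
    max_attempts = 100 * config.n_cells
    attempts = 0
    min_d2 = (2 * r) ** 2
    while n_placed < config.n_cells:
        if attempts >= max_attempts:
            density = config.n_cells * math.pi * r * r / (fx * fy)
            raise PackingError(
                f"could not place {config.n_cells} non-overlapping nuclei "
                f"after {max_attempts} attempts (nuclear area density "
                f"{density:.2f}); enlarge the field or reduce n_cells")
        attempts += 1
        cand = lo + rng.random(2) * (hi - lo)
        if n_placed:
            d2 = np.sum((centers[:n_placed] - cand) ** 2, axis=1)
            if d2.min() < min_d2:
                continue
        centers[n_placed] = cand
        n_placed += 1
    return centers


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def _offset_in_sphere(rng: np.random.Generator, anchor: np.ndarray,
                      scale: float, center: np.ndarray, radius: float,
                      what: str) -> np.ndarray:
    """anchor + isotropic Gaussian offset, rejected until inside the nucleus."""
    if scale == 0:
        return anchor.copy()
    for _ in range(1000):
        pos = anchor + rng.normal(scale=scale, size=3)
        if np.sum((pos - center) ** 2) <= radius * radius:
            return pos
    raise RuntimeError(f"could not place {what} inside the nucleus; "
                       "offset scale too large for the nuclear radius")


def simulate_ground_truth(config: SimulationConfig) -> SceneGroundTruth:
    """Draw a full scene of nuclei, alleles, boundary spots and RNA sites.

    Deterministic for a fixed ``config.seed``: nucleus packing uses one
    sub-stream and each cell an independent counter-derived sub-stream, so
    increasing ``n_cells`` extends the scene without reshuffling earlier
    cells.
    """
    config.validate()
    centers_xy = _pack_nuclei(config, np.random.default_rng([config.seed, _STREAM_PACK]))
    r = config.nucleus_radius_um
    cz = config.z_extent_um / 2.0

    # keep anchors away from the nuclear envelope so that Gaussian offsets
    # almost never need rejection (keeps the chi(3) distance model exact)
    margin = 3.0 * max(config.paired_scale_um, config.unpaired_scale_um,
                       config.rna_offset_scale_um)
    r_anchor = r - margin
    if r_anchor <= 0:
        raise ValueError("nucleus_radius_um too small for the displacement "
                         "scales (anchor margin exhausts the radius)")

    rows = []
    nuc_rows = []
    for i in range(config.n_cells):
        cell_id = i + 1
        center = np.array([centers_xy[i, 0], centers_xy[i, 1], cz])
        nuc_rows.append((cell_id, *center, r))
        rng = np.random.default_rng([config.seed, _STREAM_CELL, i])

        # allele anchors: uniform in the shrunken sphere, mutually separated
        anchors = []
        for _ in range(config.ploidy):
            sep2 = config.min_allele_separation_um ** 2
            for attempt in range(1000):
                a = center + _uniform_in_sphere(rng, r_anchor)
                if all(np.sum((a - b) ** 2) >= sep2 for b in anchors):
                    break
            else:
                raise RuntimeError("could not separate allele anchors; "
                                   "min_allele_separation_um too large")
            anchors.append(a)

        for k, pos5 in enumerate(anchors):
            active = rng.random() < config.p_active
            p_pair = config.p_pair
            if active and config.p_pair_active is not None:
                p_pair = config.p_pair_active
            paired = rng.random() < p_pair
            scale = config.paired_scale_um if paired else config.unpaired_scale_um
            pos3 = _offset_in_sphere(rng, pos5, scale, center, r, "3' boundary")
            if active:
                rna = _offset_in_sphere(rng, pos5, config.rna_offset_scale_um,
                                        center, r, "RNA site")
            else:
                rna = np.full(3, np.nan)
            rows.append((cell_id, f"{cell_id}.{k + 1}", *pos5, *pos3,
                         float(np.linalg.norm(pos3 - pos5)), paired, active,
                         *rna))

    alleles = pd.DataFrame(rows, columns=[
        "cell_id", "allele_id",
        "x5_um", "y5_um", "z5_um", "x3_um", "y3_um", "z3_um",
        "true_distance_um", "paired_state", "active",
        "rna_x_um", "rna_y_um", "rna_z_um"])
    nuclei = pd.DataFrame(nuc_rows, columns=[
        "cell_id", "cx_um", "cy_um", "cz_um", "radius_um"])
    return SceneGroundTruth(alleles=alleles, nuclei=nuclei, config=config)


def degrade_to_spot_table(truth: SceneGroundTruth,
                          config: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Emulate spot detection on the ground truth, bypassing image rendering.

    Each true spot is retained with its channel's ``detect_eff``; retained
    centroids get isotropic Gaussian localization noise (``loc_noise_um``) and
    RNA-channel coordinates are shifted by ``channel_shift_px`` — the
    pre-registration state of a sequential DNA/RNA acquisition.  ``cell_id``
    is carried over (spot-to-nucleus assignment assumed perfect), and the true
    allele id is kept for evaluation against the ground truth.
    """
    cfg = config or truth.config
    shift_um = np.array([cfg.channel_shift_px[0] * cfg.pixel_xy_um,
                         cfg.channel_shift_px[1] * cfg.pixel_xy_um, 0.0])
    a = truth.alleles
    order = np.argsort(a["cell_id"].to_numpy(), kind="stable")
    cells = a["cell_id"].to_numpy()[order]
    allele_ids = a["allele_id"].to_numpy()[order]
    pos5 = a[["x5_um", "y5_um", "z5_um"]].to_numpy(dtype=float)[order]
    pos3 = a[["x3_um", "y3_um", "z3_um"]].to_numpy(dtype=float)[order]
    rna_pos = a[["rna_x_um", "rna_y_um", "rna_z_um"]].to_numpy(dtype=float)[order]
    is_active = a["active"].to_numpy(dtype=bool)[order]

    cell_order = {c: i for i, c in enumerate(np.unique(cells))}
    rows = []
    rng = None
    current_cell = None
    for k in range(len(cells)):
        if cells[k] != current_cell:
            current_cell = cells[k]
            rng = np.random.default_rng(
                [cfg.seed, _STREAM_DETECT, cell_order[current_cell]])
        sites = [("dna5", pos5[k]), ("dna3", pos3[k])]
        if is_active[k]:
            sites.append(("rna", rna_pos[k]))
        for channel, pos in sites:
            keep = rng.random() < cfg.efficiency(channel)
            noise = (rng.normal(scale=cfg.loc_noise_um, size=3)
                     if cfg.loc_noise_um > 0 else (0.0, 0.0, 0.0))
            if not keep:
                continue
            pos = np.add(pos, noise)
            if channel == "rna":
                pos = pos + shift_um
            rows.append((channel, int(current_cell), allele_ids[k],
                         pos[0], pos[1], pos[2]))
    spots = pd.DataFrame(rows, columns=[
        "channel", "cell_id", "true_allele_id", "x_um", "y_um", "z_um"])
    spots["x_px"] = spots["x_um"] / cfg.pixel_xy_um
    spots["y_px"] = spots["y_um"] / cfg.pixel_xy_um
    spots["z_px"] = spots["z_um"] / cfg.z_step_um
    spots["registered"] = False
    return spots


def _add_gaussian_spot(plane_stack: np.ndarray, pos_px: np.ndarray,
                       sigma_xy: float, sigma_z: float, amplitude: float) -> None:
    """Accumulate a 3D Gaussian into a (Z, Y, X) array, clipped to bounds."""
    nz, ny, nx = plane_stack.shape
    x0, y0, z0 = pos_px
    wxy = max(1, int(math.ceil(4 * sigma_xy)))
    wz = max(1, int(math.ceil(4 * max(sigma_z, 1e-6))))
    xs = np.arange(max(0, int(x0) - wxy), min(nx, int(x0) + wxy + 1))
    ys = np.arange(max(0, int(y0) - wxy), min(ny, int(y0) + wxy + 1))
    zs = np.arange(max(0, int(round(z0)) - wz), min(nz, int(round(z0)) + wz + 1))
    if not (len(xs) and len(ys) and len(zs)):
        return
    gx = np.exp(-0.5 * ((xs - x0) / sigma_xy) ** 2)
    gy = np.exp(-0.5 * ((ys - y0) / sigma_xy) ** 2)
    if sigma_z > 1e-6:
        gz = np.exp(-0.5 * ((zs - z0) / sigma_z) ** 2)
    else:
        gz = (zs == int(round(z0))).astype(float)
    blob = amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    plane_stack[np.ix_(zs, ys, xs)] += blob


def render_stack(truth: SceneGroundTruth,
                 config: Optional[SimulationConfig] = None,
                 noise: bool = True) -> ImageStack:
    """Render the scene into a 4-channel (C, Z, Y, X) image stack.

    DAPI = filled nuclear spheres smoothed by the PSF; each FISH spot a 3D
    Gaussian (sd ``spot_sigma_px`` laterally, ``spot_sigma_z_um`` axially,
    expressed in z-planes) of height ``spot_amplitude`` over ``background``
    photons; the
    RNA channel is rigidly shifted by ``channel_shift_px``; Poisson shot noise
    applied to every channel unless ``noise=False``.  Spots whose center falls
    outside the field are clipped and logged.
    """
    from scipy import ndimage as ndi

    cfg = config or truth.config
    nx, ny = cfg.field_size_px
    nz = cfg.z_planes
    data = np.zeros((4, nz, ny, nx), dtype=np.float64)
    px, zst = cfg.pixel_xy_um, cfg.z_step_um
    sigma_z = cfg.spot_sigma_z_um / zst  # axial PSF sd in z-planes

    # DAPI: voxelized spheres, then PSF blur in-plane
    zz = np.arange(nz) * zst
    for _, nuc in truth.nuclei.iterrows():
        cx, cy = nuc.cx_um / px, nuc.cy_um / px
        r_px = nuc.radius_um / px
        x_lo, x_hi = max(0, int(cx - r_px) - 1), min(nx, int(cx + r_px) + 2)
        y_lo, y_hi = max(0, int(cy - r_px) - 1), min(ny, int(cy + r_px) + 2)
        xs = np.arange(x_lo, x_hi) * px
        ys = np.arange(y_lo, y_hi) * px
        d2 = ((xs[None, None, :] - nuc.cx_um) ** 2
              + (ys[None, :, None] - nuc.cy_um) ** 2
              + (zz[:, None, None] - nuc.cz_um) ** 2)
        data[0, :, y_lo:y_hi, x_lo:x_hi] += (
            0.5 * cfg.spot_amplitude * (d2 <= nuc.radius_um ** 2))
    if cfg.spot_sigma_px > 0:
        for z in range(nz):
            data[0, z] = ndi.gaussian_filter(data[0, z], cfg.spot_sigma_px)

    ch_index = {"dna5": 1, "dna3": 2, "rna": 3}
    shift = np.array([cfg.channel_shift_px[0], cfg.channel_shift_px[1], 0.0])
    n_clipped = 0
    for _, al in truth.alleles.iterrows():
        sites = [("dna5", (al.x5_um, al.y5_um, al.z5_um)),
                 ("dna3", (al.x3_um, al.y3_um, al.z3_um))]
        if al.active:
            sites.append(("rna", (al.rna_x_um, al.rna_y_um, al.rna_z_um)))
        for channel, (x, y, z) in sites:
            pos = np.array([x / px, y / px, z / zst])
            if channel == "rna":
                pos = pos + shift
            if not (0 <= pos[0] < nx and 0 <= pos[1] < ny and 0 <= pos[2] < nz):
                n_clipped += 1
            _add_gaussian_spot(data[ch_index[channel]], pos,
                               cfg.spot_sigma_px, sigma_z, cfg.spot_amplitude)
    if n_clipped:
        logger.warning("%d spot(s) rendered outside the field were clipped",
                       n_clipped)

    data[1:] += cfg.background
    if noise:
        rng = np.random.default_rng([cfg.seed, _STREAM_RENDER])
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float32)
    else:
        data = data.astype(np.float32)
    return ImageStack(data=data, pixel_xy_um=px, z_step_um=zst,
                      channel_names=tuple(DEFAULT_CHANNEL_NAMES))


# ---------------------------------------------------------------------------
# closed-form oracles for the two-state distance mixture
# ---------------------------------------------------------------------------

def mixture_distance_cdf(d_um, p_pair: float, paired_scale_um: float,
                         unpaired_scale_um: float):
    """P(boundary distance < d) under the two-state chi(3) mixture.

    The 3D distance is ``scale * chi(3 df)`` per state, so the CDF is
    ``p_pair * F_chi3(d/paired_scale) + (1 - p_pair) * F_chi3(d/unpaired_scale)``.
    Degenerate zero scales contribute a point mass at 0.
    """
    d = np.asarray(d_um, dtype=float)

    def f(scale):
        if scale == 0:
            return (d >= 0).astype(float)
        return sps.chi.cdf(d / scale, df=3)

    return p_pair * f(paired_scale_um) + (1 - p_pair) * f(unpaired_scale_um)


def mixture_median(p_pair: float, paired_scale_um: float,
                   unpaired_scale_um: float) -> float:
    """Population median of the two-state chi(3) distance mixture."""
    hi = 10.0 * max(paired_scale_um, unpaired_scale_um, 1e-9)
    return brentq(
        lambda d: mixture_distance_cdf(d, p_pair, paired_scale_um,
                                       unpaired_scale_um) - 0.5, 0.0, hi)


def write_ground_truth(truth: SceneGroundTruth, alleles_path, nuclei_path=None) -> None:
    """Write the allele table (and optionally the nucleus table) as CSV."""
    truth.alleles.to_csv(alleles_path, index=False)
    if nuclei_path is not None:
        truth.nuclei.to_csv(nuclei_path, index=False)
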