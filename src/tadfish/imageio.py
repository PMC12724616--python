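"""Calibrated multichannel image container, OME-TIFF I/O and projections."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import tifffile

#: canonical channel order: nuclear counterstain, 5' boundary DNA FISH,
#: 3' boundary DNA FISH, nascent RNA FISH
DEFAULT_CHANNEL_NAMES = ("dapi", "dna5", "dna3", "rna")


@dataclass
class ImageStack:
    """A calibrated (C, Z, Y, X) intensity stack.

    ``pixel_xy_um`` is the lateral pixel size and ``z_step_um`` the plane
    spacing; both must be positive.  Intensities must be finite and
    non-negative (photon-like counts).
    """

    data: np.ndarray
    pixel_xy_um: float
    z_step_um: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel -> (1, Z, Y, X)
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"channel count mismatch: data has {self.data.shape[0]} "
                f"channels, expected {len(self.channel_names)} "
                f"({', '.join(self.channel_names)})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be >= 0")
        if not (self.pixel_xy_um > 0 and self.z_step_um > 0):
            raise ValueError("calibration must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None


@dataclass
class Projection:
    """A 2D image that kept its lateral calibration."""

    data: np.ndarray
    pixel_xy_um: float


def write_stack(stack: ImageStack, path) -> None:
    """Write an OME-TIFF with pixel-size and channel-name metadata."""
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_xy_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_xy_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _parse_ome_calibration(ome_xml: str):
    """Extract (pixel_xy_um, z_step_um, channel names) from OME-XML."""
    root = ET.fromstring(ome_xml)
    pixels = next((el for el in root.iter() if el.tag.endswith("Pixels")), None)
    if pixels is None:
        return None, None, None
    px = pixels.get("PhysicalSizeX")
    pz = pixels.get("PhysicalSizeZ")
    names = [el.get("Name") for el in pixels if el.tag.endswith("Channel")]
    names = [n for n in names if n] or None
    return (float(px) if px else None, float(pz) if pz else None, names)


def read_stack(path, pixel_xy_um: Optional[float] = None,
               z_step_um: Optional[float] = None,
               channel_names: Optional[Sequence[str]] = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into an :class:`ImageStack`.

    Calibration comes from the OME metadata when present; the keyword
    overrides win when given.  A plain TIFF with no metadata requires both
    overrides.  The file must carry exactly the expected number of channels
    (leading axis; a 3D file is treated as single-channel only if one channel
    name is expected).
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_px = meta_pz = meta_names = None
        if tf.ome_metadata:
            meta_px, meta_pz, meta_names = _parse_ome_calibration(tf.ome_metadata)

    px = pixel_xy_um if pixel_xy_um is not None else meta_px
    pz = z_step_um if z_step_um is not None else meta_pz
    if px is None or pz is None:
        raise ValueError(
            f"{path}: no pixel-size metadata found; pass pixel_xy_um and "
            "z_step_um overrides")
    names = tuple(channel_names or meta_names or DEFAULT_CHANNEL_NAMES)

    if data.ndim == 3 and len(names) != 1:
        # ambiguous: could be (C, Y, X) single-plane multichannel
        if data.shape[0] == len(names):
            data = data[:, None]
        else:
            raise ValueError(
                f"{path}: found {data.shape[0]} channels/planes, expected "
                f"{len(names)} channels ({', '.join(names)})")
    if data.ndim == 2:
        data = data[None, None]
    if data.shape[0] != len(names):
        raise ValueError(
            f"{path}: found {data.shape[0]} channels, expected "
            f"{len(names)} ({', '.join(names)})")
    return ImageStack(data=data, pixel_xy_um=float(px), z_step_um=float(pz),
                      channel_names=names)


def max_project(stack: ImageStack, channel: str | int) -> Projection:
    """Per-pixel maximum-intensity projection over Z for one channel."""
    if isinstance(channel, str):
        img = stack.channel(channel)
    else:
        img = stack.data[channel]
    return Projection(data=img.max(axis=0), pixel_xy_um=stack.pixel_xy_um)
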