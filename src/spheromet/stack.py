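"""Multi-channel 3D image container and OME-TIFF I/O.

The universal input of the pipeline is a :class:`ChannelStack`: one 3D
intensity grid per named fluorescence channel (nuclear stain, marker
channels, F-actin), sharing a single ``(z, y, x)`` voxel grid with physical
voxel spacing in micrometres.  Axis order is fixed as ``(z, y, x)`` with
0-based voxel indices; the physical coordinate of a voxel centre is
``index * spacing``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import tifffile

__all__ = ["ChannelStack", "write_ome_tiff", "read_ome_tiff"]


@dataclass
class ChannelStack:
    """Named 3D fluorescence channels on a common voxel grid.

    Parameters
    ----------
    channels
        Mapping of channel name to a 3D ``(z, y, x)`` array of non-negative
        intensities.  All channels must share one shape.
    spacing
        Physical voxel spacing ``(z, y, x)`` in micrometres; strictly
        positive.
    """

    channels: Dict[str, np.ndarray]
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels do not share one grid shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError(f"channels must be 3D (z, y, x); got shape {shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None


def write_ome_tiff(stack: ChannelStack, path: str | Path) -> Path:
    """Write the stack as a single OME-TIFF with CZYX axes and physical
    voxel sizes (µm) plus channel names in the OME metadata."""
    path = Path(path)
    data = np.stack([stack.channels[name] for name in stack.channel_names], axis=0)
    sz, sy, sx = stack.spacing
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    return path


def _ome_pixel_info(ome_xml: str):
    """Extract (spacing, channel names) from OME-XML; None fields if absent."""
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pixels is None:
        return None, None
    spacing = tuple(
        float(pixels.get(f"PhysicalSize{ax}", "1.0")) for ax in ("Z", "Y", "X")
    )
    chans = pixels.findall("ome:Channel", ns) if ns else pixels.findall("Channel")
    names = [c.get("Name") or f"channel_{i}" for i, c in enumerate(chans)]
    return spacing, names


def read_ome_tiff(path: str | Path) -> ChannelStack:
    """Read an OME-TIFF written by :func:`write_ome_tiff` (or any CZYX /
    ZYX OME-TIFF with physical sizes) back into a :class:`ChannelStack`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        spacing, names = (None, None)
        if tf.ome_metadata:
            spacing, names = _ome_pixel_info(tf.ome_metadata)
    if axes == "ZYX":
        data = data[None]
    elif axes == "CZYX":
        pass
    elif axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"unsupported axis layout {axes!r} in {path}")
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    if not names or len(names) != data.shape[0]:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    return ChannelStack(
        channels={name: data[i] for i, name in enumerate(names)}, spacing=spacing
    )
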