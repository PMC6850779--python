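"""Multi-channel z-stack container and OME-TIFF I/O.

The in-memory representation is a plain ``(plane, channel, row, col)``
float array plus a mapping of channel *roles* (``cilia_marker``,
``probe``, optionally ``nuclei``) onto channel indices.  On disk stacks
are uint16 OME-TIFFs with the role names stored as OME channel names, so
a written stack round-trips its channel map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import tifffile

KNOWN_ROLES = ("cilia_marker", "probe", "nuclei")


@dataclass
class ImageStack:
    """A ``(z, channel, row, col)`` fluorescence stack.

    Parameters
    ----------
    voxels
        Nonnegative intensity array, shape ``(planes, channels, rows, cols)``.
    channel_map
        Mapping from channel role to channel index.  ``cilia_marker`` and
        ``probe`` are the roles the pipeline uses; ``nuclei`` is optional.
    pixel_size_um
        Lateral pixel size in microns (metadata only; all geometry in the
        pipeline is expressed in pixels).
    """

    voxels: np.ndarray
    channel_map: dict[str, int] = field(default_factory=dict)
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4D (z, channel, row, col), got {self.voxels.ndim}D"
            )
        if self.voxels.shape[0] < 1:
            raise ValueError("stack needs at least one plane")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be nonnegative")
        n_channels = self.voxels.shape[1]
        for role, idx in self.channel_map.items():
            if not 0 <= idx < n_channels:
                raise ValueError(
                    f"channel_map[{role!r}] = {idx} outside 0..{n_channels - 1}"
                )

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, row, col)`` sub-stack for a channel role."""
        if role not in self.channel_map:
            raise KeyError(f"channel role {role!r} is not mapped "
                           f"(available: {sorted(self.channel_map)})")
        return self.voxels[:, self.channel_map[role]]


def write_ome_tiff(stack: ImageStack, path) -> None:
    """Write a stack as uint16 OME-TIFF with roles as channel names."""
    n_channels = stack.voxels.shape[1]
    names = [f"channel_{i}" for i in range(n_channels)]
    for role, idx in stack.channel_map.items():
        names[idx] = role
    data = np.clip(np.rint(stack.voxels), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(
        path,
        data.astype(np.uint16),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZCYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_ome_tiff(path) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_ome_tiff`.

    Channel roles are recovered from OME channel names; channels whose
    name is not a known role are left unmapped.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tf.ome_metadata or ""

    # Normalize to ZCYX; single plane/channel files drop axes on disk.
    for ax in "ZCYX":
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in "ZCYX"]
    data = np.transpose(data, order)

    names = re.findall(r'<Channel[^>]*\bName="([^"]*)"', ome_xml)
    channel_map = {n: i for i, n in enumerate(names) if n in KNOWN_ROLES}

    pixel_size = 0.1
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', ome_xml)
    if m:
        pixel_size = float(m.group(1))

    return ImageStack(data.astype(np.float64), channel_map, pixel_size)
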