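"""Per-cilium probe quantification: the C/P ratio and ciliation frequency.

For each detected cilium the probe channel is measured plane by plane —
once inside the cilium mask and once inside a surrounding plasma-membrane
ring (the dilated mask minus the original).  The final value normalizes
the brightest ciliary plane against the brightest ring plane, by division
(a dimensionless ratio, the default) or subtraction; measuring each focal
plane independently avoids diluting the signal with out-of-focus planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .detection import CandidateObject
from .stacks import ImageStack

__all__ = [
    "RingParams",
    "CiliumQuant",
    "plane_means",
    "make_ring_mask",
    "cp_value",
    "quantify_stack",
    "ciliation_frequency",
    "count_nuclei",
]


@dataclass
class RingParams:
    """Plasma-membrane ring geometry: dilation radius and element shape."""

    dilation_radius_px: int = 5
    structuring_element: str = "disk"

    def __post_init__(self) -> None:
        if self.dilation_radius_px < 1:
            raise ValueError("dilation_radius_px must be >= 1")
        if self.structuring_element not in ("disk", "square"):
            raise ValueError("structuring_element must be 'disk' or 'square'")


@dataclass
class CiliumQuant:
    """Per-plane measurements and the final C/P value for one cilium."""

    cilium_label: int
    ciliary_plane_means: np.ndarray
    ring_plane_means: np.ndarray
    best_cilium_plane: int
    best_ring_plane: int
    cp_value: float
    mode: str


def plane_means(stack: ImageStack, channel: str, pixels: np.ndarray) -> np.ndarray:
    """Mean raw intensity over a pixel set, one value per focal plane."""
    pixels = np.asarray(pixels)
    if len(pixels) == 0:
        raise ValueError("empty mask")
    sub = stack.channel(channel)
    return sub[:, pixels[:, 0], pixels[:, 1]].mean(axis=1)


def _pixels_to_mask(pixels: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[pixels[:, 0], pixels[:, 1]] = True
    return mask


def make_ring_mask(
    cilia_pixels: np.ndarray,
    params: RingParams,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Ring pixel set: dilate the cilium mask, subtract the original.

    The ring is clipped at the image boundary and is disjoint from the
    cilium mask by construction.
    """
    cilia_pixels = np.asarray(cilia_pixels)
    if len(cilia_pixels) == 0:
        raise ValueError("empty cilia mask")
    if (cilia_pixels < 0).any() or (cilia_pixels[:, 0] >= image_shape[0]).any() \
            or (cilia_pixels[:, 1] >= image_shape[1]).any():
        raise ValueError("cilia mask outside image bounds")
    mask = _pixels_to_mask(cilia_pixels, image_shape)
    if params.structuring_element == "disk":
        selem = morphology.disk(params.dilation_radius_px)
    else:
        r = params.dilation_radius_px
        selem = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    dilated = ndimage.binary_dilation(mask, structure=selem)
    ring = dilated & ~mask
    if not ring.any():
        raise ValueError("ring mask is empty (object fills the image)")
    return np.argwhere(ring)


def cp_value(
    ciliary_means: np.ndarray,
    ring_means: np.ndarray,
    mode: str = "division",
) -> tuple[int, int, float]:
    """Normalize the brightest ciliary plane against the brightest ring plane.

    Returns ``(best_cilium_plane, best_ring_plane, value)``.  The two
    argmaxima are taken independently; ties resolve to the lowest plane
    index.  Division mode requires a strictly positive ring maximum.
    """
    ciliary_means = np.asarray(ciliary_means, dtype=np.float64)
    ring_means = np.asarray(ring_means, dtype=np.float64)
    if ciliary_means.size == 0 or ciliary_means.shape != ring_means.shape:
        raise ValueError("plane-mean vectors must be nonempty and equal length")
    if mode not in ("division", "subtraction"):
        raise ValueError("mode must be 'division' or 'subtraction'")
    ci = int(np.argmax(ciliary_means))
    ri = int(np.argmax(ring_means))
    if mode == "division":
        if ring_means[ri] <= 0:
            raise ZeroDivisionError("ring maximum is zero; cannot divide")
        value = float(ciliary_means[ci] / ring_means[ri])
    else:
        value = float(ciliary_means[ci] - ring_means[ri])
    return ci, ri, value


def quantify_stack(
    stack: ImageStack,
    cilia: list[CandidateObject],
    ring_params: RingParams | None = None,
    mode: str = "division",
) -> list[CiliumQuant]:
    """One :class:`CiliumQuant` per detected cilium on this stack."""
    if ring_params is None:
        ring_params = RingParams()
    quants = []
    for cilium in cilia:
        ring = make_ring_mask(cilium.pixels, ring_params, stack.image_shape)
        c_means = plane_means(stack, "probe", cilium.pixels)
        r_means = plane_means(stack, "probe", ring)
        ci, ri, value = cp_value(c_means, r_means, mode)
        quants.append(
            CiliumQuant(
                cilium_label=cilium.label,
                ciliary_plane_means=c_means,
                ring_plane_means=r_means,
                best_cilium_plane=ci,
                best_ring_plane=ri,
                cp_value=value,
                mode=mode,
            )
        )
    return quants


def ciliation_frequency(n_cilia: int, n_nuclei: int) -> float:
    """Cilia per nucleus in a field."""
    if n_nuclei <= 0:
        raise ValueError("nuclei count must be positive")
    return n_cilia / n_nuclei


def count_nuclei(stack: ImageStack, min_area_px: int = 50) -> int:
    """Count nuclei: Otsu-threshold the max projection, drop small specks.

    Touching nuclei merge into one component under 8-connectivity — a
    known limitation of threshold-and-count.
    """
    projection = stack.channel("nuclei").max(axis=0)
    if projection.max() == projection.min():
        return 0
    mask = projection > filters.threshold_otsu(projection)
    labeled = measure.label(mask, connectivity=2)
    sizes = np.bincount(labeled.ravel())[1:]
    return int((sizes >= min_area_px).sum())
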