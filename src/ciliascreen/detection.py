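"""Cilia identification on the projected marker channel.

The algorithm mirrors the classic confocal workflow: max-z project the
cilia-marker channel, median-filter the projection, threshold it into a
candidate mask, label connected components ("potential cilia"), compute
five shape/intensity features per component and promote a candidate to a
"true cilium" only if every test passes.  Cilia are thin elongated rods,
so the discriminating tests are a high eccentricity minimum (rejects
round blobs) and a solidity minimum (rejects concave debris), with area,
mean intensity and Feret length providing scale and brightness guards.

Coordinates are 0-based ``(row, col)`` on the projection; masks are
boolean arrays of the projection's shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .stacks import ImageStack

__all__ = [
    "DetectionParams",
    "CandidateObject",
    "max_z_project",
    "build_candidate_mask",
    "extract_candidates",
    "compute_features",
    "apply_shape_tests",
    "detect_cilia",
]

FEATURE_NAMES = ("area_px", "eccentricity", "solidity", "mean_intensity", "length_px")


@dataclass
class DetectionParams:
    """Tunable knobs of the detector.

    ``threshold`` separates signal from noise on the median-filtered
    projection and takes three forms: an absolute intensity (float);
    ``("quantile", q)`` with ``q`` in (0, 1); or the default
    ``("mad_sigma", k)`` — median plus ``k`` robust standard deviations
    (1.4826 x MAD) of the filtered image, a conservative background
    model that is invariant to offset and rescaling and returns an
    empty mask on blank fields.  Feature tests: ``area_px`` and
    ``length_px`` are inclusive ranges; eccentricity, solidity and mean
    intensity are minima.  ``exclude_border`` drops components touching
    the image edge (their plasma-membrane ring would be truncated).
    """

    median_radius_px: int = 2
    threshold: float | tuple[str, float] = ("mad_sigma", 10.0)
    connectivity: int = 8
    area_px: tuple[float, float] = (20.0, 500.0)
    eccentricity_min: float = 0.85
    solidity_min: float = 0.8
    intensity_min: float = 0.0
    length_px: tuple[float, float] = (10.0, 120.0)
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.median_radius_px < 0:
            raise ValueError("median_radius_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if isinstance(self.threshold, tuple):
            kind, value = self.threshold
            if kind == "quantile":
                if not 0 < value < 1:
                    raise ValueError("quantile threshold must be in (0, 1)")
            elif kind == "mad_sigma":
                if value <= 0:
                    raise ValueError("mad_sigma threshold must be positive")
            else:
                raise ValueError(
                    "threshold must be absolute, ('quantile', q) or ('mad_sigma', k)"
                )
        if not (self.area_px[0] <= self.area_px[1]):
            raise ValueError("area_px range must be ordered")
        if not (self.length_px[0] <= self.length_px[1]):
            raise ValueError("length_px range must be ordered")
        if not 0 <= self.eccentricity_min < 1:
            raise ValueError("eccentricity_min must be in [0, 1)")
        if not 0 < self.solidity_min <= 1:
            raise ValueError("solidity_min must be in (0, 1]")


@dataclass
class CandidateObject:
    """A labeled connected component of the candidate mask."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    features: dict[str, float]
    image_shape: tuple[int, int]
    passed: dict[str, bool] = field(default_factory=dict)

    @property
    def touches_border(self) -> bool:
        rows, cols = self.pixels[:, 0], self.pixels[:, 1]
        h, w = self.image_shape
        return bool(
            (rows.min() == 0) or (cols.min() == 0)
            or (rows.max() == h - 1) or (cols.max() == w - 1)
        )

    @property
    def fail_reasons(self) -> list[str]:
        return [k for k, ok in self.passed.items() if not ok and k != "overall"]


def max_z_project(stack: ImageStack, channel: str = "cilia_marker") -> np.ndarray:
    """Per-pixel maximum over planes of one channel."""
    return stack.channel(channel).max(axis=0)


def _resolve_threshold(filtered: np.ndarray,
                       threshold: float | tuple[str, float]) -> float:
    if isinstance(threshold, tuple):
        kind, value = threshold
        if kind == "quantile":
            if filtered.max() == filtered.min():
                warnings.warn(
                    "quantile threshold on a constant image yields an empty mask",
                    stacklevel=3,
                )
                return np.inf
            return float(np.quantile(filtered, value))
        med = float(np.median(filtered))
        sigma = 1.4826 * float(np.median(np.abs(filtered - med)))
        if sigma == 0:  # integer-concentrated noise can zero the MAD
            q75, q25 = np.percentile(filtered, [75, 25])
            sigma = float(q75 - q25) / 1.349
        return med + value * sigma
    return float(threshold)


def build_candidate_mask(
    image: np.ndarray,
    median_radius_px: int = 2,
    threshold: float | tuple[str, float] = ("mad_sigma", 10.0),
) -> np.ndarray:
    """Median-filter then threshold (strictly greater) the projection.

    The median window is a square of side ``2 * radius + 1`` with
    reflected borders; quantile thresholds are resolved against the
    *filtered* image, which makes the mask invariant to a global
    additive intensity offset.
    """
    image = np.asarray(image, dtype=np.float64)
    if median_radius_px > 0:
        filtered = ndimage.median_filter(
            image, size=2 * median_radius_px + 1, mode="reflect"
        )
    else:
        filtered = image
    return filtered > _resolve_threshold(filtered, threshold)


def extract_candidates(
    mask: np.ndarray,
    intensity_image: np.ndarray,
    connectivity: int = 8,
) -> list[CandidateObject]:
    """Label connected components and compute their features.

    Labels are assigned in raster-scan order of each component's first
    pixel, so repeated runs give identical labelings.
    """
    mask = np.asarray(mask, dtype=bool)
    intensity_image = np.asarray(intensity_image)
    if mask.shape != intensity_image.shape:
        raise ValueError(
            f"mask shape {mask.shape} != image shape {intensity_image.shape}"
        )
    labeled = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    candidates = []
    for lab in range(1, labeled.max() + 1):
        pixels = np.argwhere(labeled == lab)
        candidates.append(
            CandidateObject(
                label=lab,
                pixels=pixels,
                features=compute_features(pixels, intensity_image),
                image_shape=mask.shape,
            )
        )
    return candidates


def _hull_lattice_count(points: np.ndarray) -> int:
    """Number of lattice points inside-or-on the convex hull of `points`.

    Degenerate hulls (single pixels, collinear sets) contain exactly the
    member points, so the count falls back to ``len(points)`` there.
    """
    if len(points) <= 2:
        return len(points)
    try:
        hull = ConvexHull(points.astype(np.float64))
    except QhullError:  # collinear
        return len(points)
    rmin, cmin = points.min(axis=0)
    rmax, cmax = points.max(axis=0)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    grid = np.stack([rr.ravel(), cc.ravel(), np.ones(rr.size)], axis=1)
    inside = (grid @ hull.equations.T <= 1e-9).all(axis=1)
    return int(inside.sum())


def compute_features(pixels: np.ndarray, intensity_image: np.ndarray) -> dict[str, float]:
    """Five shape/intensity features of a pixel set.

    * ``area_px`` — pixel count.
    * ``eccentricity`` — from the ellipse with matching normalized second
      central moments, sqrt(1 - b^2/a^2); each pixel contributes its unit
      square (the +1/12 variance term), so single pixels give 0 and
      collinear segments stay strictly below 1.
    * ``solidity`` — area over the rasterized convex-hull area (lattice
      points inside-or-on the hull of the pixel centers); 1 for convex
      and collinear sets.
    * ``mean_intensity`` — mean of ``intensity_image`` over the pixels.
    * ``length_px`` — maximum pairwise pixel-center distance (max Feret).
    """
    pixels = np.asarray(pixels)
    if len(pixels) == 0:
        raise ValueError("empty pixel set")
    area = len(pixels)
    coords = pixels.astype(np.float64)
    centered = coords - coords.mean(axis=0)
    # second central moments with the unit-pixel-square correction
    mu20 = (centered[:, 0] ** 2).mean() + 1.0 / 12.0
    mu02 = (centered[:, 1] ** 2).mean() + 1.0 / 12.0
    mu11 = (centered[:, 0] * centered[:, 1]).mean()
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam_max = (mu20 + mu02 + common) / 2
    lam_min = (mu20 + mu02 - common) / 2
    eccentricity = float(np.sqrt(max(0.0, 1.0 - lam_min / lam_max)))

    solidity = area / _hull_lattice_count(pixels)

    mean_intensity = float(intensity_image[pixels[:, 0], pixels[:, 1]].mean())

    if area == 1:
        length = 0.0
    elif area <= 400:
        length = float(pdist(coords).max())
    else:
        try:  # hull vertices suffice for the max pairwise distance
            hull = ConvexHull(coords)
            length = float(pdist(coords[hull.vertices]).max())
        except QhullError:
            length = float(pdist(coords).max())

    return {
        "area_px": float(area),
        "eccentricity": eccentricity,
        "solidity": float(solidity),
        "mean_intensity": mean_intensity,
        "length_px": length,
    }


def apply_shape_tests(candidate: CandidateObject, params: DetectionParams) -> CandidateObject:
    """Flag each feature test; overall pass is the conjunction of all."""
    f = candidate.features
    passed = {
        "area": params.area_px[0] <= f["area_px"] <= params.area_px[1],
        "eccentricity": f["eccentricity"] >= params.eccentricity_min,
        "solidity": f["solidity"] >= params.solidity_min,
        "intensity": f["mean_intensity"] >= params.intensity_min,
        "length": params.length_px[0] <= f["length_px"] <= params.length_px[1],
    }
    if params.exclude_border:
        passed["border"] = not candidate.touches_border
    passed["overall"] = all(passed.values())
    candidate.passed = passed
    return candidate


def detect_cilia(stack: ImageStack, params: DetectionParams | None = None) -> list[CandidateObject]:
    """Full detection: project, mask, label, test; return passing objects."""
    if params is None:
        params = DetectionParams()
    projection = max_z_project(stack, "cilia_marker")
    mask = build_candidate_mask(projection, params.median_radius_px, params.threshold)
    # mean intensity is measured on the raw (unfiltered) projection
    candidates = extract_candidates(mask, projection, params.connectivity)
    return [c for c in (apply_shape_tests(c, params) for c in candidates)
            if c.passed["overall"]]
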