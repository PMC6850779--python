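"""Ground-truth synthetic data for every pipeline stage.

Three generators with known truth:

* :func:`make_cilium_stack` — confocal-like z-stacks with elongated
  capsule cilia in a marker channel over a uniform plasma-membrane sheet
  in the probe channel, plus optional round/concave distractors and
  nuclei, and Poisson or Gaussian noise;
* :func:`make_screen_counts` — sgRNA count tables from a FACS sorting
  design where gene knockouts shift a Normal reporter distribution and
  cells in a tail fraction are sorted;
* :func:`make_flow_population` — log-normal per-cell fluorescence with a
  requested median.

Every generator is deterministic for a fixed seed and returns its truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .stacks import ImageStack

__all__ = [
    "CiliumTruth",
    "ScreenTruth",
    "make_cilium_stack",
    "make_screen_counts",
    "make_flow_population",
    "default_distractors",
]


# --------------------------------------------------------------------------
# imaging
# --------------------------------------------------------------------------

@dataclass
class CiliumTruth:
    """Geometry and intensities of one planted cilium.

    The cilium is a 2D capsule (rectangle with semicircular caps) of
    total extent ``length_px`` and width ``width_px``, rotated by
    ``orientation_deg``, rendered across a small z-extent centred on
    ``z_center``.  ``probe_intensity_membrane`` may be left ``None``; the
    generator fills it with the stack-wide membrane level.
    """

    center: tuple[float, float]
    orientation_deg: float = 0.0
    length_px: float = 25.0
    width_px: float = 4.0
    z_center: int = 2
    marker_intensity: float = 500.0
    probe_intensity_cilium: float = 200.0
    probe_intensity_membrane: float | None = None

    def __post_init__(self) -> None:
        if not self.length_px > self.width_px >= 1:
            raise ValueError("need length_px > width_px >= 1")
        if self.marker_intensity < 0 or self.probe_intensity_cilium < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def true_cp_ratio(self) -> float:
        if not self.probe_intensity_membrane:
            raise ValueError("membrane intensity not set (render the stack first)")
        return self.probe_intensity_cilium / self.probe_intensity_membrane

    def footprint(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean capsule mask on the projection grid."""
        rows, cols = image_shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        theta = np.deg2rad(self.orientation_deg)
        direction = np.array([np.sin(theta), np.cos(theta)])
        half = (self.length_px - self.width_px) / 2.0
        p0 = np.asarray(self.center) - half * direction
        p1 = np.asarray(self.center) + half * direction
        # distance from each pixel center to the segment p0-p1
        d = p1 - p0
        pts = np.stack([rr - p0[0], cc - p0[1]], axis=-1)
        t = np.clip((pts @ d) / (d @ d), 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist = np.hypot(rr - closest[..., 0], cc - closest[..., 1])
        return dist <= self.width_px / 2.0


def default_distractors(image_shape: tuple[int, int]) -> list[dict]:
    """One round disk and one open C-shape, placed in opposite corners.

    The disk fails the eccentricity test, the C fails solidity; both are
    bright enough to enter the candidate mask.
    """
    rows, cols = image_shape
    return [
        {"kind": "disk", "center": (rows * 0.15, cols * 0.15), "radius": 5},
        {"kind": "c_shape", "center": (rows * 0.85, cols * 0.85),
         "outer_radius": 8, "inner_radius": 4},
    ]


def _distractor_mask(spec: dict, image_shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    r0, c0 = spec["center"]
    dist = np.hypot(rr - r0, cc - c0)
    if spec["kind"] == "disk":
        return dist <= spec["radius"]
    if spec["kind"] == "c_shape":
        ring = (dist <= spec["outer_radius"]) & (dist >= spec["inner_radius"])
        angle = np.arctan2(rr - r0, cc - c0)
        return ring & (np.abs(angle) > np.pi / 4)  # open a 90-degree mouth
    raise ValueError(f"unknown distractor kind {spec['kind']!r}")


def make_cilium_stack(
    truths: list[CiliumTruth],
    shape: tuple[int, int, int] = (5, 256, 256),
    background: float = 5.0,
    membrane_level: float = 100.0,
    distractors: str | list[dict] | None = None,
    noise_model: str | tuple[str, float] = "none",
    seed: int = 0,
    z_extent: int = 1,
    marker_membrane_level: float = 0.0,
    nuclei_centers: list[tuple[float, float]] | None = None,
    nuclei_radius_px: float = 10.0,
    nuclei_intensity: float = 400.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render cilia + membrane into a stack; return it with a truth table.

    Channel 0 is the cilia marker (background plus bright capsules over
    planes ``z_center ± z_extent``; distractors drawn here too), channel
    1 the lipid probe (a uniform membrane sheet with each capsule
    footprint overwritten by its ciliary probe level, identical in every
    plane so the plane-max normalization is exact), and, if
    ``nuclei_centers`` is given, channel 2 holds nuclear disks.

    ``noise_model`` is ``"none"``, ``"poisson"`` (rates = clean image) or
    ``("gaussian", sd)`` (additive, clipped at zero).
    """
    if background < 0 or membrane_level < 0:
        raise ValueError("intensities must be nonnegative")
    n_z, rows, cols = shape
    n_channels = 3 if nuclei_centers is not None else 2
    voxels = np.zeros((n_z, n_channels, rows, cols), dtype=np.float64)
    voxels[:, 0] = background
    voxels[:, 1] = membrane_level

    records = []
    for i, truth in enumerate(truths):
        if truth.probe_intensity_membrane is None:
            truth.probe_intensity_membrane = membrane_level
        foot = truth.footprint((rows, cols))
        # the capsule analytic footprint must lie fully inside the frame
        theta = np.deg2rad(truth.orientation_deg)
        half = truth.length_px / 2.0
        extent = half * np.abs([np.sin(theta), np.cos(theta)]) + truth.width_px / 2.0
        r0, c0 = truth.center
        if (r0 - extent[0] < 0 or r0 + extent[0] > rows - 1
                or c0 - extent[1] < 0 or c0 + extent[1] > cols - 1):
            raise ValueError(f"cilium {i} footprint leaves the image")
        if not 0 <= truth.z_center < n_z:
            raise ValueError(f"cilium {i} z_center outside the stack")
        z_lo = max(0, truth.z_center - z_extent)
        z_hi = min(n_z, truth.z_center + z_extent + 1)
        voxels[z_lo:z_hi, 0][:, foot] = background + truth.marker_intensity
        voxels[:, 1][:, foot] = truth.probe_intensity_cilium
        records.append(
            {
                "cilium_id": i,
                "row": truth.center[0],
                "col": truth.center[1],
                "orientation_deg": truth.orientation_deg,
                "length_px": truth.length_px,
                "width_px": truth.width_px,
                "z_center": truth.z_center,
                "marker_intensity": truth.marker_intensity,
                "probe_intensity_cilium": truth.probe_intensity_cilium,
                "probe_intensity_membrane": truth.probe_intensity_membrane,
                "true_cp_ratio": truth.true_cp_ratio,
            }
        )

    if distractors == "default":
        distractors = default_distractors((rows, cols))
    for spec in distractors or []:
        dmask = _distractor_mask(spec, (rows, cols))
        level = spec.get("marker_intensity", 500.0)
        voxels[n_z // 2, 0][dmask] = background + level

    if nuclei_centers is not None:
        rr, cc = np.mgrid[0:rows, 0:cols]
        for r0, c0 in nuclei_centers:
            nmask = np.hypot(rr - r0, cc - c0) <= nuclei_radius_px
            voxels[:, 2][:, nmask] = nuclei_intensity

    if marker_membrane_level:
        voxels[:, 0] += marker_membrane_level

    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        voxels = rng.poisson(voxels).astype(np.float64)
    elif isinstance(noise_model, tuple) and noise_model[0] == "gaussian":
        voxels = np.clip(voxels + rng.normal(0.0, noise_model[1], voxels.shape), 0, None)
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")

    channel_map = {"cilia_marker": 0, "probe": 1}
    if nuclei_centers is not None:
        channel_map["nuclei"] = 2
    stack = ImageStack(voxels, channel_map)
    return stack, pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# screen
# --------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """One gene's ground truth in a simulated sorting screen.

    ``effect`` shifts the knockout cells' reporter distribution in SD
    units; 0 marks null genes.  ``direction`` records the shift sign
    ("lowers_reporter" / "raises_reporter" / "none"); regulator semantics
    follow from the screen design at analysis time.
    """

    gene: str
    n_guides: int = 4
    effect: float = 0.0
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        if self.n_guides < 1:
            raise ValueError("n_guides must be >= 1")
        if self.effect == 0:
            self.direction = "none"
        else:
            self.direction = "lowers_reporter" if self.effect < 0 else "raises_reporter"


def make_screen_counts(
    truths: list[ScreenTruth],
    depth_unsorted: int = 2_000_000,
    depth_sorted: int = 2_000_000,
    select: tuple[str, float] = ("bottom_fraction", 0.10),
    reporter_sd: float = 1.0,
    seed: int = 0,
    n_nontargeting: int = 0,
    overdispersion: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate unsorted/sorted sgRNA counts for a tail-sorting screen.

    Each guide's cells carry a reporter ~ Normal(effect, 1) (in units of
    ``reporter_sd``); the sorter keeps the global bottom (or top)
    ``fraction`` of the pooled reporter distribution, so a guide's
    selection probability is its tail mass beyond the pool-wide cutoff.
    Unsorted counts are multinomial at uniform baseline frequencies;
    sorted counts are multinomial with probabilities proportional to
    baseline x selection probability.  With ``overdispersion`` set, each
    guide's baseline is jittered by a Gamma factor of that shape
    (negative-binomial-like extra variance).

    Non-targeting guides (effect 0) carry the reserved pseudo-gene label
    ``non-targeting``.
    """
    mode, fraction = select
    if mode not in ("bottom_fraction", "top_fraction"):
        raise ValueError("select mode must be bottom_fraction or top_fraction")
    if not 0 < fraction < 1:
        raise ValueError("selection fraction must be in (0, 1)")
    if depth_unsorted <= 0 or depth_sorted <= 0:
        raise ValueError("sequencing depths must be positive")

    from .screen import NONTARGETING_GENE  # local to avoid a cycle

    guides, genes, effects = [], [], []
    for t in truths:
        for k in range(t.n_guides):
            guides.append(f"{t.gene}_sg{k + 1}")
            genes.append(t.gene)
            effects.append(t.effect)  # SD units: reporter ~ N(effect, 1)
    for k in range(n_nontargeting):
        guides.append(f"NTC_{k + 1}")
        genes.append(NONTARGETING_GENE)
        effects.append(0.0)
    effects = np.asarray(effects, dtype=np.float64)
    n_guides = len(guides)

    rng = np.random.default_rng(seed)
    baseline = np.full(n_guides, 1.0 / n_guides)
    if overdispersion is not None:
        baseline *= rng.gamma(overdispersion, 1.0 / overdispersion, n_guides)
        baseline /= baseline.sum()

    # pool-wide sorting cutoff: mixture tail mass equals the sorted fraction
    def pooled_cdf(c: float) -> float:
        return float(np.sum(baseline * norm.cdf(c - effects)))

    lo = effects.min() - 10.0
    hi = effects.max() + 10.0
    if mode == "bottom_fraction":
        cutoff = brentq(lambda c: pooled_cdf(c) - fraction, lo, hi)
        p_select = norm.cdf(cutoff - effects)
    else:
        cutoff = brentq(lambda c: (1.0 - pooled_cdf(c)) - fraction, lo, hi)
        p_select = norm.sf(cutoff - effects)

    count_unsorted = rng.multinomial(depth_unsorted, baseline)
    p_sorted = baseline * p_select
    count_sorted = rng.multinomial(depth_sorted, p_sorted / p_sorted.sum())

    table = pd.DataFrame(
        {
            "guide_id": guides,
            "gene": genes,
            "count_unsorted": count_unsorted,
            "count_sorted": count_sorted,
        }
    )
    truth_table = pd.DataFrame(
        [
            {"gene": t.gene, "n_guides": t.n_guides, "effect": t.effect,
             "direction": t.direction}
            for t in truths
        ]
        + (
            [{"gene": NONTARGETING_GENE, "n_guides": n_nontargeting,
              "effect": 0.0, "direction": "none"}]
            if n_nontargeting else []
        )
    )
    return table, truth_table


# --------------------------------------------------------------------------
# flow cytometry
# --------------------------------------------------------------------------

def make_flow_population(
    median: float,
    log_sd: float = 0.5,
    n: int = 4000,
    seed: int = 0,
    label: str = "",
):
    """Log-normal per-cell fluorescence with the requested median.

    The natural-log SD controls spread; ``log_sd=0`` degenerates to a
    constant population at the median.
    """
    from .stats import FlowPopulation  # local to avoid a cycle

    if median <= 0:
        raise ValueError("median must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(np.log(median), log_sd, n))
    return FlowPopulation(values=values, label=label)
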