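"""Collagen fibril orientation analysis.

Fibril alignment is quantified from confocal-reflection-style images by
the orientation of pixel intensity gradients in square subregions: the
structure tensor (Gaussian-smoothed outer products of the intensity
gradient) is averaged per subregion, its dominant eigenvector gives the
local gradient orientation, and the fibre angle is that orientation
rotated by 90 degrees. Fibres are orientations, not directions, so all
circular statistics work on doubled angles (axial data): the alignment
index R is the resultant length of the doubled angles, the circular mean
is halved back, and uniformity is assessed with the Rayleigh test on
doubled angles.

Angle convention: degrees in [0, 180), 0 along +x (image columns),
counter-clockwise positive with y up (toward decreasing row index).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pingouin as pg
from scipy import ndimage


@dataclass
class OrientationSample:
    """Per-subregion fibre orientations.

    ``centers`` are subregion centres in (row, col) pixels; one axial
    angle (degrees in [0, 180)) and one coherence value in [0, 1] per
    retained subregion.
    """

    centers: np.ndarray
    angles: np.ndarray
    coherence: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float) % 180.0
        self.coherence = np.asarray(self.coherence, float)
        if len(self.angles) != len(self.coherence) or \
                len(self.angles) != len(self.centers):
            raise ValueError("one angle and coherence per subregion required")

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class OrientationHistogram:
    """Counts over [0, 180) bins; total equals the sample size."""

    bin_edges: np.ndarray
    counts: np.ndarray
    reference_angle: float | None = None


@dataclass
class AlignmentStats:
    """Axial summary statistics of an orientation sample.

    ``mean_angle``: axial circular mean in degrees, [0, 180).
    ``R``: alignment index, resultant length of doubled angles in [0, 1]
    (0 in the isotropic limit, 1 for perfect alignment).
    ``rayleigh_p``: Rayleigh uniformity test on doubled angles.
    ``delta_median``/``delta_angles``: axial deviation from the reference
    angle folded into [0, 90] degrees (0 = fibres aligned with the
    reference, e.g. an extending branch).
    """

    n: int
    mean_angle: float
    R: float
    rayleigh_p: float
    reference_angle: float | None = None
    delta_median: float | None = None
    delta_angles: np.ndarray | None = None


def subregion_orientations(
    image: np.ndarray,
    subregion_size_px: int = 24,
    coherence_min: float = 0.2,
    grad_sigma: float = 2.0,
    window_px: int | None = None,
) -> OrientationSample:
    """Dominant fibre orientation per square subregion of ``image``.

    The image is divided into a grid of ``subregion_size_px`` squares
    (edges that do not fill a full subregion are discarded). Within each
    square the structure tensor is accumulated over a centred analysis
    window of ``window_px`` (default: half the subregion): the guard
    margin around the window keeps a single fibril (and the gradient
    kernel's support) from contributing to two neighbouring subregions,
    so the per-subregion angles behave as independent samples — the
    assumption behind the Rayleigh uniformity test applied downstream.

    Gradients are Gaussian derivatives with scale ``grad_sigma``;
    subregions whose structure-tensor coherence
    (lambda1 - lambda2)/(lambda1 + lambda2) falls below ``coherence_min``
    are dropped. A flat image yields an empty sample with a warning.
    """
    if subregion_size_px < 8:
        raise ValueError("subregion size must be >= 8 px")
    img = np.asarray(image, float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValueError("image must be 2D and at least 64x64 px")
    s = subregion_size_px
    window = window_px if window_px is not None else max(s // 2, 4)
    if not (0 < window <= s):
        raise ValueError("window_px must lie in (0, subregion_size_px]")
    margin = (s - window) // 2
    # y-up convention: gy is the negated row derivative
    gx = ndimage.gaussian_filter(img, grad_sigma, order=(0, 1))
    gy = -ndimage.gaussian_filter(img, grad_sigma, order=(1, 0))

    nr, nc = img.shape[0] // s, img.shape[1] // s

    def block_sum(a: np.ndarray) -> np.ndarray:
        blocks = a[:nr * s, :nc * s].reshape(nr, s, nc, s)
        return blocks[:, margin:margin + window,
                      :, margin:margin + window].sum(axis=(1, 3))

    jxx = block_sum(gx * gx)
    jxy = block_sum(gx * gy)
    jyy = block_sum(gy * gy)
    energy = jxx + jyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coher = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2) / energy
    coher = np.where(energy > 0, coher, 0.0)
    # dominant gradient orientation; fibre axis is orthogonal to it
    grad_angle = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    fiber_angle = (grad_angle + 90.0) % 180.0

    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    centers = np.column_stack([
        (rows.ravel() + 0.5) * s, (cols.ravel() + 0.5) * s])
    keep = (coher.ravel() >= coherence_min) & (energy.ravel() > 0)
    if not np.any(keep):
        warnings.warn("no subregion passed the coherence filter (flat image?)")
    return OrientationSample(centers=centers[keep],
                             angles=fiber_angle.ravel()[keep],
                             coherence=coher.ravel()[keep])


def orientation_histogram(
    sample: OrientationSample | np.ndarray,
    n_bins: int = 18,
    reference_angle: float | None = None,
) -> OrientationHistogram:
    """Histogram of axial angles over [0, 180); counts preserve the total."""
    angles = sample.angles if isinstance(sample, OrientationSample) else \
        np.asarray(sample, float) % 180.0
    if len(angles) == 0:
        raise ValueError("empty orientation sample")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return OrientationHistogram(bin_edges=edges, counts=counts,
                                reference_angle=reference_angle)


def axial_resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """(mean_angle, R) of axial data via the doubled-angle trick."""
    doubled = np.radians(2.0 * np.asarray(angles_deg, float))
    z = np.exp(1j * doubled).mean()
    mean_angle = (math.degrees(np.angle(z)) / 2.0) % 180.0
    return mean_angle, float(abs(z))


def rayleigh_test_axial(angles_deg: np.ndarray) -> float:
    """Rayleigh uniformity p-value on doubled axial angles."""
    doubled = np.radians(2.0 * np.asarray(angles_deg, float))
    _, p = pg.circ_rayleigh(doubled)
    return float(p)


def alignment_stats(
    sample: OrientationSample | np.ndarray,
    reference_angle: float | None = None,
) -> AlignmentStats:
    """Axial circular mean, alignment index R, Rayleigh test and, when a
    reference angle (e.g. the migration direction) is given, the axial
    angle difference folded into [0, 90] degrees with its median."""
    angles = sample.angles if isinstance(sample, OrientationSample) else \
        np.asarray(sample, float) % 180.0
    if len(angles) == 0:
        raise ValueError("empty orientation sample")
    mean_angle, R = axial_resultant(angles)
    p = rayleigh_test_axial(angles)
    delta = delta_med = None
    if reference_angle is not None:
        d = np.abs(angles - reference_angle) % 180.0
        delta = np.minimum(d, 180.0 - d)
        delta_med = float(np.median(delta))
    return AlignmentStats(n=len(angles), mean_angle=mean_angle, R=R,
                          rayleigh_p=p, reference_angle=reference_angle,
                          delta_median=delta_med, delta_angles=delta)


def compare_regions(
    near_sample: OrientationSample | np.ndarray,
    far_sample: OrientationSample | np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation test on the difference in alignment index R between two
    image regions (e.g. matrix adjacent to the invasive front vs far from
    the tissue). Labels are shuffled ``n_permutations`` times; the p-value
    is two-sided with the +1 correction."""
    a_near = near_sample.angles if isinstance(near_sample, OrientationSample) \
        else np.asarray(near_sample, float)
    a_far = far_sample.angles if isinstance(far_sample, OrientationSample) \
        else np.asarray(far_sample, float)
    if len(a_near) == 0 or len(a_far) == 0:
        raise ValueError("both samples must be non-empty")
    _, r_near = axial_resultant(a_near)
    _, r_far = axial_resultant(a_far)
    observed = r_near - r_far

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a_near, a_far])
    n1 = len(a_near)
    doubled = np.exp(1j * np.radians(2.0 * pooled))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        r1 = abs(doubled[perm[:n1]].mean())
        r2 = abs(doubled[perm[n1:]].mean())
        if abs(r1 - r2) >= abs(observed) - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {"R_near": r_near, "R_far": r_far, "difference": observed,
            "p_value": p, "n_permutations": n_permutations}
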