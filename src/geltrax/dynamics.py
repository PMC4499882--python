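"""Cohort shape dynamics, matrix-coupling statistics and directionality.

Covers the time-domain and population-level quantifications: cohort
length and projected area from binary masks, the lagged sample
cross-covariance / cross-correlation between cohort shape series and
bead displacement series, near/far bead classification at the 50-um
distance threshold, per-pixel occupancy frequency maps across replicate
tissues, invasion-angle rose statistics, and nuclear/cytoplasmic signal
ratios.

Angle convention for invasion directions: degrees in [0, 360), 0 = due
east (+x / increasing column), counter-clockwise positive with y up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import ndimage, stats
from skimage import graph as skgraph
from skimage import measure

NEAR_FAR_THRESHOLD_UM = 50.0  # "adjacent to (<50 um)" vs "far from (>50 um)"


@dataclass
class CohortTimeSeries:
    """Cohort length L(t) (um) and projected area A(t) (um^2) over time (h)."""

    times: np.ndarray
    length: np.ndarray
    area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.length = np.asarray(self.length, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.length < 0):
            raise ValueError("lengths must be non-negative")
        if self.area is not None:
            self.area = np.asarray(self.area, float)
            if np.any(self.area < 0):
                raise ValueError("areas must be non-negative")

    def normalized_length(self) -> np.ndarray:
        """Length divided by its initial value."""
        return self.length / self.length[0]


@dataclass
class BeadSeries:
    """Scalar bead displacement magnitude over time with a near/far class."""

    bead_id: str
    times: np.ndarray
    displacement: np.ndarray
    distance_class: str  # "near" (< 50 um) or "far" (> 50 um)


@dataclass
class CrossCorrelation:
    """Lagged sample cross-covariance and cross-correlation coefficient.

    c_xy(k) = (1/n) sum_t (x_t - xbar)(y_{t+k} - ybar) for |k| <= max_lag
    (the biased 1/n estimator; ``estimator="unbiased"`` divides by n - |k|
    instead). r_xy(k) = c_xy(k) / (s_x s_y) with the sample standard
    deviations computed once from the full series. A positive peak lag
    means y trails x.
    """

    lags: np.ndarray
    c: np.ndarray
    r: np.ndarray
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float

    @property
    def peak_lag(self) -> int:
        """Lag of the maximum (signed) r; coupling is assumed positive —
        bead displacements grow when the cohort extends."""
        return int(self.lags[np.argmax(self.r)])

    @property
    def peak_r(self) -> float:
        """Maximum (signed) r over the lag window."""
        return float(np.max(self.r))


def cross_covariance(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int,
    estimator: str = "biased",
    sd_ddof: int = 1,
) -> CrossCorrelation:
    """Sample cross-covariance / cross-correlation of two equal-length series.

    With the default conventions (1/n covariance, ddof-1 standard
    deviations) the zero-lag autocorrelation of a series with itself is
    (n-1)/n; choosing ``sd_ddof=0`` makes it exactly 1.

    Raises on unequal lengths, series shorter than 2*max_lag + 2, or a
    zero-variance input (r undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    n = len(x)
    if n < 2 * max_lag + 2:
        raise ValueError("series too short for the requested max_lag")
    if estimator not in ("biased", "unbiased"):
        raise ValueError("estimator must be 'biased' or 'unbiased'")
    sx = float(np.std(x, ddof=sd_ddof))
    sy = float(np.std(y, ddof=sd_ddof))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance series: cross-correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            prod = xc[: n - k] * yc[k:]
        else:
            prod = xc[-k:] * yc[: n + k]
        denom = n if estimator == "biased" else n - abs(k)
        c[i] = prod.sum() / denom
    r = c / (sx * sy)
    return CrossCorrelation(lags=lags, c=c, r=r,
                            mean_x=float(x.mean()), mean_y=float(y.mean()),
                            sd_x=sx, sd_y=sy)


# --------------------------------------------------------------------------
# Morphometry
# --------------------------------------------------------------------------

def cohort_length(
    mask: np.ndarray,
    body_edge: int,
    pixel_size: float = 1.0,
    method: str = "euclidean",
) -> float:
    """Length of the migrating cohort, edge of the original tissue to tip.

    ``body_edge`` is the column index of the first pixel column beyond the
    tissue body; cohort pixels are mask pixels in columns >= body_edge.
    ``method="euclidean"`` measures straight-line extent past the edge;
    ``"geodesic"`` measures along the cohort (shortest path within the
    mask from the edge column), which differs for bent cohorts. Returns 0
    with a warning when no cohort extends past the edge.
    """
    m = np.asarray(mask, bool)
    cohort = m[:, body_edge:]
    if not cohort.any():
        warnings.warn("no cohort pixels beyond the tissue edge")
        return 0.0
    if method == "euclidean":
        cols = np.nonzero(cohort.any(axis=0))[0]
        return float((cols.max() + 1) * pixel_size)
    if method == "geodesic":
        costs = np.where(cohort, 1.0, np.inf)
        starts = [(r, 0) for r in np.nonzero(cohort[:, 0])[0]]
        if not starts:
            warnings.warn("cohort not connected to the tissue edge")
            return 0.0
        mcp = skgraph.MCP_Geometric(costs)
        dist, _ = mcp.find_costs(starts)
        finite = dist[np.isfinite(dist)]
        return float((finite.max() + 1) * pixel_size)
    raise ValueError("method must be 'euclidean' or 'geodesic'")


def projected_area(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Projected cohort/tissue area: pixel count times pixel_size^2 (um^2)."""
    return float(np.count_nonzero(np.asarray(mask, bool)) * pixel_size**2)


def series_from_masks(
    masks: np.ndarray,
    times: np.ndarray,
    body_edge: int,
    pixel_size: float = 1.0,
) -> CohortTimeSeries:
    """Cohort length/area time series extracted frame-by-frame."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        L = [cohort_length(m, body_edge, pixel_size) for m in masks]
    A = [projected_area(m, pixel_size) for m in masks]
    return CohortTimeSeries(times=np.asarray(times, float),
                            length=np.asarray(L), area=np.asarray(A))


# --------------------------------------------------------------------------
# Near / far classification and correlation report
# --------------------------------------------------------------------------

def classify_beads(
    positions: np.ndarray,
    cohort: np.ndarray,
    threshold: float = NEAR_FAR_THRESHOLD_UM,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Label beads "near" (< threshold) or "far" by minimum distance to the
    cohort.

    ``cohort`` is either a binary mask (2D; positions then are (row, col)
    pixels scaled by ``pixel_size``) or an (m, d) array of cohort points in
    um matching the dimensionality of ``positions``. Distances exactly at
    the threshold are classed "far" (the classes are strict inequalities).
    """
    pos = np.atleast_2d(np.asarray(positions, float))
    cohort = np.asarray(cohort)
    if cohort.ndim == 2 and cohort.dtype == bool:
        # distance transform of the complement gives distance to the mask
        dist_px = ndimage.distance_transform_edt(~cohort)
        idx = np.clip(np.round(pos).astype(int), 0,
                      np.array(cohort.shape) - 1)
        d = dist_px[idx[:, 0], idx[:, 1]] * pixel_size
    else:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(np.atleast_2d(cohort)).query(pos)
    return np.where(d < threshold, "near", "far")


def near_far_correlation_report(
    cohort_series: CohortTimeSeries,
    bead_series_set: list[BeadSeries],
    max_lag: int = 5,
    estimator: str = "biased",
    detrend: str = "difference",
) -> dict:
    """Peak cross-correlation of each bead with the cohort length series,
    summarised per distance class with a Welch two-sample test.

    By default both series are first-differenced before correlating
    (``detrend="none"`` disables this): the comparison targets the
    temporal *change* in cohort length, and a shared monotone growth trend
    would otherwise dominate the lagged covariance and mask the lag of the
    coupled fluctuations.

    Requires at least 3 beads in each class. Flags degenerate class
    variance (all beads identical) instead of failing the t-test.
    """
    if detrend not in ("difference", "none"):
        raise ValueError("detrend must be 'difference' or 'none'")

    def prep(v: np.ndarray) -> np.ndarray:
        return np.diff(v) if detrend == "difference" else v

    x = prep(cohort_series.length)
    per_bead = []
    for bs in bead_series_set:
        cc = cross_covariance(x, prep(bs.displacement),
                              max_lag, estimator=estimator)
        per_bead.append({"bead_id": bs.bead_id, "class": bs.distance_class,
                         "peak_r": cc.peak_r, "peak_lag": cc.peak_lag})
    df = pd.DataFrame(per_bead)
    for cls in ("near", "far"):
        if (df["class"] == cls).sum() < 3:
            raise ValueError(f"need >= 3 beads in class {cls!r}")
    near_r = df.loc[df["class"] == "near", "peak_r"].to_numpy()
    far_r = df.loc[df["class"] == "far", "peak_r"].to_numpy()
    degenerate = bool(np.var(near_r) == 0 or np.var(far_r) == 0)
    if degenerate:
        p = t = float("nan")
    else:
        t, p = stats.ttest_ind(near_r, far_r, equal_var=False)
    return {"per_bead": df,
            "near_mean_r": float(near_r.mean()),
            "far_mean_r": float(far_r.mean()),
            "near_n": int(len(near_r)), "far_n": int(len(far_r)),
            "welch_t": float(t), "p_value": float(p),
            "zero_variance": degenerate}


# --------------------------------------------------------------------------
# Population-level directionality
# --------------------------------------------------------------------------

@dataclass
class FrequencyMap:
    """Per-pixel occupancy frequency across registered binary masks."""

    frequency: np.ndarray
    n_tissues: int


def frequency_map(mask_stack: np.ndarray) -> FrequencyMap:
    """Pixel frequency map of a stack of registered binarised tissues.

    frequency = (number of masks in which the pixel is set) / n_tissues,
    exactly; pixels of the shared base geometry are 1 by construction.
    """
    stack = np.asarray(mask_stack)
    if stack.ndim != 3:
        raise ValueError("mask stack must be (n_tissues, H, W)")
    n = stack.shape[0]
    counts = np.sum(stack.astype(bool), axis=0)
    return FrequencyMap(frequency=counts / n, n_tissues=n)


def invasion_angles(
    mask_stack: np.ndarray,
    tissue_centroid: tuple[float, float] | None = None,
    base_mask: np.ndarray | None = None,
    min_size_px: int = 5,
) -> dict:
    """Invasion direction of each cohort across a stack of tissue masks.

    Cohorts are connected components outside the shared base geometry
    (default: the intersection of all masks). Each cohort contributes one
    angle: the direction from the tissue centroid to the cohort pixel
    farthest from it, in degrees [0, 360), 0 = due east, CCW with y up.
    These are directions, not axes, so plain (non-axial) circular
    statistics apply; uniformity is assessed with the Rayleigh test.

    Returns a dict with ``angles``, per-mask angle lists, the circular
    mean, resultant length ``R`` and ``rayleigh_p``. Empty result (no
    cohorts) warns and reports NaN statistics.
    """
    stack = np.asarray(mask_stack).astype(bool)
    if base_mask is None:
        base_mask = np.logical_and.reduce(stack, axis=0)
    base = np.asarray(base_mask, bool)
    if tissue_centroid is None:
        rows, cols = np.nonzero(base)
        if len(rows) == 0:
            raise ValueError("base mask is empty")
        tissue_centroid = (float(rows.mean()), float(cols.mean()))
    r0, c0 = tissue_centroid

    angles: list[float] = []
    per_mask: list[list[float]] = []
    for m in stack:
        outside = m & ~base
        labels = measure.label(outside, connectivity=2)
        mask_angles = []
        for region in measure.regionprops(labels):
            if region.area < min_size_px:
                continue
            coords = region.coords  # (k, 2) row, col
            d2 = (coords[:, 0] - r0) ** 2 + (coords[:, 1] - c0) ** 2
            tip = coords[np.argmax(d2)]
            ang = math.degrees(math.atan2(-(tip[0] - r0), tip[1] - c0)) % 360.0
            mask_angles.append(ang)
        per_mask.append(mask_angles)
        angles.extend(mask_angles)

    if not angles:
        warnings.warn("no cohorts found outside the base geometry")
        return {"angles": np.array([]), "per_mask": per_mask,
                "circular_mean": float("nan"), "R": float("nan"),
                "rayleigh_p": float("nan")}
    rad = np.radians(angles)
    z = np.exp(1j * rad).mean()
    _, p = pg.circ_rayleigh(rad)
    return {"angles": np.asarray(angles), "per_mask": per_mask,
            "circular_mean": math.degrees(np.angle(z)) % 360.0,
            "R": float(abs(z)), "rayleigh_p": float(p)}


def nuclear_cytoplasmic_ratio(
    signal_image: np.ndarray,
    nuclear_mask: np.ndarray,
    cell_mask: np.ndarray,
    background: float | str = "outside",
) -> float:
    """Mean nuclear over mean cytoplasmic signal intensity.

    The cytoplasmic compartment is cell_mask minus nuclear_mask. The
    background offset (default: median intensity outside the cell mask,
    or an explicit float) is subtracted before forming the ratio.
    """
    sig = np.asarray(signal_image, float)
    nuc = np.asarray(nuclear_mask, bool)
    cell = np.asarray(cell_mask, bool)
    if not np.all(cell[nuc]):
        raise ValueError("nuclear mask must lie within the cell mask")
    cyto = cell & ~nuc
    if not nuc.any() or not cyto.any():
        raise ValueError("empty nuclear or cytoplasmic compartment")
    if background == "outside":
        outside = ~cell
        bg = float(np.median(sig[outside])) if outside.any() else 0.0
    else:
        bg = float(background)
    return float((sig[nuc].mean() - bg) / (sig[cyto].mean() - bg))
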