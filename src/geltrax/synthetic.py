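"""Synthetic ground-truth generators for the full analysis pipeline.

Every input the pipeline consumes can be generated here with known ground
truth: bead clouds deformed by closed-form elastic fields (pressurised
spherical cavity, Kelvin point force), confocal-reflection-style fibril
images with controlled axial orientation concentration, cohort
length/area time series coupled to nearby bead displacements with a
controllable lag, and stacks of binarised tissue masks with controlled
invasion-angle distributions.

Sign convention (used everywhere): a cavity pressure ``p > 0`` denotes a
tensile, inward pull — the matrix is displaced toward the tissue, matching
the inward-directed bead motion observed around migrating cohorts.

Units: micrometres, hours, Pa. Point forces are carried in Pa*um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .materials import ElasticMaterial, lame_from_engineering

# Bead seeding density used in the experiments being emulated:
# ~4e8 beads/ml = 4e-4 beads/um^3.
DEFAULT_BEAD_DENSITY = 4e-4
# Sub-pixel tracking accuracy for 1-um beads.
DEFAULT_TRACKING_NOISE = 0.1


# --------------------------------------------------------------------------
# Domains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxDomain:
    """Axis-aligned box, corners ``lo`` and ``hi`` in um."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @property
    def volume(self) -> float:
        d = np.asarray(self.hi, float) - np.asarray(self.lo, float)
        return float(np.prod(d))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return rng.uniform(lo, hi, size=(n, 3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)


@dataclass(frozen=True)
class CylinderDomain:
    """Right circular cylinder, axis along z, centred at ``center``."""

    height: float
    diameter: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def volume(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2 * self.height

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = (self.diameter / 2.0) * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        z = rng.uniform(-self.height / 2.0, self.height / 2.0, size=n)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        return pts + np.asarray(self.center, float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - np.asarray(self.center, float)
        radial = np.hypot(p[:, 0], p[:, 1]) <= self.diameter / 2.0
        axial = np.abs(p[:, 2]) <= self.height / 2.0
        return radial & axial


Domain = BoxDomain | CylinderDomain


# --------------------------------------------------------------------------
# Loadings and scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CavityPressure:
    """Uniform tensile pressure ``p`` (Pa) on a spherical cavity of
    radius ``a`` (um) centred at ``center``; p > 0 pulls the matrix inward."""

    a: float
    p: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PointForce:
    """Concentrated force ``F`` (Pa*um^2) applied at ``location`` (um)."""

    F: tuple[float, float, float]
    location: tuple[float, float, float]


@dataclass(frozen=True)
class SyntheticScene:
    """A bead-seeded gel around a loaded tissue surface.

    The scene couples a material, a loading (cavity pressure or point
    force), a sampling domain for the beads, a bead density and a tracking
    noise level. All randomness flows from ``seed``.
    """

    material: ElasticMaterial
    loading: CavityPressure | PointForce
    domain: Domain
    bead_density: float = DEFAULT_BEAD_DENSITY
    noise_sigma: float = DEFAULT_TRACKING_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_density <= 0:
            raise ValueError("bead_density must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if isinstance(self.loading, CavityPressure):
            if not self.domain.contains(np.asarray(self.loading.center))[0]:
                raise ValueError("cavity center must lie inside the domain")
        else:
            if not self.domain.contains(np.asarray(self.loading.location))[0]:
                raise ValueError("force location must lie inside the domain")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the scene's closed-form displacement field (um)."""
        if isinstance(self.loading, CavityPressure):
            return cavity_displacement_field(
                self.material, self.loading.a, self.loading.p, points,
                center=self.loading.center)
        return kelvin_displacement_field(
            self.material, self.loading.F, self.loading.location, points)


# --------------------------------------------------------------------------
# Closed-form elastic fields (forward oracles)
# --------------------------------------------------------------------------

def cavity_displacement_field(
    material: ElasticMaterial,
    a: float,
    p: float,
    points: np.ndarray,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Displacement around a pressurised spherical cavity (Lame solution).

    In an infinite isotropic medium a spherical cavity of radius ``a``
    carrying a uniform radial traction of magnitude ``p`` produces a purely
    radial displacement

        u_r(r) = p a^3 / (4 mu r^2),

    directed inward (toward the cavity) for tensile ``p > 0``.

    Parameters
    ----------
    points : (n, 3) array
        Evaluation points in um; all must satisfy ``|x - center| >= a``.

    Returns
    -------
    (n, 3) array of displacement vectors in um.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    rel = pts - np.asarray(center, float)
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < a * (1.0 - 1e-12)):
        raise ValueError("evaluation point inside the cavity (r < a)")
    if material.mu <= 0:
        raise ValueError("shear modulus must be positive")
    mag = p * a**3 / (4.0 * material.mu * r**2)
    # tensile p > 0 pulls radially inward
    return -mag[:, None] * (rel / r[:, None])


def kelvin_displacement_field(
    material: ElasticMaterial,
    F: Sequence[float],
    location: Sequence[float],
    points: np.ndarray,
) -> np.ndarray:
    """Kelvin solution: point force in an infinite isotropic medium.

        u_i = F_j / (16 pi mu (1 - nu) r) * [(3 - 4 nu) delta_ij + rhat_i rhat_j]

    The magnitude decays as 1/r and the field is symmetric about the force
    axis. Mimics a localised pull at the invasive front of a cohort.
    """
    if material.nu >= 0.5:
        raise ValueError("Kelvin solution requires nu < 0.5")
    pts = np.atleast_2d(np.asarray(points, float))
    rel = pts - np.asarray(location, float)
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0.0):
        raise ValueError("evaluation at the singular point of the Kelvin field")
    rhat = rel / r[:, None]
    Fv = np.asarray(F, float)
    c = 1.0 / (16.0 * math.pi * material.mu * (1.0 - material.nu) * r)
    iso = (3.0 - 4.0 * material.nu) * Fv[None, :]
    rad = (rhat @ Fv)[:, None] * rhat
    return c[:, None] * (iso + rad)


# --------------------------------------------------------------------------
# Bead sampling and track synthesis
# --------------------------------------------------------------------------

def sample_bead_positions(
    domain: Domain, density: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson point process in ``domain``.

    Expected count = density * volume; the count itself is Poisson.
    Deterministic for a fixed integer seed.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if domain.volume <= 0:
        raise ValueError("domain has zero volume")
    rng = np.random.default_rng(seed)
    n = rng.poisson(density * domain.volume)
    return domain.sample(n, rng)


def synthesize_bead_tracks(
    scene: SyntheticScene,
    timepoints: Sequence[float],
    amplitude_schedule: Sequence[float],
) -> pd.DataFrame:
    """Bead trajectories under a time-modulated forward field.

    position(t) = rest + amplitude_schedule[t] * u(rest) + N(0, sigma^2).
    The first amplitude must be 0 so that t[0] is a force-free reference
    state (the synthetic analogue of imaging before/after tissue lysis).

    Beads falling inside the cavity (for cavity loadings) or within 1 um of
    a point-force singularity are discarded.

    Returns
    -------
    DataFrame with columns ``bead_id, t, x, y, z`` (one row per bead per
    timepoint), the bead-track table dialect of :mod:`geltrax.io`.
    """
    t = np.asarray(timepoints, float)
    amp = np.asarray(amplitude_schedule, float)
    if t.ndim != 1 or len(t) != len(amp):
        raise ValueError("timepoints and amplitude_schedule must align")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if amp[0] != 0.0:
        raise ValueError("amplitude_schedule[0] must be 0 (force-free reference)")

    rng = np.random.default_rng(scene.seed)
    n = rng.poisson(scene.bead_density * scene.domain.volume)
    rest = scene.domain.sample(n, rng)
    if isinstance(scene.loading, CavityPressure):
        r = np.linalg.norm(rest - np.asarray(scene.loading.center), axis=1)
        rest = rest[r >= scene.loading.a]
    else:
        r = np.linalg.norm(rest - np.asarray(scene.loading.location), axis=1)
        rest = rest[r >= 1.0]
    u = scene.displacement(rest)

    frames = []
    for k, (tk, ak) in enumerate(zip(t, amp)):
        pos = rest + ak * u
        if scene.noise_sigma > 0:
            pos = pos + rng.normal(0.0, scene.noise_sigma, size=pos.shape)
        frames.append(pd.DataFrame({
            "bead_id": [f"b{i:05d}" for i in range(len(rest))],
            "t": tk,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        }))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Fibrillar images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberFieldSpec:
    """Specification of a synthetic confocal-reflection-style fibril image.

    Axial fibre angles (orientations modulo 180 deg) are drawn from a
    doubled-angle von Mises distribution: theta = 0.5 * VM(2*mean_angle,
    kappa). ``kappa = 0`` gives an isotropic network.
    """

    n_fibers: int = 6000
    mean_angle: float = 0.0          # degrees, axial, in [0, 180)
    kappa: float = 0.0               # axial concentration; 0 = isotropic
    image_size: int = 720            # pixels (square)
    pixel_size: float = 0.5          # um / px
    fiber_length: float = 10.0       # pixels
    fiber_width: float = 1.0         # pixels (drawn via blur)
    blur_sigma: float = 1.0          # pixels
    noise_sigma: float = 0.02        # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not (0.0 <= self.mean_angle < 180.0):
            raise ValueError("mean_angle must lie in [0, 180)")


def sample_axial_angles(
    n: int, mean_angle: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` axial angles (degrees in [0, 180)) from a doubled-angle
    von Mises distribution; kappa = 0 degenerates to the uniform law."""
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(math.radians(2.0 * mean_angle), kappa, size=n)
    return np.degrees(doubled % (2.0 * math.pi)) / 2.0


def render_fiber_image(spec: FiberFieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a grayscale image of anti-aliased fibre segments.

    Returns ``(image, true_angles)`` where ``image`` is a float array in
    [0, ~1] of shape (image_size, image_size) and ``true_angles`` are the
    sampled axial angles in degrees.

    Angles follow the mathematical image convention used throughout the
    package: 0 deg points along +x (columns), increasing counter-clockwise
    with y up (i.e. toward decreasing row index).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = np.zeros((size, size), float)
    angles = sample_axial_angles(spec.n_fibers, spec.mean_angle, spec.kappa, rng)
    if spec.n_fibers > 0:
        centers = rng.uniform(0.0, size, size=(spec.n_fibers, 2))  # (row, col)
        half = spec.fiber_length / 2.0
        th = np.radians(angles)
        # y-up convention: +angle rotates toward decreasing row index
        drow, dcol = -np.sin(th) * half, np.cos(th) * half
        for (r0, c0), dr, dc in zip(centers, drow, dcol):
            rr0 = int(round(r0 - dr)); cc0 = int(round(c0 - dc))
            rr1 = int(round(r0 + dr)); cc1 = int(round(c0 + dc))
            rr, cc, val = line_aa(rr0, cc0, rr1, cc1)
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            np.maximum.at(img, (rr[keep], cc[keep]), val[keep])
    if spec.fiber_width > 1.0 or spec.blur_sigma > 0:
        sigma = math.hypot(spec.blur_sigma, (spec.fiber_width - 1.0) / 2.0)
        img = ndimage.gaussian_filter(img, sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, None), angles


# --------------------------------------------------------------------------
# Coupled cohort / bead time series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoupledSeriesSpec:
    """Ground truth for the correlation analysis.

    A cohort length series (linear growth plus a periodic fluctuation) is
    coupled to a set of "near" bead displacement series through a gain and
    an integer sample lag; "far" beads carry independent noise with the
    same marginal variance. Sampling interval defaults to the 2-hour
    imaging cadence of the experiments being emulated.

    The default fluctuation period (16 h = 8 samples) keeps lags of a few
    samples identifiable: a periodic fluctuation aliases lags separated by
    a full period, so recoverable lags must stay well inside half a period.
    The default noise level sets a signal-to-noise ratio of 5 against the
    RMS of the informative fluctuation component (the monotone growth
    trend carries no lag information).
    """

    duration: float = 40.0           # hours
    dt: float = 2.0                  # hours
    baseline_length: float = 50.0    # um
    growth_rate: float = 1.5         # um / h
    fluctuation_amplitude: float = 8.0   # um
    fluctuation_period: float = 16.0     # hours
    coupling_gain: float = 1.0
    lag: int = 0                     # samples (near beads trail the cohort)
    noise_sigma: float | None = None     # um; None -> fluctuation RMS / 5
    n_near: int = 7
    n_far: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must be at least 10 dt")
        if abs(self.lag) * self.dt >= self.duration / 4:
            raise ValueError("lag too large for the series duration")


def _length_fn(spec: CoupledSeriesSpec, t: np.ndarray) -> np.ndarray:
    return (spec.baseline_length + spec.growth_rate * t
            + spec.fluctuation_amplitude
            * np.sin(2.0 * math.pi * t / spec.fluctuation_period))


def synthesize_coupled_series(spec: CoupledSeriesSpec) -> dict:
    """Generate a cohort series plus coupled near / independent far beads.

    Returns a dict with keys ``times`` (h), ``length`` (um), ``area``
    (um^2), ``near`` and ``far`` (lists of displacement series, um), and
    ``true_lag`` (samples). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    length = _length_fn(spec, t)
    # projected area tracks length with a nominal 30-um cohort width
    area = 30.0 * length

    signal = spec.coupling_gain * _length_fn(spec, t - spec.lag * spec.dt)
    fluct_rms = abs(spec.coupling_gain) * spec.fluctuation_amplitude / math.sqrt(2.0)
    if spec.noise_sigma is not None:
        sigma = spec.noise_sigma
    elif fluct_rms > 0:
        sigma = fluct_rms / 5.0
    else:
        sigma = spec.fluctuation_amplitude / (5.0 * math.sqrt(2.0))

    near = [signal + rng.normal(0.0, sigma, len(t)) for _ in range(spec.n_near)]
    signal_sd = float(np.std(signal))
    far_sd = math.hypot(signal_sd, sigma)
    far = [rng.normal(0.0, far_sd, len(t)) for _ in range(spec.n_far)]
    return {"times": t, "length": length, "area": area,
            "near": near, "far": far, "true_lag": spec.lag}


# --------------------------------------------------------------------------
# Binary mask stacks (invasion directionality)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortAngleSpec:
    """Invasion-angle law for mask-stack synthesis: uniform on the circle or
    von Mises with ``mean_deg``/``kappa``. One cohort per tissue by default.

    Angles are directions (mod 360 deg): 0 = due east (+x), counter-
    clockwise positive with y up.
    """

    distribution: Literal["uniform", "vonmises"] = "uniform"
    mean_deg: float = 0.0
    kappa: float = 4.0
    n_cohorts: int = 1
    length_px: float = 20.0
    width_px: float = 7.0


def make_disk_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    """Binary disk centred in an image of the given shape."""
    rr, cc = np.indices(shape)
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def synthesize_mask_stack(
    n_tissues: int,
    base_shape: np.ndarray,
    cohort_angles_spec: CohortAngleSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of binarised tissue masks with protruding cohorts.

    Each mask is the union of the shared ``base_shape`` with one or more
    finger-like protrusions leaving the base-shape boundary at angles drawn
    from ``cohort_angles_spec``. Returns ``(stack, true_angles)`` where
    ``stack`` is boolean of shape (n_tissues, H, W) and ``true_angles`` are
    the drawn invasion angles in degrees.
    """
    base = np.asarray(base_shape, bool)
    rng = np.random.default_rng(seed)
    H, W = base.shape
    r0, c0 = (H - 1) / 2.0, (W - 1) / 2.0
    # base-shape radius along each direction, from the centroid
    rows, cols = np.nonzero(base)
    if len(rows) == 0:
        raise ValueError("base_shape is empty")
    base_radius = float(np.max(np.hypot(rows - r0, cols - c0)))

    spec = cohort_angles_spec
    total = n_tissues * spec.n_cohorts
    if spec.distribution == "uniform":
        angles = rng.uniform(0.0, 360.0, size=total)
    else:
        angles = np.degrees(
            rng.vonmises(math.radians(spec.mean_deg), spec.kappa, size=total)
        ) % 360.0

    stack = np.empty((n_tissues, H, W), bool)
    brush = make_disk_mask(
        (int(spec.width_px) | 1,) * 2, spec.width_px / 2.0)
    for i in range(n_tissues):
        mask = base.copy().astype(float)
        for j in range(spec.n_cohorts):
            th = math.radians(angles[i * spec.n_cohorts + j])
            # y-up convention: +angle toward decreasing row
            d = np.array([-math.sin(th), math.cos(th)])
            start = np.array([r0, c0]) + (base_radius - 1.0) * d
            stop = start + spec.length_px * d
            n_steps = max(int(2 * spec.length_px), 2)
            for s in np.linspace(0.0, 1.0, n_steps):
                ctr = start + s * (stop - start)
                _stamp(mask, brush, ctr)
        stack[i] = mask > 0
    return stack, angles


def _stamp(canvas: np.ndarray, brush: np.ndarray, center: np.ndarray) -> None:
    bh, bw = brush.shape
    r = int(round(center[0])) - bh // 2
    c = int(round(center[1])) - bw // 2
    r0, r1 = max(r, 0), min(r + bh, canvas.shape[0])
    c0, c1 = max(c, 0), min(c + bw, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    canvas[r0:r1, c0:c1] = np.maximum(
        canvas[r0:r1, c0:c1], brush[r0 - r:r1 - r, c0 - c:c1 - c])


def synthesize_cohort_mask_series(
    lengths_px: Sequence[float],
    body_cols: int = 30,
    shape: tuple[int, int] = (64, 128),
    cohort_rows: tuple[int, int] = (24, 40),
) -> np.ndarray:
    """Frames of a rectangular tissue body with a protrusion whose length
    follows ``lengths_px``; used to validate cohort-length extraction."""
    frames = np.zeros((len(lengths_px), *shape), bool)
    for k, L in enumerate(lengths_px):
        frames[k, :, :body_cols] = True
        tip = body_cols + int(round(L))
        frames[k, cohort_rows[0]:cohort_rows[1], body_cols:tip] = True
    return frames
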