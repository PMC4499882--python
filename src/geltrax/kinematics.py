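"""Bead-based matrix deformation mapping.

Fiducial beads embedded in the gel are tracked over time; subtracting each
bead's position in a force-free reference state (experimentally obtained by
lysing the tissue, synthetically by a zero-amplitude frame) yields a
scattered displacement field. The field is interpolated mesh-free with
radial basis functions, differentiated by central differences to obtain the
displacement gradient, and converted to finite (Green-Lagrange) and
infinitesimal strain tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree


@dataclass
class BeadTrack:
    """One bead's trajectory: strictly increasing times (h) and positions (um)."""

    bead_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError(f"track {self.bead_id}: need >= 2 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"track {self.bead_id}: times must strictly increase")
        if self.positions.shape != (len(self.times), 3):
            raise ValueError(f"track {self.bead_id}: positions must be (n_t, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.bead_id}: non-finite positions")

    def position_at(self, t: float, atol: float = 1e-6) -> np.ndarray | None:
        hits = np.flatnonzero(np.isclose(self.times, t, atol=atol))
        return self.positions[hits[0]] if len(hits) else None


@dataclass
class DisplacementField:
    """Scattered displacement samples with a lazily built RBF interpolant.

    ``sample_points`` are the reference (force-free) bead positions; one
    displacement vector per sample point. ``method`` is the RBF kernel
    ("thin_plate_spline" default, or "gaussian" which uses ``length_scale``
    as the kernel width). ``length_scale`` defaults to the mean nearest-
    neighbour bead spacing and also sets the extrapolation-warning radius.
    """

    sample_points: np.ndarray
    vectors: np.ndarray
    reference_label: str = "t0"
    method: str = "thin_plate_spline"
    length_scale: float | None = None
    neighbors: int | None = 128
    _interp: RBFInterpolator | None = dc_field(default=None, repr=False)
    _tree: cKDTree | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, float)
        self.vectors = np.asarray(self.vectors, float)
        if self.sample_points.shape != self.vectors.shape:
            raise ValueError("one vector per sample point required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite displacement vectors")
        if self.length_scale is None and len(self.sample_points) >= 2:
            tree = cKDTree(self.sample_points)
            d, _ = tree.query(self.sample_points, k=2)
            self.length_scale = float(np.mean(d[:, 1]))
            self._tree = tree

    def _interpolator(self) -> RBFInterpolator:
        if self._interp is None:
            n = len(self.sample_points)
            if n < 4:
                raise ValueError("need >= 4 sample points for 3D interpolation")
            nb = min(self.neighbors, n) if self.neighbors else None
            kw: dict = {"neighbors": nb}
            if self.method == "gaussian":
                kw["kernel"] = "gaussian"
                kw["epsilon"] = 1.0 / self.length_scale
            else:
                kw["kernel"] = self.method
            self._interp = RBFInterpolator(self.sample_points, self.vectors, **kw)
        return self._interp


def displacements_from_tracks(
    tracks: Sequence[BeadTrack],
    reference_time: float,
    time: float | None = None,
    atol: float = 1e-6,
    **field_kwargs,
) -> DisplacementField:
    """Displacement field of a bead ensemble relative to a reference frame.

    vector = position(time) - position(reference_time); the sample point is
    the reference position. ``time`` defaults to the last timepoint shared
    by all retained tracks. Tracks missing either timepoint are excluded
    with a warning; an empty result raises.
    """
    if time is None:
        time = max(tr.times[-1] for tr in tracks)
    pts, vecs, dropped = [], [], 0
    for tr in tracks:
        p_ref = tr.position_at(reference_time, atol)
        p_t = tr.position_at(time, atol)
        if p_ref is None or p_t is None:
            dropped += 1
            continue
        pts.append(p_ref)
        vecs.append(p_t - p_ref)
    if dropped:
        warnings.warn(
            f"{dropped} track(s) missing t={reference_time} or t={time}; excluded")
    if not pts:
        raise ValueError("no track spans both the reference time and the query time")
    return DisplacementField(
        np.asarray(pts), np.asarray(vecs),
        reference_label=f"t{reference_time:g}", **field_kwargs)


def interpolate(
    field: DisplacementField,
    query_points: np.ndarray,
    warn_extrapolation: bool = True,
) -> np.ndarray:
    """Evaluate the field's RBF interpolant at ``query_points`` (n, 3).

    Interpolating kernels reproduce the sample vectors exactly at the
    sample points. Queries farther than ``length_scale`` from every sample
    point trigger an extrapolation warning.
    """
    q = np.atleast_2d(np.asarray(query_points, float))
    if warn_extrapolation and field.length_scale is not None:
        if field._tree is None:
            field._tree = cKDTree(field.sample_points)
        d, _ = field._tree.query(q, k=1)
        n_out = int(np.sum(d > field.length_scale))
        if n_out:
            warnings.warn(
                f"{n_out} query point(s) farther than the length scale "
                f"({field.length_scale:.3g} um) from all bead samples; "
                "values there are extrapolated")
    return field._interpolator()(q)


@dataclass(frozen=True)
class DeformationGradient:
    """Local kinematics at a point: F = I + grad_u (both 3x3)."""

    point: np.ndarray
    F: np.ndarray
    grad_u: np.ndarray

    @property
    def is_physical(self) -> bool:
        """det F > 0: orientation-preserving local deformation."""
        return float(np.linalg.det(self.F)) > 0.0


@dataclass(frozen=True)
class StrainTensor:
    """Finite (Green-Lagrange) and infinitesimal strain at a point."""

    point: np.ndarray
    E_green: np.ndarray
    eps_small: np.ndarray


def displacement_gradient(
    field: DisplacementField, point: np.ndarray, h: float = 1.0
) -> DeformationGradient:
    """Displacement gradient by central differences of the interpolant.

    grad_u[i, j] = d u_i / d x_j evaluated with step ``h`` (um); exact for
    affine fields. F = I + grad_u.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    p = np.asarray(point, float).reshape(3)
    offsets = np.vstack([p + h * np.eye(3), p - h * np.eye(3)])
    vals = interpolate(field, offsets, warn_extrapolation=False)
    grad_u = (vals[:3] - vals[3:]).T / (2.0 * h)
    return DeformationGradient(point=p, F=np.eye(3) + grad_u, grad_u=grad_u)


def green_lagrange(grad_u: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = 1/2 (grad_u + grad_u^T + grad_u^T grad_u).

    Exactly zero for any rigid-body motion (F orthogonal)."""
    g = np.asarray(grad_u, float)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite displacement gradient")
    return 0.5 * (g + g.T + g.T @ g)


def small_strain(grad_u: np.ndarray) -> np.ndarray:
    """Infinitesimal strain eps = 1/2 (grad_u + grad_u^T)."""
    g = np.asarray(grad_u, float)
    return 0.5 * (g + g.T)


def strain_at(field: DisplacementField, point: np.ndarray, h: float = 1.0) -> StrainTensor:
    """Both strain measures at a query point, via the interpolated gradient."""
    dg = displacement_gradient(field, point, h)
    return StrainTensor(point=dg.point,
                        E_green=green_lagrange(dg.grad_u),
                        eps_small=small_strain(dg.grad_u))
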