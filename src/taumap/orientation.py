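"""Relative orientations of paired subcomplexes from RELION Euler angles.

RELION describes a particle's refined orientation by three Euler angles
alpha/beta/gamma (named rot, tilt, psi) in an intrinsic ZYZ convention;
the corresponding rotation matrix is

    R(alpha, beta, gamma) = Rz(gamma) @ Ry(beta) @ Rz(alpha)

For a matched tauA/tauB particle pair with absolute rotations RA and RB
(each relative to its own 3D reference), the orientation of tauB relative
to tauA is the rotation

    R_r = RB @ RA^-1

which is converted back to an Euler triplet (d_alpha, d_beta, d_gamma).
Across many pairs these triplets form a population in angular space whose
joint mode characterizes the preferred relative arrangement of the two
lobes on the DNA.

The Euler <-> matrix conversions are written out explicitly here so the
convention is pinned down in code; the test suite cross-checks them
against scipy.spatial.transform.Rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import circstd

from .particle_io import wrap_angle

logger = logging.getLogger("taumap")

#: |sin(beta)| below this is treated as gimbal degeneracy (beta ~ 0 or 180).
GIMBAL_TOL = 1e-6

#: Orthonormality / determinant tolerance for validating rotation matrices.
ROTATION_TOL = 1e-9

MODE_UNDEFINED = (float("nan"), float("nan"), float("nan"))


@dataclass(frozen=True)
class EulerTriplet:
    """RELION Euler angles (rot, tilt, psi) = (alpha, beta, gamma) in degrees."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 180.0:
            raise ValueError(f"beta (tilt) {self.beta} outside [0, 180]")

    def canonical(self) -> "EulerTriplet":
        return EulerTriplet(wrap_angle(self.alpha), self.beta, wrap_angle(self.gamma))


@dataclass(frozen=True)
class RelativeOrientation:
    """Euler-angle representation of R_r = RB @ RA^-1 for one pair."""

    d_alpha: float
    d_beta: float
    d_gamma: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d_alpha, self.d_beta, self.d_gamma)


@dataclass
class OrientationPopulation:
    """Population of relative orientations with joint and per-angle modes."""

    orientations: list[RelativeOrientation]
    mode: tuple[float, float, float]       # joint histogram mode (NaN sentinel if empty)
    per_angle_mode: tuple[float, float, float]
    spread: tuple[float, float, float]     # circular std per angle, degrees
    n: int
    bin_width: float


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def validate_rotation(R: np.ndarray, tol: float = 1e-6) -> None:
    """Raise if R is not a proper rotation (orthonormal, det +1) within tol."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal within tolerance")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise ValueError("matrix determinant is not +1 within tolerance")


def euler_to_matrix(e: EulerTriplet) -> np.ndarray:
    """Rotation matrix of a RELION Euler triplet: Rz(gamma) @ Ry(beta) @ Rz(alpha)."""
    return _rz(e.gamma) @ _ry(e.beta) @ _rz(e.alpha)


def matrix_to_euler(R: np.ndarray, tol: float = 1e-6) -> tuple[EulerTriplet, bool]:
    """Invert :func:`euler_to_matrix`; returns (triplet, degenerate_flag).

    With R = Rz(g) Ry(b) Rz(a):
        R[2,2] = cos b,  R[0,2] = cos g sin b,  R[1,2] = sin g sin b,
        R[2,0] = -sin b cos a,  R[2,1] = sin b sin a.
    At gimbal degeneracy (b ~ 0 or 180, |sin b| < GIMBAL_TOL) only the
    sum/difference of a and g is defined; the convention here is g = 0
    with a absorbing the full in-plane angle.
    """
    validate_rotation(R, tol=tol)
    R = np.asarray(R, dtype=float)
    cos_b = float(np.clip(R[2, 2], -1.0, 1.0))
    sin_b = float(np.hypot(R[0, 2], R[1, 2]))
    beta = float(np.rad2deg(np.arctan2(sin_b, cos_b)))
    if sin_b < GIMBAL_TOL:
        if cos_b > 0:  # beta ~ 0: R = Rz(g + a)
            alpha = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
            beta = 0.0
        else:          # beta ~ 180: R = Rz(g) Ry(180) Rz(a); with g=0, a from Ry(180)Rz(a)
            alpha = float(np.rad2deg(np.arctan2(R[1, 0], R[1, 1])))
            beta = 180.0
        return EulerTriplet(wrap_angle(alpha), beta, 0.0), True
    alpha = float(np.rad2deg(np.arctan2(R[2, 1], -R[2, 0])))
    gamma = float(np.rad2deg(np.arctan2(R[1, 2], R[0, 2])))
    return EulerTriplet(wrap_angle(alpha), beta, wrap_angle(gamma)), False


def relative_orientation(eA: EulerTriplet, eB: EulerTriplet) -> RelativeOrientation:
    """Relative orientation of B with respect to A: Euler angles of RB @ RA^-1."""
    RA = euler_to_matrix(eA)
    RB = euler_to_matrix(eB)
    Rr = RB @ RA.T  # RA^-1 == RA.T for a rotation
    triplet, degenerate = matrix_to_euler(Rr)
    return RelativeOrientation(
        d_alpha=triplet.alpha,
        d_beta=triplet.beta,
        d_gamma=triplet.gamma,
        degenerate=degenerate,
    )


def _wrapped_histogram_mode_1d(
    values: np.ndarray, bin_width: float, circular: bool
) -> float:
    """Mode (bin center of max count) of one angle; circular axes wrap at +-180."""
    if circular:
        edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
        vals = np.array([wrap_angle(v) for v in values])
        # values exactly at +180 belong to the last bin under (-180, 180]
        vals = np.where(vals == 180.0, 180.0 - 1e-9, vals)
    else:
        edges = np.arange(0.0, 180.0 + bin_width, bin_width)
        vals = np.clip(values, 0.0, 180.0 - 1e-9)
    counts, _ = np.histogram(vals, bins=edges)
    imax = int(np.argmax(counts))
    return float(0.5 * (edges[imax] + edges[imax + 1]))


def orientation_population(
    pairs: list,
    max_distance: float = 200.0,
    bin_width: float = 10.0,
) -> OrientationPopulation:
    """Characterize the relative-orientation population of paired particles.

    Pairs are filtered to inter-particle distance < ``max_distance`` (the
    co-localized complexes); the relative Euler triplet is computed per
    pair, then the joint mode is taken as the center of the maximum-count
    cell of a wrapped 3D histogram (``bin_width`` degrees per axis;
    d_alpha and d_gamma wrap at +-180, d_beta spans [0, 180]).  Per-angle
    1D wrapped-histogram modes and circular standard deviations are also
    reported.  An empty filtered set yields NaN sentinels.
    """
    kept = [p for p in pairs if p.distance < max_distance]
    orientations: list[RelativeOrientation] = []
    for p in kept:
        if p.rel_orientation is not None:
            orientations.append(p.rel_orientation)
        elif p.eulerA is not None and p.eulerB is not None:
            eA = EulerTriplet(*p.eulerA)
            eB = EulerTriplet(*p.eulerB)
            orientations.append(relative_orientation(eA, eB))
        else:
            raise ValueError(f"pair {p.idA}/{p.idB} carries no Euler triplets")
    n = len(orientations)
    if n == 0:
        return OrientationPopulation(
            orientations=[], mode=MODE_UNDEFINED, per_angle_mode=MODE_UNDEFINED,
            spread=MODE_UNDEFINED, n=0, bin_width=bin_width,
        )

    da = np.array([o.d_alpha for o in orientations])
    db = np.array([o.d_beta for o in orientations])
    dg = np.array([o.d_gamma for o in orientations])

    edges_circ = np.arange(-180.0, 180.0 + bin_width, bin_width)
    edges_beta = np.arange(0.0, 180.0 + bin_width, bin_width)
    da_h = np.where(da == 180.0, 180.0 - 1e-9, da)
    dg_h = np.where(dg == 180.0, 180.0 - 1e-9, dg)
    db_h = np.clip(db, 0.0, 180.0 - 1e-9)
    hist, _ = np.histogramdd(
        np.column_stack([da_h, db_h, dg_h]),
        bins=(edges_circ, edges_beta, edges_circ),
    )
    ia, ib, ig = np.unravel_index(int(np.argmax(hist)), hist.shape)
    joint_mode = (
        float(0.5 * (edges_circ[ia] + edges_circ[ia + 1])),
        float(0.5 * (edges_beta[ib] + edges_beta[ib + 1])),
        float(0.5 * (edges_circ[ig] + edges_circ[ig + 1])),
    )
    per_angle_mode = (
        _wrapped_histogram_mode_1d(da, bin_width, circular=True),
        _wrapped_histogram_mode_1d(db, bin_width, circular=False),
        _wrapped_histogram_mode_1d(dg, bin_width, circular=True),
    )
    spread = (
        float(circstd(da, high=180.0, low=-180.0)),
        float(circstd(db, high=180.0, low=-180.0)),
        float(circstd(dg, high=180.0, low=-180.0)),
    )
    return OrientationPopulation(
        orientations=orientations,
        mode=joint_mode,
        per_angle_mode=per_angle_mode,
        spread=spread,
        n=n,
        bin_width=bin_width,
    )
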