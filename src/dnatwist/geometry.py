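"""Base-pair reference frames and helical parameters.

Implements the mid-frame (CEHS/3DNA-style) decomposition of the relative
rotation and translation between orthonormal base / base-pair frames into
the six inter-base-pair parameters (shift, slide, rise, tilt, roll, twist)
and the six intra-base-pair parameters (shear, stretch, stagger, buckle,
propeller, opening), together with its exact inverse, end-to-end twist,
per-step axis bending, groove geometry, and Watson-Crick hydrogen-bond
integrity checks.

Conventions
-----------
* angles in degrees, lengths in Angstrom;
* a frame is a right-handed orthonormal 3x3 matrix whose columns are the
  x, y, z unit vectors, plus an origin;
* step i joins base pairs i and i+1 (1-based, inclusive) and parameters are
  decomposed in the mid-frame of the two frames;
* the Crick base frame is flipped 180 degrees about its x-axis before
  pairing (``flip_crick``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bases import (
    GROOVE_P_RADIUS_CORRECTION,
    RING_ATOMS,
    STANDARD_BASE_COORDS,
    WC_HBOND_PAIRS,
    standard_base_atoms,
)
from .constants import DEG2RAD, RAD2DEG

__all__ = [
    "BaseFrame",
    "StepParams",
    "IntraBpParams",
    "BendProfile",
    "GrooveProfile",
    "fit_base_frame",
    "flip_crick",
    "bp_frame_and_params",
    "compose_bp",
    "step_params",
    "compose_step",
    "end_to_end_twist",
    "axis_bending",
    "groove_geometry",
    "wc_hbond_check",
    "rotation_about_axis",
]

STEP_PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
INTRA_PARAM_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")

#: Watson-Crick heavy-atom distance threshold for the melted flag, Angstrom.
WC_MELT_DISTANCE = 4.0


# --------------------------------------------------------------------------
# frames
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseFrame:
    """Orthonormal reference frame: origin (A) and rotation matrix.

    Columns of ``axes`` are the x, y, z unit vectors.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.origin.shape != (3,) or self.axes.shape != (3, 3):
            raise ValueError("BaseFrame requires a 3-vector origin and 3x3 axes")

    def validate(self, tol: float = 1e-8) -> "BaseFrame":
        """Raise if the axes are not a proper rotation to within ``tol``."""
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        if err > tol:
            raise ValueError(f"frame axes not orthonormal (max deviation {err:.2e})")
        if abs(np.linalg.det(self.axes) - 1.0) > max(tol, 1e-8):
            raise ValueError("frame axes are not right-handed (det != +1)")
        return self

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    @classmethod
    def identity(cls) -> "BaseFrame":
        return cls(np.zeros(3), np.eye(3))

    def transform_points(self, local: np.ndarray) -> np.ndarray:
        """Map points from frame coordinates into the global frame."""
        return np.asarray(local, dtype=float) @ self.axes.T + self.origin


@dataclass(frozen=True)
class StepParams:
    """Six inter-base-pair helical parameters (A / degrees)."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("step parameters must be finite")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError(f"twist must lie in (-180, 180], got {self.twist}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist]
        )

    @classmethod
    def from_array(cls, a: np.ndarray) -> "StepParams":
        return cls(*(float(v) for v in np.asarray(a, dtype=float)))


@dataclass(frozen=True)
class IntraBpParams:
    """Six intra-base-pair parameters (A / degrees)."""

    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.to_array())):
            raise ValueError("intra-bp parameters must be finite")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.shear, self.stretch, self.stagger,
             self.buckle, self.propeller, self.opening]
        )

    @classmethod
    def from_array(cls, a: np.ndarray) -> "IntraBpParams":
        return cls(*(float(v) for v in np.asarray(a, dtype=float)))


@dataclass
class BendProfile:
    """Per-step axis bending angles in degrees, one per bp step."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any((self.angles < -1e-9) | (self.angles > 180.0 + 1e-9)):
            raise ValueError("bend angles must lie in [0, 180] degrees")


@dataclass
class GrooveProfile:
    """Groove widths/depths (A) per interior bp level.

    ``defined`` flags levels where both grooves could be measured; undefined
    levels carry NaN rather than silent zeros.
    """

    levels: np.ndarray          # 1-based bp indices
    minor_width: np.ndarray
    minor_depth: np.ndarray
    major_width: np.ndarray
    major_depth: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("levels", "minor_width", "minor_depth", "major_width", "major_depth"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.defined is None:
            self.defined = np.isfinite(self.minor_width) & np.isfinite(self.major_width)
        self.defined = np.asarray(self.defined, dtype=bool)
        for w in (self.minor_width, self.major_width):
            if np.any(w[np.isfinite(w)] < -1e-9):
                raise ValueError("groove widths must be non-negative")


# --------------------------------------------------------------------------
# rotation helpers
# --------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-15:
        raise ValueError("rotation axis must be non-zero")
    u = axis / n
    a = angle_deg * DEG2RAD
    c, s = np.cos(a), np.sin(a)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def _signed_angle(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from v1 to v2 about ``axis`` (right-hand rule)."""
    return float(np.arctan2(np.dot(np.cross(v1, v2), axis), np.dot(v1, v2)) * RAD2DEG)


def _decompose_frames(T1: np.ndarray, T2: np.ndarray, d: np.ndarray):
    """Mid-frame decomposition of the rotation/translation from frame 1 to 2.

    Returns ``(trans3, tilt, roll, twist, Tm)`` where ``trans3`` is the
    displacement projected on the mid-frame axes and ``Tm`` the mid-frame
    rotation matrix.
    """
    z1, z2 = T1[:, 2], T2[:, 2]
    cross = np.cross(z1, z2)
    sin_g = np.linalg.norm(cross)
    gamma = np.arctan2(sin_g, float(np.dot(z1, z2))) * RAD2DEG
    if sin_g < 1e-12:
        # coplanar z-axes: pure twist step, hinge arbitrary
        hinge = T1[:, 1]
    else:
        hinge = cross / sin_g
    T1p = rotation_about_axis(hinge, +gamma / 2.0) @ T1
    T2p = rotation_about_axis(hinge, -gamma / 2.0) @ T2
    zm = T1p[:, 2]
    twist = _signed_angle(T1p[:, 1], T2p[:, 1], zm)
    Tm = rotation_about_axis(zm, twist / 2.0) @ T1p
    phi = _signed_angle(hinge, Tm[:, 1], zm)
    roll = gamma * np.cos(phi * DEG2RAD)
    tilt = gamma * np.sin(phi * DEG2RAD)
    trans3 = Tm.T @ d
    return trans3, float(tilt), float(roll), float(twist), Tm


def _compose_frames(T1: np.ndarray, o1: np.ndarray, params6: np.ndarray):
    """Exact inverse of :func:`_decompose_frames`: successor frame from
    frame 1 and a parameter 6-vector (shift, slide, rise, tilt, roll, twist).
    """
    shift, slide, rise, tilt, roll, twist = (float(v) for v in params6)
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.arctan2(tilt, roll) * RAD2DEG)
    hinge_m = np.array([np.sin(phi * DEG2RAD), np.cos(phi * DEG2RAD), 0.0])
    Rz = rotation_about_axis(np.array([0.0, 0.0, 1.0]), twist / 2.0)
    Rh_minus = rotation_about_axis(hinge_m, -gamma / 2.0) if gamma > 0 else np.eye(3)
    Rh_plus = rotation_about_axis(hinge_m, +gamma / 2.0) if gamma > 0 else np.eye(3)
    # T1 = Tm @ Rh_minus @ Rz^-1  =>  Tm = T1 @ (Rh_minus @ Rz^-1)^T
    A1 = Rh_minus @ Rz.T
    Tm = T1 @ A1.T
    T2 = Tm @ Rh_plus @ Rz
    o2 = o1 + Tm @ np.array([shift, slide, rise])
    return T2, o2, Tm


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def fit_base_frame(base_atoms: dict[str, np.ndarray], base_type: str) -> BaseFrame:
    """Fit the standard reference frame to observed base heavy atoms.

    Least-squares (Kabsch) superposition of the embedded standard base ring
    geometry onto the observed ring atoms; the fitted rigid transform *is*
    the base frame.

    Parameters
    ----------
    base_atoms : mapping of atom name -> (3,) coordinates in Angstrom.
    base_type : one of ``A``, ``C``, ``G``, ``T``.
    """
    base_type = base_type.upper()
    if base_type not in RING_ATOMS:
        raise ValueError(f"unknown base type {base_type!r}")
    ring = RING_ATOMS[base_type]
    missing = [a for a in ring if a not in base_atoms]
    if missing:
        raise ValueError(
            f"missing ring atom(s) {', '.join(missing)} for base type {base_type}"
        )
    std = STANDARD_BASE_COORDS[base_type]
    P = np.array([std[a] for a in ring], dtype=float)            # standard
    Q = np.array([np.asarray(base_atoms[a], float) for a in ring])  # observed
    p_mean, q_mean = P.mean(axis=0), Q.mean(axis=0)
    H = (P - p_mean).T @ (Q - q_mean)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    return BaseFrame(t, R).validate(1e-6)


def flip_crick(frame: BaseFrame) -> BaseFrame:
    """Flip a Crick-strand base frame 180 degrees about its own x-axis."""
    return BaseFrame(frame.origin, frame.axes @ np.diag([1.0, -1.0, -1.0]))


def bp_frame_and_params(
    frame_w: BaseFrame, frame_c: BaseFrame
) -> tuple[BaseFrame, IntraBpParams]:
    """Base-pair mid-frame and intra-bp parameters.

    ``frame_c`` must already be flipped to the Watson convention
    (:func:`flip_crick`).  Parameters describe the Watson base relative to
    the (flipped) Crick base, decomposed in their mid-frame; buckle,
    propeller and opening are the rotations about the mid-frame x, y and z
    axes respectively.
    """
    frame_w.validate(1e-6)
    frame_c.validate(1e-6)
    d = frame_w.origin - frame_c.origin
    trans3, buckle, propeller, opening, Tm = _decompose_frames(
        frame_c.axes, frame_w.axes, d
    )
    mid = BaseFrame(0.5 * (frame_w.origin + frame_c.origin), Tm)
    params = IntraBpParams(
        shear=float(trans3[0]),
        stretch=float(trans3[1]),
        stagger=float(trans3[2]),
        buckle=buckle,
        propeller=propeller,
        opening=opening,
    )
    return mid, params


def compose_bp(
    mid: BaseFrame, params: IntraBpParams
) -> tuple[BaseFrame, BaseFrame]:
    """Watson and (flipped) Crick frames realizing the given mid-frame and
    intra-bp parameters; exact inverse of :func:`bp_frame_and_params`."""
    p = params.to_array()
    # build the Crick frame such that composing gives back the mid-frame
    T2, o2, Tm_check = _compose_frames(np.eye(3), np.zeros(3), p)
    # express: crick = mid @ inv(Tm_check), watson follows by composition
    Tc = mid.axes @ Tm_check.T
    Tw = Tc @ T2
    d_global = mid.axes @ np.array([p[0], p[1], p[2]])
    o_c = mid.origin - 0.5 * d_global
    o_w = mid.origin + 0.5 * d_global
    return BaseFrame(o_w, Tw), BaseFrame(o_c, Tc)


def step_params(frame1: BaseFrame, frame2: BaseFrame) -> StepParams:
    """Six helical step parameters between consecutive bp frames."""
    frame1.validate(1e-6)
    frame2.validate(1e-6)
    d = frame2.origin - frame1.origin
    trans3, tilt, roll, twist, _ = _decompose_frames(frame1.axes, frame2.axes, d)
    return StepParams(
        shift=float(trans3[0]),
        slide=float(trans3[1]),
        rise=float(trans3[2]),
        tilt=tilt,
        roll=roll,
        twist=twist,
    )


def compose_step(frame: BaseFrame, params: StepParams | np.ndarray) -> BaseFrame:
    """Successor bp frame whose decomposition against ``frame`` reproduces
    ``params`` exactly."""
    p = params.to_array() if isinstance(params, StepParams) else np.asarray(params, float)
    T2, o2, _ = _compose_frames(frame.axes, frame.origin, p)
    return BaseFrame(o2, T2)


def frames_from_params(
    params: np.ndarray, start: BaseFrame | None = None
) -> list[BaseFrame]:
    """Chain of bp frames generated by successive :func:`compose_step`.

    ``params`` has shape (n_steps, 6); returns n_steps + 1 frames.
    """
    params = np.asarray(params, dtype=float)
    frames = [start if start is not None else BaseFrame.identity()]
    for row in params:
        frames.append(compose_step(frames[-1], row))
    return frames


def end_to_end_twist(
    frames: list[BaseFrame], region: tuple[int, int] | None = None
) -> float:
    """Sum of step twists over a region of bp steps (degrees).

    ``region`` is (first_step, last_step), 1-based inclusive; step i joins
    bp i and i+1.  Defaults to all steps.
    """
    n_steps = len(frames) - 1
    if n_steps < 1:
        raise ValueError("need at least two bp frames (one step)")
    if region is None:
        region = (1, n_steps)
    lo, hi = region
    if not (1 <= lo <= hi <= n_steps):
        raise ValueError(f"region {region} invalid for {n_steps} steps")
    total = 0.0
    for i in range(lo - 1, hi):
        total += step_params(frames[i], frames[i + 1]).twist
    return total


def axis_bending(frames: list[BaseFrame]) -> BendProfile:
    """Per-step bend: angle between consecutive bp-frame z-axes (degrees)."""
    if len(frames) < 2:
        raise ValueError("need at least two bp frames")
    angles = []
    for f1, f2 in zip(frames[:-1], frames[1:]):
        c = float(np.clip(np.dot(f1.z, f2.z), -1.0, 1.0))
        angles.append(np.arccos(c) * RAD2DEG)
    return BendProfile(np.asarray(angles))


# --------------------------------------------------------------------------
# groove geometry
# --------------------------------------------------------------------------

def _point_polyline_min(
    point: np.ndarray, poly: np.ndarray
) -> tuple[float, np.ndarray] | None:
    """Minimal distance from a point to a polyline, with the closest point.

    ``poly`` rows may contain NaN (chain breaks)."""
    best: tuple[float, np.ndarray] | None = None
    for a, b in zip(poly[:-1], poly[1:]):
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            continue
        ab = b - a
        denom = float(np.dot(ab, ab))
        t = 0.0 if denom < 1e-12 else float(np.clip(np.dot(point - a, ab) / denom, 0.0, 1.0))
        c = a + t * ab
        dist = float(np.linalg.norm(point - c))
        if best is None or dist < best[0]:
            best = (dist, c)
    return best


def _groove_candidates(point, other_poly, origin, x_axis):
    """Closest approach from a phosphate to the opposite backbone, split by
    groove side (minor on the -x side of the bp frame, major on +x)."""
    minor = major = None
    for a, b in zip(other_poly[:-1], other_poly[1:]):
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            continue
        ab = b - a
        denom = float(np.dot(ab, ab))
        t = 0.0 if denom < 1e-12 else float(np.clip(np.dot(point - a, ab) / denom, 0.0, 1.0))
        c = a + t * ab
        dist = float(np.linalg.norm(point - c))
        side = float(np.dot(0.5 * (point + c) - origin, x_axis))
        if side < 0:
            if minor is None or dist < minor[0]:
                minor = (dist, c)
        else:
            if major is None or dist < major[0]:
                major = (dist, c)
    return minor, major


def _segment_depth(origin: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Distance from the groove floor (bp origin) to the width segment."""
    pq = q - p
    denom = float(np.dot(pq, pq))
    t = 0.0 if denom < 1e-12 else float(np.clip(np.dot(origin - p, pq) / denom, 0.0, 1.0))
    return float(np.linalg.norm(origin - (p + t * pq)))


def groove_geometry(
    p_watson: np.ndarray,
    p_crick: np.ndarray,
    frames: list[BaseFrame],
    radius_correction: float = GROOVE_P_RADIUS_CORRECTION,
) -> GrooveProfile:
    """Major/minor groove widths and depths from cross-strand phosphates.

    Refined cross-strand minimal P-P distances (point-to-backbone-polyline),
    minus a fixed backbone-radius correction; depths measured from the bp
    mid-frame origin to the width segment.  ``p_watson[i]`` / ``p_crick[i]``
    are the phosphate coordinates associated with bp level i (NaN rows where
    the phosphate is absent, e.g. 5' termini).

    Levels that cannot be measured are flagged (NaN), not silently zeroed.
    """
    p_w = np.asarray(p_watson, dtype=float)
    p_c = np.asarray(p_crick, dtype=float)
    n = len(frames)
    if p_w.shape != (n, 3) or p_c.shape != (n, 3):
        raise ValueError("phosphate arrays must have one (3,) row per bp level")
    levels = np.arange(1, n + 1, dtype=float)
    out = {k: np.full(n, np.nan) for k in
           ("minor_width", "minor_depth", "major_width", "major_depth")}
    for i in range(1, n - 1):
        origin, x_axis = frames[i].origin, frames[i].x
        results = {"minor": None, "major": None}
        for point, other in ((p_w[i], p_c), (p_c[i], p_w)):
            if not np.all(np.isfinite(point)):
                continue
            minor, major = _groove_candidates(point, other, origin, x_axis)
            for key, cand, anchor in (("minor", minor, point), ("major", major, point)):
                if cand is not None and (
                    results[key] is None or cand[0] < results[key][0]
                ):
                    results[key] = (cand[0], anchor, cand[1])
        for key in ("minor", "major"):
            if results[key] is not None:
                dist, a, b = results[key]
                out[f"{key}_width"][i] = max(dist - radius_correction, 0.0)
                out[f"{key}_depth"][i] = _segment_depth(origin, a, b)
    return GrooveProfile(levels=levels, **out)


# --------------------------------------------------------------------------
# Watson-Crick hydrogen bonds
# --------------------------------------------------------------------------

def wc_hbond_check(
    atoms_w: dict[str, np.ndarray],
    atoms_c: dict[str, np.ndarray],
    bp_type: str,
) -> tuple[float, bool, dict[tuple[str, str], float]]:
    """Max Watson-Crick heavy-atom H-bond distance and melted flag.

    ``bp_type`` is the two-letter pair, e.g. ``"GC"`` or ``"AT"`` (Watson
    base first).  The pair is flagged melted when any canonical WC
    heavy-atom distance is >= 4.0 A (strict reading of "below 4 A"; a
    distance of exactly 4.0 A counts as melted).
    """
    bp_type = bp_type.upper()
    if len(bp_type) != 2:
        raise ValueError(f"bp_type must be two letters, got {bp_type!r}")
    w, c = bp_type
    if w in WC_HBOND_PAIRS:
        pairs = WC_HBOND_PAIRS[w]
        pur_atoms, pyr_atoms = atoms_w, atoms_c
    elif c in WC_HBOND_PAIRS:
        pairs = WC_HBOND_PAIRS[c]
        pur_atoms, pyr_atoms = atoms_c, atoms_w
    else:
        raise ValueError(f"unknown base pair type {bp_type!r}")
    dists: dict[tuple[str, str], float] = {}
    for a_pur, a_pyr in pairs:
        if a_pur not in pur_atoms or a_pyr not in pyr_atoms:
            raise ValueError(f"missing WC atom {a_pur} or {a_pyr} for pair {bp_type}")
        dists[(a_pur, a_pyr)] = float(
            np.linalg.norm(np.asarray(pur_atoms[a_pur]) - np.asarray(pyr_atoms[a_pyr]))
        )
    max_dist = max(dists.values())
    return max_dist, max_dist >= WC_MELT_DISTANCE, dists
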