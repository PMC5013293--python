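"""Rigid-body geometry of the dimer interface.

The quantities computed here operationalize the filament-geometry questions
asked of an FtsZ dimer trajectory:

* :func:`superpose` — least-RMSD proper rigid superposition (Kabsch, with the
  reflection correction), the primitive behind everything else;
* :func:`interface_transform` — the rigid map carrying subunit A onto subunit
  B; applied repeatedly it extrapolates the protofilament;
* :func:`screw_decompose` / :func:`screw_compose` — the canonical
  rotation-about-an-axis-plus-rise form of that map, whose angle and rise are
  the helical twist and rise per subunit;
* :func:`twist_bend` / :func:`twist_series` — per-frame inter-subunit twist
  (signed rotation of the subunits' long principal axes about the
  inter-centroid axis, zeroed at the first frame) and bend (the swing
  component of the relative subunit rotation).

Angles are degrees, distances Angstroms, times nanoseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import AxisAmbiguityWarning, GeometryError, UndefinedTwistWarning
from .structures import DimerFrame, Protomer, Selection, Trajectory

#: Default atom selection for superposition / principal axes: Calpha only.
#: Insensitive to side-chain noise and standard in filament-geometry work.
DEFAULT_SELECTION: Selection = "CA"

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHO_TOL:
            raise GeometryError("rotation matrix is not orthonormal within 1e-8")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise GeometryError("rotation determinant is not +1 within 1e-8 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def power(self, k: int) -> "RigidTransform":
        out = RigidTransform.identity()
        base = self if k >= 0 else self.inverse()
        for _ in range(abs(k)):
            out = base.compose(out)
        return out


@dataclass(frozen=True)
class ScrewParameters:
    """Rotation by angle_deg about (axis through axis_point) plus rise_A along axis."""

    angle_deg: float
    axis: np.ndarray
    rise_A: float
    axis_point: np.ndarray
    degenerate: bool = False  # identity transform: axis arbitrary

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, float).reshape(3))
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, float).reshape(3))
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-10:
            raise GeometryError("screw axis must be a unit vector")


@dataclass
class PrincipalFrame:
    """Centroid and descending-variance orthonormal axes of an atom selection."""

    centroid: np.ndarray
    axes: np.ndarray  # rows e1 (longest) .. e3; right-handed
    eigenvalues: np.ndarray  # variances, A^2, non-increasing
    axis_ambiguous: bool = False


@dataclass
class TwistSeries:
    """Per-frame inter-subunit twist and bend along a trajectory."""

    times_ns: np.ndarray
    twist_deg: np.ndarray  # signed; NaN where undefined
    bend_deg: np.ndarray  # non-negative

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times_ns, "twist_deg": self.twist_deg, "bend_deg": self.bend_deg}
        )

    def to_csv(self, path) -> None:
        # NaN -> empty field
        self.to_dataframe().to_csv(path, index=False, na_rep="")


def _as_points(x, name: str) -> np.ndarray:
    pts = np.asarray(x, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"{name}: expected an (n, 3) point array")
    return pts


def superpose(moving, target) -> tuple[RigidTransform, float]:
    """Least-RMSD proper superposition of ``moving`` onto ``target`` (Kabsch).

    Returns the transform T with T(moving) ~= target and the post-fit RMSD.
    Reflections are corrected: the returned rotation always has det +1.
    """
    P = _as_points(moving, "moving")
    Q = _as_points(target, "target")
    if P.shape != Q.shape:
        raise GeometryError(f"point counts differ: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise GeometryError("need at least 3 points to superpose")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) point configuration")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _canonical_sign(axes: np.ndarray) -> np.ndarray:
    """Fix eigenvector signs: e1, e2 oriented toward +z (ties broken toward +x,
    then +y); e3 completes a right-handed triple."""
    out = axes.copy()
    for i in (0, 1):
        v = out[i]
        for comp in (2, 0, 1):
            if abs(v[comp]) > 1e-12:
                if v[comp] < 0:
                    out[i] = -v
                break
    out[2] = np.cross(out[0], out[1])
    return out


def principal_frame(obj, selection: Selection = DEFAULT_SELECTION) -> PrincipalFrame:
    """Principal axes of the (mass-unweighted) covariance of an atom selection.

    ``obj`` may be a :class:`Protomer` or a bare (n, 3) coordinate array.
    Axes are ordered by descending variance and made right-handed; near-equal
    consecutive eigenvalues (relative gap < 1e-6) set ``axis_ambiguous`` and
    emit :class:`AxisAmbiguityWarning`.
    """
    coords = obj.coords(selection) if isinstance(obj, Protomer) else _as_points(obj, "coords")
    if coords.shape[0] < 3:
        raise GeometryError("principal frame needs at least 3 atoms in the selection")
    centroid = coords.mean(axis=0)
    X = coords - centroid
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) atom selection")
    cov = X.T @ X / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = _canonical_sign(evecs[:, order].T)
    gaps = np.abs(np.diff(evals)) / max(evals[0], 1e-300)
    ambiguous = bool(np.any(gaps < 1e-6))
    if ambiguous:
        warnings.warn(
            "near-degenerate covariance eigenvalues: principal axes ambiguous",
            AxisAmbiguityWarning,
            stacklevel=2,
        )
    return PrincipalFrame(centroid, axes, evals, ambiguous)


def interface_transform(frame: DimerFrame, selection: Selection = DEFAULT_SELECTION) -> RigidTransform:
    """Rigid map superposing subunit A's matched atoms onto subunit B's.

    Atoms are matched by (resseq, atom name); this is the generator that,
    applied repeatedly, extrapolates the dimer interface into a filament.
    """
    xa, xb, keys = frame.matched_coords(selection)
    if xa.shape[0] < 3:
        seqs_a = {r.resseq for r in frame.subunit_a.residues}
        seqs_b = {r.resseq for r in frame.subunit_b.residues}
        unmatched = sorted(seqs_a ^ seqs_b)
        raise GeometryError(
            f"only {xa.shape[0]} matched atom(s) for selection {selection!r}; "
            f"unmatched residues: {unmatched[:20]}"
        )
    transform, _ = superpose(xa, xb)
    return transform


def screw_decompose(t: RigidTransform) -> ScrewParameters:
    """Canonical screw form of a rigid transform.

    The rotation angle comes from the rotation's axis-angle form; the rise is
    the translation component along the axis; the axis point solves the
    in-plane fixed-point equation (I - R) p = t_perp (minimum-norm solution,
    which lies in the plane perpendicular to the axis).  The axis is oriented
    so the rise is non-negative; the angle is signed accordingly.  Rotations
    below 0.01 deg are reported as angle 0 with the axis along the
    translation (or flagged degenerate for a near-identity transform).
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    trans = t.translation
    if np.degrees(angle) < 0.01:
        tn = float(np.linalg.norm(trans))
        if tn < 1e-12:
            return ScrewParameters(0.0, np.array([0.0, 0.0, 1.0]), 0.0, np.zeros(3), degenerate=True)
        axis = trans / tn
        return ScrewParameters(0.0, axis, tn, np.zeros(3))
    axis = rotvec / angle
    rise = float(trans @ axis)
    if rise < 0:
        axis, angle, rise = -axis, -angle, -rise
    t_perp = trans - rise * axis
    # minimum-norm solution of (I - R) p = t_perp is orthogonal to the axis
    p, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    return ScrewParameters(float(np.degrees(angle)), axis, rise, p)


def screw_compose(p: ScrewParameters) -> RigidTransform:
    """Rebuild the rigid transform from its screw parameters."""
    R = Rotation.from_rotvec(np.radians(p.angle_deg) * p.axis).as_matrix()
    t = (np.eye(3) - R) @ p.axis_point + p.rise_A * p.axis
    return RigidTransform(R, t)


def swing_twist(rotation: np.ndarray, axis: np.ndarray) -> tuple[float, float]:
    """Swing-twist decomposition of a rotation about ``axis``.

    Returns (twist_deg signed about axis, swing_deg >= 0) with
    R = R_swing @ R_twist (twist applied first).
    """
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    x, y, z, w = Rotation.from_matrix(np.asarray(rotation, float)).as_quat()
    qv = np.array([x, y, z])
    proj = float(qv @ u)
    norm = np.hypot(proj, w)
    if norm < 1e-12:
        # 180 deg rotation about an axis perpendicular to u: pure swing
        return 0.0, 180.0
    twist_rad = 2.0 * np.arctan2(proj, w)
    # wrap to (-pi, pi]
    twist_rad = (twist_rad + np.pi) % (2 * np.pi) - np.pi
    qt = np.array([*(proj / norm * u), w / norm])  # unit twist quaternion
    qt_conj = np.array([-qt[0], -qt[1], -qt[2], qt[3]])
    swing = Rotation.from_quat([x, y, z, w]) * Rotation.from_quat(qt_conj)
    swing_deg = float(np.degrees(swing.magnitude()))
    return float(np.degrees(twist_rad)), swing_deg


def _signed_plane_angle(va: np.ndarray, vb: np.ndarray, u: np.ndarray) -> float:
    """Signed angle (deg, right-hand rule about u) between the projections of
    va and vb onto the plane perpendicular to u."""
    pa = va - (va @ u) * u
    pb = vb - (vb @ u) * u
    pa /= np.linalg.norm(pa)
    pb /= np.linalg.norm(pb)
    return float(np.degrees(np.arctan2(u @ np.cross(pa, pb), pa @ pb)))


def _raw_twist_bend(
    frame: DimerFrame,
    selection: Selection,
    prev_axes: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Unreferenced twist/bend of one frame, with optional axis-sign continuity."""
    pf_a = principal_frame(frame.subunit_a, selection)
    pf_b = principal_frame(frame.subunit_b, selection)
    axes_a, axes_b = pf_a.axes.copy(), pf_b.axes.copy()
    if prev_axes is not None:
        for axes, prev in zip((axes_a, axes_b), prev_axes):
            for i in (0, 1):
                if axes[i] @ prev[i] < 0:
                    axes[i] = -axes[i]
            axes[2] = np.cross(axes[0], axes[1])
    else:
        # single-frame convention: orient B's long axis with A's
        if axes_b[0] @ axes_a[0] < 0:
            axes_b[0] = -axes_b[0]
            axes_b[2] = np.cross(axes_b[0], axes_b[1])
    u = pf_b.centroid - pf_a.centroid
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise GeometryError("inter-centroid axis is zero: subunits coincide")
    u = u / nu
    # bend: swing component of the relative subunit rotation about u
    rel = interface_transform(frame, selection)
    _, bend = swing_twist(rel.rotation, u)
    # twist: projected principal axes
    cos_a = abs(axes_a[0] @ u)
    cos_b = abs(axes_b[0] @ u)
    limit = np.cos(np.radians(1.0))
    if cos_a > limit or cos_b > limit:
        warnings.warn(
            f"frame t={frame.time_ns:g} ns: principal axis within 1 deg of the "
            "inter-centroid axis; twist undefined",
            UndefinedTwistWarning,
            stacklevel=3,
        )
        return float("nan"), bend, (axes_a, axes_b)
    twist = _signed_plane_angle(axes_a[0], axes_b[0], u)
    return twist, bend, (axes_a, axes_b)


def twist_bend(
    frame: DimerFrame,
    reference: DimerFrame | None = None,
    selection: Selection = DEFAULT_SELECTION,
) -> tuple[float, float]:
    """Inter-subunit twist and bend of a single dimer frame.

    Twist: signed angle (right-hand rule about the A->B inter-centroid axis)
    between the projections of the two subunits' longest principal axes onto
    the plane perpendicular to that axis, minus the same quantity measured in
    ``reference`` (no offset if ``reference`` is None).  Bend: swing component
    of the relative subunit rotation about the inter-centroid axis
    (non-negative).  Twist is NaN if either long axis lies within 1 degree of
    the inter-centroid axis.
    """
    twist, bend, _ = _raw_twist_bend(frame, selection)
    if reference is not None:
        ref_twist, _, _ = _raw_twist_bend(reference, selection)
        twist = twist - ref_twist
        twist = (twist + 180.0) % 360.0 - 180.0
    return twist, bend


def twist_series(
    traj: Trajectory,
    selection: Selection = DEFAULT_SELECTION,
    absolute: bool = False,
) -> TwistSeries:
    """Twist and bend for every frame of a trajectory.

    Principal-axis signs follow temporal continuity (each frame's axes are
    flipped to maximize the dot product with the previous frame's).  Unless
    ``absolute=True``, twist is referenced to the first frame with a defined
    value — simulations start from a straight, untwisted state, so frame 0
    reads zero — and the series is unwrapped so no step exceeds 180 deg.
    """
    twists = np.empty(len(traj))
    bends = np.empty(len(traj))
    prev_axes = None
    for k, frame in enumerate(traj):
        t, b, prev_axes = _raw_twist_bend(frame, selection, prev_axes)
        twists[k] = t
        bends[k] = b
    valid = np.flatnonzero(~np.isnan(twists))
    if valid.size and not absolute:
        twists = twists - twists[valid[0]]
    # sign-continuity unwrap over defined values
    for i, j in zip(valid, valid[1:]):
        step = twists[j] - twists[i]
        twists[j] -= 360.0 * np.round(step / 360.0)
    return TwistSeries(traj.times_ns, twists, bends)
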