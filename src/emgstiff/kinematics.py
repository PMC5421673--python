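"""Sagittal-plane kinematics of the thigh-shank-foot chain.

The global frame sits at the hip: x anterior, y superior, z mediolateral.
All segment frames are right-handed with the same axis convention; file-level
configuration is in metres and degrees, everything here is metres and radians.

The upper ankle joint (articulatio talocruralis) is a single hinge whose axis
is tilted relative to the shank by two angles: ``alpha_TC_tla`` between tibia
long axis and rotation axis, and ``alpha_TC_fml`` between foot mid-line and
rotation axis.  Foot-frame points are mapped into the knee (shank) frame by a
homogeneous transform built from the tilt rotation and the ankle angle, and
muscle path geometry is evaluated on the sagittal projection of the resulting
3-D points, so the projected centre of rotation moves with the ankle angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MUSCLES = ("RF", "HAMS", "VM", "GAS", "SOL", "TA")

#: alias used by some EMG protocols for the instrumented hamstring muscle
HAMS_ALIAS = "ST"


class RangeError(ValueError):
    """A joint angle fell outside its configured validity range."""


class DegenerateLineError(ValueError):
    """The two points defining a muscle's line of action coincide."""


class NoCentreError(ValueError):
    """Perpendicular bisectors are parallel: no instantaneous centre."""


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class AnkleAxisGeometry:
    """Tilted hinge axis of the upper ankle joint.

    ``beta`` and ``gamma`` are derived quantities kept consistent with the
    configured axis angles: beta = alpha_TC_fml - 90 deg,
    gamma = 90 deg - alpha_TC_tla.
    """

    alpha_tc_tla_deg: float = 84.0
    alpha_tc_fml_deg: float = 96.0
    x_trans: float = 0.0
    y_trans: float = -0.43

    @property
    def beta(self) -> float:
        return math.radians(self.alpha_tc_fml_deg - 90.0)

    @property
    def gamma(self) -> float:
        return math.radians(90.0 - self.alpha_tc_tla_deg)


@dataclass
class JointRanges:
    """Validity ranges of the three sagittal joint angles (radians)."""

    hip: tuple[float, float] = (math.radians(-20.0), math.radians(150.0))
    knee: tuple[float, float] = (0.0, math.radians(100.0))
    ankle: tuple[float, float] = (math.radians(-60.0), math.radians(20.0))

    def check(self, joint: str, value: float, clamp: bool = False) -> float:
        lo, hi = getattr(self, joint)
        if lo <= value <= hi:
            return value
        if clamp:
            return min(max(value, lo), hi)
        raise RangeError(
            f"{joint} angle {value:.4f} rad outside [{lo:.4f}, {hi:.4f}]"
        )


@dataclass
class JointConfiguration:
    """Generalised coordinates q = (hip, knee, ankle) in radians."""

    hip: float = 0.0
    knee: float = 0.0
    ankle: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.hip, self.knee, self.ankle])


@dataclass
class MusclePath:
    """Ordered nodal points (origin, via points, insertion) of one muscle.

    Coordinates are non-canonical, literature-style values and are meant to be
    overridden from the geometry configuration file.  Each point is tagged with
    the body frame it is fixed in (``pelvis``, ``thigh``, ``shank``, ``foot``).
    ``effective_origin``/``effective_contact`` index the nodal points that span
    the line of action used for the lever arm (e.g. for TA the retinaculum
    point in the shank and the insertion in the foot).
    """

    name: str
    points: list[tuple[str, np.ndarray]]
    effective_origin: int = 0
    effective_contact: int = -1
    pennation_deg: float = 0.0
    joints: tuple[str, ...] = ("ankle",)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"{self.name}: a path needs at least 2 points")
        if not 0.0 <= self.pennation_deg < 90.0:
            raise ValueError(f"{self.name}: pennation must be in [0, 90) deg")
        self.points = [(f, np.asarray(p, dtype=float)) for f, p in self.points]

    @property
    def pennation(self) -> float:
        return math.radians(self.pennation_deg)


def foot_transform(phi_ankle: float, geom: AnkleAxisGeometry) -> np.ndarray:
    """Homogeneous 4x4 transform mapping foot-frame points to the knee frame.

    T(phi) = Trans(x_trans, y_trans) . Ry(gamma) . Rx(beta) . Rz(phi): at
    phi = 0 only the fixed axis-tilt rotation and the translation remain.
    """
    T = np.eye(4)
    T[:3, :3] = _rot_y(geom.gamma) @ _rot_x(geom.beta) @ _rot_z(phi_ankle)
    T[0, 3] = geom.x_trans
    T[1, 3] = geom.y_trans
    return T


def project_sagittal(point: np.ndarray) -> np.ndarray:
    """Project a global 3-vector onto the sagittal plane (drop z)."""
    point = np.asarray(point, dtype=float)
    return point[..., :2]


def lever_arm(p_ic: np.ndarray, p_o: np.ndarray, p_i: np.ndarray) -> float:
    """Perpendicular distance from the rotation centre to the line of action.

    Implements the 2-D cross-product form |(p_ic - p_o) x (p_i - p_o)| /
    |p_i - p_o|; always non-negative.
    """
    p_ic, p_o, p_i = (np.asarray(p, dtype=float) for p in (p_ic, p_o, p_i))
    d = p_i - p_o
    norm = math.hypot(d[0], d[1])
    if norm < 1e-12:
        raise DegenerateLineError("effective origin and contact point coincide")
    v = p_ic - p_o
    return abs(d[0] * v[1] - d[1] * v[0]) / norm


def contraction_velocity_uni(
    phi_dot: float, dlmt_dphi: float, alpha_p: float
) -> float:
    """Fibre velocity of a uniarticular muscle (rigid tendon)."""
    if not 0.0 <= alpha_p < 0.5 * math.pi:
        raise ValueError("pennation angle must lie in [0, pi/2)")
    c = math.cos(alpha_p)
    return phi_dot * dlmt_dphi / c


def contraction_velocity_bi(
    phi_dot_ankle: float,
    phi_dot_knee: float,
    dlmt_dankle: float,
    dlmt_dknee: float,
    alpha_p: float,
) -> float:
    """Fibre velocity of a biarticular muscle from both joint rates."""
    if not 0.0 <= alpha_p < 0.5 * math.pi:
        raise ValueError("pennation angle must lie in [0, pi/2)")
    c = math.cos(alpha_p)
    return (phi_dot_ankle * dlmt_dankle + phi_dot_knee * dlmt_dknee) / c


def instantaneous_centre(
    points_before: np.ndarray, points_after: np.ndarray
) -> np.ndarray:
    """Centre of a planar displacement from >= 2 tracked points.

    Intersects the perpendicular bisectors of the point displacement chords;
    exact for rigid rotations, raises :class:`NoCentreError` for (near) pure
    translations.
    """
    a = np.asarray(points_before, dtype=float)
    b = np.asarray(points_after, dtype=float)
    mids = 0.5 * (a + b)
    chords = b - a
    # each bisector: chord . (x - mid) = 0  ->  chord . x = chord . mid
    A = chords
    rhs = np.einsum("ij,ij->i", chords, mids)
    scale = np.linalg.norm(chords, axis=1).max()
    if scale < 1e-15:
        raise NoCentreError("no displacement between the tracked points")
    sol, res, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 2 or sv[-1] / sv[0] < 1e-10:
        raise NoCentreError("perpendicular bisectors are parallel")
    return sol


# ---------------------------------------------------------------------------
# default muscle path geometry (non-canonical placeholder coordinates)
# ---------------------------------------------------------------------------

def default_muscle_paths() -> dict[str, MusclePath]:
    """Plausible literature-style nodal points for the six modelled muscles.

    These coordinates are placeholders with anatomically sensible lever arms
    (3-5 cm at the ankle, 2-5 cm at the knee); they are configuration data,
    not canonical values, and can be replaced from the geometry file.
    """
    P = MusclePath
    return {
        "TA": P(
            "TA",
            [
                ("shank", (0.015, -0.08, 0.0)),
                ("shank", (0.035, -0.40, 0.0)),   # retinaculum node
                ("foot", (0.09, -0.01, 0.0)),     # medial cuneiform
            ],
            effective_origin=1,
            effective_contact=2,
            pennation_deg=5.0,
            joints=("ankle",),
        ),
        "SOL": P(
            "SOL",
            [
                ("shank", (-0.02, -0.10, 0.0)),
                ("foot", (-0.045, -0.025, 0.0)),  # calcaneus
            ],
            pennation_deg=25.0,
            joints=("ankle",),
        ),
        "GAS": P(
            "GAS",
            [
                ("thigh", (-0.015, -0.39, 0.0)),  # femoral condyles
                ("foot", (-0.045, -0.025, 0.0)),  # calcaneus
            ],
            pennation_deg=12.0,
            joints=("knee", "ankle"),
        ),
        "RF": P(
            "RF",
            [
                ("pelvis", (0.02, 0.03, 0.0)),
                ("thigh", (0.06, -0.40, 0.0)),    # patella node
                ("shank", (0.045, -0.08, 0.0)),   # tibial tuberosity
            ],
            effective_origin=1,
            effective_contact=2,
            pennation_deg=8.0,
            joints=("hip", "knee"),
        ),
        "VM": P(
            "VM",
            [
                ("thigh", (0.03, -0.20, 0.0)),
                ("thigh", (0.06, -0.40, 0.0)),
                ("shank", (0.045, -0.08, 0.0)),
            ],
            effective_origin=1,
            effective_contact=2,
            pennation_deg=18.0,
            joints=("knee",),
        ),
        "HAMS": P(
            "HAMS",
            [
                ("pelvis", (-0.06, -0.03, 0.0)),  # ischial tuberosity
                ("thigh", (-0.025, -0.38, 0.0)),  # condyle wrap node
                ("shank", (-0.025, -0.06, 0.0)),
            ],
            effective_origin=1,
            effective_contact=2,
            pennation_deg=10.0,
            joints=("hip", "knee"),
        ),
    }


class LowerLimbGeometry:
    """Frame transforms, muscle path lengths and lever arms of the chain."""

    def __init__(
        self,
        axis: AnkleAxisGeometry | None = None,
        paths: dict[str, MusclePath] | None = None,
        ranges: JointRanges | None = None,
        thigh_length: float = 0.41,
        shank_length: float = 0.43,
        ic_delta: float = 1e-3,
    ) -> None:
        self.axis = axis or AnkleAxisGeometry(y_trans=-shank_length)
        self.paths = paths or default_muscle_paths()
        self.ranges = ranges or JointRanges()
        self.thigh_length = thigh_length
        self.shank_length = shank_length
        self.ic_delta = ic_delta
        # foot-frame markers tracked to determine the instantaneous centre
        self._ic_markers = np.array(
            [[0.06, 0.0, 0.0], [-0.05, -0.02, 0.0]]
        )

    # -- frame transforms ---------------------------------------------------

    def _check(self, q: JointConfiguration, clamp: bool) -> JointConfiguration:
        return JointConfiguration(
            self.ranges.check("hip", q.hip, clamp),
            self.ranges.check("knee", q.knee, clamp),
            self.ranges.check("ankle", q.ankle, clamp),
        )

    def knee_centre(self, q: JointConfiguration) -> np.ndarray:
        t1 = q.hip
        return self.thigh_length * np.array([math.sin(t1), -math.cos(t1), 0.0])

    def point_global(
        self, frame: str, p: np.ndarray, q: JointConfiguration
    ) -> np.ndarray:
        """Map a segment-frame point to global 3-D coordinates."""
        p = np.asarray(p, dtype=float)
        if frame == "pelvis":
            return p.copy()
        if frame == "thigh":
            return _rot_z(q.hip) @ p
        theta2 = q.hip - q.knee
        knee = self.knee_centre(q)
        if frame == "shank":
            return knee + _rot_z(theta2) @ p
        if frame == "foot":
            T = foot_transform(q.ankle, self.axis)
            p_shank = T[:3, :3] @ p + T[:3, 3]
            return knee + _rot_z(theta2) @ p_shank
        raise ValueError(f"unknown frame {frame!r}")

    def ankle_centre(self, q: JointConfiguration) -> np.ndarray:
        return self.point_global("foot", np.zeros(3), q)

    def joint_centre(self, joint: str, q: JointConfiguration) -> np.ndarray:
        if joint == "hip":
            return np.zeros(3)
        if joint == "knee":
            return self.knee_centre(q)
        if joint == "ankle":
            return self.ankle_centre(q)
        raise ValueError(f"unknown joint {joint!r}")

    # -- muscle geometry ----------------------------------------------------

    def path_points_sagittal(
        self, name: str, q: JointConfiguration, clamp: bool = False
    ) -> np.ndarray:
        q = self._check(q, clamp)
        path = self.paths[name]
        return np.array(
            [project_sagittal(self.point_global(f, p, q)) for f, p in path.points]
        )

    def mtc_length(
        self, name: str, q: JointConfiguration, clamp: bool = False
    ) -> float:
        """Muscle-tendon-complex length: summed projected segment lengths."""
        pts = self.path_points_sagittal(name, q, clamp)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def ankle_instantaneous_centre(
        self, q: JointConfiguration, delta: float | None = None
    ) -> np.ndarray:
        """Projected ankle centre of rotation for a small angle change.

        Tracks two foot-fixed markers under phi_ankle +/- delta and intersects
        the perpendicular bisectors of their displacement chords.
        """
        d = self.ic_delta if delta is None else delta
        if d == 0.0:
            raise ValueError("delta_phi must be non-zero")
        qm = JointConfiguration(q.hip, q.knee, q.ankle - d)
        qp = JointConfiguration(q.hip, q.knee, q.ankle + d)
        before = np.array(
            [
                project_sagittal(self.point_global("foot", m, qm))
                for m in self._ic_markers
            ]
        )
        after = np.array(
            [
                project_sagittal(self.point_global("foot", m, qp))
                for m in self._ic_markers
            ]
        )
        return instantaneous_centre(before, after)

    def rotation_centre(self, joint: str, q: JointConfiguration) -> np.ndarray:
        """Sagittal-projected rotation centre used by the lever-arm formula."""
        if joint == "ankle":
            return self.ankle_instantaneous_centre(q)
        return project_sagittal(self.joint_centre(joint, q))

    def muscle_lever_arm(
        self, name: str, joint: str, q: JointConfiguration, clamp: bool = False
    ) -> float:
        """Distance-to-line lever arm of a muscle about a joint."""
        q = self._check(q, clamp)
        path = self.paths[name]
        if joint not in path.joints:
            raise ValueError(f"{name} does not act on the {joint}")
        p_o = project_sagittal(
            self.point_global(*path.points[path.effective_origin], q)
        )
        p_i = project_sagittal(
            self.point_global(*path.points[path.effective_contact], q)
        )
        return lever_arm(self.rotation_centre(joint, q), p_o, p_i)


# ---------------------------------------------------------------------------
# fourth-order polynomial geometry tables
# ---------------------------------------------------------------------------

_POLY_DEG = 4


def _fit_poly1d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    V = np.polynomial.polynomial.polyvander(x, _POLY_DEG)
    c, *_ = np.linalg.lstsq(V, y, rcond=None)
    return c


def _fit_poly2d(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    V = np.polynomial.polynomial.polyvander2d(x, y, [_POLY_DEG, _POLY_DEG])
    c, *_ = np.linalg.lstsq(V, z, rcond=None)
    return c.reshape(_POLY_DEG + 1, _POLY_DEG + 1)


@dataclass
class MuscleGeometryTable:
    """Quartic polynomial approximation of l_MT and lever arms of one muscle.

    Uniarticular muscles store univariate quartics in the driving joint angle;
    biarticular muscles store a bivariate quartic surface over both angles
    (first joint is the first axis).  ``signs`` holds the torque direction of
    the muscle about each joint (+1 increases the joint angle), derived from
    the sign of dl_MT/dphi at mid-range.
    """

    name: str
    joints: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    length_coef: np.ndarray
    lever_coef: dict[str, np.ndarray]
    signs: dict[str, int]
    pennation: float
    fit_residual_length: float
    fit_residual_lever: float
    clamp_default: bool = False

    # -- evaluation ---------------------------------------------------------

    def _coef(self, which: str, joint: str | None, order: int):
        """Cached plain-list coefficients of a (derived) polynomial."""
        cache = self.__dict__.setdefault("_coef_cache", {})
        key = (which, joint, order)
        if key not in cache:
            coef = self.length_coef if which == "length" else self.lever_coef[joint]
            if order:
                axis = self.joints.index(joint)
                for _ in range(order):
                    coef = np.polynomial.polynomial.polyder(coef, axis=axis)
            c = np.atleast_1d(np.asarray(coef, dtype=float))
            cache[key] = c.tolist() if c.ndim == 1 else [r for r in c.tolist()]
        return cache[key]

    @staticmethod
    def _horner(coef, ang: list[float]) -> float:
        if len(ang) == 1:
            x = ang[0]
            r = 0.0
            for a in reversed(coef):
                r = r * x + a
            return r
        x, y = ang
        r = 0.0
        for row in reversed(coef):
            ry = 0.0
            for a in reversed(row):
                ry = ry * y + a
            r = r * x + ry
        return r

    def _angles(self, q: dict[str, float], clamp: bool | None) -> list[float]:
        clamp = self.clamp_default if clamp is None else clamp
        out = []
        for j in self.joints:
            lo, hi = self.ranges[j]
            v = q[j]
            if not lo <= v <= hi:
                if not clamp:
                    raise RangeError(
                        f"{self.name}: {j} angle {v:.4f} outside table range"
                    )
                v = min(max(v, lo), hi)
            out.append(v)
        return out

    def length(self, clamp: bool | None = None, **q: float) -> float:
        return self._horner(self._coef("length", None, 0), self._angles(q, clamp))

    def dlength(self, joint: str, clamp: bool | None = None, **q: float) -> float:
        """dl_MT/dphi_joint: also the virtual-displacement lever arm (signed)."""
        return self._horner(
            self._coef("length", joint, 1), self._angles(q, clamp)
        )

    def d2length(self, joint: str, clamp: bool | None = None, **q: float) -> float:
        return self._horner(
            self._coef("length", joint, 2), self._angles(q, clamp)
        )

    def dlength_mixed(
        self, j1: str, j2: str, clamp: bool | None = None, **q: float
    ) -> float:
        """Mixed second partial of l_MT over two driving joints."""
        if j1 == j2:
            return self.d2length(j1, clamp=clamp, **q)
        cache = self.__dict__.setdefault("_coef_cache", {})
        key = ("length-mixed", j1, j2)
        if key not in cache:
            coef = self.length_coef
            for j in (j1, j2):
                coef = np.polynomial.polynomial.polyder(
                    coef, axis=self.joints.index(j)
                )
            c = np.atleast_1d(np.asarray(coef, dtype=float))
            cache[key] = c.tolist()
        return self._horner(cache[key], self._angles(q, clamp))

    def lever(self, joint: str, clamp: bool | None = None, **q: float) -> float:
        return self._horner(self._coef("lever", joint, 0), self._angles(q, clamp))

    def dlever(self, joint: str, clamp: bool | None = None, **q: float) -> float:
        return self._horner(
            self._coef("lever", joint, 1), self._angles(q, clamp)
        )

    def contraction_velocity(
        self, rates: dict[str, float], clamp: bool | None = None, **q: float
    ) -> float:
        """Fibre velocity from joint rates (lengthening positive)."""
        total = sum(
            rates.get(j, 0.0) * self.dlength(j, clamp=clamp, **q)
            for j in self.joints
        )
        return total / math.cos(self.pennation)


def lever_arm_virtual(
    table: MuscleGeometryTable, joint: str, clamp: bool | None = None, **q: float
) -> float:
    """Signed lever arm from the principle of virtual displacements.

    Returns dl_MT/dphi_joint; used for cross-validation against the
    distance-to-line lever arms, which it is not required to equal.
    """
    return table.dlength(joint, clamp=clamp, **q)


def fit_geometry_polynomials(
    geometry: LowerLimbGeometry,
    name: str,
    grid_step_deg: float = 1.0,
) -> MuscleGeometryTable:
    """Fit quartic l_MT and lever-arm tables on a 1-degree evaluation grid."""
    path = geometry.paths[name]
    joints = path.joints
    step = math.radians(grid_step_deg)
    grids = {}
    for j in joints:
        lo, hi = getattr(geometry.ranges, j)
        n = int(round((hi - lo) / step)) + 1
        if n < _POLY_DEG + 1:
            raise ValueError(f"{name}/{j}: grid too coarse for a quartic fit")
        grids[j] = np.linspace(lo, hi, n)

    def q_of(vals: dict[str, float]) -> JointConfiguration:
        return JointConfiguration(
            vals.get("hip", 0.0), vals.get("knee", 0.0), vals.get("ankle", 0.0)
        )

    if len(joints) == 1:
        (j,) = joints
        x = grids[j]
        L = np.array([geometry.mtc_length(name, q_of({j: v})) for v in x])
        R = np.array(
            [geometry.muscle_lever_arm(name, j, q_of({j: v})) for v in x]
        )
        cl = _fit_poly1d(x, L)
        cr = {j: _fit_poly1d(x, R)}
        res_l = float(
            np.max(np.abs(np.polynomial.polynomial.polyval(x, cl) - L))
        )
        res_r = float(
            np.max(np.abs(np.polynomial.polynomial.polyval(x, cr[j]) - R))
        )
    else:
        ja, jb = joints
        A, B = np.meshgrid(grids[ja], grids[jb], indexing="ij")
        a, b = A.ravel(), B.ravel()
        L = np.array(
            [geometry.mtc_length(name, q_of({ja: u, jb: v})) for u, v in zip(a, b)]
        )
        cl = _fit_poly2d(a, b, L)
        cr = {}
        res_r = 0.0
        # lever arms are tabulated only where muscle torques enter the
        # dynamics (knee, ankle); the hip torque is an unknown input and the
        # hip only contributes through l_MT and its partials
        for j in (jj for jj in joints if jj != "hip"):
            R = np.array(
                [
                    geometry.muscle_lever_arm(name, j, q_of({ja: u, jb: v}))
                    for u, v in zip(a, b)
                ]
            )
            cr[j] = _fit_poly2d(a, b, R)
            res_r = max(
                res_r,
                float(
                    np.max(
                        np.abs(
                            np.polynomial.polynomial.polyval2d(a, b, cr[j]) - R
                        )
                    )
                ),
            )
        res_l = float(
            np.max(np.abs(np.polynomial.polynomial.polyval2d(a, b, cl) - L))
        )

    ranges = {j: (float(grids[j][0]), float(grids[j][-1])) for j in joints}
    table = MuscleGeometryTable(
        name=name,
        joints=joints,
        ranges=ranges,
        length_coef=cl,
        lever_coef=cr,
        signs={},
        pennation=path.pennation,
        fit_residual_length=res_l,
        fit_residual_lever=res_r,
    )
    # torque sign: a muscle that shortens as the angle grows pulls the joint
    # in the direction of increasing angle
    mid = {j: 0.5 * (ranges[j][0] + ranges[j][1]) for j in joints}
    for j in joints:
        table.signs[j] = -1 if table.dlength(j, **mid) > 0 else 1
    return table


def build_geometry_tables(
    geometry: LowerLimbGeometry, grid_step_deg: float = 1.0
) -> dict[str, MuscleGeometryTable]:
    return {
        name: fit_geometry_polynomials(geometry, name, grid_step_deg)
        for name in geometry.paths
    }
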