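"""Geometric model of a 7-DOF anthropomorphic right arm.

The arm is a serial chain of three segments (upper arm, forearm, hand)
articulated by a 3-DOF shoulder (abduction, flexion, rotation), a 2-DOF
elbow (flexion, pronation) and a 2-DOF wrist (flexion, abduction).  The
end effector sits at the fingertip of an outstretched middle finger.

Frame convention (right-handed): x forward (away from the body), y left,
z up; the shoulder is at the origin.  In the zero pose the arm is fully
extended along +x with the palm facing -z (palm down).  Positive shoulder
abduction rotates the arm about +z (towards +y), positive shoulder and
wrist flexion rotate about +y (lowering the distal segment towards -z),
positive elbow flexion rotates about -y (raising the forearm towards +z,
as a palm-down arm flexes anatomically), and shoulder rotation and elbow
pronation spin the limb about its own +x axis.

All public interfaces use degrees; radians are internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JOINT_NAMES",
    "ArmModel",
    "Pose",
    "ReachabilityError",
    "JointLimitError",
    "forward_kinematics",
    "inverse_kinematics_swivel",
]

#: Order of the seven joint angles in every joint vector.
JOINT_NAMES = ("s_abd", "s_flex", "s_rot", "e_flex", "e_pron", "w_flex", "w_abd")

#: Indices of the five recorded channels, in dataset order
#: (S_rot, S_flex, S_abd, E_pron, E_flex).
RECORDED_JOINTS = (2, 1, 0, 4, 3)

_DEFAULT_LIMITS_DEG = {
    "s_abd": (-30.0, 180.0),
    "s_flex": (-60.0, 180.0),
    "s_rot": (-165.0, 165.0),
    "e_flex": (0.0, 150.0),
    "e_pron": (-90.0, 90.0),
    "w_flex": (-70.0, 70.0),
    "w_abd": (-70.0, 70.0),
}


class ReachabilityError(ValueError):
    """Raised when a fingertip target lies outside the arm's workspace."""


class JointLimitError(ValueError):
    """Raised when an inverse-kinematics solution violates joint limits."""


@dataclass(frozen=True)
class ArmModel:
    """Segment lengths, base position and joint limits of the arm.

    Default lengths (0.30, 0.25, 0.18) m are typical adult anthropometry
    for upper arm, forearm and hand (shoulder to fingertip via elbow and
    wrist).
    """

    upper_arm_len: float = 0.30
    forearm_len: float = 0.25
    hand_len: float = 0.18
    shoulder_origin: np.ndarray = field(
        default_factory=lambda: np.zeros(3), repr=False
    )
    joint_limits_deg: np.ndarray = field(
        default_factory=lambda: np.array(
            [_DEFAULT_LIMITS_DEG[n] for n in JOINT_NAMES]
        ),
        repr=False,
    )

    def __post_init__(self):
        if min(self.upper_arm_len, self.forearm_len, self.hand_len) <= 0:
            raise ValueError("segment lengths must be positive")
        object.__setattr__(
            self, "shoulder_origin", np.asarray(self.shoulder_origin, dtype=float)
        )
        lim = np.asarray(self.joint_limits_deg, dtype=float)
        if lim.shape != (7, 2) or np.any(lim[:, 0] >= lim[:, 1]):
            raise ValueError("joint_limits_deg must be (7, 2) with min < max")
        object.__setattr__(self, "joint_limits_deg", lim)

    @property
    def reach(self) -> float:
        """Total arm length: maximum fingertip distance from the shoulder."""
        return self.upper_arm_len + self.forearm_len + self.hand_len

    # -- config serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "segment_lengths": [
                self.upper_arm_len, self.forearm_len, self.hand_len
            ],
            "shoulder_origin": list(map(float, self.shoulder_origin)),
            "joint_limits_deg": {
                name: list(map(float, self.joint_limits_deg[i]))
                for i, name in enumerate(JOINT_NAMES)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmModel":
        kwargs = {}
        if "segment_lengths" in d:
            lu, lf, lh = d["segment_lengths"]
            kwargs.update(upper_arm_len=lu, forearm_len=lf, hand_len=lh)
        if "shoulder_origin" in d:
            kwargs["shoulder_origin"] = np.asarray(d["shoulder_origin"], float)
        if "joint_limits_deg" in d:
            lim = d["joint_limits_deg"]
            kwargs["joint_limits_deg"] = np.array(
                [lim[name] for name in JOINT_NAMES], dtype=float
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class Pose:
    """Task-space pose of the arm: key points in metres, palm normal unit."""

    fingertip: np.ndarray
    elbow_point: np.ndarray
    palm_normal: np.ndarray


def _rot_x(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _rot_y(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 1, 1] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _rot_z(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 2, 2] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def forward_kinematics(arm: ArmModel, q_deg: np.ndarray) -> Pose:
    """Fingertip, elbow point and palm normal for joint angles ``q_deg``.

    ``q_deg`` is a length-7 vector (or an (..., 7) batch) ordered per
    :data:`JOINT_NAMES`, in degrees.
    """
    q = np.asarray(q_deg, dtype=float)
    if q.shape[-1] != 7:
        raise ValueError(f"expected 7 joint angles, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("joint angles must be finite")
    r = np.deg2rad(q)

    r1 = _rot_z(r[..., 0]) @ _rot_y(r[..., 1]) @ _rot_x(r[..., 2])
    elbow = arm.shoulder_origin + arm.upper_arm_len * r1[..., :, 0]
    r2 = r1 @ _rot_y(-r[..., 3]) @ _rot_x(r[..., 4])
    wrist = elbow + arm.forearm_len * r2[..., :, 0]
    r3 = r2 @ _rot_y(r[..., 5]) @ _rot_z(r[..., 6])
    fingertip = wrist + arm.hand_len * r3[..., :, 0]
    palm_normal = -r3[..., :, 2]
    return Pose(fingertip=fingertip, elbow_point=elbow, palm_normal=palm_normal)


def _euler_zyx(
    r1: np.ndarray, limits_rad: np.ndarray, path_continuity: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angles (z, y, x) such that Rz(a) Ry(f) Rx(g) == r1 (batched).

    Each rotation matrix has two Euler branches (cos f >= 0 and
    cos f <= 0).  For independent targets the branch that best respects
    ``limits_rad`` (shoulder abd/flex/rot limit rows) is returned,
    preferring small abduction on ties.  For sampled paths
    (``path_continuity``) the branch closest to the previous sample's
    angles is chosen instead and the result is unwrapped, so joint
    trajectories never jump between equivalent representations
    mid-path.  Also returns a per-sample feasibility mask: whether at
    least one branch lies within the limits (the physical pose is then
    achievable even when the continuous representation sweeps outside
    the box near the Euler singularity).
    """
    sf = np.clip(-r1[..., 2, 0], -1.0, 1.0)
    f_a = np.arcsin(sf)
    a_a = np.arctan2(r1[..., 1, 0], r1[..., 0, 0])
    g_a = np.arctan2(r1[..., 2, 1], r1[..., 2, 2])
    f_b = np.where(f_a >= 0, np.pi - f_a, -np.pi - f_a)
    a_b = np.arctan2(-r1[..., 1, 0], -r1[..., 0, 0])
    g_b = np.arctan2(-r1[..., 2, 1], -r1[..., 2, 2])
    branches = np.stack(
        [np.stack([a_a, f_a, g_a], axis=-1), np.stack([a_b, f_b, g_b], axis=-1)],
        axis=0,
    )  # (2, n, 3)

    def violation(angles):
        lo, hi = limits_rad[:, 0], limits_rad[:, 1]
        return np.maximum(lo - angles, angles - hi).clip(min=0).sum(axis=-1)

    v_a = violation(branches[0])
    v_b = violation(branches[1])
    feasible = np.minimum(v_a, v_b) <= 1e-9
    pick_b = (v_b < v_a - 1e-12) | (
        (np.abs(v_b - v_a) <= 1e-12) & (np.abs(a_b) < np.abs(a_a))
    )
    if path_continuity and branches.shape[1] > 1:
        chosen = np.empty_like(branches[0])
        prev = branches[1 if pick_b[0] else 0, 0]
        chosen[0] = prev
        for k in range(1, branches.shape[1]):
            diff = branches[:, k, :] - prev
            dist = np.abs((diff + np.pi) % (2 * np.pi) - np.pi).sum(axis=-1)
            prev = branches[int(np.argmin(dist)), k]
            chosen[k] = prev
        chosen = np.unwrap(chosen, axis=0)
        return chosen[:, 0], chosen[:, 1], chosen[:, 2], feasible
    out = np.where(pick_b[..., None], branches[1], branches[0])
    return out[..., 0], out[..., 1], out[..., 2], feasible


def inverse_kinematics_swivel(
    arm: ArmModel,
    fingertip_target: np.ndarray,
    swivel_deg: float | np.ndarray,
    palm_down: bool = True,
    check_limits: bool = True,
    path_continuity: bool = True,
) -> np.ndarray:
    """Joint angles that place the fingertip at ``fingertip_target``.

    The arm's kinematic redundancy is resolved by the swivel angle: the
    elbow lies on its redundancy circle about the shoulder-fingertip
    axis, rotated ``swivel_deg`` away from the lowest (vertical-plane)
    reference position, with positive swivel swinging the elbow outward
    (towards -y, away from the body for a right arm).  The wrist is held
    neutral so the hand extends the forearm, and elbow pronation is
    chosen so the palm normal comes as close to straight down as the
    forearm axis permits (``palm_down``) or is left at zero.

    Accepts a single 3-vector or an (N, 3) batch of targets (with scalar
    or per-target swivel) and returns joint angles in degrees, shape
    (7,) or (N, 7).  A batch is treated as a sampled path
    (``path_continuity``): the shoulder Euler branch follows the
    previous sample instead of being re-selected per sample, keeping
    joint trajectories continuous.

    Raises :class:`ReachabilityError` for targets outside the annular
    workspace and :class:`JointLimitError` if the solution violates the
    arm's joint limits (``check_limits``).
    """
    p = np.asarray(fingertip_target, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    # Positive swivel rotates the elbow outward (-y) for a right arm.
    phi = -np.deg2rad(
        np.broadcast_to(np.asarray(swivel_deg, float), p.shape[:1])
    )

    l1 = arm.upper_arm_len
    l2 = arm.forearm_len + arm.hand_len
    v = p - arm.shoulder_origin
    d = np.linalg.norm(v, axis=-1)
    if np.any(d >= l1 + l2 - 1e-12) or np.any(d <= abs(l1 - l2) + 1e-12):
        raise ReachabilityError(
            f"target distance outside reachable annulus ({abs(l1-l2):.3f}, "
            f"{l1+l2:.3f}) m"
        )

    axis = v / d[:, None]
    # Reference direction for swivel 0: straight down, projected onto the
    # plane orthogonal to the shoulder-fingertip axis.
    down = np.array([0.0, 0.0, -1.0])
    n0 = down - axis * (axis @ down)[:, None]
    n0_norm = np.linalg.norm(n0, axis=-1)
    vertical = n0_norm < 1e-9  # target straight below/above the shoulder
    if np.any(vertical):
        fallback = np.array([1.0, 0.0, 0.0]) - axis * axis[:, 0:1]
        n0 = np.where(vertical[:, None], fallback, n0)
        n0_norm = np.linalg.norm(n0, axis=-1)
    n0 /= n0_norm[:, None]

    # Elbow on the redundancy circle (law of cosines at the shoulder).
    cos_a = np.clip((l1**2 + d**2 - l2**2) / (2 * l1 * d), -1.0, 1.0)
    sin_a = np.sqrt(1.0 - cos_a**2)
    # Rodrigues rotation of n0 about the shoulder-fingertip axis by phi.
    cph, sph = np.cos(phi)[:, None], np.sin(phi)[:, None]
    m = (
        n0 * cph
        + np.cross(axis, n0) * sph
        + axis * (np.sum(axis * n0, axis=-1, keepdims=True)) * (1 - cph)
    )
    u1 = cos_a[:, None] * axis + sin_a[:, None] * m
    elbow = arm.shoulder_origin + l1 * u1
    u2 = p - elbow
    u2 /= np.linalg.norm(u2, axis=-1)[:, None]

    cos_e = np.clip(np.sum(u1 * u2, axis=-1), -1.0, 1.0)
    theta_e = np.arccos(cos_e)
    sin_e = np.sin(theta_e)
    # Shoulder frame: column 1 is the upper-arm axis; column 3 follows from
    # the forearm direction (u2 = cos(theta_e) c1 + sin(theta_e) c3, since
    # elbow flexion is a rotation about the local -y axis).
    c1 = u1
    straight = sin_e < 1e-9
    safe_sin = np.where(straight, 1.0, sin_e)
    c3 = (u2 - cos_e[:, None] * u1) / safe_sin[:, None]
    if np.any(straight):
        c3 = np.where(straight[:, None], -m, c3)
    c2 = np.cross(c3, c1)
    r1 = np.stack([c1, c2, c3], axis=-1)

    path_mode = path_continuity and not single
    s_abd, s_flex, s_rot, shoulder_ok = _euler_zyx(
        r1, np.deg2rad(arm.joint_limits_deg[:3]), path_continuity=path_mode
    )

    q = np.zeros((p.shape[0], 7))
    q[:, 0] = s_abd
    q[:, 1] = s_flex
    q[:, 2] = s_rot
    q[:, 3] = theta_e
    if palm_down:
        m23 = r1 @ _rot_y(-theta_e)
        # Palm normal after pronation rho is sin(rho) m2 - cos(rho) m3;
        # choose rho maximising alignment with straight down.
        m2z = m23[:, 2, 1]
        m3z = m23[:, 2, 2]
        rho = np.arctan2(-m2z, m3z)
        q[:, 4] = np.unwrap(rho) if path_mode else rho
    q = np.rad2deg(q)

    if check_limits:
        # Shoulder: the pose must have some in-limits Euler branch (the
        # continuous path representation itself may sweep outside the
        # box near the flexion = 90 deg singularity).
        if np.any(~shoulder_ok):
            k = int(np.argmin(shoulder_ok))
            raise JointLimitError(
                f"shoulder pose at sample {k} has no representation inside "
                f"the joint limits"
            )
        lo, hi = arm.joint_limits_deg[3:, 0], arm.joint_limits_deg[3:, 1]
        bad = (q[:, 3:] < lo - 1e-9) | (q[:, 3:] > hi + 1e-9)
        if np.any(bad):
            idx = np.argwhere(bad)[0]
            raise JointLimitError(
                f"IK solution violates limit on joint {JOINT_NAMES[3 + idx[1]]} "
                f"(value {q[idx[0], 3 + idx[1]]:.2f} deg)"
            )
    return q[0] if single else q
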