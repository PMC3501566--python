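"""Rigid-body dynamics of a virtual hammer: a point mass on a massless rod.

The tool is rotated in the horizontal plane about its handle.  For a head
mass ``m`` at rod length ``r`` and rod bearing ``theta(t)`` the head sits at
``p(t) = r*u(theta)``, so the translational force the subject must supply at
the handle to rotate the tool (handle held fixed) is

    F(t) = m * p''(t) = m * r * (alpha(t) * u_perp - omega(t)^2 * u)

with ``omega``/``alpha`` the angular velocity/acceleration in radians and
``u_perp`` the CCW normal of ``u``.  The accompanying torque about the
vertical axis is ``tau = m * r^2 * alpha``.

Angular trajectories follow a Gaussian angular-velocity profile truncated at
+/-3 sigma (sigma = duration/6) and renormalized so the integrated angle
equals the movement amplitude exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.signal import lfilter
from scipy.special import erf

from .angles import bearing_to_vec, vec_to_bearing, wrap_deg

__all__ = [
    "ToolSpec",
    "KinematicProfile",
    "LoadSeries",
    "HandImpedance",
    "TrialCondition",
    "make_velocity_profile",
    "simulate_tool_loads",
    "predicted_force_offset",
    "simulate_handle_motion",
    "first_peak_index",
]

TrialCondition = Literal["full_dynamics", "error_clamp", "zero_force"]

#: number of sigma at which the Gaussian velocity profile is truncated
PROFILE_TRUNCATION_SIGMA = 3.0


@dataclass(frozen=True)
class ToolSpec:
    """Virtual hammer: point head mass on a rigid, massless rod.

    ``visual_orientation`` is the orientation shown to the subject;
    ``dynamics_orientation`` is the orientation the simulated loads obey.
    They coincide for congruent tools and differ by 180 deg for
    incongruent ones.
    """

    head_mass: float  # kg
    rod_length: float = 0.3  # m
    visual_orientation: float = 0.0  # deg, CCW-positive
    dynamics_orientation: float = 0.0  # deg
    body_mass_fraction: Optional[float] = None  # head mass as % body mass

    def __post_init__(self):
        if self.head_mass < 0:
            raise ValueError("head_mass must be >= 0")
        if self.rod_length <= 0:
            raise ValueError("rod_length must be > 0")
        object.__setattr__(
            self, "visual_orientation", wrap_deg(self.visual_orientation)
        )
        object.__setattr__(
            self, "dynamics_orientation", wrap_deg(self.dynamics_orientation)
        )

    @property
    def congruent(self) -> bool:
        return bool(
            np.isclose(self.visual_orientation, self.dynamics_orientation)
        )


@dataclass(frozen=True)
class KinematicProfile:
    """Time-sampled rotation trajectory (angles in degrees)."""

    amplitude: float  # deg, signed (+ CCW)
    duration: float  # s
    sample_rate: float  # Hz
    times: np.ndarray = field(repr=False)  # s
    omega: np.ndarray = field(repr=False)  # deg/s
    alpha: np.ndarray = field(repr=False)  # deg/s^2
    theta: np.ndarray = field(repr=False)  # deg, relative to start

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LoadSeries:
    """Handle loads over time: planar force (N) and vertical-axis torque (N m)."""

    times: np.ndarray = field(repr=False)
    force: np.ndarray = field(repr=False)  # (n, 2) in N
    torque: np.ndarray = field(repr=False)  # (n,) in N m

    def __post_init__(self):
        if not (len(self.times) == len(self.force) == len(self.torque)):
            raise ValueError("LoadSeries: mismatched series lengths")


@dataclass(frozen=True)
class HandImpedance:
    """Lumped hand/arm plant at the handle plus the error-clamp spring."""

    effective_mass: float = 2.0  # kg
    damping: float = 8.0  # N s/m
    clamp_stiffness: float = 1.0e4  # N/m

    def __post_init__(self):
        for name in ("effective_mass", "damping", "clamp_stiffness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_velocity_profile(
    amplitude: float, duration: float = 0.7, sample_rate: float = 1000.0
) -> KinematicProfile:
    """Gaussian angular-velocity profile for a rotation of ``amplitude`` deg.

    The bell is truncated to +/-3 sigma (sigma = duration/6), shifted to span
    [0, duration] and renormalized so the integrated angle equals the
    amplitude; ``alpha`` and ``theta`` are the analytic derivative and
    integral of the same truncated Gaussian.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sample_rate < 100.0:
        raise ValueError("sample_rate must be >= 100 Hz")
    if amplitude == 0:
        raise ValueError("amplitude must be nonzero")

    sigma = duration / (2.0 * PROFILE_TRUNCATION_SIGMA)
    mu = duration / 2.0
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    z = (t - mu) / sigma
    # mass of the Gaussian inside the truncation window
    phi = lambda x: 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    w = phi(PROFILE_TRUNCATION_SIGMA) - phi(-PROFILE_TRUNCATION_SIGMA)
    dens = np.exp(-0.5 * z**2) / (sigma * np.sqrt(2.0 * np.pi) * w)
    omega = amplitude * dens
    alpha = -z / sigma * omega
    theta = amplitude * (phi(z) - phi(-PROFILE_TRUNCATION_SIGMA)) / w
    return KinematicProfile(
        amplitude=float(amplitude),
        duration=float(duration),
        sample_rate=float(sample_rate),
        times=t,
        omega=omega,
        alpha=alpha,
        theta=theta,
    )


def simulate_tool_loads(tool: ToolSpec, profile: KinematicProfile) -> LoadSeries:
    """Handle force and torque required for a pure rotation of the tool.

    The rotation starts at the tool's ``dynamics_orientation`` and follows
    ``profile.theta``; the handle is assumed fixed.
    """
    th = tool.dynamics_orientation + profile.theta  # deg bearing of the rod
    u = bearing_to_vec(th)
    u_perp = bearing_to_vec(th + 90.0)
    om = np.deg2rad(profile.omega)
    al = np.deg2rad(profile.alpha)
    mr = tool.head_mass * tool.rod_length
    force = mr * (al[:, None] * u_perp - (om**2)[:, None] * u)
    torque = tool.head_mass * tool.rod_length**2 * al
    return LoadSeries(times=profile.times, force=force, torque=torque)


def first_peak_index(magnitude: np.ndarray, rel_tol: float = 1e-9) -> int:
    """Index of the earliest sample within ``rel_tol`` of the global maximum.

    A symmetric rotation profile has equal acceleration- and
    deceleration-phase force maxima; this tie-break selects the
    acceleration-phase (earlier) one deterministically.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    m = magnitude.max()
    return int(np.flatnonzero(magnitude >= m * (1.0 - rel_tol))[0])


def predicted_force_offset(
    rotation_direction: str,
    amplitude: float = 40.0,
    profile: Optional[KinematicProfile] = None,
) -> float:
    """Predicted angle between the presented tool orientation and the
    compensatory force at peak force magnitude (deg, CCW-positive).

    The trial presents the tool at the midpoint of the rotation (the start
    and target bars sit at -/+ amplitude/2 around it) and the offset is
    reported in the display frame, which is mirror-reflected relative to the
    force frame: ``offset = wrap(180 - (force_dir - presented))``.  With a
    Gaussian velocity profile and a 40 deg rotation this gives -93.1 deg for
    CW and +93.1 deg for CCW rotations, independent of head mass, rod length
    and movement duration (these scale out).
    """
    if rotation_direction not in ("CW", "CCW"):
        raise ValueError("rotation_direction must be 'CW' or 'CCW'")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive (sign comes from direction)")
    signed = amplitude if rotation_direction == "CCW" else -amplitude
    if profile is None:
        profile = make_velocity_profile(signed)
    elif not np.isclose(profile.amplitude, signed):
        raise ValueError("profile amplitude does not match rotation direction")
    if np.allclose(profile.omega, 0.0):
        raise ValueError("degenerate profile: all-zero angular velocity")
    presented = 0.0
    start = presented - signed / 2.0
    tool = ToolSpec(head_mass=1.0, rod_length=1.0, dynamics_orientation=start)
    loads = simulate_tool_loads(tool, profile)
    mag = np.linalg.norm(loads.force, axis=1)
    i = first_peak_index(mag)
    F = loads.force[i]
    if 0 < i < len(mag) - 1:
        # sub-sample peak refinement: parabola through the three samples
        # around the maximum, force components interpolated at its vertex
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            d = 0.5 * (y0 - y2) / denom
            d = float(np.clip(d, -0.5, 0.5))
            a = loads.force[i - 1], loads.force[i], loads.force[i + 1]
            F = (
                a[1]
                + 0.5 * d * (a[2] - a[0])
                + 0.5 * d * d * (a[2] - 2.0 * a[1] + a[0])
            )
    force_dir = vec_to_bearing(F)
    return float(wrap_deg(180.0 - (force_dir - presented)))


def simulate_handle_motion(
    applied_force: np.ndarray,
    condition: TrialCondition,
    tool: ToolSpec,
    impedance: HandImpedance,
    times: Optional[np.ndarray] = None,
    profile: Optional[KinematicProfile] = None,
) -> np.ndarray:
    """Handle displacement (m) produced by ``applied_force`` under a trial
    condition.

    error_clamp:   quasi-static deflection of the stiff clamp spring
                   (idealized; the measured force equals the applied force).
    zero_force:    effective_mass * x'' + damping * x' = F, from rest.
    full_dynamics: same plant driven by F minus the required tool load
                   (computed from ``tool`` and ``profile``).
    """
    F = np.asarray(applied_force, dtype=float)
    if F.ndim != 2 or F.shape[1] != 2:
        raise ValueError("applied_force must have shape (n, 2)")
    if condition == "error_clamp":
        return F / impedance.clamp_stiffness
    if condition == "full_dynamics":
        if profile is None:
            raise ValueError("full_dynamics requires the rotation profile")
        req = simulate_tool_loads(tool, profile).force
        if req.shape != F.shape:
            raise ValueError("applied force and required load length mismatch")
        F = F - req
        times = profile.times if times is None else times
    elif condition != "zero_force":
        raise ValueError(f"unknown condition: {condition!r}")
    if impedance.effective_mass <= 0:
        raise ValueError("zero effective_mass: free-handle motion undefined")
    if times is None:
        raise ValueError("times required for free-handle conditions")
    dt = float(times[1] - times[0])
    m, b = impedance.effective_mass, impedance.damping
    if b > 0:
        # exact response of m v' + b v = F for stepwise-constant force
        a = np.exp(-b * dt / m)
        v = lfilter([(1.0 - a) / b], [1.0, -a], F, axis=0)
    else:
        v = np.cumsum(F, axis=0) * dt / m
    v = np.vstack([np.zeros((1, 2)), v[:-1]])  # starts from rest
    x = np.cumsum(v, axis=0) * dt
    return x
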