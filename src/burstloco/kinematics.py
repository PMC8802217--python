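"""Marker smoothing and the kinematic velocity profile.

Hip-marker coordinates are fit per axis with a quintic smoothing spline
(default tolerance 0.75 mm^2), which suppresses digitizing noise and
interpolates frames where the marker was not visible. The spline's analytic
first derivative gives the sagittal-plane velocity profile around limb
contact, whose pre-contact mean seeds the initial-velocity estimate that the
kinetics module later refines against the force record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from .errors import InsufficientDataError
from .io import MarkerTrajectory

__all__ = ["SmoothedTrajectory", "VelocityProfile",
           "smooth_trajectory", "kinematic_velocity_window"]

DEFAULT_TOLERANCE_MM2 = 0.75


@dataclass
class SmoothedTrajectory:
    """Spline-smoothed marker path, defined on the full frame range."""

    time: np.ndarray
    position: np.ndarray   # (n, 3) m, gaps interpolated
    velocity: np.ndarray   # (n, 3) m/s, analytic spline derivative
    residual_rms_m: float  # per-coordinate RMS residual vs visible frames
    splines: tuple         # per-axis UnivariateSpline objects

    def position_at(self, t: np.ndarray) -> np.ndarray:
        return np.column_stack([s(t) for s in self.splines])

    def velocity_at(self, t: np.ndarray) -> np.ndarray:
        return np.column_stack([s.derivative()(t) for s in self.splines])


def smooth_trajectory(markers: MarkerTrajectory,
                      tolerance_mm2: float = DEFAULT_TOLERANCE_MM2,
                      mode: str = "per-frame") -> SmoothedTrajectory:
    """Fit per-axis quintic smoothing splines to the visible frames.

    ``tolerance_mm2`` bounds the squared residual of the fit; with
    ``mode='per-frame'`` the bound applies to the mean squared residual per
    visible frame (total SSR <= tolerance * n_visible), with ``mode='total'``
    to the summed squared residual. Positions and velocities are evaluated at
    every frame, including dropped ones.
    """
    if tolerance_mm2 <= 0:
        raise ValueError("tolerance must be > 0")
    vis = markers.visible
    n_vis = int(vis.sum())
    if n_vis < 7:
        raise InsufficientDataError(f"only {n_vis} visible frames; need >= 7")
    tol_m2 = tolerance_mm2 * 1e-6
    s = tol_m2 * n_vis if mode == "per-frame" else tol_m2

    t_vis = markers.time[vis]
    splines = tuple(
        UnivariateSpline(t_vis, markers.position[vis, axis], k=5, s=s)
        for axis in range(3)
    )
    position = np.column_stack([sp(markers.time) for sp in splines])
    velocity = np.column_stack([sp.derivative()(markers.time) for sp in splines])
    resid = position[vis] - markers.position[vis]
    residual_rms = float(np.sqrt(np.mean(resid**2)))
    return SmoothedTrajectory(time=markers.time, position=position,
                              velocity=velocity, residual_rms_m=residual_rms,
                              splines=splines)


@dataclass
class VelocityProfile:
    """Sagittal-plane marker velocity over the contact window."""

    time: np.ndarray
    v_fa: np.ndarray      # fore-aft velocity, m/s
    v_vert: np.ndarray    # vertical velocity, m/s
    speed: np.ndarray     # sagittal-plane speed magnitude, m/s
    v0_seed: float        # mean fore-aft velocity over pre-contact frames


def kinematic_velocity_window(traj: SmoothedTrajectory,
                              contact_start: float,
                              contact_end: float | None = None,
                              frames_before: int = 10,
                              frames_after: int = 10) -> VelocityProfile:
    """Velocity profile from ``frames_before`` frames before contact to
    ``frames_after`` frames after the contact period.

    The sagittal plane is fore-aft x vertical; mediolateral motion is
    ignored. ``v0_seed`` is the mean fore-aft velocity over the strictly
    pre-contact frames of the window.
    """
    if contact_end is None:
        contact_end = contact_start
    if contact_end < contact_start:
        raise ValueError("contact_end precedes contact_start")
    dt = float(np.median(np.diff(traj.time)))
    t_lo = contact_start - frames_before * dt
    t_hi = contact_end + frames_after * dt
    eps = 0.5 * dt
    if t_lo < traj.time[0] - eps or t_hi > traj.time[-1] + eps:
        raise ValueError(
            f"window [{t_lo:.4f}, {t_hi:.4f}] s exceeds trajectory "
            f"[{traj.time[0]:.4f}, {traj.time[-1]:.4f}] s"
        )
    sel = (traj.time >= t_lo - eps) & (traj.time <= t_hi + eps)
    t = traj.time[sel]
    v_fa = traj.velocity[sel, 0]
    v_vert = traj.velocity[sel, 2]
    pre = t < contact_start - eps
    if not pre.any():
        raise ValueError("no pre-contact frames in window")
    return VelocityProfile(
        time=t, v_fa=v_fa, v_vert=v_vert,
        speed=np.hypot(v_fa, v_vert),
        v0_seed=float(v_fa[pre].mean()),
    )
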