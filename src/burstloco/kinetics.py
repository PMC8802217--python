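"""Stride segmentation and per-trial performance metrics.

The per-trial chain:

1. stance detection per plate (vertical force above a body-weight-scaled
   threshold), stride = first stance onset to last stance offset; the
   earlier-contacting plate is the forelimb pair, the later the hindlimb;
2. mean COM acceleration a_COM = mean fore-aft force / M_b over the stride;
3. escape speed v_esc = (integral of F_FA over the stride)/M_b + v0;
4. v0 refined by least-squares matching of the kinetic velocity profile
   (cumulative force integral) to the spline-based kinematic profile;
5. mean COM mechanical power P_COM from positive increments of COM energy
   (kinetic + potential by default) over the hindlimb push-off, divided by
   the hindlimb stroke duration.

The work-energy relation a = sqrt(P_COM / (2 M_b t)) ties mean acceleration
to mass-specific power and stroke duration and is exposed for scenario
modelling and internal consistency checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar

from .config import GRAVITY, RunConfig, DEFAULT_CONFIG
from .errors import NoStrideError, ValidationError
from .io import ForceTrace, TrialBundle
from .kinematics import (VelocityProfile, kinematic_velocity_window,
                         smooth_trajectory)

__all__ = [
    "StrideSegment", "TrialPerformance", "stance_threshold_n",
    "segment_stride", "mean_acceleration", "escape_speed", "optimize_v0",
    "com_power", "work_energy_acceleration", "girdle_accelerations",
    "process_trial",
]


@dataclass
class StrideSegment:
    """One segmented stride with per-plate stance intervals."""

    t0: float
    t_end: float
    stance: dict          # plate_id -> list of (onset, offset) tuples
    fore_plate: int | None
    hind_plate: int | None
    fore_interval: tuple[float, float] | None
    hind_interval: tuple[float, float] | None

    @property
    def duration(self) -> float:
        return self.t_end - self.t0

    @property
    def stroke_duration(self) -> float:
        """Hindlimb stroke duration: the hindlimb stance interval length."""
        if self.hind_interval is None:
            raise ValidationError("no hindlimb stance interval detected")
        return self.hind_interval[1] - self.hind_interval[0]


@dataclass
class TrialPerformance:
    """Derived per-trial metrics."""

    trial_id: str
    rabbit_id: str
    body_mass_kg: float
    a_com: float          # m/s^2, stride mean
    v0: float             # m/s
    v_esc: float          # m/s
    p_com: float          # W
    p_com_per_kg: float   # W/kg
    stroke_duration: float  # s
    fore_a_com: float     # m/s^2 (nan if no forelimb interval)
    hind_a_com: float     # m/s^2
    collar: bool = False


def stance_threshold_n(body_mass_kg: float,
                       fraction: float = 0.02) -> float:
    """Stance-detection threshold: a fraction of body weight, in newtons."""
    return fraction * body_mass_kg * GRAVITY


def _noise_floor(signal: np.ndarray) -> float:
    """Robust noise sd of a mostly-unloaded channel (scaled MAD)."""
    med = np.median(signal)
    return 1.4826 * float(np.median(np.abs(signal - med)))


def _runs_above(time: np.ndarray, signal: np.ndarray, threshold: float,
                min_duration_s: float, merge_gap_s: float) -> list[tuple[float, float]]:
    """Contiguous intervals with signal > threshold, gap-merged and
    duration-filtered, with sub-sample midpoint edge refinement.

    The signal is median-filtered (width 5) before thresholding, which
    rejects broadband sensor noise without smearing the loading edges, and
    the threshold is floored at 4x the robust noise sd of the channel.
    Interval edges are placed half a sample outside the first/last
    suprathreshold sample, where the true crossing is expected on average.
    """
    from scipy.ndimage import median_filter
    filt = median_filter(signal, size=5, mode="nearest")
    eff = max(threshold, 4.0 * _noise_floor(filt))
    above = filt > eff
    if not above.any():
        return []
    dt = time[1] - time[0]
    edges = np.diff(above.astype(int))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1))
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(len(above) - 1)
    runs = [(time[i] - (0.5 * dt if i > 0 else 0.0),
             time[j] + (0.5 * dt if j < len(time) - 1 else 0.0))
            for i, j in zip(onsets, offsets)]
    merged: list[tuple[float, float]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap_s:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [r for r in merged if r[1] - r[0] >= min_duration_s]


def segment_stride(force: ForceTrace, threshold_n: float,
                   min_stance_s: float = 0.02,
                   merge_gap_s: float = 0.02) -> StrideSegment:
    """Detect stance intervals per plate and assign plates to girdles.

    Stance is any contiguous interval with plate vertical force above
    ``threshold_n`` (default 2% body weight upstream); the stride spans the
    first stance onset to the last stance offset. The earlier-contacting
    plate is assigned to the forelimb girdle, the later to the hindlimb.
    With a single loaded plate the stance is attributed to the hindlimb
    (push-off dominates burst trials) and the forelimb is flagged absent.
    """
    if threshold_n <= 0:
        raise ValidationError("threshold must be > 0 N")
    stance: dict[int, list[tuple[float, float]]] = {}
    for j, pid in enumerate(force.plate_ids):
        runs = _runs_above(force.time, force.f_v[:, j], threshold_n,
                           min_stance_s, merge_gap_s)
        if runs:
            stance[pid] = runs
    if not stance:
        raise NoStrideError(f"no vertical force above {threshold_n:.3g} N")

    t0 = min(r[0][0] for r in stance.values())
    t_end = max(r[-1][1] for r in stance.values())

    loaded = sorted(stance, key=lambda pid: stance[pid][0][0])
    if len(loaded) >= 2:
        fore_plate, hind_plate = loaded[0], loaded[-1]
        fore_iv = stance[fore_plate][0]
        hind_iv = stance[hind_plate][-1]
    else:
        pid = loaded[0]
        if len(stance[pid]) >= 2:
            # both girdles struck the same plate: earlier contact is fore
            fore_plate = hind_plate = pid
            fore_iv = stance[pid][0]
            hind_iv = stance[pid][-1]
        else:
            fore_plate, fore_iv = None, None
            hind_plate, hind_iv = pid, stance[pid][0]
    return StrideSegment(t0=t0, t_end=t_end, stance=stance,
                         fore_plate=fore_plate, hind_plate=hind_plate,
                         fore_interval=fore_iv, hind_interval=hind_iv)


def _window(force: ForceTrace, lo: float, hi: float,
            pad_samples: int = 0) -> np.ndarray:
    """Boolean mask of force samples in [lo, hi], optionally padded by whole
    samples on each side (padding captures the sub-threshold loading ramps
    at window edges when integrating)."""
    eps = 1e-6 * force.dt
    sel = (force.time >= lo - eps) & (force.time <= hi + eps)
    if sel.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] s selects <2 force samples")
    if pad_samples:
        idx = np.flatnonzero(sel)
        lo_i = max(idx[0] - pad_samples, 0)
        hi_i = min(idx[-1] + pad_samples, len(force.time) - 1)
        sel = np.zeros_like(sel)
        sel[lo_i:hi_i + 1] = True
    return sel


def mean_acceleration(stride: StrideSegment, force: ForceTrace,
                      body_mass_kg: float) -> float:
    """Stride-mean COM acceleration: mean fore-aft force over body mass."""
    if body_mass_kg <= 0:
        raise ValidationError("body mass must be > 0")
    sel = _window(force, stride.t0, stride.t_end)
    return float(force.total_f_fa[sel].mean() / body_mass_kg)


def escape_speed(stride: StrideSegment, force: ForceTrace,
                 body_mass_kg: float, v0: float) -> float:
    """Final COM velocity: fore-aft impulse over mass, plus v0."""
    if body_mass_kg <= 0:
        raise ValidationError("body mass must be > 0")
    if not math.isfinite(v0):
        raise ValidationError("v0 must be finite")
    sel = _window(force, stride.t0, stride.t_end, pad_samples=1)
    f = force.total_f_fa[sel]
    if not np.isfinite(f).all():
        raise ValidationError("NaN in force window")
    impulse = np.trapezoid(f, force.time[sel])
    return float(impulse / body_mass_kg + v0)


def _kinetic_velocity_at(force: ForceTrace, stride: StrideSegment,
                         body_mass_kg: float, t_query: np.ndarray) -> np.ndarray:
    """Cumulative fore-aft impulse / mass from stride onset, evaluated at
    arbitrary timestamps (constant before t0, frozen after t_end)."""
    sel = _window(force, stride.t0, stride.t_end, pad_samples=1)
    t = force.time[sel]
    dv = cumulative_trapezoid(force.total_f_fa[sel] / body_mass_kg, t, initial=0.0)
    return np.interp(t_query, t, dv, left=0.0, right=dv[-1])


def optimize_v0(stride: StrideSegment, force: ForceTrace, body_mass_kg: float,
                kin_profile: VelocityProfile, v0_seed: float,
                cross_check: bool = True) -> tuple[float, float]:
    """Initial velocity minimizing the kinetic/kinematic profile mismatch.

    The kinetic profile is v(t; v0) = v0 + cumulative impulse / mass; the
    objective sum of squared differences over the marker frames is quadratic
    in v0, so the minimizer is the mean residual in closed form. A bounded
    golden-section search mirrors the iterative original as a cross-check.
    Returns (v0, SSD at the optimum).
    """
    dv = _kinetic_velocity_at(force, stride, body_mass_kg, kin_profile.time)
    resid = kin_profile.v_fa - dv
    v0 = float(resid.mean())

    def ssd(v: float) -> float:
        return float(np.sum((v + dv - kin_profile.v_fa) ** 2))

    if cross_check:
        res = minimize_scalar(ssd, bounds=(v0_seed - 2.0, v0_seed + 2.0),
                              method="bounded",
                              options={"xatol": 1e-9})
        if abs(res.x - v0) > 1e-6 and ssd(res.x) < ssd(v0) - 1e-12:
            warnings.warn(
                f"iterative v0 search ({res.x:.6f}) disagrees with closed "
                f"form ({v0:.6f}) beyond 1e-6", stacklevel=2)
    return v0, ssd(v0)


def com_power(stride: StrideSegment, force: ForceTrace, body_mass_kg: float,
              v0: float, window: str = "hindlimb",
              include_potential: bool = True,
              vertical_v0: float = 0.0) -> float:
    """Mean COM mechanical power from energy fluctuations.

    COM velocities come from integrating F_FA/M (from ``v0``) and
    (F_V - M g)/M (from ``vertical_v0``, zero for a static start) across the
    stride; height from integrating vertical velocity. Positive increments
    of E = 1/2 M (v_fa^2 + v_v^2) + M g h are summed over the hindlimb
    stance (``window='hindlimb'``) or the whole stride (``'stride'``) and
    divided by the hindlimb stroke duration (resp. stride duration).
    """
    if body_mass_kg <= 0:
        raise ValidationError("body mass must be > 0")
    sel = _window(force, stride.t0, stride.t_end, pad_samples=1)
    t = force.time[sel]
    v_fa = v0 + cumulative_trapezoid(force.total_f_fa[sel] / body_mass_kg, t,
                                     initial=0.0)
    # vertical acceleration from plate forces applies only within the
    # stride; outside it the body is supported off-plate, not in free fall
    in_stride = (t >= stride.t0 - 1e-9) & (t <= stride.t_end + 1e-9)
    a_v = np.where(in_stride,
                   (force.total_f_v[sel] - body_mass_kg * GRAVITY)
                   / body_mass_kg, 0.0)
    v_v = vertical_v0 + cumulative_trapezoid(a_v, t, initial=0.0)
    h = cumulative_trapezoid(v_v, t, initial=0.0)
    energy = 0.5 * body_mass_kg * (v_fa**2 + v_v**2)
    if include_potential:
        energy = energy + body_mass_kg * GRAVITY * h

    if window == "hindlimb":
        lo, hi = stride.hind_interval
        duration = stride.stroke_duration
    elif window == "stride":
        lo, hi = stride.t0, stride.t_end
        duration = stride.duration
    else:
        raise ValueError(f"unknown power window '{window}'")
    if duration <= 0:
        raise ValueError("zero-duration power window")
    # pad by one sample to include the work done in the edge loading ramps
    in_win = (t >= lo - 1.01 * force.dt) & (t <= hi + 1.01 * force.dt)
    de = np.diff(energy[in_win])
    return float(de[de > 0].sum() / duration)


def work_energy_acceleration(p_com_w: float, body_mass_kg: float,
                             stroke_duration_s: float) -> float:
    """Mean acceleration implied by the work-energy relation:
    a = sqrt(P_COM / (2 M_b t))."""
    if min(p_com_w, body_mass_kg, stroke_duration_s) <= 0:
        raise ValidationError("P_COM, mass and stroke duration must be > 0")
    return math.sqrt(p_com_w / (2.0 * body_mass_kg * stroke_duration_s))


def girdle_accelerations(stride: StrideSegment, force: ForceTrace,
                         body_mass_kg: float) -> tuple[float, float]:
    """Mean fore-aft acceleration during forelimb vs hindlimb contact.

    A missing girdle interval yields NaN for that girdle (flagged absent,
    not an error).
    """
    out = []
    for iv in (stride.fore_interval, stride.hind_interval):
        if iv is None:
            out.append(float("nan"))
            continue
        sel = _window(force, iv[0], iv[1])
        out.append(float(force.total_f_fa[sel].mean() / body_mass_kg))
    return out[0], out[1]


def process_trial(bundle: TrialBundle,
                  config: RunConfig = DEFAULT_CONFIG) -> TrialPerformance:
    """Run the full per-trial pipeline on one loaded/simulated trial."""
    threshold = stance_threshold_n(bundle.body_mass,
                                   config.stance_threshold_bw_fraction)
    stride = segment_stride(bundle.force, threshold)
    traj = smooth_trajectory(bundle.markers, config.spline_tolerance_mm2,
                             mode=config.spline_tolerance_mode)
    profile = kinematic_velocity_window(
        traj, stride.t0, stride.t_end,
        frames_before=config.frames_before_contact,
        frames_after=config.frames_after_contact)
    v0, _ = optimize_v0(stride, bundle.force, bundle.body_mass, profile,
                        profile.v0_seed)
    a_com = mean_acceleration(stride, bundle.force, bundle.body_mass)
    v_esc = escape_speed(stride, bundle.force, bundle.body_mass, v0)
    p_com = com_power(stride, bundle.force, bundle.body_mass, v0,
                      window=config.power_window,
                      include_potential=config.include_potential_energy,
                      vertical_v0=config.vertical_v0)
    fore_a, hind_a = girdle_accelerations(stride, bundle.force, bundle.body_mass)
    return TrialPerformance(
        trial_id=bundle.trial_id, rabbit_id=bundle.rabbit_id,
        body_mass_kg=bundle.body_mass,
        a_com=a_com, v0=v0, v_esc=v_esc, p_com=p_com,
        p_com_per_kg=p_com / bundle.body_mass,
        stroke_duration=stride.stroke_duration,
        fore_a_com=fore_a, hind_a_com=hind_a,
        collar=bundle.collar,
    )
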