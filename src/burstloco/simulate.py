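"""Synthetic half-bound trial and cohort generators with known ground truth.

The trial generator produces physically consistent (not biofidelic) traces:
a prescribed fore-aft acceleration profile a(t) over one stride gives
F_FA(t) = M_b a(t); vertical force is delivered as half-sine stance pulses
(forelimb pair first, hindlimb pair second, flight in between) whose summed
impulse balances gravity over the stride, so vertical velocity returns to
zero at stride end. Hip-marker positions are the double integral of the
acceleration from (v0, standing height), sampled at the camera rate with
Gaussian noise and random dropout.

The cohort generator draws individuals whose true peak acceleration is
quadratic in body mass (inverted parabola), splits trial-to-trial variation
into between- and within-individual components (fixing the designed ICC),
scales muscle architecture allometrically with mass, and draws survival
durations from a linear model in standardized peak escape speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import GRAVITY
from .errors import ValidationError
from .io import ForceTrace, MarkerTrajectory, TrialBundle

__all__ = [
    "TrialSimParams",
    "TrialGroundTruth",
    "CohortSimParams",
    "CohortTables",
    "simulate_trial",
    "simulate_level_trial",
    "simulate_cohort",
]


@dataclass
class TrialSimParams:
    """Ground-truth parameters for one synthetic burst trial.

    ``accel_mean`` is the true stride-mean fore-aft acceleration; for the
    half-sine profile the instantaneous peak is (pi/2) * accel_mean.
    """

    body_mass_kg: float = 0.8
    v0_m_s: float = 0.0
    accel_profile: str = "constant"  # 'constant' | 'half-sine'
    accel_mean_m_s2: float = 4.0
    stride_duration_s: float = 0.25
    stance_fraction: float = 0.6
    force_noise_sd_n: float = 0.0
    marker_noise_sd_m: float = 0.0
    marker_dropout_p: float = 0.0
    force_rate_hz: float = 500.0
    marker_rate_hz: float = 250.0
    pre_s: float = 0.1   # quiet lead-in before stride onset
    post_s: float = 0.1  # quiet tail after stride end
    seed: int = 0
    trial_id: str = "sim"
    rabbit_id: str = "sim"
    collar: bool = False

    def __post_init__(self) -> None:
        if min(self.stride_duration_s, self.pre_s, self.post_s) <= 0:
            raise ValidationError("durations must be > 0")
        if not 0 < self.stance_fraction <= 1:
            raise ValidationError("stance fraction must be in (0, 1]")
        if self.force_noise_sd_n < 0 or self.marker_noise_sd_m < 0:
            raise ValidationError("noise sds must be >= 0")
        if not 0 <= self.marker_dropout_p <= 0.5:
            raise ValidationError("dropout probability must be in [0, 0.5]")
        if self.accel_profile not in ("constant", "half-sine"):
            raise ValidationError(f"unknown accel profile '{self.accel_profile}'")
        if self.body_mass_kg <= 0:
            raise ValidationError("body mass must be > 0")


@dataclass
class TrialGroundTruth:
    """True quantities the pipeline should recover from a synthetic trial."""

    accel_mean_m_s2: float
    v0_m_s: float
    v_esc_m_s: float
    p_com_w: float
    stride_t0_s: float
    stride_t_end_s: float
    fore_stance_s: tuple[float, float]
    hind_stance_s: tuple[float, float]
    stroke_duration_s: float
    seed: int


def _accel_fa(params: TrialSimParams, t: np.ndarray, t0: float, t_end: float) -> np.ndarray:
    """True fore-aft acceleration at times t (zero outside the stride)."""
    a = np.zeros_like(t)
    inside = (t >= t0) & (t <= t_end)
    if params.accel_profile == "constant":
        a[inside] = params.accel_mean_m_s2
    else:  # half-sine: peak = (pi/2) * mean so the stride mean is accel_mean
        peak = 0.5 * math.pi * params.accel_mean_m_s2
        phase = (t[inside] - t0) / (t_end - t0)
        a[inside] = peak * np.sin(math.pi * phase)
    return a


def simulate_trial(params: TrialSimParams) -> tuple[TrialBundle, TrialGroundTruth]:
    """Generate one synthetic trial and its ground truth."""
    rng = np.random.default_rng(params.seed)
    m = params.body_mass_kg
    T = params.stride_duration_s
    dt_f = 1.0 / params.force_rate_hz
    # stride boundaries at half-sample offsets: force samples then straddle
    # the on/off discontinuities symmetrically, making the trapezoidal
    # impulse of the sampled trace exact for piecewise-constant profiles
    t0 = params.pre_s + 0.5 * dt_f
    t_end = t0 + T
    total = params.pre_s + T + params.post_s + dt_f

    # stance windows: fore pair at stride onset, hind pair at stride end
    half_stance = 0.5 * params.stance_fraction * T
    fore = (t0, t0 + half_stance)
    hind = (t_end - half_stance, t_end)

    # --- force record (500 Hz, two plates) -------------------------------
    n_f = int(round(total * params.force_rate_hz)) + 1
    tf = np.arange(n_f) / params.force_rate_hz
    a_fa = _accel_fa(params, tf, t0, t_end)
    f_fa_total = m * a_fa
    # impulse-exact sampling: rescale so the trapezoidal integral of the
    # sampled trace matches the analytic impulse m * a_mean * T exactly
    impulse = np.trapezoid(f_fa_total, tf)
    target = m * params.accel_mean_m_s2 * T
    if impulse != 0.0:
        f_fa_total = f_fa_total * (target / impulse)

    # vertical: half-sine pulses per stance, summed impulse = m g T over the
    # stride so that vertical velocity returns to zero at stride end
    peak_v = m * GRAVITY * T * math.pi / (2.0 * (fore[1] - fore[0] + hind[1] - hind[0]))

    def _pulse(t: np.ndarray, win: tuple[float, float]) -> np.ndarray:
        out = np.zeros_like(t)
        inside = (t >= win[0]) & (t <= win[1])
        out[inside] = peak_v * np.sin(math.pi * (t[inside] - win[0]) / (win[1] - win[0]))
        return out

    f_v_fore = _pulse(tf, fore)
    f_v_hind = _pulse(tf, hind)
    in_fore = (tf >= fore[0]) & (tf <= fore[1])
    # fore-aft force rides on whichever girdle is in stance (hind otherwise)
    f_fa_fore = np.where(in_fore, f_fa_total, 0.0)
    f_fa_hind = f_fa_total - f_fa_fore

    f_fa = np.column_stack([f_fa_fore, f_fa_hind])
    f_v = np.column_stack([f_v_fore, f_v_hind])
    if params.force_noise_sd_n > 0:
        f_fa = f_fa + rng.normal(0.0, params.force_noise_sd_n, f_fa.shape)
        f_v = f_v + rng.normal(0.0, params.force_noise_sd_n, f_v.shape)
    force = ForceTrace(time=tf, f_fa=f_fa, f_v=f_v, plate_ids=[1, 2])

    # --- marker record (250 Hz) ------------------------------------------
    # integrate the *analytic* dynamics on a fine grid, then sample
    tg = np.linspace(0.0, total, 20 * n_f)
    ag_fa = _accel_fa(params, tg, t0, t_end)
    in_stride = (tg >= t0) & (tg <= t_end)
    ag_v = np.where(in_stride, (_pulse(tg, fore) + _pulse(tg, hind)) / m - GRAVITY, 0.0)

    from scipy.integrate import cumulative_trapezoid
    vx = params.v0_m_s + cumulative_trapezoid(ag_fa, tg, initial=0.0)
    vz = cumulative_trapezoid(ag_v, tg, initial=0.0)
    x = cumulative_trapezoid(vx, tg, initial=0.0)
    h0 = 0.08  # standing hip height, m
    z = h0 + cumulative_trapezoid(vz, tg, initial=0.0)

    n_m = int(round(total * params.marker_rate_hz)) + 1
    tm = np.arange(n_m) / params.marker_rate_hz
    pos = np.column_stack([
        np.interp(tm, tg, x),
        np.zeros(n_m),
        np.interp(tm, tg, z),
    ])
    if params.marker_noise_sd_m > 0:
        pos = pos + rng.normal(0.0, params.marker_noise_sd_m, pos.shape)
    visible = rng.random(n_m) >= params.marker_dropout_p
    # keep the trajectory valid: force at least the endpoints visible
    visible[[0, -1]] = True
    markers = MarkerTrajectory(time=tm, position=pos, visible=visible)

    bundle = TrialBundle(
        trial_id=params.trial_id, rabbit_id=params.rabbit_id,
        body_mass=m, force=force, markers=markers, collar=params.collar,
    )

    # --- ground truth -----------------------------------------------------
    v_esc = params.v0_m_s + params.accel_mean_m_s2 * T
    # COM energy on the fine grid; positive increments over hindlimb stance
    energy = 0.5 * m * (vx**2 + vz**2) + m * GRAVITY * z
    in_hind = (tg >= hind[0]) & (tg <= hind[1])
    de = np.diff(energy[in_hind])
    p_com = float(de[de > 0].sum() / (hind[1] - hind[0]))

    truth = TrialGroundTruth(
        accel_mean_m_s2=params.accel_mean_m_s2,
        v0_m_s=params.v0_m_s,
        v_esc_m_s=v_esc,
        p_com_w=p_com,
        stride_t0_s=t0,
        stride_t_end_s=t_end,
        fore_stance_s=fore,
        hind_stance_s=hind,
        stroke_duration_s=hind[1] - hind[0],
        seed=params.seed,
    )
    return bundle, truth


def simulate_level_trial(mass: float = 1.0, accel: float = 4.0,
                         stride: float = 0.25, v0: float = 0.0,
                         rate: float = 500.0, hind_frac: float = 1.0,
                         pre: float = 0.1, post: float = 0.1) -> TrialBundle:
    """Constructed level (no vertical motion) constant-force trial.

    Total vertical force equals body weight throughout the stride, carried
    by a fore plate over the first ``1 - hind_frac`` of the stride and a
    hind plate over the final ``hind_frac``; fore-aft force is a constant
    ``mass * accel`` across the stride. With ``hind_frac=1`` the whole
    stride is a single hindlimb stance on one plate. Because the COM never
    moves vertically, work-energy identities hold in closed form, which
    makes this the canonical fixture for consistency checks.
    """
    dt = 1.0 / rate
    t0 = pre + 0.5 * dt
    t_end = t0 + stride
    total = pre + stride + post + dt
    n = int(round(total * rate)) + 1
    t = np.arange(n) * dt
    in_stride = (t >= t0) & (t <= t_end)
    split = t_end - hind_frac * stride
    in_hind = in_stride & (t >= split)
    in_fore = in_stride & ~in_hind
    bw = mass * GRAVITY
    f_v = np.column_stack([np.where(in_fore, bw, 0.0),
                           np.where(in_hind, bw, 0.0)])
    ffa = np.where(in_stride, mass * accel, 0.0)
    f_fa = np.column_stack([np.where(in_fore, ffa, 0.0),
                            np.where(in_hind, ffa, 0.0)])
    if hind_frac >= 1.0:
        f_v, f_fa, plates = f_v[:, 1:], f_fa[:, 1:], [1]
    else:
        plates = [1, 2]
    force = ForceTrace(time=t, f_fa=f_fa, f_v=f_v, plate_ids=plates)

    tm = np.arange(int(round(total * 250.0)) + 1) / 250.0
    x = (v0 * tm + 0.5 * accel * np.clip(tm - t0, 0, stride)**2
         + accel * stride * np.clip(tm - t_end, 0, None))
    pos = np.column_stack([x, np.zeros_like(tm), np.full_like(tm, 0.08)])
    markers = MarkerTrajectory(time=tm, position=pos,
                               visible=np.ones_like(tm, dtype=bool))
    return TrialBundle(trial_id="level", rabbit_id="lv", body_mass=mass,
                       force=force, markers=markers)


# --------------------------------------------------------------------------
# cohort-level generator
# --------------------------------------------------------------------------

#: adult (1 kg) reference architecture for the ten sampled hindlimb
#: extensors: (belly mass g, fascicle length cm, pennation deg)
BASE_ARCHITECTURE = {
    "gluteus profundus": (2.0, 1.8, 15.0),
    "gluteus medialis": (4.5, 2.6, 12.0),
    "biceps femoris (vertebral head)": (5.5, 5.0, 8.0),
    "biceps femoris (pelvic head)": (4.0, 4.4, 8.0),
    "semimembranosus": (3.5, 4.0, 10.0),
    "vastus lateralis": (5.0, 2.8, 14.0),
    "rectus femoris": (3.0, 2.4, 12.0),
    "gastrocnemius (lateral head)": (2.8, 1.2, 20.0),
    "gastrocnemius (medial head)": (2.2, 1.1, 22.0),
    "soleus": (0.4, 1.0, 8.0),
}


@dataclass
class CohortSimParams:
    """Design of a synthetic ontogenetic cohort.

    Peak acceleration is quadratic in mass with an interior maximum
    (``curvature`` < 0). Trial values decompose as individual mean
    (quadratic + between-individual deviate) plus within-individual noise,
    so the designed ICC is between_sd^2 / (between_sd^2 + within_sd^2).
    Muscle belly mass scales as M_b^muscle_mass_exponent, which the
    architecture chain propagates into P_musc with the same exponent.
    """

    n_individuals: int = 38
    mass_range_kg: tuple[float, float] = (0.106, 1.434)
    vertex_mass_kg: float = 0.74
    vertex_value: float = 6.0       # peak a_COM at the vertex, m/s^2
    curvature: float = -6.0         # m/s^2 per kg^2; must be < 0
    between_sd: float = 0.6         # individual-level sd of a_COM, m/s^2
    within_sd: float = 0.8          # trial-level sd of a_COM, m/s^2
    trials_per_individual: int = 5
    stride_duration_s: float = 0.25
    v0_mean_m_s: float = 0.2
    v0_sd_m_s: float = 0.1
    muscle_mass_exponent: float = 1.33   # mechanical similarity
    muscle_coefficient: float = 1.0      # multiplier on the base architecture
    muscle_noise_sd_dex: float = 0.02    # lognormal scatter on muscle masses
    survival_baseline_days: float = 60.0
    survival_effect_days_per_sd: float = 10.0
    survival_noise_sd_days: float = 29.0
    collared_fraction: float = 0.58      # 22 of 38 in the study design
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ValidationError("need at least 3 individuals")
        if self.curvature >= 0:
            raise ValidationError("curvature must be < 0 (inverted parabola)")
        for sd in (self.between_sd, self.within_sd, self.muscle_noise_sd_dex,
                   self.survival_noise_sd_days, self.v0_sd_m_s):
            if sd < 0:
                raise ValidationError("sds must be >= 0")

    @property
    def designed_icc(self) -> float:
        return self.between_sd**2 / (self.between_sd**2 + self.within_sd**2)

    def true_peak_accel(self, mass_kg: np.ndarray) -> np.ndarray:
        """Quadratic performance-mass curve in vertex form."""
        mass_kg = np.asarray(mass_kg, dtype=float)
        return self.vertex_value + self.curvature * (mass_kg - self.vertex_mass_kg) ** 2


@dataclass
class CohortTables:
    """Synthetic cohort output: tidy tables plus the generating truth."""

    cohort: pd.DataFrame   # rabbit_id, body_mass_kg, age_class, collared, survival_days, p_musc_w
    trials: pd.DataFrame   # rabbit_id, trial, a_com, v0, v_esc
    muscles: pd.DataFrame  # rabbit_id, muscle, mm_g, lf_cm, theta_deg
    truth: dict = field(default_factory=dict)


def simulate_cohort(params: CohortSimParams) -> CohortTables:
    """Draw a full synthetic cohort: trials, muscle tables, survival."""
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals
    lo, hi = params.mass_range_kg
    masses = np.sort(rng.uniform(lo, hi, n))
    rabbit_ids = [f"R{i + 1:03d}" for i in range(n)]

    mean_accel = params.true_peak_accel(masses)
    indiv_accel = mean_accel + rng.normal(0.0, params.between_sd, n)

    rows = []
    for rid, m, mu in zip(rabbit_ids, masses, indiv_accel):
        a = mu + rng.normal(0.0, params.within_sd, params.trials_per_individual)
        v0 = np.clip(rng.normal(params.v0_mean_m_s, params.v0_sd_m_s,
                                params.trials_per_individual), 0.0, None)
        for j, (aj, v0j) in enumerate(zip(a, v0)):
            rows.append({
                "rabbit_id": rid, "trial": j + 1, "body_mass_kg": m,
                "a_com": aj, "v0": v0j,
                "v_esc": v0j + aj * params.stride_duration_s,
            })
    trials = pd.DataFrame(rows)

    # muscle architecture: MM ~ coeff * base * M^b, L_F ~ base * M^(1/3)
    muscle_rows = []
    for rid, m in zip(rabbit_ids, masses):
        for name, (mm0, lf0, theta) in BASE_ARCHITECTURE.items():
            scatter = 10.0 ** rng.normal(0.0, params.muscle_noise_sd_dex)
            muscle_rows.append({
                "rabbit_id": rid, "muscle": name,
                "mm_g": params.muscle_coefficient * mm0
                        * m ** params.muscle_mass_exponent * scatter,
                "lf_cm": lf0 * m ** (1.0 / 3.0),
                "theta_deg": theta,
            })
    muscles = pd.DataFrame(muscle_rows)

    from .muscle import MuscleRecord, total_hindlimb_power
    p_musc = []
    for rid in rabbit_ids:
        sub = muscles[muscles["rabbit_id"] == rid]
        recs = [MuscleRecord(name=r.muscle, mm_g=r.mm_g, lf_cm=r.lf_cm,
                             theta_deg=r.theta_deg, rabbit_id=rid)
                for r in sub.itertuples()]
        p_musc.append(total_hindlimb_power(recs).p_musc_w)

    # survival: linear in standardized peak v_esc, floored at one day
    peak_vesc = trials.groupby("rabbit_id", sort=True)["v_esc"].max().to_numpy()
    z = (peak_vesc - peak_vesc.mean()) / peak_vesc.std(ddof=1)
    survival = (params.survival_baseline_days
                + params.survival_effect_days_per_sd * z
                + rng.normal(0.0, params.survival_noise_sd_days, n))
    survival = np.maximum(survival, 1.0)

    collared = rng.random(n) < params.collared_fraction
    from .io import age_class
    cohort = pd.DataFrame({
        "rabbit_id": rabbit_ids,
        "body_mass_kg": masses,
        "age_class": [age_class(m) for m in masses],
        "collared": collared,
        "survival_days": np.round(survival, 1),
        "p_musc_w": p_musc,
    })

    truth = {
        "vertex_mass_kg": params.vertex_mass_kg,
        "vertex_value": params.vertex_value,
        "curvature": params.curvature,
        "designed_icc": params.designed_icc,
        "p_musc_exponent": params.muscle_mass_exponent,
        "survival_effect_days_per_sd": params.survival_effect_days_per_sd,
        "seed": params.seed,
        "params": asdict(params),
    }
    return CohortTables(cohort=cohort, trials=trials, muscles=muscles, truth=truth)
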