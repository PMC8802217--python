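"""Hindlimb extensor muscle power capacity from architectural measurements.

The chain runs: belly mass MM (g), fascicle length L_F (cm), and pennation
angle θ give physiological cross-sectional area

    PCSA = MM cos(θ) / (L_F ρ)          [cm², ρ = 1.06 g/cm³]

maximum isometric force F_max = σ PCSA with σ = 30 N/cm², maximum shortening
velocity V_max = 6.3 L_F per second (fast MHC-2X fibres), and peak
instantaneous power P_peak = 0.1 F_max V_max. Total hindlimb capacity is
twice the sum over the sampled extensors, because the half-bounding gait
extends both hindlimbs synchronously.

Inputs stay in g/cm units so the PCSA formula reads as conventionally
printed; conversion to SI happens only inside the power computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

MUSCLE_DENSITY_G_CM3 = 1.06
MAX_ISOMETRIC_STRESS_N_CM2 = 30.0
VMAX_FASCICLE_LENGTHS_PER_S = 6.3
#: fraction of F_max * V_max realised as peak instantaneous power
POWER_FRACTION = 0.1
#: both hindlimbs extend together in a half-bound
HALF_BOUND_DOUBLING = 2.0

#: the ten extensor muscles/heads conventionally sampled (hip, knee, ankle)
SAMPLED_EXTENSORS = [
    "gluteus profundus",
    "gluteus medialis",
    "biceps femoris (vertebral head)",
    "biceps femoris (pelvic head)",
    "semimembranosus",
    "vastus lateralis",
    "rectus femoris",
    "gastrocnemius (lateral head)",
    "gastrocnemius (medial head)",
    "soleus",
]


def pcsa(mm_g: float, theta_deg: float, lf_cm: float,
         rho: float = MUSCLE_DENSITY_G_CM3) -> float:
    """Physiological cross-sectional area in cm²."""
    if not 0.0 <= theta_deg < 90.0:
        raise ValidationError(f"pennation angle must be in [0, 90) deg, got {theta_deg}")
    if mm_g <= 0 or lf_cm <= 0 or rho <= 0:
        raise ValidationError("muscle mass, fascicle length and density must be > 0")
    return mm_g * math.cos(math.radians(theta_deg)) / (lf_cm * rho)


def max_isometric_force(pcsa_cm2: float,
                        sigma: float = MAX_ISOMETRIC_STRESS_N_CM2) -> float:
    """F_max in newtons from PCSA in cm²."""
    if pcsa_cm2 <= 0:
        raise ValidationError("PCSA must be > 0")
    return sigma * pcsa_cm2


def peak_muscle_power(f_max_n: float, lf_cm: float,
                      vmax_per_length: float = VMAX_FASCICLE_LENGTHS_PER_S) -> float:
    """Peak instantaneous power in watts: 0.1 F_max V_max, V_max = 6.3 L_F/s."""
    if f_max_n <= 0 or lf_cm <= 0:
        raise ValidationError("F_max and fascicle length must be > 0")
    v_max_m_s = vmax_per_length * lf_cm / 100.0  # cm/s -> m/s
    return POWER_FRACTION * f_max_n * v_max_m_s


def mean_pennation_deg(site_angles_deg) -> float:
    """Representative pennation from raw site measurements: mean angle.

    The representative θ is the arithmetic mean of the 5-10 site angles; the
    cosine is taken afterwards, matching the single-θ PCSA formula.
    """
    angles = np.asarray(site_angles_deg, dtype=float)
    if angles.size == 0:
        raise ValidationError("need at least one site angle")
    return float(angles.mean())


@dataclass
class MuscleRecord:
    """One muscle's architecture and derived capacities.

    Derived fields (PCSA cm², F_max N, V_max cm/s, P_peak W) are computed on
    construction from MM (g), L_F (cm), and θ (deg).
    """

    name: str
    mm_g: float
    lf_cm: float
    theta_deg: float
    rabbit_id: str = ""
    pcsa_cm2: float = field(init=False)
    f_max_n: float = field(init=False)
    v_max_cm_s: float = field(init=False)
    p_peak_w: float = field(init=False)

    def __post_init__(self) -> None:
        self.pcsa_cm2 = pcsa(self.mm_g, self.theta_deg, self.lf_cm)
        self.f_max_n = max_isometric_force(self.pcsa_cm2)
        self.v_max_cm_s = VMAX_FASCICLE_LENGTHS_PER_S * self.lf_cm
        self.p_peak_w = peak_muscle_power(self.f_max_n, self.lf_cm)


@dataclass
class HindlimbPower:
    """Total hindlimb extensor power capacity for one individual."""

    rabbit_id: str
    p_musc_w: float
    contributions_w: dict[str, float]


def total_hindlimb_power(muscles: list[MuscleRecord]) -> HindlimbPower:
    """P_musc = 2 Σ P_peak over the listed muscles (half-bound doubling)."""
    if not muscles:
        raise ValidationError("need at least one muscle record")
    rabbit_ids = {m.rabbit_id for m in muscles}
    if len(rabbit_ids) > 1:
        raise ValidationError(f"records span multiple rabbits: {sorted(rabbit_ids)}")
    contributions = {m.name: m.p_peak_w for m in muscles}
    return HindlimbPower(
        rabbit_id=muscles[0].rabbit_id,
        p_musc_w=HALF_BOUND_DOUBLING * sum(m.p_peak_w for m in muscles),
        contributions_w=contributions,
    )
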