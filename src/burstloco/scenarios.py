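"""Constant-acceleration escape-performance scenarios.

From fitted peak-acceleration curves, predicts what a juvenile and an adult
achieve under constant acceleration from a standing start: distance covered
in the first second (a/2), time to reach a refuge R metres away
(sqrt(2R/a)), and the number of strides needed to reach top recorded speed
(ceil((v_top/a)/stride_duration)). Defaults: refuge 10 m, top speed
11.1 m/s, subject masses 0.8 kg (juvenile) and 1.2 kg (adult).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ValidationError
from .ontogeny import QuadraticFit

__all__ = ["ScenarioResult", "predict_accel", "run_scenarios",
           "DEFAULT_JUVENILE_MASS_KG", "DEFAULT_ADULT_MASS_KG",
           "DEFAULT_REFUGE_M", "DEFAULT_TOP_SPEED_M_S"]

DEFAULT_JUVENILE_MASS_KG = 0.8
DEFAULT_ADULT_MASS_KG = 1.2
DEFAULT_REFUGE_M = 10.0
DEFAULT_TOP_SPEED_M_S = 11.1  # fastest recorded cottontail sprint


def predict_accel(fit: QuadraticFit, mass_kg: float) -> float:
    """Evaluate the peak-acceleration quadratic at a body mass."""
    masses = fit.data[fit.mass_col]
    if not masses.min() <= mass_kg <= masses.max():
        warnings.warn(f"mass {mass_kg} kg outside fitted range "
                      f"[{masses.min():.3g}, {masses.max():.3g}] kg",
                      stacklevel=2)
    return float(fit.predict(mass_kg))


@dataclass
class ScenarioResult:
    """Predicted escape performance for one juvenile/adult pair."""

    juvenile_mass_kg: float
    adult_mass_kg: float
    accel_juvenile: float
    accel_adult: float
    distance_first_second_juvenile_m: float
    distance_first_second_adult_m: float
    time_to_refuge_juvenile_s: float
    time_to_refuge_adult_s: float
    strides_to_top_speed_juvenile: int | None
    strides_to_top_speed_adult: int | None
    distance_ratio: float   # juvenile / adult
    time_ratio: float       # juvenile / adult
    stride_difference: int | None  # adult strides - juvenile strides


def run_scenarios(accel_juvenile: float, accel_adult: float,
                  refuge_m: float = DEFAULT_REFUGE_M,
                  top_speed_m_s: float = DEFAULT_TOP_SPEED_M_S,
                  stride_duration_s: float | None = None,
                  juvenile_mass_kg: float = DEFAULT_JUVENILE_MASS_KG,
                  adult_mass_kg: float = DEFAULT_ADULT_MASS_KG) -> ScenarioResult:
    """Evaluate the three constant-acceleration scenarios.

    The stride-count scenario needs a stride duration (no published value);
    pass the mean hindlimb stride period of the processed dataset, or None
    to skip that scenario.
    """
    if accel_juvenile <= 0 or accel_adult <= 0:
        raise ValidationError("accelerations must be > 0")
    if refuge_m <= 0 or top_speed_m_s <= 0:
        raise ValidationError("refuge distance and top speed must be > 0")

    def strides(a: float) -> int | None:
        if stride_duration_s is None:
            return None
        if stride_duration_s <= 0:
            raise ValidationError("stride duration must be > 0")
        return math.ceil((top_speed_m_s / a) / stride_duration_s)

    d_j, d_a = 0.5 * accel_juvenile, 0.5 * accel_adult
    t_j = math.sqrt(2.0 * refuge_m / accel_juvenile)
    t_a = math.sqrt(2.0 * refuge_m / accel_adult)
    s_j, s_a = strides(accel_juvenile), strides(accel_adult)
    return ScenarioResult(
        juvenile_mass_kg=juvenile_mass_kg, adult_mass_kg=adult_mass_kg,
        accel_juvenile=accel_juvenile, accel_adult=accel_adult,
        distance_first_second_juvenile_m=d_j,
        distance_first_second_adult_m=d_a,
        time_to_refuge_juvenile_s=t_j, time_to_refuge_adult_s=t_a,
        strides_to_top_speed_juvenile=s_j, strides_to_top_speed_adult=s_a,
        distance_ratio=accel_juvenile / accel_adult,
        time_ratio=t_j / t_a,
        stride_difference=None if s_j is None else s_a - s_j,
    )
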