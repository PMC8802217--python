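"""File I/O for trials, cohorts, and muscle tables.

All on-disk formats are plain comma-separated text with a header row
('.' decimal, UTF-8), one file per trial per stream:

* force CSV:  ``time_s, plate, f_fa_N, f_v_N`` (long format, one block per plate)
* marker CSV: ``time_s, x_m, y_m, z_m, visible``
* cohort CSV: ``rabbit_id, body_mass_kg, collared, survival_days``
* muscle CSV: ``rabbit_id, muscle, mm_g, lf_cm, theta_deg``

Axes follow the package convention (fore-aft positive in the direction of
travel, vertical positive up); x is fore-aft, y mediolateral, z vertical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError, ValidationError
from .muscle import MuscleRecord

__all__ = [
    "ForceTrace",
    "MarkerTrajectory",
    "TrialBundle",
    "load_trial",
    "save_force_csv",
    "save_marker_csv",
    "load_force_csv",
    "load_marker_csv",
    "load_muscle_table",
    "load_cohort",
]

_UNIFORMITY_RTOL = 1e-3  # max relative deviation of sample spacing


def _check_uniform(time: np.ndarray, what: str) -> float:
    """Validate a strictly increasing, uniform time base; return dt."""
    if time.ndim != 1 or time.size < 2:
        raise SamplingError(f"{what}: need at least 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise SamplingError(f"{what}: time not strictly increasing")
    dt0 = np.median(dt)
    if np.max(np.abs(dt - dt0)) > _UNIFORMITY_RTOL * dt0:
        raise SamplingError(
            f"{what}: sampling non-uniform beyond 1 part in 10^3 "
            f"(max deviation {np.max(np.abs(dt - dt0)) / dt0:.2e})"
        )
    return float(dt0)


@dataclass
class ForceTrace:
    """Synchronized force-plate time series for one trial.

    ``f_fa`` and ``f_v`` are (n_samples, n_plates) arrays in newtons on a
    shared uniform time base (500 Hz default). Fore-aft is positive in the
    direction of travel; vertical is positive up with an unloaded baseline
    near 0 N.
    """

    time: np.ndarray
    f_fa: np.ndarray
    f_v: np.ndarray
    plate_ids: list[int] = field(default_factory=lambda: [1])

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f_fa = np.atleast_2d(np.asarray(self.f_fa, dtype=float).T).T
        self.f_v = np.atleast_2d(np.asarray(self.f_v, dtype=float).T).T
        if not (np.isfinite(self.time).all() and np.isfinite(self.f_fa).all()
                and np.isfinite(self.f_v).all()):
            raise ValidationError("force trace contains non-finite values")
        if self.f_fa.shape != self.f_v.shape or self.f_fa.shape[0] != self.time.size:
            raise ValidationError("force channel shapes do not match time base")
        self.dt = _check_uniform(self.time, "force trace")

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.dt

    @property
    def total_f_fa(self) -> np.ndarray:
        """Whole-body fore-aft force: sum across plates."""
        return self.f_fa.sum(axis=1)

    @property
    def total_f_v(self) -> np.ndarray:
        return self.f_v.sum(axis=1)


@dataclass
class MarkerTrajectory:
    """Time-stamped 3-D hip-marker positions with per-frame visibility.

    ``position`` is (n_frames, 3) metres in (fore-aft, mediolateral,
    vertical) order; ``visible`` flags frames where the marker was tracked.
    """

    time: np.ndarray
    position: np.ndarray
    visible: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.position.shape != (self.time.size, 3):
            raise ValidationError("marker position must be (n_frames, 3)")
        if self.visible.shape != (self.time.size,):
            raise ValidationError("visible flags must match frame count")
        if self.time.size < 21:
            raise ValidationError("marker trajectory needs >= 21 frames")
        frac_missing = 1.0 - self.visible.mean()
        if frac_missing >= 0.5:
            raise ValidationError(
                f"{frac_missing:.0%} of marker frames invisible (limit 50%)"
            )
        if not np.isfinite(self.position[self.visible]).all():
            raise ValidationError("visible marker frames contain non-finite values")
        self.dt = _check_uniform(self.time, "marker trajectory")

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.dt


@dataclass
class TrialBundle:
    """One burst trial: synchronized forces and markers plus metadata."""

    trial_id: str
    rabbit_id: str
    body_mass: float  # kg
    force: ForceTrace
    markers: MarkerTrajectory
    collar: bool = False

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValidationError(f"body_mass must be > 0 kg, got {self.body_mass}")
        if self.force.rate_hz <= self.markers.rate_hz:
            raise ValidationError("force sampling rate must exceed marker rate")


_FORCE_COLS = ["time_s", "plate", "f_fa_N", "f_v_N"]
_MARKER_COLS = ["time_s", "x_m", "y_m", "z_m", "visible"]


def save_force_csv(force: ForceTrace, path: str | Path) -> None:
    blocks = []
    for j, pid in enumerate(force.plate_ids):
        blocks.append(pd.DataFrame({
            "time_s": force.time,
            "plate": pid,
            "f_fa_N": force.f_fa[:, j],
            "f_v_N": force.f_v[:, j],
        }))
    pd.concat(blocks, ignore_index=True).to_csv(path, index=False)


def save_marker_csv(markers: MarkerTrajectory, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": markers.time,
        "x_m": markers.position[:, 0],
        "y_m": markers.position[:, 1],
        "z_m": markers.position[:, 2],
        "visible": markers.visible.astype(int),
    }).to_csv(path, index=False)


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def load_force_csv(path: str | Path, subtract_baseline: bool = False) -> ForceTrace:
    df = _read_csv(path, _FORCE_COLS)
    plate_ids = sorted(df["plate"].unique().tolist())
    per_plate = [df[df["plate"] == pid].sort_values("time_s") for pid in plate_ids]
    time = per_plate[0]["time_s"].to_numpy()
    f_fa = np.column_stack([b["f_fa_N"].to_numpy() for b in per_plate])
    f_v = np.column_stack([b["f_v_N"].to_numpy() for b in per_plate])
    for b in per_plate[1:]:
        if b.shape[0] != time.size or not np.allclose(b["time_s"], time):
            raise FormatError(f"{path}: plate blocks have mismatched time bases")
    if subtract_baseline:
        # unloaded level estimated from the quietest decile of |F_V|
        for j in range(f_v.shape[1]):
            q = np.quantile(np.abs(f_v[:, j]), 0.1)
            quiet = np.abs(f_v[:, j]) <= q
            f_v[:, j] -= f_v[quiet, j].mean()
            f_fa[:, j] -= f_fa[quiet, j].mean()
    return ForceTrace(time=time, f_fa=f_fa, f_v=f_v, plate_ids=plate_ids)


def load_marker_csv(path: str | Path) -> MarkerTrajectory:
    df = _read_csv(path, _MARKER_COLS)
    return MarkerTrajectory(
        time=df["time_s"].to_numpy(),
        position=df[["x_m", "y_m", "z_m"]].to_numpy(),
        visible=df["visible"].to_numpy().astype(bool),
    )


def load_trial(force_path: str | Path, marker_path: str | Path,
               meta: dict, subtract_baseline: bool = False) -> TrialBundle:
    """Load one trial from its force and marker CSVs.

    ``meta`` must provide ``body_mass`` (kg) and ``rabbit_id``; optional keys
    are ``trial_id`` (defaults to the force-file stem) and ``collar``.
    """
    for key in ("body_mass", "rabbit_id"):
        if key not in meta:
            raise ValidationError(f"trial metadata missing required key '{key}'")
    return TrialBundle(
        trial_id=str(meta.get("trial_id", Path(force_path).stem)),
        rabbit_id=str(meta["rabbit_id"]),
        body_mass=float(meta["body_mass"]),
        force=load_force_csv(force_path, subtract_baseline=subtract_baseline),
        markers=load_marker_csv(marker_path),
        collar=bool(meta.get("collar", False)),
    )


def load_muscle_table(path: str | Path) -> list[MuscleRecord]:
    """Read a muscle-architecture table into records (g / cm / degree units)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty muscle table", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty muscle table", stacklevel=2)
        return []
    missing = [c for c in ("muscle", "mm_g", "lf_cm", "theta_deg") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(MuscleRecord(
            name=str(row["muscle"]),
            rabbit_id=str(row["rabbit_id"]) if "rabbit_id" in df.columns else "",
            mm_g=float(row["mm_g"]),
            lf_cm=float(row["lf_cm"]),
            theta_deg=float(row["theta_deg"]),
        ))
    return records


JUVENILE_MASS_CUTOFF_KG = 1.0


def age_class(body_mass_kg: float) -> str:
    """'juvenile' below 1 kg, 'adult' at or above (boundary mass -> adult)."""
    return "juvenile" if body_mass_kg < JUVENILE_MASS_CUTOFF_KG else "adult"


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table and derive the age class from body mass."""
    df = _read_csv(path, ["rabbit_id", "body_mass_kg"])
    dup = df["rabbit_id"][df["rabbit_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate rabbit_id(s): {sorted(dup.unique().tolist())}")
    if (df["body_mass_kg"] <= 0).any():
        raise ValidationError("cohort contains non-positive body mass")
    df = df.copy()
    df["age_class"] = df["body_mass_kg"].map(age_class)
    if "collared" in df.columns:
        df["collared"] = df["collared"].astype(bool)
    return df
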