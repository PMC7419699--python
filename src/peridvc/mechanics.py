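"""Pullout-curve mechanics: stepwise in situ force-displacement records
and their macroscopic summary metrics.

An in situ pullout protocol loads the screw in displacement control in
steps (0.1 mm at 0.1 mm/min), pausing ~400 s for relaxation and scanning
between steps, until the force drops. The resulting curve is therefore a
staircase: loading ramps interleaved with holds at near-zero crosshead
velocity. Stiffness is fitted on the loading envelope only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import ParameterError

CSV_COLUMNS = ("time_s", "disp_mm", "force_N")


@dataclass
class LoadCurve:
    time_s: np.ndarray
    disp_mm: np.ndarray
    force_N: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.disp_mm = np.asarray(self.disp_mm, dtype=np.float64)
        self.force_N = np.asarray(self.force_N, dtype=np.float64)
        if not (len(self.time_s) == len(self.disp_mm) == len(self.force_N)):
            raise ParameterError("time/displacement/force channels differ in length")
        if len(self.time_s) < 2 or not np.all(np.diff(self.time_s) > 0):
            raise ParameterError("time must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LoadCurve":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"load-curve CSV missing columns {missing}; expected {CSV_COLUMNS}")
        return cls(df["time_s"].to_numpy(), df["disp_mm"].to_numpy(), df["force_N"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time_s, "disp_mm": self.disp_mm, "force_N": self.force_N}).to_csv(
            path, index=False
        )


@dataclass
class MechSummary:
    stiffness_N_per_mm: float
    max_force_N: float
    displacement_at_max_force_mm: float
    failure_step: int            # sample index of first detected force drop, -1 if none
    preload_N: float
    fit_window: tuple[float, float] = (0.2, 0.8)
    n_fit_samples: int = 0

    def as_dict(self) -> dict:
        return {
            "stiffness_N_per_mm": self.stiffness_N_per_mm,
            "max_force_N": self.max_force_N,
            "displacement_at_max_force_mm": self.displacement_at_max_force_mm,
            "failure_step": self.failure_step,
            "preload_N": self.preload_N,
            "fit_window": list(self.fit_window),
            "n_fit_samples": self.n_fit_samples,
        }


def loading_mask(curve: LoadCurve, velocity_fraction: float = 0.1) -> np.ndarray:
    """Samples belonging to loading ramps: crosshead velocity above a
    fraction of the robust (90th percentile) ramp velocity. Excludes the
    relaxation holds of a stepwise protocol."""
    v = np.gradient(curve.disp_mm, curve.time_s)
    vmax = np.percentile(v[v > 0], 90) if np.any(v > 0) else 0.0
    if vmax <= 0:
        return np.ones_like(v, dtype=bool)
    return v > velocity_fraction * vmax


def summarize_curve(
    curve: LoadCurve,
    fit_window: tuple[float, float] = (0.2, 0.8),
    drop_fraction: float = 0.9,
) -> MechSummary:
    """Macro-mechanical summary of a pullout record.

    stiffness: least-squares slope of force vs displacement over loading
    samples whose force lies in ``fit_window`` (fractions of max force),
    taken before the force maximum. max_force is the plain channel
    maximum. failure_step is the first sample where force falls below
    ``drop_fraction`` of the running maximum (after the fit region).
    preload is the initial force level.
    """
    f = curve.force_N
    d = curve.disp_mm
    if len(f) < 10:
        raise ParameterError("need at least 10 samples")
    if np.ptp(f) == 0:
        raise ParameterError("force range is zero")
    lo, hi = fit_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ParameterError(f"invalid fit window {fit_window}")
    imax = int(np.argmax(f))
    fmax = float(f[imax])
    preload = float(f[0])
    active = loading_mask(curve)
    span = fmax - preload
    fit = active & (f >= preload + lo * span) & (f <= preload + hi * span)
    fit[imax + 1:] = False
    if fit.sum() < 2:
        raise ParameterError("not enough loading samples in the fit window")
    slope = float(np.polyfit(d[fit], f[fit], 1)[0])
    running_max = np.maximum.accumulate(f)
    dropped = f < drop_fraction * running_max
    dropped[: imax] = dropped[: imax] & (running_max[: imax] >= preload + lo * span)
    failure = int(np.argmax(dropped)) if dropped.any() else -1
    return MechSummary(
        stiffness_N_per_mm=slope,
        max_force_N=fmax,
        displacement_at_max_force_mm=float(d[imax]),
        failure_step=failure,
        preload_N=preload,
        fit_window=(lo, hi),
        n_fit_samples=int(fit.sum()),
    )


def synthetic_pullout_curve(
    stiffness_N_per_mm: float = 161.0,
    max_force_N: float = 38.0,
    preload_N: float = 5.9,
    step_mm: float = 0.1,
    rate_mm_per_min: float = 0.1,
    relax_s: float = 400.0,
    drop_to_N: float = 5.0,
    dt_s: float = 1.0,
    noise_N: float = 0.0,
    seed: int = 0,
) -> LoadCurve:
    """Synthetic stepwise in situ pullout record.

    Linear elastic loading at the given stiffness from the preload up to
    max force, applied in displacement steps with relaxation holds, then a
    sharp force drop (interface failure). Defaults emulate the published
    protocol and its average stiffness / max force / preload.
    """
    rate = rate_mm_per_min / 60.0
    d_fail = (max_force_N - preload_N) / stiffness_N_per_mm
    t_list: list[float] = [0.0]
    d_list: list[float] = [0.0]
    t = 0.0
    d = 0.0
    while d < d_fail + step_mm:
        target = min(d + step_mm, d_fail + step_mm)
        while d < target:
            d = min(d + rate * dt_s, target)
            t += dt_s
            t_list.append(t)
            d_list.append(d)
        for _ in range(int(relax_s / dt_s)):
            t += dt_s
            t_list.append(t)
            d_list.append(d)
    time = np.asarray(t_list)
    disp = np.asarray(d_list)
    force = preload_N + stiffness_N_per_mm * disp
    post = disp > d_fail
    force[post] = drop_to_N
    force = np.clip(force, None, max_force_N)
    if noise_N > 0:
        force = force + np.random.default_rng(seed).normal(0.0, noise_N, size=force.size)
    return LoadCurve(time, disp, force, meta={"synthetic": True, "stiffness": stiffness_N_per_mm})
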