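"""Quasi-periodic synthetic gait signals with exact ground truth.

Each trial emulates a toddler walking straight at self-selected speed while
wearing a trunk IMU (3-axis acceleration: vertical V, medio-lateral ML,
antero-posterior AP) and one gyroscope per shank. The signal model is
deliberately phenomenological, not musculoskeletal:

* trunk acceleration per axis is a per-stride harmonic series (harmonics of
  that stride's own fundamental) plus broadband white noise — so harmonic
  ratio, entropy and recurrence structure are controlled analytically;
* shank angular velocity is a per-stride template with one dominant positive
  mid-swing peak flanked by negative minima placed exactly at toe-off and
  heel-strike times — so event detection is verifiable against ground truth.

Stride durations are jittered i.i.d. Gaussian; step timing within the stride
carries the left/right asymmetry. The ``truth`` annotation stores every event
time and per-stride duration exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort import ChildRecord, GaitEffects, child_rng
from .errors import ValidationError

AXES = ("v", "ml", "ap")

#: Default per-axis harmonic amplitudes (m/s^2) at multiples of the stride
#: frequency. V and AP are even-dominant (two steps per stride), ML is
#: odd-dominant (one lateral sway cycle per stride) — the standard pattern
#: behind the harmonic-ratio conventions.
DEFAULT_HARMONICS: dict[str, dict[int, float]] = {
    "v": {1: 0.4, 2: 1.5, 3: 0.2, 4: 0.5},
    "ml": {1: 0.8, 2: 0.25, 3: 0.3},
    "ap": {1: 0.35, 2: 1.0, 4: 0.3},
}


class GaitParams(BaseModel):
    """Signal-model parameters for one trial."""

    model_config = ConfigDict(extra="forbid")

    fs: float = Field(default=100.0, gt=0)
    duration_s: float = Field(default=60.0, gt=0)
    stride_time_mean: float = Field(default=0.95, gt=0)
    stride_time_sd: float = Field(default=0.03, ge=0)
    #: Ratio of left step time to right step time (1 = symmetric).
    step_asymmetry: float = Field(default=1.0, gt=0)
    #: Stance duration as a fraction of the stride; double support (%) for a
    #: symmetric gait equals 200 * (stance_fraction - 0.5).
    stance_fraction: float = Field(default=0.64, gt=0.5, lt=1.0)
    harmonics: dict[str, dict[int, float]] = Field(
        default_factory=lambda: {a: dict(DEFAULT_HARMONICS[a]) for a in AXES}
    )
    noise_sd: float = Field(default=0.12, ge=0)
    gyro_peak_amp: float = Field(default=300.0, gt=0)
    gyro_noise_sd: float = Field(default=5.0, ge=0)


def params_for_child(child: ChildRecord, effects: dict[str, GaitEffects],
                     base: Optional[GaitParams] = None) -> GaitParams:
    """Apply the child's group effect sizes to the baseline gait parameters."""
    p = (base or GaitParams()).model_copy(deep=True)
    eff = effects.get(child.risk, GaitEffects())
    p.stride_time_mean += eff.stride_time_shift_s
    p.stride_time_sd *= eff.stride_time_sd_scale
    ds_pct = 200.0 * (p.stance_fraction - 0.5) + eff.double_support_shift_pct
    p.stance_fraction = min(0.95, 0.5 + ds_pct / 200.0)
    p.harmonics = {
        ax: {k: a * eff.harmonic_amp_scale for k, a in amps.items()}
        for ax, amps in p.harmonics.items()
    }
    p.noise_sd *= eff.noise_scale
    return p


@dataclass
class TrialTruth:
    """Exact ground-truth annotations of a synthetic trial."""

    heel_strikes_left: np.ndarray
    heel_strikes_right: np.ndarray
    toe_offs_left: np.ndarray
    toe_offs_right: np.ndarray
    mid_swings_left: np.ndarray
    mid_swings_right: np.ndarray
    stride_durations_left: np.ndarray
    stride_durations_right: np.ndarray
    harmonics: dict[str, dict[int, float]]
    stance_fraction: float
    step_phase: float

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, dict):
                out[k] = {ax: {str(h): a for h, a in amps.items()} for ax, amps in v.items()} \
                    if k == "harmonics" else v
            else:
                out[k] = v
        return out

    @classmethod
    def from_jsonable(cls, d: dict) -> "TrialTruth":
        kw = dict(d)
        for k in ("heel_strikes_left", "heel_strikes_right", "toe_offs_left",
                  "toe_offs_right", "mid_swings_left", "mid_swings_right",
                  "stride_durations_left", "stride_durations_right"):
            kw[k] = np.asarray(kw[k], dtype=float)
        kw["harmonics"] = {ax: {int(h): float(a) for h, a in amps.items()}
                           for ax, amps in kw["harmonics"].items()}
        return cls(**kw)


@dataclass
class GaitTrial:
    """One child's walking trial: trunk acceleration + per-leg shank gyro."""

    child_id: str
    fs: float
    time_s: np.ndarray
    trunk_acc: dict[str, np.ndarray]          # keys "v", "ml", "ap"; m/s^2
    shank_gyro_left: np.ndarray               # (N, 3), deg/s; sagittal = col 2
    shank_gyro_right: np.ndarray
    truth: Optional[TrialTruth] = None
    params: Optional[GaitParams] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for ax in AXES:
            if len(self.trunk_acc[ax]) != n:
                raise ValidationError(f"trunk_acc[{ax}] length mismatch")
        if self.shank_gyro_left.shape != (n, 3) or self.shank_gyro_right.shape != (n, 3):
            raise ValidationError("shank gyro arrays must be (N, 3)")


def _add_gaussians(signal: np.ndarray, t: np.ndarray, centers: np.ndarray,
                   amp: float, sigma: float) -> None:
    fs = 1.0 / (t[1] - t[0])
    half = int(np.ceil(4 * sigma * fs))
    for c in centers:
        i = int(round((c - t[0]) * fs))
        lo, hi = max(0, i - half), min(len(t), i + half + 1)
        if lo >= hi:
            continue
        signal[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)


def generate_gait_trial(child: ChildRecord, params: GaitParams,
                        seed: int, with_truth: bool = True) -> GaitTrial:
    """Synthesize one walking trial for ``child``.

    Deterministic given (seed, child_id). Raises if fewer than 10 complete
    strides fit in ``duration_s`` and truth annotations were requested.
    """
    rng = child_rng(seed, child.child_id, "gait")
    fs, dur = params.fs, params.duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    # Stride (gait-cycle) durations; left heel strikes are cycle boundaries.
    mean_c, sd_c = params.stride_time_mean, params.stride_time_sd
    durs = []
    t0 = 0.5
    total = t0
    while total < dur - 0.3:
        c = max(0.4 * mean_c, rng.normal(mean_c, sd_c))
        if total + c > dur - 0.3:
            break
        durs.append(c)
        total += c
    durs = np.asarray(durs)
    if with_truth and len(durs) < 10:
        raise ValidationError(
            f"duration {dur}s holds only {len(durs)} strides; >=10 required for truth"
        )

    hs_left = t0 + np.concatenate([[0.0], np.cumsum(durs)])   # len(durs)+1 events
    a = params.step_asymmetry
    phi = 1.0 / (1.0 + a)          # right heel strike at phi of the cycle
    s = params.stance_fraction
    hs_right = hs_left[:-1] + phi * durs
    to_left = hs_left[:-1] + s * durs
    ms_left = hs_left[:-1] + (s + 0.5 * (1 - s)) * durs
    durs_right = np.diff(hs_right)
    r_last = durs_right[-1] if len(durs_right) else mean_c
    to_right = hs_right + s * np.concatenate([durs_right, [r_last]])
    ms_right = hs_right + (s + 0.5 * (1 - s)) * np.concatenate([durs_right, [r_last]])

    # Shank gyro: mid-swing positive peak, negative dips at toe-off and heel
    # strike; off-sagittal channels carry only low-level noise.
    sig_ms = 0.05 * mean_c
    sig_e = 0.025 * mean_c
    amp = params.gyro_peak_amp
    gyros = {}
    for leg, (hs, to, ms) in (("left", (hs_left, to_left, ms_left)),
                              ("right", (hs_right, to_right, ms_right))):
        sag = np.zeros(n)
        _add_gaussians(sag, t, ms, amp, sig_ms)
        _add_gaussians(sag, t, hs, -0.5 * amp, sig_e)
        _add_gaussians(sag, t, to, -0.4 * amp, sig_e)
        g = rng.normal(0.0, params.gyro_noise_sd, size=(n, 3))
        g[:, 2] += sag
        gyros[leg] = g

    # Trunk acceleration: per-stride harmonic series on the stride's own phase.
    trunk = {}
    idx = np.searchsorted(hs_left, t, side="right") - 1
    in_stride = (idx >= 0) & (idx < len(durs))
    ii = np.clip(idx, 0, max(0, len(durs) - 1))
    theta = np.where(in_stride, (t - hs_left[ii]) / durs[ii] if len(durs) else 0.0, 0.0)
    for ax in AXES:
        x = np.zeros(n)
        for k, ak in params.harmonics.get(ax, {}).items():
            x += np.where(in_stride, ak * np.sin(2 * np.pi * k * theta), 0.0)
        x += rng.normal(0.0, params.noise_sd, size=n)
        trunk[ax] = x

    truth = None
    if with_truth:
        truth = TrialTruth(
            heel_strikes_left=hs_left,
            heel_strikes_right=hs_right,
            toe_offs_left=to_left,
            toe_offs_right=to_right,
            mid_swings_left=ms_left,
            mid_swings_right=ms_right,
            stride_durations_left=durs,
            stride_durations_right=durs_right,
            harmonics={ax: dict(params.harmonics.get(ax, {})) for ax in AXES},
            stance_fraction=s,
            step_phase=phi,
        )
    return GaitTrial(child_id=child.child_id, fs=fs, time_s=t, trunk_acc=trunk,
                     shank_gyro_left=gyros["left"], shank_gyro_right=gyros["right"],
                     truth=truth, params=params)


TRIAL_COLUMNS = ["time_s", "trunk_v", "trunk_ml", "trunk_ap",
                 "gyroL_x", "gyroL_y", "gyroL_z", "gyroR_x", "gyroR_y", "gyroR_z"]


def write_trial_csv(trial: GaitTrial, csv_path, meta_path=None) -> None:
    """Write the trial as CSV plus a JSON sidecar with fs and ground truth."""
    df = pd.DataFrame({
        "time_s": trial.time_s,
        "trunk_v": trial.trunk_acc["v"],
        "trunk_ml": trial.trunk_acc["ml"],
        "trunk_ap": trial.trunk_acc["ap"],
        "gyroL_x": trial.shank_gyro_left[:, 0],
        "gyroL_y": trial.shank_gyro_left[:, 1],
        "gyroL_z": trial.shank_gyro_left[:, 2],
        "gyroR_x": trial.shank_gyro_right[:, 0],
        "gyroR_y": trial.shank_gyro_right[:, 1],
        "gyroR_z": trial.shank_gyro_right[:, 2],
    })
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {"child_id": trial.child_id, "fs": trial.fs,
            "truth": trial.truth.to_jsonable() if trial.truth else None}
    meta_path = meta_path or Path(str(csv_path)).with_suffix(".json")
    Path(meta_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_trial_csv(csv_path, meta_path=None) -> GaitTrial:
    df = pd.read_csv(csv_path)
    meta_path = meta_path or Path(str(csv_path)).with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    truth = TrialTruth.from_jsonable(meta["truth"]) if meta.get("truth") else None
    return GaitTrial(
        child_id=meta["child_id"], fs=float(meta["fs"]),
        time_s=df["time_s"].to_numpy(),
        trunk_acc={"v": df["trunk_v"].to_numpy(), "ml": df["trunk_ml"].to_numpy(),
                   "ap": df["trunk_ap"].to_numpy()},
        shank_gyro_left=df[["gyroL_x", "gyroL_y", "gyroL_z"]].to_numpy(),
        shank_gyro_right=df[["gyroR_x", "gyroR_y", "gyroR_z"]].to_numpy(),
        truth=truth,
    )
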