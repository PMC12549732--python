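"""Gait-event detection and temporal gait parameters.

Events are detected from shank angular velocity using the standard sagittal
convention: the swing phase produces one dominant positive peak (mid-swing);
the most prominent minimum shortly after it marks heel strike and the most
prominent minimum shortly before it marks toe-off. From left/right event
series the stride, step, stance and double-support times follow, together
with a dimensionless (Hof-style) stride-time normalization and Poincaré
variability indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import signal as sps

from .errors import (EventSequenceError, InsufficientStrides, NoStridesDetected,
                     ValidationError)

G_M_S2 = 9.81


class EventConfig(BaseModel):
    """Thresholds of the event detector. All values are tunable configuration."""

    model_config = ConfigDict(extra="forbid")

    band_hz: tuple[float, float] = (0.5, 10.0)
    filter_order: int = 4
    midswing_threshold: float = 50.0         # deg/s
    min_stride_gap_s: float = 0.4
    hs_window_s: tuple[float, float] = (0.05, 0.4)   # after mid-swing
    to_window_s: tuple[float, float] = (0.4, 0.05)   # before mid-swing
    #: "auto" picks the gyro channel with maximal variance as sagittal.
    sagittal_axis: Literal["auto", 0, 1, 2] = "auto"


@dataclass
class StrideSeries:
    """Detected event times (s) for one leg."""

    leg: Literal["left", "right"]
    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    mid_swings: np.ndarray

    def __post_init__(self) -> None:
        for name in ("heel_strikes", "toe_offs", "mid_swings"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ValidationError(f"{self.leg} {name} not strictly increasing")

    @property
    def n_strides(self) -> int:
        return max(0, len(self.heel_strikes) - 1)

    def stride_times(self) -> np.ndarray:
        return np.diff(self.heel_strikes)


def select_sagittal_axis(gyro: np.ndarray, cfg: EventConfig) -> np.ndarray:
    """Return the 1-D sagittal angular-velocity series from an (N,3) array."""
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim == 1:
        return gyro
    if cfg.sagittal_axis == "auto":
        axis = int(np.argmax(np.var(gyro, axis=0)))
    else:
        axis = int(cfg.sagittal_axis)
    return gyro[:, axis]


def _most_prominent_minimum(seg: np.ndarray) -> Optional[int]:
    """Index of the most prominent local minimum of ``seg``; None if monotone."""
    peaks, props = sps.find_peaks(-seg, prominence=0)
    if len(peaks) == 0:
        return None
    return int(peaks[np.argmax(props["prominences"])])


def detect_gait_events(gyro_sagittal: np.ndarray, fs: float,
                       config: Optional[EventConfig] = None,
                       leg: Literal["left", "right"] = "left") -> StrideSeries:
    """Detect mid-swing, heel-strike and toe-off times from shank gyro.

    ``gyro_sagittal`` may be an (N,) sagittal series or an (N,3) gyro block
    from which the sagittal axis is selected per config. Raises
    ``NoStridesDetected`` if no mid-swing peak clears the threshold and
    ``InsufficientStrides`` below 3 detected strides.
    """
    cfg = config or EventConfig()
    if fs <= 0:
        raise ValidationError("fs must be positive")
    x = select_sagittal_axis(gyro_sagittal, cfg)
    if len(x) < 2 * fs:
        raise ValidationError("need at least 2 s of data")

    lo, hi = cfg.band_hz
    sos = sps.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)

    peaks, _ = sps.find_peaks(xf, height=cfg.midswing_threshold,
                              distance=max(1, int(cfg.min_stride_gap_s * fs)))
    if len(peaks) == 0:
        raise NoStridesDetected("no mid-swing peak above threshold")

    hs_idx, to_idx, ms_idx = [], [], []
    w_hs = (int(cfg.hs_window_s[0] * fs), int(cfg.hs_window_s[1] * fs))
    w_to = (int(cfg.to_window_s[0] * fs), int(cfg.to_window_s[1] * fs))
    for p in peaks:
        a, b = p + w_hs[0], min(len(xf), p + w_hs[1] + 1)
        c, d = max(0, p - w_to[0]), p - w_to[1] + 1
        if b - a < 3 or d - c < 3:
            continue
        seg_hs = xf[a:b]
        seg_to = xf[c:d]
        i_hs = _most_prominent_minimum(seg_hs)
        i_to = _most_prominent_minimum(seg_to)
        if i_hs is None:
            i_hs = int(np.argmin(seg_hs))
        if i_to is None:
            i_to = int(np.argmin(seg_to))
        ms_idx.append(p)
        hs_idx.append(a + i_hs)
        to_idx.append(c + i_to)

    if len(ms_idx) < 3:
        raise InsufficientStrides(f"only {len(ms_idx)} strides detected")
    return StrideSeries(
        leg=leg,
        heel_strikes=np.asarray(hs_idx) / fs,
        toe_offs=np.asarray(to_idx) / fs,
        mid_swings=np.asarray(ms_idx) / fs,
    )


@dataclass
class TemporalParams:
    """Stride/step/stance/double-support summary for one trial."""

    stride_times_left: np.ndarray
    stride_times_right: np.ndarray
    step_times_left: np.ndarray       # contralateral HS -> left HS
    step_times_right: np.ndarray      # left HS -> right HS
    stance_pct_left: np.ndarray       # per left stride, % of stride time
    stance_pct_right: np.ndarray
    ds_pct_left: np.ndarray           # per left stride, % of stride time
    ds_pct_right: np.ndarray
    strideT: float = field(init=False)
    stepT: float = field(init=False)
    stanceT: float = field(init=False)
    DS: float = field(init=False)
    nstrideT: Optional[float] = None
    nstepT: Optional[float] = None

    def __post_init__(self) -> None:
        self.strideT = float(np.mean(np.concatenate(
            [self.stride_times_left, self.stride_times_right])))
        self.stepT = float(np.mean(np.concatenate(
            [self.step_times_left, self.step_times_right])))
        self.stanceT = float(np.mean(self.stance_pct))
        self.DS = float(np.mean(self.ds_pct))
        if not (0 < self.stanceT < 100):
            raise ValidationError(f"stanceT {self.stanceT} outside (0, 100)")
        if not (0 <= self.DS < self.stanceT):
            raise ValidationError(f"DS {self.DS} not in [0, stanceT)")

    @property
    def stance_pct(self) -> np.ndarray:
        return np.concatenate([self.stance_pct_left, self.stance_pct_right])

    @property
    def ds_pct(self) -> np.ndarray:
        return np.concatenate([self.ds_pct_left, self.ds_pct_right])

    def stride_times(self) -> np.ndarray:
        return np.concatenate([self.stride_times_left, self.stride_times_right])

    def step_times(self) -> np.ndarray:
        return np.concatenate([self.step_times_left, self.step_times_right])


def _events_between(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return times[(times > lo) & (times < hi)]


def temporal_parameters(left: StrideSeries, right: StrideSeries,
                        body_length_m: Optional[float] = None) -> TemporalParams:
    """Compute stride/step/stance/double-support times from left/right events.

    Per ipsilateral stride (heel strike to next heel strike): stance% is the
    ipsilateral toe-off delay, double support% is the sum of the two bilateral
    overlap intervals (contralateral toe-off after ipsilateral heel strike,
    plus ipsilateral toe-off after contralateral heel strike).

    ``nstrideT``/``nstepT`` are Hof-dimensionless: t / sqrt(L / g) with L the
    body length (m); omitted with a warning when L is unknown.
    """
    for s in (left, right):
        if s.n_strides < 3:
            raise InsufficientStrides(f"{s.leg}: {s.n_strides} strides (<3)")

    stance = {"left": [], "right": []}
    ds = {"left": [], "right": []}
    steps = {"left": [], "right": []}
    for ipsi, contra in ((left, right), (right, left)):
        for i in range(ipsi.n_strides):
            t0, t1 = ipsi.heel_strikes[i], ipsi.heel_strikes[i + 1]
            c = t1 - t0
            hs_c = _events_between(contra.heel_strikes, t0, t1)
            if len(hs_c) != 1:
                raise EventSequenceError(
                    f"{ipsi.leg} stride [{t0:.3f}, {t1:.3f}] contains "
                    f"{len(hs_c)} contralateral heel strikes (expected 1)")
            to_i = _events_between(ipsi.toe_offs, t0, t1)
            to_c = _events_between(contra.toe_offs, t0, hs_c[0])
            # step: ipsilateral HS -> contralateral HS
            steps[contra.leg].append(float(hs_c[0] - t0))
            if len(to_i) != 1 or len(to_c) != 1:
                continue   # edge stride without both toe-offs
            stance[ipsi.leg].append(float(to_i[0] - t0) / c * 100.0)
            ds[ipsi.leg].append(
                (float(to_c[0] - t0) + float(to_i[0] - hs_c[0])) / c * 100.0)

    if not (stance["left"] or stance["right"]):
        raise EventSequenceError("no stride with a complete toe-off pattern")
    tp = TemporalParams(
        stride_times_left=left.stride_times(),
        stride_times_right=right.stride_times(),
        step_times_left=np.asarray(steps["left"], dtype=float),
        step_times_right=np.asarray(steps["right"], dtype=float),
        stance_pct_left=np.asarray(stance["left"], dtype=float),
        stance_pct_right=np.asarray(stance["right"], dtype=float),
        ds_pct_left=np.asarray(ds["left"], dtype=float),
        ds_pct_right=np.asarray(ds["right"], dtype=float),
    )
    if body_length_m is None:
        warnings.warn("body length unknown: stride-time normalization skipped")
    else:
        tau = np.sqrt(body_length_m / G_M_S2)
        tp.nstrideT = tp.strideT / tau
        tp.nstepT = tp.stepT / tau
    return tp


def symmetry_index(mean_left: float, mean_right: float) -> float:
    """Relative absolute left/right difference, % of the leg-average.

    0 for perfect symmetry; invariant under leg relabelling.
    """
    denom = 0.5 * (mean_left + mean_right)
    if denom == 0:
        raise ValidationError("zero mean in symmetry index")
    return 100.0 * abs(mean_left - mean_right) / denom


def symmetry_indices(tp: TemporalParams) -> tuple[float, float]:
    """(symm_stride, symm_step) from per-leg stride and step time means."""
    for arr in (tp.stride_times_left, tp.stride_times_right,
                tp.step_times_left, tp.step_times_right):
        if len(arr) == 0:
            raise ValidationError("empty stride/step list")
    symm_stride = symmetry_index(float(np.mean(tp.stride_times_left)),
                                 float(np.mean(tp.stride_times_right)))
    symm_step = symmetry_index(float(np.mean(tp.step_times_left)),
                               float(np.mean(tp.step_times_right)))
    return symm_stride, symm_step


@dataclass
class PoincareResult:
    SD1: float
    SD2: float
    std: float


def poincare(x: Sequence[float]) -> PoincareResult:
    """Poincaré short/long-term variability of a stride-to-stride series.

    SD1 follows the RMSSD convention (root mean square of successive
    differences, uncentered, over sqrt(2)); std and SD2 use the population
    (1/N) variance, so that SD1^2 + SD2^2 = 2 std^2 exactly (SD2 is floored
    at 0 in the degenerate strongly anticorrelated case).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValidationError("poincare requires at least 3 points")
    d = np.diff(x)
    sd1 = float(np.sqrt(np.mean(d ** 2) / 2.0))
    var = float(np.var(x))
    sd2 = float(np.sqrt(max(0.0, 2.0 * var - sd1 ** 2)))
    return PoincareResult(SD1=sd1, SD2=sd2, std=float(np.sqrt(var)))
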