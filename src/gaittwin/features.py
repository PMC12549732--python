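"""Assembly of the per-child metric vector.

One row per child: temporal gait parameters, motor-quality metrics (harmonic
ratios, symmetry indices), Poincaré variability of the temporal parameters,
multiscale sample entropy and RQA of the three trunk-acceleration axes, plus
the retained clinical covariates. Gestational age and birth weight are never
included as features because they define the high-risk label.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .cohort import ChildRecord
from .complexity import ComplexityConfig, harmonic_ratio, multiscale_entropy, rqa
from .errors import ValidationError
from .events import (EventConfig, PoincareResult, StrideSeries, TemporalParams,
                     detect_gait_events, poincare, symmetry_indices,
                     temporal_parameters)
from .gaitsim import AXES, GaitTrial

TEMPORAL_NAMES = ["strideT", "nstrideT", "stepT", "nstepT", "stanceT", "DS"]
HR_NAMES = [f"HR_{ax}" for ax in AXES]
SYMM_NAMES = ["symm_stride", "symm_step"]
VARIABILITY_NAMES = [f"{p}_{s}" for p in ("strideT", "stepT", "DS")
                     for s in ("SD1", "SD2", "std")]
SEN_NAMES = [f"SEN_{ax}_{tau}" for ax in AXES for tau in range(1, 7)]
RQA_NAMES = [f"{m}_{ax}" for ax in AXES for m in ("RR", "DET", "AvgL")]
CLINICAL_FEATURES = ["sex", "twin", "length_birth_cm", "length_t24_cm",
                     "weight_t24_g", "walk_exp_weeks", "cog_score"]

#: Feature columns of the metric vector, fixed order. GA and birth weight are
#: deliberately absent (they define the class label).
FEATURE_NAMES = (TEMPORAL_NAMES + HR_NAMES + SYMM_NAMES + VARIABILITY_NAMES
                 + SEN_NAMES + RQA_NAMES + CLINICAL_FEATURES)

#: Full metric-vector schema: identifier + features + labels.
METRIC_COLUMNS = ["child_id"] + FEATURE_NAMES + ["group", "risk"]

_FORBIDDEN_FEATURES = {"ga_weeks", "bw_g"}


def _poincare_or_nan(x: np.ndarray) -> PoincareResult:
    if len(x) < 3:
        return PoincareResult(float("nan"), float("nan"), float("nan"))
    return poincare(x)


def _interleaved_steps(tp: TemporalParams) -> np.ndarray:
    """Step times in temporal order (right step then left step per cycle)."""
    n = min(len(tp.step_times_right), len(tp.step_times_left))
    out = np.empty(2 * n)
    out[0::2] = tp.step_times_right[:n]
    out[1::2] = tp.step_times_left[:n]
    return out


def assemble_metric_vector(child: ChildRecord,
                           temporal: Optional[TemporalParams],
                           hrs: dict[str, float],
                           mse: dict[str, dict[int, float]],
                           rqa_res: dict[str, object]) -> dict:
    """Merge all per-trial metrics and clinical covariates into one row.

    Missing components are represented as NaN; the schema (column set and
    order) is always :data:`METRIC_COLUMNS`.
    """
    row: dict = {name: float("nan") for name in FEATURE_NAMES}
    row["child_id"] = child.child_id
    row["group"] = child.group
    row["risk"] = child.risk

    if temporal is not None:
        row["strideT"] = temporal.strideT
        row["stepT"] = temporal.stepT
        row["stanceT"] = temporal.stanceT
        row["DS"] = temporal.DS
        row["nstrideT"] = temporal.nstrideT if temporal.nstrideT is not None else float("nan")
        row["nstepT"] = temporal.nstepT if temporal.nstepT is not None else float("nan")
        symm_stride, symm_step = symmetry_indices(temporal)
        row["symm_stride"] = symm_stride
        row["symm_step"] = symm_step
        for pname, series in (("strideT", temporal.stride_times_left),
                              ("stepT", _interleaved_steps(temporal)),
                              ("DS", temporal.ds_pct_left)):
            pr = _poincare_or_nan(np.asarray(series))
            row[f"{pname}_SD1"] = pr.SD1
            row[f"{pname}_SD2"] = pr.SD2
            row[f"{pname}_std"] = pr.std

    for ax in AXES:
        if ax in hrs:
            row[f"HR_{ax}"] = hrs[ax]
        for tau, v in mse.get(ax, {}).items():
            row[f"SEN_{ax}_{tau}"] = v
        if ax in rqa_res:
            r = rqa_res[ax]
            row[f"RR_{ax}"] = r.RR
            row[f"DET_{ax}"] = r.DET
            row[f"AvgL_{ax}"] = r.AvgL

    row["sex"] = 1.0 if child.sex == "F" else 0.0
    row["twin"] = 1.0 if child.twin else 0.0
    for name in ("length_birth_cm", "length_t24_cm", "weight_t24_g",
                 "walk_exp_weeks"):
        row[name] = float(getattr(child, name))
    row["cog_score"] = float(child.cog_score) if child.cog_score is not None else float("nan")

    assert not (_FORBIDDEN_FEATURES & set(row)), "risk-defining variables leaked"
    return row


def extract_features(trial: GaitTrial, child: ChildRecord,
                     event_cfg: Optional[EventConfig] = None,
                     cx_cfg: Optional[ComplexityConfig] = None) -> dict:
    """Run the full metric battery on one trial and return the metric row."""
    if trial.child_id != child.child_id:
        raise ValidationError("trial/child id mismatch")
    event_cfg = event_cfg or EventConfig()
    cx_cfg = cx_cfg or ComplexityConfig()

    left = detect_gait_events(trial.shank_gyro_left, trial.fs, event_cfg, leg="left")
    right = detect_gait_events(trial.shank_gyro_right, trial.fs, event_cfg, leg="right")
    tp = temporal_parameters(left, right, body_length_m=child.length_t24_cm / 100.0)

    hrs = {ax: harmonic_ratio(trial.trunk_acc[ax], left.heel_strikes, trial.fs,
                              axis=ax, cfg=cx_cfg) for ax in AXES}
    mse = {ax: multiscale_entropy(trial.trunk_acc[ax], cx_cfg) for ax in AXES}
    rqa_res = {ax: rqa(trial.trunk_acc[ax], cx_cfg) for ax in AXES}
    return assemble_metric_vector(child, tp, hrs, mse, rqa_res)


def metrics_frame(rows: list[dict]) -> pd.DataFrame:
    """Rows from :func:`assemble_metric_vector` as a schema-ordered DataFrame."""
    df = pd.DataFrame(rows)
    return df[METRIC_COLUMNS]
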