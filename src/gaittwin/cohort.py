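"""Synthetic cohort of preterm and full-term toddlers.

Generates per-child clinical records with the composition used throughout the
pipeline: a preterm group (gestational age <= 37 weeks) and full-term controls,
with a clinical high-risk rule of GA <= 28 weeks and/or birth weight <= 1000 g.
All covariate distributions are configuration, not claims about any real
sample; defaults are chosen to be clinically plausible for an Italian
follow-up population assessed at 24 months corrected age.
"""

from __future__ import annotations

import hashlib
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ValidationError

RiskLabel = Literal["high", "low"]
Group = Literal["fullterm", "preterm"]

#: High-risk rule thresholds: extremely preterm and/or extremely low birth weight.
HIGH_RISK_GA_WEEKS = 28.0
HIGH_RISK_BW_G = 1000.0


def assign_risk_label(ga_weeks: float, bw_g: float) -> RiskLabel:
    """Clinical risk rule: high iff GA <= 28 weeks or birth weight <= 1000 g.

    Parameters
    ----------
    ga_weeks : gestational age at birth, weeks (> 0).
    bw_g : birth weight, grams (> 0).
    """
    if ga_weeks <= 0 or bw_g <= 0:
        raise ValidationError(
            f"ga_weeks and bw_g must be positive, got {ga_weeks}, {bw_g}"
        )
    if ga_weeks <= HIGH_RISK_GA_WEEKS or bw_g <= HIGH_RISK_BW_G:
        return "high"
    return "low"


class GaitEffects(BaseModel):
    """Additive/multiplicative shifts applied to a group's gait parameters.

    Directions default to the high-risk pattern the analyses are designed to
    detect: slower cadence (longer stride), more variable timing, longer
    double support, a more periodic (harmonic-dominated) and less noisy trunk
    signal, i.e. a more automatic, less complex gait.
    """

    model_config = ConfigDict(extra="forbid")

    stride_time_shift_s: float = 0.0
    stride_time_sd_scale: float = 1.0
    double_support_shift_pct: float = 0.0
    harmonic_amp_scale: float = 1.0
    noise_scale: float = 1.0


#: Default high-risk effect sizes (low-risk children use the neutral defaults).
DEFAULT_EFFECTS: dict[str, GaitEffects] = {
    "high": GaitEffects(
        stride_time_shift_s=0.10,
        stride_time_sd_scale=1.8,
        double_support_shift_pct=4.0,
        harmonic_amp_scale=1.5,
        noise_scale=0.4,
    ),
    "low": GaitEffects(),
}


class CohortSpec(BaseModel):
    """Configuration for cohort generation.

    Defaults reproduce the study composition: 29 preterm (<= 37 wk GA) and
    17 full-term controls, with an expected high-risk count close to 8 of 46.
    """

    model_config = ConfigDict(extra="forbid")

    n_preterm: int = Field(default=29, ge=0)
    n_fullterm: int = Field(default=17, ge=0)
    ga_preterm_range: tuple[float, float] = (23.0, 36.0)
    #: Shape of the preterm GA distribution: GA = low + (high-low) * U**(1/skew).
    #: skew > 1 weights late-preterm weeks more, as observed clinically.
    ga_preterm_skew: float = Field(default=1.4, gt=0)
    ga_fullterm_mean_sd: tuple[float, float] = (39.5, 1.0)
    #: Birth weight | GA: linear mean above a 22-week baseline, Gaussian noise.
    bw_baseline_g: float = Field(default=500.0, gt=0)
    bw_slope_g_per_wk: float = Field(default=180.0, ge=0)
    bw_sd_g: float = Field(default=250.0, ge=0)
    bw_floor_g: float = Field(default=350.0, gt=0)
    effect_sizes: dict[str, GaitEffects] = Field(
        default_factory=lambda: {k: v.model_copy() for k, v in DEFAULT_EFFECTS.items()}
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "CohortSpec":
        lo, hi = self.ga_preterm_range
        if not (22.0 <= lo <= hi <= 42.0):
            raise ValidationError(f"ga_preterm_range {self.ga_preterm_range} outside [22, 42]")
        mu, sd = self.ga_fullterm_mean_sd
        if not (22.0 <= mu <= 42.0) or sd < 0:
            raise ValidationError(f"invalid ga_fullterm_mean_sd {self.ga_fullterm_mean_sd}")
        return self


class ChildRecord(BaseModel):
    """One child's clinical variables, group membership and risk label."""

    model_config = ConfigDict(extra="forbid")

    child_id: str
    sex: Literal["F", "M"]
    ga_weeks: float = Field(ge=22.0, le=42.0)
    twin: bool
    bw_g: float = Field(gt=0)
    length_birth_cm: float = Field(gt=0)
    length_t24_cm: float = Field(gt=0)
    weight_t24_g: float = Field(gt=0)
    walk_exp_weeks: float = Field(ge=0)
    cog_score: Optional[float] = None
    group: Group
    risk: RiskLabel

    @model_validator(mode="after")
    def _check_risk(self) -> "ChildRecord":
        expected = assign_risk_label(self.ga_weeks, self.bw_g)
        if self.risk != expected:
            raise ValidationError(
                f"{self.child_id}: risk={self.risk} inconsistent with rule ({expected})"
            )
        return self


def child_rng(master_seed: int, child_id: str, stream: str = "") -> np.random.Generator:
    """Per-child random stream derived by stable hashing of (seed, id, stream)."""
    digest = hashlib.sha256(f"{master_seed}|{child_id}|{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def _make_child(spec: CohortSpec, idx: int, group: Group) -> ChildRecord:
    child_id = f"{'pt' if group == 'preterm' else 'ft'}{idx:03d}"
    rng = child_rng(spec.seed, child_id, "clinical")

    if group == "preterm":
        lo, hi = spec.ga_preterm_range
        ga = lo + (hi - lo) * rng.uniform() ** (1.0 / spec.ga_preterm_skew)
        twin = bool(rng.uniform() < 0.20)
    else:
        mu, sd = spec.ga_fullterm_mean_sd
        ga = float(np.clip(rng.normal(mu, sd), 37.5, 42.0))
        twin = bool(rng.uniform() < 0.03)

    bw_mean = spec.bw_baseline_g + spec.bw_slope_g_per_wk * (ga - 22.0)
    bw = max(spec.bw_floor_g, rng.normal(bw_mean, spec.bw_sd_g))
    # label from the stored (rounded) values so the rule holds exactly
    ga, bw = round(ga, 1), round(bw, 0)
    risk = assign_risk_label(ga, bw)

    sex = "F" if rng.uniform() < 0.5 else "M"
    length_birth = float(np.clip(50.0 + 1.1 * (ga - 40.0) + rng.normal(0, 1.5), 25.0, 58.0))
    deficit = 1.5 if risk == "high" else 0.0
    length_t24 = float(np.clip(rng.normal(87.0 - deficit, 3.0), 75.0, 98.0))
    weight_t24 = float(np.clip(rng.normal(12000.0 - (800.0 if risk == "high" else 0.0), 1200.0), 8000.0, 17000.0))
    walk_exp = float(np.clip(rng.normal(44.0 - (6.0 if risk == "high" else 0.0), 8.0), 8.0, 62.0))
    base_cog = 100.0 - (10.0 if risk == "high" else (5.0 if group == "preterm" else 0.0))
    cog = float(np.clip(round(rng.normal(base_cog, 15.0)), 55.0, 145.0))

    return ChildRecord(
        child_id=child_id,
        sex=sex,
        ga_weeks=ga,
        twin=twin,
        bw_g=bw,
        length_birth_cm=round(length_birth, 1),
        length_t24_cm=round(length_t24, 1),
        weight_t24_g=round(weight_t24, 0),
        walk_exp_weeks=round(walk_exp, 1),
        cog_score=cog,
        group=group,
        risk=risk,
    )


def generate_cohort(spec: CohortSpec) -> list[ChildRecord]:
    """Generate the cohort deterministically from ``spec.seed``.

    Each child draws from an independent stream keyed by (seed, child_id), so
    records are stable under changes to cohort size or generation order.
    """
    children = [_make_child(spec, i, "preterm") for i in range(spec.n_preterm)]
    children += [_make_child(spec, i, "fullterm") for i in range(spec.n_fullterm)]
    return children


COHORT_COLUMNS = [
    "child_id", "sex", "ga_weeks", "twin", "bw_g", "length_birth_cm",
    "length_t24_cm", "weight_t24_g", "walk_exp_weeks", "cog_score",
    "group", "risk",
]


def cohort_to_frame(children: list[ChildRecord]) -> pd.DataFrame:
    df = pd.DataFrame([c.model_dump() for c in children])
    return df[COHORT_COLUMNS]


def write_cohort_csv(children: list[ChildRecord], path) -> None:
    cohort_to_frame(children).to_csv(path, index=False)


def read_cohort_csv(path) -> list[ChildRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict(orient="records"):
        if pd.isna(row.get("cog_score")):
            row["cog_score"] = None
        records.append(ChildRecord(**row))
    return records
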