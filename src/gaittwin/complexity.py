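"""Motor-quality and complexity metrics on trunk acceleration.

Implements the nonlinear battery used to characterise gait automaticity and
complexity: per-stride harmonic ratio, sample entropy and its multiscale
extension (coarse-graining at scales 1..6), and recurrence quantification
analysis (recurrence rate, determinism, average diagonal line length) on the
time-delay-embedded signal.

Conventions (all exposed through :class:`ComplexityConfig`):

* SampEn: m = 2, tolerance r = 0.2 x SD, Chebyshev distance, self-matches
  excluded; multiscale keeps r fixed from the scale-1 SD (original
  coarse-graining convention).
* RQA: embedding (5, 10 samples), radius 0.2 x SD, Euclidean norm, Theiler
  window 1, minimal diagonal length 2.
* Harmonic ratio: per stride, Fourier amplitudes at harmonics 1..20 of the
  stride's own fundamental; even/odd amplitude sums for V and AP, odd/even
  for ML; averaged across strides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree
from pydantic import BaseModel, ConfigDict, Field

from .errors import InsufficientStrides, ValidationError


class ComplexityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    m: int = Field(default=2, ge=1)
    r_frac: float = Field(default=0.2, gt=0)
    scales: list[int] = Field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    rqa_dim: int = Field(default=5, ge=2)
    rqa_delay: int = Field(default=10, ge=1)
    rqa_radius_frac: float = Field(default=0.2, gt=0)
    lmin: int = Field(default=2, ge=2)
    theiler: int = Field(default=1, ge=0)
    n_harmonics: int = Field(default=20, ge=2)
    hr_eps_den: float = Field(default=1e-9, gt=0)
    hr_cap: float = Field(default=50.0, gt=0)


# ---------------------------------------------------------------------------
# Harmonic ratio

def harmonic_ratio(acc: np.ndarray, stride_events: Sequence[float], fs: float,
                   axis: Literal["v", "ml", "ap"],
                   cfg: ComplexityConfig | None = None) -> float:
    """Mean per-stride harmonic ratio of one trunk-acceleration axis.

    ``stride_events`` are consecutive ipsilateral heel-strike times bounding
    the strides. Within each stride the signal is linearly detrended and its
    Fourier amplitudes taken at harmonics 1..K of that stride's fundamental
    (the stride spans exactly one fundamental period, so harmonic k is DFT
    bin k of the stride segment). V and AP use even/odd amplitude sums, ML
    the reciprocal, reflecting the biphasic (two steps) vs. monophasic (one
    sway) structure of a stride.
    """
    cfg = cfg or ComplexityConfig()
    acc = np.asarray(acc, dtype=float)
    ev = np.asarray(stride_events, dtype=float)
    if len(ev) < 4:
        raise InsufficientStrides("harmonic ratio requires >= 3 complete strides")
    ratios = []
    capped = 0
    for t0, t1 in zip(ev[:-1], ev[1:]):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = acc[max(0, i0):min(len(acc), i1)]
        if len(seg) < 2 * cfg.n_harmonics + 2:
            continue
        # DC removal only: a least-squares linear detrend over a single
        # period has non-zero slope for odd harmonics and would leak power
        # across bins, biasing the even/odd amplitude sums.
        x = seg - seg.mean()
        spec = np.fft.rfft(x)
        kmax = min(cfg.n_harmonics, len(spec) - 1)
        amps = 2.0 * np.abs(spec[1:kmax + 1]) / len(x)
        even = float(np.sum(amps[1::2]))   # harmonics 2, 4, ...
        odd = float(np.sum(amps[0::2]))    # harmonics 1, 3, ...
        num, den = (even, odd) if axis in ("v", "ap") else (odd, even)
        if den < cfg.hr_eps_den:
            ratios.append(cfg.hr_cap)
            capped += 1
        else:
            ratios.append(num / den)
    if len(ratios) < 3:
        raise InsufficientStrides("fewer than 3 usable strides for harmonic ratio")
    if capped:
        warnings.warn(f"harmonic ratio denominator ~0 in {capped} strides; capped")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Sample entropy / multiscale entropy

def _match_counts(x: np.ndarray, m: int, r_abs: float) -> tuple[int, int]:
    """Pairs (i<j) of m- and (m+1)-templates within Chebyshev distance r.

    Both template lengths use the same index range (the first N-m windows),
    so the m-template of every counted pair has an (m+1)-extension. Counting
    goes through a KD-tree under the max norm; the result is an exact integer
    pair count, identical to the O(N^2) double loop.
    """
    tpl = sliding_window_view(x, m + 1)          # (n-m, m+1)
    tree_m = cKDTree(tpl[:, :m])
    tree_m1 = cKDTree(tpl)
    b_count = (tree_m.count_neighbors(tree_m, r_abs, p=np.inf) - len(tpl)) // 2
    a_count = (tree_m1.count_neighbors(tree_m1, r_abs, p=np.inf) - len(tpl)) // 2
    return int(b_count), int(a_count)


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    B counts template pairs of length m, A of length m+1 (self-matches
    excluded); SampEn = -ln(A/B). Returns NaN with a warning when no pairs
    match at either length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= m + 1:
        raise ValidationError(f"series length {len(x)} <= m+1 = {m + 1}")
    if r_abs is None or r_abs <= 0:
        raise ValidationError("r_abs must be positive")
    b, a = _match_counts(x, m, r_abs)
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no template matches)")
        return float("nan")
    return float(-np.log(a / b))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Means of consecutive non-overlapping windows of length ``scale``."""
    x = np.asarray(x, dtype=float)
    n = (len(x) // scale) * scale
    if n == 0:
        raise ValidationError(f"series too short for scale {scale}")
    return x[:n].reshape(-1, scale).mean(axis=1)


def multiscale_entropy(x: np.ndarray, cfg: ComplexityConfig | None = None
                       ) -> dict[int, float]:
    """SampEn of the coarse-grained series at each configured scale.

    The tolerance r is fixed at r_frac x SD of the original (scale-1) series
    for every scale. A scale whose coarse-grained series is too short yields
    NaN for that scale only, with a warning.
    """
    cfg = cfg or ComplexityConfig()
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        return {tau: 0.0 for tau in cfg.scales}
    r_abs = cfg.r_frac * sd
    out: dict[int, float] = {}
    for tau in cfg.scales:
        try:
            y = coarse_grain(x, tau)
            if len(y) <= cfg.m + 1:
                raise ValidationError("coarse-grained series too short")
            out[tau] = sample_entropy(y, cfg.m, r_abs)
        except ValidationError:
            warnings.warn(f"series too short for MSE scale {tau}; NaN")
            out[tau] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Recurrence quantification analysis

@dataclass
class RQAResult:
    RR: float
    DET: float
    AvgL: float


def embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Time-delay embedding: rows x_i = (x[i], x[i+delay], ..., x[i+(dim-1)delay])."""
    x = np.asarray(x, dtype=float)
    n = len(x) - (dim - 1) * delay
    if n < 2:
        raise ValidationError("series too short to embed")
    return np.column_stack([x[i * delay:i * delay + n] for i in range(dim)])


def rqa(x: np.ndarray, cfg: ComplexityConfig | None = None) -> RQAResult:
    """Recurrence rate, determinism and average diagonal line length.

    The recurrence matrix uses Euclidean distance <= radius
    (radius = rqa_radius_frac x SD of x), excluding the Theiler band
    |i-j| <= theiler. Statistics are computed on the upper triangle
    (the matrix is symmetric). A zero-variance series returns the degenerate
    convention RR = DET = 1 with AvgL the longest possible diagonal.
    """
    cfg = cfg or ComplexityConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < cfg.rqa_dim * cfg.rqa_delay + 10:
        raise ValidationError("series too short for RQA embedding")
    emb = embed(x, cfg.rqa_dim, cfg.rqa_delay)
    npts = len(emb)
    sd = float(np.std(x))
    if sd == 0:
        return RQAResult(RR=1.0, DET=1.0, AvgL=float(npts - cfg.theiler - 1))
    radius = cfg.rqa_radius_frac * sd

    # Sparse recurrence: only pairs within the radius are materialised; the
    # diagonal-line statistics follow from run-length encoding of pairs
    # sharing an offset j - i with consecutive i.
    tree = cKDTree(emb)
    pairs = tree.query_pairs(radius, p=2.0, output_type="ndarray")
    offsets = pairs[:, 1] - pairs[:, 0]
    keep = offsets > cfg.theiler
    pairs, offsets = pairs[keep], offsets[keep]
    m = npts - cfg.theiler - 1
    total_pairs = m * (m + 1) // 2          # upper triangle beyond Theiler band
    rec_pairs = len(pairs)
    if rec_pairs == 0:
        return RQAResult(RR=0.0, DET=0.0, AvgL=0.0)

    order = np.lexsort((pairs[:, 0], offsets))
    i_sorted = pairs[order, 0]
    d_sorted = offsets[order]
    new_run = np.concatenate(
        [[True], (np.diff(d_sorted) != 0) | (np.diff(i_sorted) != 1)])
    run_id = np.cumsum(new_run)
    lengths = np.bincount(run_id)[1:]
    long_lines = lengths[lengths >= cfg.lmin]
    det = float(long_lines.sum() / rec_pairs)
    avgl = float(long_lines.mean()) if len(long_lines) else 0.0
    return RQAResult(RR=float(rec_pairs / total_pairs), DET=det, AvgL=avgl)
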