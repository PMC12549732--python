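"""Independent reference implementations used only as test oracles.

These deliberately use direct dense/double-loop formulations, independent of
the KD-tree and sparse-pair code paths in the package.
"""

from __future__ import annotations

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int, r_abs: float) -> float:
    """Sample entropy by explicit pairwise template comparison."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m          # both m- and (m+1)-templates over the same range
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r_abs:
                b += 1
                if max(d_m, abs(x[i + m] - x[j + m])) <= r_abs:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def sampen_bruteforce_fast(x: np.ndarray, m: int, r_abs: float) -> float:
    """Dense-matrix variant of the brute-force oracle (same counts)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    tpl = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    diff = np.abs(tpl[:, None, :] - tpl[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    d_m1 = diff.max(axis=2)
    iu = np.triu_indices(len(tpl), k=1)
    b = int(np.count_nonzero(d_m[iu] <= r_abs))
    a = int(np.count_nonzero(d_m1[iu] <= r_abs))
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def rqa_bruteforce(x: np.ndarray, dim: int, delay: int, radius_frac: float,
                   lmin: int, theiler: int) -> tuple[float, float, float]:
    """RQA statistics from the full dense recurrence matrix."""
    x = np.asarray(x, dtype=float)
    npts = len(x) - (dim - 1) * delay
    emb = np.column_stack([x[i * delay:i * delay + npts] for i in range(dim)])
    r = radius_frac * np.std(x)
    dist = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2))
    rec_mat = dist <= r
    total = rec = 0
    lengths = []
    for d in range(theiler + 1, npts):
        diag = np.diagonal(rec_mat, offset=d)
        total += len(diag)
        rec += int(diag.sum())
        run = 0
        for v in list(diag) + [False]:
            if v:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
    lengths = np.asarray(lengths, dtype=int)
    long_lines = lengths[lengths >= lmin]
    rr = rec / total if total else 0.0
    det = long_lines.sum() / rec if rec else 0.0
    avgl = float(long_lines.mean()) if len(long_lines) else 0.0
    return float(rr), float(det), float(avgl)


def dft_amplitudes(x: np.ndarray, kmax: int) -> np.ndarray:
    """Single-sided Fourier amplitudes at bins 1..kmax (direct summation)."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    amps = []
    for k in range(1, kmax + 1):
        c = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        amps.append(2 * abs(c) / n)
    return np.asarray(amps)
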