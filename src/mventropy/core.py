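"""Shared multiscale machinery: normalization, coarse-graining, embeddings.

Coarse-graining replaces each channel by non-overlapping window means of
width ``s`` (the scale factor); the refined-composite variant produces the
``s`` phase-shifted coarse series whose match statistics are later averaged.
Multivariate embedding concatenates, channel by channel, ``m`` delayed
samples of each of the ``p`` channels into a single composite vector.
"""

from __future__ import annotations

import numpy as np

from .containers import CoarseSeries, DegenerateInputError, MultichannelSeries

__all__ = [
    "zscore_channels",
    "coarse_grain",
    "refined_coarse_grain",
    "embed_composite",
    "embed_extended",
    "embed_per_channel",
    "chebyshev",
]


def zscore_channels(series: MultichannelSeries) -> MultichannelSeries:
    """Standardize each channel to sample mean 0 and sample SD 1 (ddof=1).

    Applied once to the original (scale-1) series, so a similarity tolerance
    expressed in SD units (r = 0.15 x std) becomes the fixed absolute
    tolerance 0.15 at every scale.
    """
    x = series.values
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateInputError(f"channel {bad} is constant; cannot z-score")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return series.with_values(z)


def _window_means(x: np.ndarray, s: int, start: int) -> np.ndarray:
    """Means of consecutive windows of width s beginning at column ``start``."""
    n = (x.shape[1] - start) // s
    if n < 1:
        raise DegenerateInputError(
            f"length {x.shape[1]} too short for scale {s} at offset {start + 1}"
        )
    trimmed = x[:, start : start + n * s]
    return trimmed.reshape(x.shape[0], n, s).mean(axis=2)


def coarse_grain(series: MultichannelSeries | CoarseSeries, s: int) -> CoarseSeries:
    """Standard coarse-graining: non-overlapping window means of width s.

    Output length is ``floor(L / s)``; s = 1 is the identity.
    """
    if s < 1:
        raise ValueError("scale factor must be >= 1")
    x = np.asarray(series.values, dtype=float)
    if x.shape[1] // s < 2:
        raise DegenerateInputError(f"floor(L/s) < 2 for L={x.shape[1]}, s={s}")
    return CoarseSeries(_window_means(x, s, 0), scale=s, offset=1)


def refined_coarse_grain(series: MultichannelSeries, s: int, t: int) -> CoarseSeries:
    """Coarse-graining with window start shifted by offset ``t`` (1-based).

    The offset-t series averages samples ``(b-1)s + t .. bs + t - 1``; its
    length is ``floor((L - t + 1) / s)`` so no window reads past the end.
    ``t = 1`` reproduces :func:`coarse_grain` exactly.
    """
    if not 1 <= t <= s:
        raise ValueError(f"offset t={t} outside 1..s={s}")
    x = np.asarray(series.values, dtype=float)
    return CoarseSeries(_window_means(x, s, t - 1), scale=s, offset=t)


def embed_composite(coarse: CoarseSeries, m: int, d: int) -> np.ndarray:
    """Composite multivariate delay vectors at embedding dimension m.

    Returns an ``(N - n, m*p)`` matrix, ``n = m*d``: row i concatenates,
    channel by channel, the samples ``x[k, i], x[k, i+d], ..., x[k, i+(m-1)d]``.
    """
    x = coarse.values
    p, N = x.shape
    n = m * d
    count = N - n
    if count < 2:
        raise DegenerateInputError(f"N - m*d = {count} < 2 (N={N}, m={m}, d={d})")
    out = np.empty((count, m * p))
    for k in range(p):
        for l in range(m):
            out[:, k * m + l] = x[k, l * d : l * d + count]
    return out


def embed_extended(coarse: CoarseSeries, m: int, d: int) -> np.ndarray:
    """The p families of dimension-(m+1) vectors, pooled.

    There are p ways to extend the composite embedding from m to m+1 (grow
    one channel's window by one delayed sample). Start indices run over the
    same ``1..N-n`` range as at dimension m, so the pooled matrix has
    ``p * (N - n)`` rows of length ``m*p + 1``. Channel blocks stay
    contiguous: the family extending channel k holds m+1 delayed samples
    inside channel k's block and m in every other block.
    """
    x = coarse.values
    p, N = x.shape
    n = m * d
    count = N - n
    if count < 2:
        raise DegenerateInputError(f"N - m*d = {count} < 2 (N={N}, m={m}, d={d})")
    out = np.empty((p * count, m * p + 1))
    for k in range(p):
        block = out[k * count : (k + 1) * count]
        col = 0
        for kk in range(p):
            mk = m + 1 if kk == k else m
            for l in range(mk):
                block[:, col] = x[kk, l * d : l * d + count]
                col += 1
    return out


def embed_per_channel(coarse: CoarseSeries, m: int, d: int) -> np.ndarray:
    """Per-channel delay windows: shape ``(p, N - (m-1)d, m)``."""
    x = coarse.values
    p, N = x.shape
    count = N - (m - 1) * d
    if count < 1:
        raise DegenerateInputError(f"N - (m-1)d = {count} < 1 (N={N}, m={m}, d={d})")
    out = np.empty((p, count, m))
    for l in range(m):
        out[:, :, l] = x[:, l * d : l * d + count]
    return out


def chebyshev(u: np.ndarray, v: np.ndarray) -> float:
    """Chebyshev (max-coordinate) distance between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))
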