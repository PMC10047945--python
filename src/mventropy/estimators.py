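"""The six multivariate multiscale entropy estimators.

All six share the same front end — z-score the original series once, then
coarse-grain at each scale factor s — and differ in the per-scale statistic:

mvMSE
    multivariate sample entropy: -ln of the ratio of hard template-match
    probabilities at composite embedding dimensions m+1 and m.
mvMFE
    as mvMSE with the hard threshold replaced by the fuzzy membership
    weight exp(-ln2 * ((dist - r)/r)^2).
RCmvMFE
    refined-composite mvMFE: the s phase-shifted coarse-grained series each
    contribute a match statistic; the s statistics are averaged at each
    dimension before taking the log, and the membership anchor is relaxed
    to lambda*r.
mvMPE
    multivariate permutation entropy: Shannon entropy of the ordinal
    patterns of per-channel delay windows, counts pooled across channels.
mvMDE
    multivariate dispersion entropy: channels are mapped through the normal
    CDF and digitized into c classes; every non-redundant m-element
    selection from the m*p-long composite class vector contributes one
    dispersion pattern.
mvMIE
    multivariate increment entropy: per-channel windows of m first
    differences map to words of (sign, quantized magnitude) pairs.

Entropy is natural-log throughout. An undefined value (zero matches in
mvMSE) is returned as NaN, never raised.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm

from . import _kernels
from .containers import (
    CoarseSeries,
    DegenerateInputError,
    EntropyParams,
    MultichannelSeries,
    ScaleCurve,
)
from .core import (
    coarse_grain,
    embed_composite,
    embed_extended,
    embed_per_channel,
    refined_coarse_grain,
    zscore_channels,
)

__all__ = [
    "fuzzy_similarity",
    "rc_fuzzy_similarity",
    "mv_sample_entropy",
    "mv_fuzzy_entropy",
    "mv_rc_fuzzy_entropy",
    "mv_permutation_entropy",
    "ncdf_map",
    "dispersion_digitize",
    "mv_dispersion_entropy",
    "increment_series",
    "increment_word",
    "mv_increment_entropy",
    "pattern_distribution",
    "multiscale_curve",
    "ALGORITHMS",
]

_LN2 = float(np.log(2.0))

#: Cap on C(m*p, m) selections per window in mvMDE.
MAX_DISPERSION_COMBOS = 100_000


# ---------------------------------------------------------------------------
# similarity functions

def fuzzy_similarity(dist: float, r: float) -> float:
    """Fuzzy membership weight: 1 within r, Gaussian-tailed beyond.

    Continuous at dist = r and equal to 1/2 at dist = 2r.
    """
    return rc_fuzzy_similarity(dist, r, 1.0)


def rc_fuzzy_similarity(dist: float, r: float, lam: float) -> float:
    """Fuzzy membership with the threshold relaxed to lam*r."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if dist <= lam * r:
        return 1.0
    z = (dist - lam * r) / r
    return float(np.exp(-_LN2 * z * z))


# ---------------------------------------------------------------------------
# sample / fuzzy family

def _check_vector_budget(coarse: CoarseSeries, m: int, d: int, minimum: int) -> None:
    count = coarse.length - m * d
    if count < minimum:
        raise DegenerateInputError(
            f"need at least {minimum} embedding vectors, have {count} "
            f"(N={coarse.length}, m={m}, d={d})"
        )


def mv_sample_entropy(coarse: CoarseSeries, params: EntropyParams) -> float:
    """Multivariate sample entropy of one coarse-grained series.

    Returns NaN when either match probability is zero (no templates within
    tolerance), which a caller should treat as "undefined at this scale".
    """
    m, d, r = params.embed_m, params.delay_d, params.tolerance_r
    _check_vector_budget(coarse, m, d, 3)
    phi_m = _kernels.phi_hard(embed_composite(coarse, m, d), r)
    phi_m1 = _kernels.phi_hard(embed_extended(coarse, m, d), r)
    if phi_m == 0.0 or phi_m1 == 0.0:
        return float("nan")
    return float(-np.log(phi_m1 / phi_m))


def mv_fuzzy_entropy(coarse: CoarseSeries, params: EntropyParams) -> float:
    """Multivariate fuzzy entropy; always finite (fuzzy weights are > 0)."""
    m, d, r = params.embed_m, params.delay_d, params.tolerance_r
    _check_vector_budget(coarse, m, d, 3)
    phi_m = _kernels.phi_fuzzy(embed_composite(coarse, m, d), r, 1.0)
    phi_m1 = _kernels.phi_fuzzy(embed_extended(coarse, m, d), r, 1.0)
    return float(-np.log(phi_m1 / phi_m))


def mv_rc_fuzzy_entropy(
    series: MultichannelSeries | CoarseSeries, s: int, params: EntropyParams
) -> float:
    """Refined-composite multivariate fuzzy entropy at scale factor s.

    The s offset coarse-grained series (truncated to their common length so
    every offset contributes equally) each yield fuzzy match statistics at
    dimensions m and m+1 with membership anchor lambda*r; the statistics
    are averaged across offsets before the log ratio. At s=1, lambda=1 this
    reduces exactly to :func:`mv_fuzzy_entropy` at scale 1.

    The input series is used as-is: apply :func:`zscore_channels` first if
    the tolerance is meant in SD units (``multiscale_curve`` does).
    """
    m, d, r, lam = params.embed_m, params.delay_d, params.tolerance_r, params.lambda_adj
    if isinstance(series, CoarseSeries):
        series = MultichannelSeries(series.values)
    L = series.length
    n_common = (L - s + 1) // s  # shortest offset length
    if n_common - m * d < 3:
        raise DegenerateInputError(
            f"common coarse length {n_common} too short for m={m}, d={d} at scale {s}"
        )
    phis_m = np.empty(s)
    phis_m1 = np.empty(s)
    for t in range(1, s + 1):
        coarse = refined_coarse_grain(series, s, t)
        coarse = CoarseSeries(coarse.values[:, :n_common], scale=s, offset=t)
        phis_m[t - 1] = _kernels.phi_fuzzy(embed_composite(coarse, m, d), r, lam)
        phis_m1[t - 1] = _kernels.phi_fuzzy(embed_extended(coarse, m, d), r, lam)
    return float(-np.log(phis_m1.mean() / phis_m.mean()))


# ---------------------------------------------------------------------------
# permutation

def _permutation_freqs(coarse: CoarseSeries, params: EntropyParams) -> np.ndarray:
    m, d = params.embed_m, params.delay_d
    windows = embed_per_channel(coarse, m, d)  # (p, count, m)
    p, count, _ = windows.shape
    patterns = np.argsort(windows, axis=2, kind="stable")
    # encode each pattern as an integer in base m
    codes = np.zeros((p, count), dtype=np.int64)
    for l in range(m):
        codes = codes * m + patterns[:, :, l]
    freqs = np.bincount(codes.ravel()) / (count * p)
    return freqs[freqs > 0]


def mv_permutation_entropy(coarse: CoarseSeries, params: EntropyParams) -> float:
    """Multivariate permutation entropy.

    Each per-channel delay window maps to its ordinal pattern (stable
    argsort, earlier index wins ties); pattern counts are pooled across
    channels and normalized by (N - (m-1)d) * p. Bounded by ln(m!).
    """
    freqs = _permutation_freqs(coarse, params)
    return float(-(freqs * np.log(freqs)).sum())


# ---------------------------------------------------------------------------
# dispersion

def ncdf_map(
    coarse: CoarseSeries, mu_sigma: tuple[float, float] | None = None
) -> np.ndarray:
    """Map each channel through a normal CDF into (0, 1).

    With ``mu_sigma=None`` each channel uses its own mean and sample SD (the
    mean maps to 1/2). Passing ``mu_sigma=(mu, sigma)`` freezes the mapping
    parameters; in a multiscale sweep the parameters are frozen from the
    scale-1 series so that the amplitude shrinkage of coarse-graining is
    visible to the dispersion patterns instead of being renormalized away.
    """
    x = coarse.values
    if mu_sigma is None:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateInputError("constant channel: zero SD in NCDF map")
    else:
        mu, sd = float(mu_sigma[0]), float(mu_sigma[1])
        if sd <= 0:
            raise ValueError("sigma must be positive")
    return norm.cdf((x - mu) / sd)


def dispersion_digitize(y: np.ndarray | float, c: int) -> np.ndarray | int:
    """Digitize NCDF-mapped values in (0,1) into classes 1..c.

    z = round(c*y + 0.5) with half-away-from-zero rounding, clamped to [1, c].
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("values must lie strictly in (0, 1)")
    z = np.floor(c * arr + 0.5 + 0.5).astype(np.int64)  # round half away from zero (y > 0)
    z = np.clip(z, 1, c)
    return int(z) if np.isscalar(y) else z


def _dispersion_freqs(
    coarse: CoarseSeries,
    params: EntropyParams,
    mu_sigma: tuple[float, float] | None = None,
) -> np.ndarray:
    m, d, c = params.embed_m, params.delay_d, params.classes_c
    n_combos = comb(m * coarse.n_channels, m)
    if n_combos > MAX_DISPERSION_COMBOS:
        raise ValueError(
            f"C(m*p, m) = {n_combos} exceeds the cap {MAX_DISPERSION_COMBOS}"
        )
    classes = dispersion_digitize(ncdf_map(coarse, mu_sigma), c)
    embedded = embed_per_channel(CoarseSeries(classes, coarse.scale, coarse.offset), m, d)
    p, count, _ = embedded.shape
    # composite class vector per window: (count, m*p), channel-major
    composite = np.swapaxes(embedded, 0, 1).reshape(count, p * m).astype(np.int64)
    weights = c ** np.arange(m - 1, -1, -1, dtype=np.int64)
    counts = np.zeros(c**m, dtype=np.int64)
    for idx in combinations(range(p * m), m):
        codes = (composite[:, idx] - 1) @ weights
        counts += np.bincount(codes, minlength=c**m)
    return counts[counts > 0] / (count * n_combos)


def mv_dispersion_entropy(
    coarse: CoarseSeries,
    params: EntropyParams,
    mu_sigma: tuple[float, float] | None = None,
) -> float:
    """Multivariate dispersion entropy.

    Channels are NCDF-mapped and digitized into classes 1..c; for each
    window the m*p-long composite class vector contributes one dispersion
    pattern per non-redundant m-element selection (index combinations in
    lexicographic order, temporal/channel order preserved within a
    selection). Bounded by ln(c^m). ``mu_sigma`` freezes the NCDF
    parameters (see :func:`ncdf_map`); by default each channel of the
    given series maps through its own mean and SD.
    """
    freqs = _dispersion_freqs(coarse, params, mu_sigma)
    return float(-(freqs * np.log(freqs)).sum())


# ---------------------------------------------------------------------------
# increment

def increment_series(coarse: CoarseSeries) -> CoarseSeries:
    """First differences per channel (length N-1)."""
    if coarse.length < 2:
        raise DegenerateInputError("need at least 2 samples for increments")
    return CoarseSeries(np.diff(coarse.values, axis=1), coarse.scale, coarse.offset)


def increment_word(window: np.ndarray, R: int) -> tuple[tuple[int, int], ...]:
    """Map a window of increments to its (sign, magnitude) word.

    Signs are the signum of each increment. Magnitudes quantize |z| against
    the window's sample SD: q = min(R, floor(|z| * R / SD)), or 0 for every
    element when the window SD is zero. There are at most (2(R+1)+1)^m
    distinct words for windows of length m.
    """
    z = np.asarray(window, dtype=float)
    if z.size == 0:
        raise ValueError("empty window")
    if R < 1:
        raise ValueError("R must be >= 1")
    signs = np.sign(z).astype(int)
    sd = z.std(ddof=1) if z.size > 1 else 0.0
    if sd == 0:
        mags = np.zeros(z.size, dtype=int)
    else:
        mags = np.minimum(R, np.floor(np.abs(z) * R / sd)).astype(int)
    return tuple(zip(signs.tolist(), mags.tolist()))


def _increment_freqs(coarse: CoarseSeries, params: EntropyParams) -> np.ndarray:
    m, d, R = params.embed_m, params.delay_d, params.resolution_R
    inc = increment_series(coarse)
    windows = embed_per_channel(inc, m, d)  # (p, count, m)
    p, count, _ = windows.shape
    signs = np.sign(windows).astype(np.int64)
    sd = windows.std(axis=2, ddof=1) if m > 1 else np.zeros((p, count))
    mags = np.zeros_like(signs)
    nz = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.floor(np.abs(windows) * R / sd[:, :, None])
    mags[nz] = np.minimum(R, scaled[nz]).astype(np.int64)
    # encode (sign, mag) pairs; the mapping below is injective on the
    # reachable pairs {(0,0)} U {(+-1, 0..R)}
    symbol = (signs + 1) * (R + 1) + mags
    base = 3 * (R + 1)
    codes = np.zeros((p, count), dtype=np.int64)
    for l in range(m):
        codes = codes * base + symbol[:, :, l]
    _, word_counts = np.unique(codes.ravel(), return_counts=True)
    return word_counts / (count * p)


def mv_increment_entropy(coarse: CoarseSeries, params: EntropyParams) -> float:
    """Multivariate increment entropy.

    Per-channel delay windows of m increments map to words; word counts are
    pooled across channels with normalizer (N - (m-1)d - 1) * p. Bounded by
    ln((2(R+1)+1)^m).
    """
    freqs = _increment_freqs(coarse, params)
    return float(-(freqs * np.log(freqs)).sum())


def pattern_distribution(
    coarse: CoarseSeries, algorithm: str, params: EntropyParams
) -> np.ndarray:
    """Relative frequencies of the observed patterns (mvMPE/mvMDE/mvMIE).

    Returns the nonzero relative frequencies; they sum to 1.
    """
    table = {
        "mvmpe": _permutation_freqs,
        "mvmde": _dispersion_freqs,
        "mvmie": _increment_freqs,
    }
    try:
        return table[algorithm.lower()](coarse, params)
    except KeyError:
        raise ValueError(f"no pattern distribution for {algorithm!r}") from None


# ---------------------------------------------------------------------------
# multiscale driver

ALGORITHMS = {
    "mvmse": lambda coarse, params: mv_sample_entropy(coarse, params),
    "mvmfe": lambda coarse, params: mv_fuzzy_entropy(coarse, params),
    "mvmpe": lambda coarse, params: mv_permutation_entropy(coarse, params),
    "mvmde": lambda coarse, params: mv_dispersion_entropy(coarse, params),
    "mvmie": lambda coarse, params: mv_increment_entropy(coarse, params),
}


def multiscale_curve(
    series: MultichannelSeries, algorithm: str, params: EntropyParams
) -> ScaleCurve:
    """Entropy versus scale factor 1..max_scale for the named algorithm.

    The series is z-scored once (so tolerance_r is in SD units of the
    original signal); RCmvMFE uses refined-composite coarse-graining, every
    other algorithm the standard one. mvMDE maps every scale through the
    NCDF of the z-scored scale-1 series (mu=0, sigma=1), so the variance
    shrinkage of coarse-graining registers in the dispersion patterns.
    Scales that are degenerate for the requested parameters yield NaN
    entries instead of raising.
    """
    algorithm = algorithm.lower()
    if algorithm != "rcmvmfe" and algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    z = zscore_channels(series)
    values = np.full(params.max_scale, np.nan)
    for s in range(1, params.max_scale + 1):
        try:
            if algorithm == "rcmvmfe":
                values[s - 1] = mv_rc_fuzzy_entropy(z, s, params)
            elif algorithm == "mvmde":
                values[s - 1] = mv_dispersion_entropy(
                    coarse_grain(z, s), params, mu_sigma=(0.0, 1.0)
                )
            else:
                values[s - 1] = ALGORITHMS[algorithm](coarse_grain(z, s), params)
        except DegenerateInputError:
            values[s - 1] = np.nan
    return ScaleCurve(algorithm=algorithm, values=values)
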