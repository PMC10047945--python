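"""Synthetic benchmark signals.

The signal families used to characterize multivariate multiscale entropy
estimators:

* white Gaussian noise (WGN) — irregular, structurally simple;
* 1/f (pink) noise — long-range correlated, structurally complex;
* correlated channel pairs with a prescribed population correlation;
* the MIX(p) process — a sinusoid in which a fraction p of samples is
  replaced by Uniform(-3, 3) noise, so complexity grows with p;
* the two-channel coupled-MIX model
      A = C*MIX(p0) + (1-C)*MIX(p1),  B = C*MIX(p0) + (1-C)*MIX(p2)
  whose inter-channel coupling is controlled by C in [0, 1];
* additive white noise at a prescribed signal-to-noise ratio.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DegenerateInputError, MultichannelSeries

__all__ = [
    "CoupledMixParams",
    "NoiseSpec",
    "gen_wgn",
    "gen_pink_noise",
    "gen_correlated_pair",
    "gen_mix",
    "gen_coupled_mix",
    "add_noise_at_snr",
]


@dataclass(frozen=True)
class CoupledMixParams:
    """Parameters of the two-channel coupled-MIX model.

    p0, p1, p2 are the replacement probabilities of the shared and the two
    private MIX components; C is the coupling coefficient; N the length;
    fs the divisor of the sinusoid phase 2*pi*t/fs (default 12).
    """

    p0: float = 0.2
    p1: float = 0.5
    p2: float = 0.8
    C: float = 0.4
    N: int = 6000
    fs: float = 12.0

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "p2", "C"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.N < self.fs:
            raise ValueError(f"N={self.N} shorter than one period fs={self.fs}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-WGN specification: target SNR in dB and noise seed."""

    snr_db: float
    seed: int = 0


def _check_dims(n_channels: int, length: int, min_length: int = 2) -> None:
    if n_channels < 1:
        raise ValueError(f"n_channels must be >= 1, got {n_channels}")
    if length < min_length:
        raise ValueError(f"length must be >= {min_length}, got {length}")


def gen_wgn(n_channels: int, length: int, seed: int) -> MultichannelSeries:
    """Independent standard-Gaussian channels (zero mean, unit SD)."""
    _check_dims(n_channels, length)
    rng = np.random.default_rng(seed)
    return MultichannelSeries(rng.standard_normal((n_channels, length)), label="wgn")


def _pink_channel(length: int, rng: np.random.Generator) -> np.ndarray:
    # Spectral synthesis: shape white-noise Fourier amplitudes by 1/sqrt(f)
    # (power ~ 1/f), zero out DC, invert, standardize.
    white = rng.standard_normal(length)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(length)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=length)
    return (x - x.mean()) / x.std(ddof=1)


def gen_pink_noise(n_channels: int, length: int, seed: int) -> MultichannelSeries:
    """Independent 1/f-noise channels, each standardized to mean 0, SD 1."""
    _check_dims(n_channels, length, min_length=64)
    rng = np.random.default_rng(seed)
    out = np.vstack([_pink_channel(length, rng) for _ in range(n_channels)])
    return MultichannelSeries(out, label="pink")


def gen_correlated_pair(
    kind: str, rho: float, length: int, seed: int
) -> MultichannelSeries:
    """Two channels of the given kind with population correlation rho.

    Built by linear mixing of two independent unit-variance processes,
    z2 = rho*z1 + sqrt(1 - rho^2)*z1'; mixing two 1/f processes preserves
    the 1/f spectrum. rho = 0 returns two independent channels.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if kind not in ("wgn", "pink"):
        raise ValueError(f"kind must be 'wgn' or 'pink', got {kind!r}")
    gen = gen_wgn if kind == "wgn" else gen_pink_noise
    base = gen(2, length, seed).values
    z2 = rho * base[0] + np.sqrt(1.0 - rho**2) * base[1]
    return MultichannelSeries(
        np.vstack([base[0], z2]), label=f"{kind}-pair(rho={rho})"
    )


def _mix_channel(p: float, length: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(length)
    x = 2.0 * np.sin(2.0 * np.pi * t / fs)
    k = int(round(length * p))
    if k > 0:
        pos = rng.choice(length, size=k, replace=False)
        x[pos] = rng.uniform(-3.0, 3.0, size=k)
    return x


def gen_mix(p: float, length: int, fs: float = 12.0, seed: int = 0) -> MultichannelSeries:
    """Single-channel MIX(p): sinusoid 2*sin(2*pi*t/fs) with round(N*p)
    uniformly chosen samples replaced by Uniform(-3, 3) draws."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    _check_dims(1, length)
    rng = np.random.default_rng(seed)
    return MultichannelSeries(_mix_channel(p, length, fs, rng), label=f"mix(p={p})")


def gen_coupled_mix(params: CoupledMixParams, seed: int) -> MultichannelSeries:
    """Two-channel coupled-MIX model.

    Three independent MIX realizations on a common time grid combine as
    A = C*MIX(p0) + (1-C)*MIX(p1) and B = C*MIX(p0) + (1-C)*MIX(p2): the
    shared MIX(p0) component carries the inter-channel coupling.
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]
    m0 = _mix_channel(params.p0, params.N, params.fs, streams[0])
    m1 = _mix_channel(params.p1, params.N, params.fs, streams[1])
    m2 = _mix_channel(params.p2, params.N, params.fs, streams[2])
    a = params.C * m0 + (1.0 - params.C) * m1
    b = params.C * m0 + (1.0 - params.C) * m2
    return MultichannelSeries(np.vstack([a, b]), label=f"coupled-mix(C={params.C})")


def add_noise_at_snr(series: MultichannelSeries, spec: NoiseSpec) -> MultichannelSeries:
    """Superimpose white Gaussian noise at the given per-channel SNR.

    Power is the mean squared deviation from the channel mean; noise SD is
    scaled per channel so 10*log10(P_signal / P_noise) = snr_db.
    """
    x = series.values
    power = x.var(axis=1)  # per-channel mean squared deviation from the mean
    if np.any(power == 0):
        raise DegenerateInputError("constant channel has zero signal power")
    rng = np.random.default_rng(spec.seed)
    noise_sd = np.sqrt(power / 10.0 ** (spec.snr_db / 10.0))
    noisy = x + noise_sd[:, None] * rng.standard_normal(x.shape)
    return series.with_values(noisy)
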