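"""Core in-memory containers shared across the package.

A multichannel recording is a ``p x L`` real matrix (channels x samples).
Entropy estimators consume coarse-grained views of it and emit entropy
values per coarse-graining scale factor, collected in :class:`ScaleCurve`.
Undefined entropy values (e.g. multivariate sample entropy with zero
template matches) are carried as ``NaN`` with an explicit ``defined`` mask —
they are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultichannelSeries",
    "CoarseSeries",
    "EntropyParams",
    "ScaleCurve",
    "CurveEnsemble",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Input is structurally valid but too short / constant for the operation."""


@dataclass(frozen=True)
class MultichannelSeries:
    """A ``p x L`` multichannel time series.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_channels, length)``; must be finite.
    label
        Free-text description of the signal (condition name, subject id...).
    channel_names
        Optional channel labels, used by the EEG pipeline's region maps.
    """

    values: np.ndarray
    label: str = ""
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError(f"values must be 1-D or 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError(f"need p >= 1 channels and L >= 2 samples, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite")
        if self.channel_names is not None and len(self.channel_names) != arr.shape[0]:
            raise ValueError("channel_names length must equal the channel count")
        object.__setattr__(self, "values", arr)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def select_channels(self, names: Sequence[str]) -> "MultichannelSeries":
        """Return the sub-series holding the named channels, in the given order."""
        if self.channel_names is None:
            raise ValueError("series has no channel names")
        index = {c: i for i, c in enumerate(self.channel_names)}
        missing = [c for c in names if c not in index]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        rows = [index[c] for c in names]
        return MultichannelSeries(
            self.values[rows], label=self.label, channel_names=tuple(names)
        )

    def with_values(self, values: np.ndarray) -> "MultichannelSeries":
        return replace(self, values=values)


@dataclass(frozen=True)
class CoarseSeries:
    """A coarse-grained series at scale factor ``scale`` and offset ``offset``.

    ``offset`` is 1 for the standard coarse-graining; refined-composite
    coarse-graining produces one series per offset ``t = 1..scale``.
    """

    values: np.ndarray
    scale: int
    offset: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        object.__setattr__(self, "values", arr)
        if self.scale < 1 or self.offset < 1 or self.offset > self.scale:
            raise ValueError("require scale >= 1 and 1 <= offset <= scale")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the entropy estimators.

    embed_m : per-channel embedding dimension m (same for every channel)
    delay_d : time delay d
    tolerance_r : similarity tolerance r, in units of the normalized
        (z-scored) signal SD; 0.15 is the conventional default
    lambda_adj : adjustment factor for the refined-composite fuzzy
        membership, typically in [0.5, 1.5]
    classes_c : dispersion-entropy class count c
    resolution_R : increment-entropy quantization resolution R (usually <= 4)
    max_scale : largest coarse-graining scale factor
    """

    embed_m: int = 2
    delay_d: int = 1
    tolerance_r: float = 0.15
    lambda_adj: float = 0.8
    classes_c: int = 3
    resolution_R: int = 4
    max_scale: int = 20

    def __post_init__(self) -> None:
        if self.embed_m < 1 or self.delay_d < 1:
            raise ValueError("embed_m and delay_d must be positive")
        if self.tolerance_r <= 0:
            raise ValueError("tolerance_r must be positive")
        if not (0.5 <= self.lambda_adj <= 1.5):
            raise ValueError("lambda_adj must lie in [0.5, 1.5]")
        if self.classes_c < 2:
            raise ValueError("classes_c must be >= 2")
        if self.resolution_R < 1 or self.max_scale < 1:
            raise ValueError("resolution_R and max_scale must be >= 1")


#: Conventional parameter sets: m=2, d=1 for the sample/fuzzy family and
#: m=3, d=1 for the pattern-counting family (permutation, dispersion,
#: increment), with r=0.15, lambda=0.8, c=3, R=4.
DEFAULT_PARAMS: dict[str, EntropyParams] = {
    "mvmse": EntropyParams(embed_m=2),
    "mvmfe": EntropyParams(embed_m=2),
    "rcmvmfe": EntropyParams(embed_m=2),
    "mvmpe": EntropyParams(embed_m=3),
    "mvmde": EntropyParams(embed_m=3),
    "mvmie": EntropyParams(embed_m=3),
}


def default_params(algorithm: str, **overrides) -> EntropyParams:
    """Conventional parameters for the named algorithm, with overrides."""
    base = DEFAULT_PARAMS[algorithm.lower()]
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class ScaleCurve:
    """Entropy versus scale factor for one signal and one algorithm.

    Scales are contiguous from 1; undefined values are NaN with the
    corresponding entry of :attr:`defined` set to False.
    """

    algorithm: str
    values: np.ndarray  # shape (max_scale,), NaN = undefined

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def scales(self) -> np.ndarray:
        return np.arange(1, self.values.size + 1)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __getitem__(self, scale: int) -> float:
        if not 1 <= scale <= self.values.size:
            raise KeyError(f"scale {scale} outside 1..{self.values.size}")
        return float(self.values[scale - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale": self.scales,
                "value": self.values,
                "defined": self.defined,
            }
        )


@dataclass(frozen=True)
class CurveEnsemble:
    """Replicate x scale entropy matrix for one condition, with summaries."""

    condition: str
    values: np.ndarray  # shape (n_replicates, max_scale)
    algorithm: str = ""

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", arr)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def scales(self) -> np.ndarray:
        return np.arange(1, self.values.shape[1] + 1)

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.values.shape[0] < 2:
            return np.zeros(self.values.shape[1])
        return np.nanstd(self.values, axis=0, ddof=1)
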