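"""Seeded simulation experiments characterizing the six estimators.

Five experiments, each a deterministic function of its spec and seed,
emitting tidy long-format tables (algorithm, condition, replicate, scale,
value, defined):

complexity
    three channels mixing 1/f noise and WGN (3/2/1/0 pink channels);
correlation
    two-channel 1/f and WGN pairs, correlated (rho = 0.95) vs uncorrelated;
coupling
    the two-channel coupled-MIX model swept over the coupling coefficient
    C with matched single-channel complexity;
noise
    the coupled-MIX reference signal plus additive WGN at several SNRs;
length
    the coupled-MIX signal at data lengths 100..2000.

The detector helpers operationalize the qualitative readouts: the scale
above which four mean curves keep a strict ordering, the coupling value
maximizing mean entropy, and the data length where the mean stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CurveEnsemble, EntropyParams, MultichannelSeries, default_params
from .estimators import multiscale_curve
from .signals import (
    CoupledMixParams,
    NoiseSpec,
    add_noise_at_snr,
    gen_coupled_mix,
    gen_correlated_pair,
    gen_pink_noise,
    gen_wgn,
)

__all__ = [
    "ExperimentSpec",
    "run_complexity_experiment",
    "run_correlation_experiment",
    "run_joint_coupling_experiment",
    "run_noise_experiment",
    "run_length_experiment",
    "ensembles_from_table",
    "detect_ordering_threshold",
    "find_peak_coupling",
    "find_stabilization_length",
]

ALL_ALGORITHMS = ("mvmse", "mvmfe", "rcmvmfe", "mvmpe", "mvmde", "mvmie")

# seed-derivation offsets: conditions occupy disjoint blocks, replicates
# are consecutive within a block, noise streams live in their own block
_COND_STRIDE = 1_000_000
_AUX_OFFSET = 500_000


@dataclass(frozen=True)
class ExperimentSpec:
    """Shared experiment configuration.

    Defaults are the study conditions: 20 replicates of length-6000
    signals, scale factors 1..20, correlation 0.95, SNR levels
    {20, 10, 0, -10, -20} dB, coupling grid 0..1 in steps of 0.1 with equal
    probability triples, coupled-MIX reference parameters
    (C=0.4, p0=0.2, p1=0.5, p2=0.8), and length grid 100..2000 step 100.
    """

    name: str = "experiment"
    reps: int = 20
    length: int = 6000
    seed: int = 0
    max_scale: int = 20
    algorithms: tuple[str, ...] = ALL_ALGORITHMS
    rho: float = 0.95
    snr_levels: tuple[float, ...] = (20.0, 10.0, 0.0, -10.0, -20.0)
    c_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    p_triples: tuple[tuple[float, float, float], ...] = tuple(
        (q, q, q) for q in (0.1, 0.3, 0.5, 0.7, 0.9)
    )
    mix_params: CoupledMixParams = field(
        default_factory=lambda: CoupledMixParams(p0=0.2, p1=0.5, p2=0.8, C=0.4)
    )
    length_grid: tuple[int, ...] = tuple(range(100, 2001, 100))

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.algorithms:
            raise ValueError("algorithms must be non-empty")

    def params_for(self, algorithm: str) -> EntropyParams:
        return default_params(algorithm, max_scale=self.max_scale)


def _curve_rows(
    spec: ExperimentSpec,
    algorithm: str,
    condition: str,
    rep: int,
    seed: int,
    series: MultichannelSeries,
    extra: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    curve = multiscale_curve(series, algorithm, spec.params_for(algorithm))
    frame = curve.to_frame()
    frame.insert(0, "experiment", spec.name)
    frame.insert(1, "algorithm", algorithm)
    frame.insert(2, "condition", condition)
    frame.insert(3, "replicate", rep)
    frame["seed"] = seed
    if extra:
        for key, val in extra.items():
            frame[key] = val
    return frame


def run_complexity_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Three-channel mixtures of 1/f noise and WGN (3, 2, 1, 0 pink channels)."""
    rows = []
    for cond_idx, n_pink in enumerate((3, 2, 1, 0)):
        condition = f"{n_pink}x1f"
        for rep in range(spec.reps):
            seed = spec.seed + _COND_STRIDE * (cond_idx + 1) + rep
            chans = []
            if n_pink:
                chans.append(gen_pink_noise(n_pink, spec.length, seed).values)
            if n_pink < 3:
                chans.append(gen_wgn(3 - n_pink, spec.length, seed + _AUX_OFFSET).values)
            series = MultichannelSeries(np.vstack(chans), label=condition)
            for algorithm in spec.algorithms:
                rows.append(_curve_rows(spec, algorithm, condition, rep, seed, series))
    return pd.concat(rows, ignore_index=True)


def run_correlation_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Two-channel pairs: {1/f, WGN} x {correlated rho, uncorrelated}."""
    conditions = [
        ("corr-1f", "pink", spec.rho),
        ("uncorr-1f", "pink", 0.0),
        ("corr-wgn", "wgn", spec.rho),
        ("uncorr-wgn", "wgn", 0.0),
    ]
    rows = []
    for cond_idx, (condition, kind, rho) in enumerate(conditions):
        for rep in range(spec.reps):
            seed = spec.seed + _COND_STRIDE * (cond_idx + 1) + rep
            series = gen_correlated_pair(kind, rho, spec.length, seed)
            for algorithm in spec.algorithms:
                rows.append(_curve_rows(spec, algorithm, condition, rep, seed, series))
    return pd.concat(rows, ignore_index=True)


def run_joint_coupling_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Coupled-MIX sweep over C for each probability triple.

    For every (C, (p0, p1, p2), replicate) the table holds the two-channel
    entropy (``value``) and the single-channel entropy of channel A
    (``sc_value``) at each scale.
    """
    rows = []
    cond_idx = 0
    for p0, p1, p2 in spec.p_triples:
        for C in spec.c_grid:
            cond_idx += 1
            for rep in range(spec.reps):
                seed = spec.seed + _COND_STRIDE * cond_idx + rep
                params = CoupledMixParams(p0=p0, p1=p1, p2=p2, C=C, N=spec.length)
                series = gen_coupled_mix(params, seed)
                chan_a = MultichannelSeries(series.values[:1], label="channel-A")
                for algorithm in spec.algorithms:
                    multi = _curve_rows(
                        spec,
                        algorithm,
                        f"C={C:g},p=({p0:g},{p1:g},{p2:g})",
                        rep,
                        seed,
                        series,
                        extra={"C": C, "p0": p0, "p1": p1, "p2": p2},
                    )
                    sc = multiscale_curve(chan_a, algorithm, spec.params_for(algorithm))
                    multi["sc_value"] = sc.values
                    rows.append(multi)
    return pd.concat(rows, ignore_index=True)


def run_noise_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Coupled-MIX reference signal plus additive WGN at each SNR level.

    All SNR conditions of a replicate share the same clean base signal.
    """
    rows = []
    conditions: list[tuple[str, float | None]] = [("clean", None)]
    conditions += [(f"snr={lvl:g}dB", lvl) for lvl in spec.snr_levels]
    for rep in range(spec.reps):
        seed = spec.seed + rep
        base = gen_coupled_mix(replace(spec.mix_params, N=spec.length), seed)
        for cond_idx, (condition, snr) in enumerate(conditions):
            if snr is None:
                series = base
            else:
                noise_seed = spec.seed + _AUX_OFFSET + _COND_STRIDE * cond_idx + rep
                series = add_noise_at_snr(base, NoiseSpec(snr_db=snr, seed=noise_seed))
            for algorithm in spec.algorithms:
                rows.append(
                    _curve_rows(spec, algorithm, condition, rep, seed, series)
                )
    return pd.concat(rows, ignore_index=True)


def run_length_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Coupled-MIX signal at each data length on the grid.

    Replicate seeds do not depend on N, so every N follows the same
    generator path; scales a length cannot support appear as undefined
    rows, never as errors.
    """
    rows = []
    for n in spec.length_grid:
        for rep in range(spec.reps):
            seed = spec.seed + rep
            series = gen_coupled_mix(replace(spec.mix_params, N=int(n)), seed)
            for algorithm in spec.algorithms:
                rows.append(
                    _curve_rows(
                        spec, algorithm, f"N={n}", rep, seed, series, extra={"N": n}
                    )
                )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# detectors


def ensembles_from_table(
    table: pd.DataFrame, algorithm: str
) -> dict[str, CurveEnsemble]:
    """Pivot a tidy result table into one CurveEnsemble per condition."""
    sub = table[table["algorithm"] == algorithm]
    out: dict[str, CurveEnsemble] = {}
    for condition, grp in sub.groupby("condition", sort=False):
        mat = grp.pivot_table(
            index="replicate", columns="scale", values="value", dropna=False
        )
        out[condition] = CurveEnsemble(
            condition=str(condition), values=mat.to_numpy(), algorithm=algorithm
        )
    return out


def detect_ordering_threshold(
    ensembles: Sequence[CurveEnsemble] | Mapping[str, CurveEnsemble],
    ordering: Sequence[str],
) -> int | None:
    """Smallest s* such that the ensemble means obey the strict ordering
    at every scale > s*.

    ``ordering`` lists condition labels from largest expected mean to
    smallest. Returns 0 when the ordering holds everywhere and None when it
    fails at the largest scale (no threshold).
    """
    if not isinstance(ensembles, Mapping):
        ensembles = {e.condition: e for e in ensembles}
    try:
        chosen = [ensembles[name] for name in ordering]
    except KeyError as exc:
        raise ValueError(f"condition {exc} missing from the ensembles") from None
    grids = {e.values.shape[1] for e in chosen}
    if len(grids) != 1:
        raise ValueError(f"ensembles on mismatched scale grids: {sorted(grids)}")
    means = np.vstack([e.mean for e in chosen])  # (4, S)
    ordered = np.all(np.diff(means, axis=0) < 0, axis=0)  # strict at each scale
    failing = np.flatnonzero(~ordered)
    if failing.size == 0:
        return 0
    s_star = int(failing[-1]) + 1  # scales are 1-based
    return None if s_star == means.shape[1] else s_star


def find_peak_coupling(
    table: pd.DataFrame, algorithm: str, scale: int = 1
) -> float:
    """Coupling coefficient maximizing the mean multi-channel entropy.

    Grid argmax of the replicate mean at the given scale; ties resolve to
    the smaller C.
    """
    sub = table[(table["algorithm"] == algorithm) & (table["scale"] == scale)]
    if sub.empty:
        raise ValueError(f"no rows for algorithm={algorithm!r}, scale={scale}")
    means = sub.groupby("C")["value"].mean().sort_index()
    return float(means.index[int(np.argmax(means.to_numpy()))])


def find_stabilization_length(
    means_by_n: Mapping[int, float] | pd.Series, tol_fraction: float
) -> int | None:
    """Smallest grid length N* whose mean stays within tol_fraction of the
    mean at the largest N for every N >= N*; None if even the largest
    predecessor fails (no stabilization).
    """
    if isinstance(means_by_n, pd.Series):
        means_by_n = means_by_n.to_dict()
    ns = np.array(sorted(means_by_n))
    vals = np.array([means_by_n[n] for n in ns], dtype=float)
    ref = vals[-1]
    if ref == 0:
        raise ValueError("reference mean at the largest N is zero")
    ok = np.abs(vals - ref) <= tol_fraction * abs(ref)
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return int(ns[0])
    if bad[-1] >= ns.size - 2:
        # only the reference point itself qualifies: no stabilization
        return None
    return int(ns[bad[-1] + 1])
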