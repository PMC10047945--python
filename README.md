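# mventropy

Multivariate multiscale entropy analysis of multichannel time series —
six estimators, the synthetic signal families used to characterize them,
and a region-wise EEG group-analysis pipeline.

## The problem

Entropy rates quantify the irregularity of a signal; *multiscale* entropy
quantifies how that irregularity changes as the signal is coarse-grained
(replaced by window means of width `s`, the scale factor), separating
short-range randomness from long-range structure; *multivariate* variants
extend this to multichannel recordings, where inter-channel coupling and
per-channel complexity both shape the result. Such curves are used as
nonlinear biomarkers — notably for EEG in mild cognitive impairment, where
patients show lower complexity at short scales and the reversal at long
scales. This package implements the six standard multivariate multiscale
estimators with shared conventions so their behavior can be compared like
for like:

| name | statistic |
|---|---|
| mvMSE | multivariate sample entropy: `-ln(phi^{m+1}/phi^m)` from hard Chebyshev template matches of composite delay vectors |
| mvMFE | as mvMSE with the fuzzy membership `exp(-ln2 ((d-r)/r)^2)` in place of the hard threshold |
| RCmvMFE | refined-composite mvMFE: match statistics of the `s` phase-shifted coarse-grainings averaged before the log, membership anchored at `lambda*r` |
| mvMPE | Shannon entropy of ordinal patterns, counts pooled across channels |
| mvMDE | Shannon entropy of dispersion patterns after a normal-CDF map into `c` classes, over all `C(m*p, m)` selections per window |
| mvMIE | Shannon entropy of (sign, quantized magnitude) words of increment windows |

The package also ships the benchmark signal families (white Gaussian
noise, 1/f noise, correlated pairs, MIX and coupled-MIX processes, SNR
injection), the five seeded simulation experiments that characterize what
each estimator measures (complexity, inter-channel correlation, coupling
strength, noise resistance, data-length dependence), and an EEG pipeline
(epoching, region-wise RCmvMFE, short/long scale-band summaries, Welch
t-tests with Benjamini–Hochberg FDR, score correlations) exercised on a
synthetic two-group cohort generator. See `docs/methods.md` for the
conventions and their rationale.

## Worked example

Refined-composite multivariate fuzzy entropy separates correlated from
uncorrelated 1/f noise at every scale:

```python
from mventropy import gen_correlated_pair
from mventropy.containers import default_params
from mventropy.estimators import multiscale_curve

params = default_params("rcmvmfe", max_scale=10)   # m=2, d=1, r=0.15, lambda=0.8
corr = multiscale_curve(gen_correlated_pair("pink", 0.95, 3000, seed=7), "rcmvmfe", params)
uncorr = multiscale_curve(gen_correlated_pair("pink", 0.0, 3000, seed=7), "rcmvmfe", params)
for s in (1, 5, 10):
    print(f"scale {s:2d}:  correlated {corr[s]:.3f}   uncorrelated {uncorr[s]:.3f}")
```

```
scale  1:  correlated 1.313   uncorrelated 1.220
scale  5:  correlated 1.318   uncorrelated 1.120
scale 10:  correlated 1.360   uncorrelated 1.130
```

The correlated pair (population correlation 0.95) carries more shared
structure and scores consistently higher — the property that makes this
estimator useful for signals where complexity and connectivity change
together. The 1/f curves stay roughly flat across scales, the signature of
long-range correlated noise.

The same operations are available from the shell:

```bash
mventropy simulate-signal --kind pair --pair-kind pink --rho 0.95 \
    --length 3000 --seed 7 --out pair.csv
mventropy compute --input pair.csv --algo rcmvmfe --max-scale 10 --out curve.csv
mventropy simulate correlation --reps 20 --seed 1 --out runs/
mventropy eeg-run --data subjects/ --regions regions.yaml --scores scores.csv --out results/
```

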