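"""Text-format readers and writers.

Matrix dialect: delimited text (comma or tab, auto-detected on read),
channels as rows, one header row of channel labels, optional ``#``-prefixed
comment lines, '.' decimal point. Region maps are YAML
(``region: [channels...]``); scores tables are CSV keyed by subject id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MultichannelSeries
from .eeg import RegionMap

__all__ = ["read_matrix", "write_matrix", "read_region_map", "write_region_map", "read_scores"]


def write_matrix(series: MultichannelSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a channels-x-samples matrix with a channel-label header row."""
    path = Path(path)
    names = series.channel_names or tuple(
        f"ch{i + 1}" for i in range(series.n_channels)
    )
    with path.open("w") as fh:
        if series.label:
            fh.write(f"# {series.label}\n")
        fh.write(delimiter.join(names) + "\n")
        np.savetxt(fh, series.values, delimiter=delimiter, fmt="%.12g")


def read_matrix(path: str | Path, label: str = "") -> MultichannelSeries:
    """Read a delimited channels-x-samples matrix written by :func:`write_matrix`."""
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path} holds no data")
    delimiter = "\t" if "\t" in lines[0] else ","
    names = tuple(tok.strip() for tok in lines[0].split(delimiter))
    data = np.array(
        [[float(tok) for tok in ln.split(delimiter)] for ln in lines[1:]], dtype=float
    )
    return MultichannelSeries(data, label=label or path.stem, channel_names=names)


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    payload = {region: list(chans) for region, chans in region_map.regions.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_region_map(path: str | Path) -> RegionMap:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path} is not a region: [channels] mapping")
    return RegionMap({str(k): tuple(map(str, v)) for k, v in payload.items()})


def read_scores(path: str | Path, subject_col: str = "subject") -> pd.DataFrame:
    scores = pd.read_csv(path)
    if subject_col not in scores.columns:
        raise ValueError(f"scores table lacks the {subject_col!r} column")
    return scores
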