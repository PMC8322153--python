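"""Reading and writing the tidy spike-record table and YAML session configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .core import NeuronMeta
from .synthetic import (AdaptationSpec, ClusterSpec, PairSpec, RECORD_COLUMNS,
                        SyntheticConfig)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write the spike-record table as UTF-8 CSV with a header row."""
    records.to_csv(path, index=False, columns=RECORD_COLUMNS, encoding="utf-8")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a spike-record CSV; validates the schema and latency window."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record table missing columns: {sorted(missing)}")
    if ((df.first_spike_ms < 0) | (df.first_spike_ms >= 50)).any():
        raise ValueError("first_spike_ms values must lie in [0, 50)")
    return df


def load_config(path: str | Path, seed: int | None = None) -> SyntheticConfig:
    """Parse a YAML session config into a :class:`SyntheticConfig`.

    The file must carry a ``seed`` unless one is supplied explicitly.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if seed is None:
        if "seed" not in raw:
            raise ValueError("config must define a seed")
        seed = int(raw["seed"])
    neurons = [NeuronMeta(**n) for n in raw["neurons"]]
    pairs = []
    for p in raw["pairs"]:
        clusters = [ClusterSpec(prob=float(c["prob"]),
                                means=tuple(c["means"]),
                                loadings=tuple(c["loadings"]),
                                sigmas=tuple(c["sigmas"]))
                    for c in p["clusters"]]
        pairs.append(PairSpec(p["neuron_x"], p["neuron_y"], clusters))
    adapt = AdaptationSpec(**raw.get("adaptation", {}))
    return SyntheticConfig(
        neurons=neurons, pairs=pairs, seed=seed,
        n_trials=int(raw.get("n_trials", 200)),
        frequencies=tuple(raw.get("frequencies", [1.0])),
        adaptation=adapt,
        reliability={k: float(v) for k, v in raw.get("reliability", {}).items()},
        session=raw.get("session", "synthetic"),
        whisker=raw.get("whisker", "C2"),
    )
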