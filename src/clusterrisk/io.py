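"""Delimited-text and config-file interfaces.

Populations and study samples travel as TSV with columns
``center_id, x1..x6, u0, lp, p_true, y``; generic clustered datasets need
only ``cluster_id``, ``y`` and named predictor columns.  Scenario configs
are YAML key-value files mirroring :class:`~clusterrisk.dgp.ScenarioConfig`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dgp import ScenarioConfig, SourcePopulation

__all__ = [
    "write_population",
    "read_population",
    "read_clustered_data",
    "read_config",
    "write_config",
]


def write_population(pop: SourcePopulation, path, sep: str = "\t") -> None:
    # %.17g keeps the text round-trip bit-exact for float64
    pop.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_population(path, sep: str = "\t") -> SourcePopulation:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return SourcePopulation.from_frame(df)


def read_clustered_data(
    path, cluster_col: str = "cluster_id", outcome_col: str = "y", sep: str | None = None
):
    """Read any clustered binary dataset from delimited text.

    Returns (X, y, cluster, predictor_names); every column other than the
    cluster id and outcome is treated as a predictor.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in (cluster_col, outcome_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    predictors = [c for c in df.columns if c not in (cluster_col, outcome_col)]
    X = df[predictors].to_numpy(dtype=float)
    y = df[outcome_col].to_numpy(dtype=int)
    cluster = df[cluster_col].to_numpy()
    return X, y, cluster, predictors


def read_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ScenarioConfig(**raw)


def write_config(config: ScenarioConfig, path) -> None:
    data = {
        k: (v.item() if isinstance(v, np.generic) else v)
        for k, v in config.__dict__.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
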