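"""Table readers/writers with schema validation.

Spike tables are tidy long format (neuron_id, trial_id, spike_time_ms);
trial tables carry the session, condition, choice, reaction time and event
times.  CSV is the default interchange format; Parquet is used when the
path ends in ``.parquet`` (requires pyarrow).  Decoding feature matrices are
written as MatrixMarket sparse files with a sidecar label/group CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

SPIKE_COLUMNS = ["neuron_id", "trial_id", "spike_time_ms"]
TRIAL_COLUMNS = [
    "trial_id", "neuron_id", "monkey_id", "scene", "value", "direction",
    "choice", "rt_ms", "scene_on_ms", "target_on_ms", "saccade_on_ms",
]

__all__ = [
    "read_spikes", "write_spikes", "read_trials", "write_trials",
    "write_feature_table", "SchemaError",
]


class SchemaError(ValueError):
    pass


def _read(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.12g")


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {', '.join(missing)}")


def read_spikes(path) -> pd.DataFrame:
    df = _read(path)
    _require(df, SPIKE_COLUMNS, "spike")
    return df


def write_spikes(df: pd.DataFrame, path) -> None:
    _require(df, SPIKE_COLUMNS, "spike")
    _write(df[SPIKE_COLUMNS], path)


def read_trials(path) -> pd.DataFrame:
    df = _read(path)
    _require(df, TRIAL_COLUMNS, "trial")
    rt = df["rt_ms"].dropna()
    if (rt < 0).any():
        raise SchemaError("rt_ms contains negative values")
    bad = ~df["value"].isin(["good", "bad"])
    if bad.any():
        raise SchemaError(f"value column has unknown levels: {df.loc[bad, 'value'].unique()}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    _require(df, TRIAL_COLUMNS, "trial")
    _write(df[TRIAL_COLUMNS], path)


def write_feature_table(table, directory) -> None:
    """MTX sparse matrix plus labels/groups sidecar CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "features.mtx", sparse.csr_matrix(table.X))
    pd.DataFrame(
        {
            "choice": table.choice,
            "rt_ms": table.rt_ms,
            "neuron_id": table.groups,
            "cluster": table.clusters,
        }
    ).to_csv(directory / "samples.csv", index=False)
    np.savetxt(directory / "time_ms.csv", table.time_ms, fmt="%.1f")
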