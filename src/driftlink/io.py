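"""Reading and writing the delimited-text formats used by the package.

Response matrices are delimited text with a header row of item ids and one
required time-label column (default name ``time``, values 1/2); missing
responses are empty cells or an NA token.  Item-parameter tables carry
columns ``item_id``, ``a``, ``d`` (difficulty b = d/a is derived, never
stored as primary).
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from .irt_core import ItemBank, ResponseData

__all__ = [
    "read_response_data", "write_response_data",
    "read_item_bank", "write_item_bank",
    "write_trend_estimates", "config_hash",
]


def read_response_data(path, time_col: str = "time", sep: str | None = None
                       ) -> ResponseData:
    """Load a person-by-item response matrix with a time-label column."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if time_col not in df.columns:
        raise ValueError(f"time column {time_col!r} not found in {path}")
    time = df[time_col].to_numpy(dtype=int)
    items = [c for c in df.columns if c != time_col]
    X = df[items].to_numpy(dtype=float)
    return ResponseData(responses=X, time=time, item_ids=tuple(items))


def write_response_data(data: ResponseData, path, time_col: str = "time",
                        sep: str = ","):
    df = pd.DataFrame(data.responses, columns=list(data.item_ids))
    df.insert(0, time_col, data.time)
    df.to_csv(path, sep=sep, index=False)


def read_item_bank(path, sep: str = ",") -> ItemBank:
    df = pd.read_csv(path, sep=sep)
    for col in ("item_id", "a", "d"):
        if col not in df.columns:
            raise ValueError(f"item table must have a {col!r} column")
    return ItemBank(tuple(df["item_id"].astype(str)),
                    df["a"].to_numpy(float), df["d"].to_numpy(float))


def write_item_bank(bank: ItemBank, path, sep: str = ","):
    pd.DataFrame({"item_id": bank.item_ids, "a": bank.a, "d": bank.d}
                 ).to_csv(path, sep=sep, index=False)


def write_trend_estimates(records: list, path, sep: str = ","):
    """Write trend-estimate records (one row per estimator)."""
    pd.DataFrame(records).to_csv(path, sep=sep, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
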