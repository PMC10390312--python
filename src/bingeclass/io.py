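"""Tabular I/O and pipeline configuration.

Cohort files are UTF-8 CSV with a header row; column names map onto the
canonical item names through an optional JSON mapping.  Every record is
validated (range-checked, listwise-complete) on ingestion; a malformed row
is rejected with its file line number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DEFAULT_PRICES
from .survey import ITEM_FIELDS, RecordValidationError, serialize, validate_record


def read_cohort(
    path, mapping: dict[str, str] | None = None, percent_scale: str = "tenths"
) -> pd.DataFrame:
    """Read and validate a cohort CSV into canonical columns.

    ``mapping`` translates file column names to canonical ones
    (``{"file_column": "canonical_name"}``).  Raises on a missing mapped
    column, and on any malformed row with its line number.
    """
    raw = pd.read_csv(path, encoding="utf-8")
    if mapping:
        missing = [c for c in mapping if c not in raw.columns]
        if missing:
            raise ValueError(f"mapped column(s) {missing} absent from {path}")
        raw = raw.rename(columns=mapping)
    absent = [c for c in ITEM_FIELDS if c not in raw.columns]
    if absent:
        raise ValueError(f"cohort file {path} lacks item column(s) {absent}")

    rows = []
    for idx, record in raw.iterrows():
        try:
            resp = validate_record(record.to_dict(), percent_scale=percent_scale)
        except RecordValidationError as exc:
            raise RecordValidationError(
                f"{path}, line {idx + 2}: {exc}"  # +2: header + 1-based
            ) from exc
        rows.append(serialize(resp))
    return pd.DataFrame(rows)


def read_apt_long(path) -> dict[str, "np.ndarray"]:
    """Read a long-format APT CSV (id, price, consumption) grouped by id."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"id", "price", "consumption"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"APT file {path} lacks column(s) {sorted(missing)}")
    return {
        str(rid): g.sort_values("price")[["price", "consumption"]].to_numpy(float)
        for rid, g in df.groupby("id")
    }


def write_table(path, table: pd.DataFrame, index: bool = False) -> None:
    """Write a DataFrame as UTF-8 CSV with stable column order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=index, encoding="utf-8")


@dataclass
class PipelineConfig:
    """All knobs of the simulate -> derive -> classify -> validate -> apt run."""

    seed: int = 1
    n: int = 1277  # simulated cohort size when no input file given
    input_csv: str | None = None
    apt_csv: str | None = None
    column_mapping: dict[str, str] = field(default_factory=dict)
    percent_scale: str = "tenths"
    k_range: tuple[int, ...] = tuple(range(2, 9))
    n_clusters: int | None = None  # None -> elbow selection
    n_restarts: int = 25
    alpha_level: float = 0.05
    corr_threshold: float = 0.7
    coefficient_set: str = "published-rounded"
    trend_threshold: float = 0.025
    bounce_threshold: float = 0.10
    prices: tuple[float, ...] = DEFAULT_PRICES
    simulate_apt: bool = True
    apt_noise_sd: float = 0.15
    output_dir: str = "bingeclass_out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic stage")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["prices"] = list(self.prices)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        if "prices" in d:
            d["prices"] = tuple(d["prices"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
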