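"""Tabular input/output and validation for the transplant pipeline.

Formats are plain UTF-8 text with header rows:

* ``fragments.csv`` — one row per transplanted branch with columns
  ``fragment_id, colony_id, origin, location, crate_id, fate,
  initial_weight, final_weight, branch_count``.
* ``counts.tsv`` — tab-separated gene x sample integer matrix, first
  column ``gene_id``, remaining columns one per sample.
* ``temperature.csv`` — long-format logger records
  ``crate_id, timestamp, temp_c``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

POOLS = ("HV", "MV")
FATES = ("alive", "dead", "missing")

FRAGMENT_COLUMNS = [
    "fragment_id",
    "colony_id",
    "origin",
    "location",
    "crate_id",
    "fate",
    "initial_weight",
    "final_weight",
    "branch_count",
]


class ValidationError(ValueError):
    """A table violated one of the pipeline's structural invariants."""


class DuplicateIdError(ValidationError):
    pass


class CrateLocationError(ValidationError):
    pass


class WeightError(ValidationError):
    pass


class CountsError(ValidationError):
    pass


def _check_fragment_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in FRAGMENT_COLUMNS[:6] if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"fragment table missing required columns: {missing_cols}")

    dup = df["fragment_id"][df["fragment_id"].duplicated()]
    if len(dup):
        raise DuplicateIdError(f"duplicate fragment_id values: {sorted(dup.unique())}")

    bad_pool = df[~df["origin"].isin(POOLS) | ~df["location"].isin(POOLS)]
    if len(bad_pool):
        raise ValidationError(
            f"origin/location must be one of {POOLS}; offending rows: "
            f"{bad_pool['fragment_id'].tolist()[:5]}"
        )

    bad_fate = df[~df["fate"].isin(FATES)]
    if len(bad_fate):
        raise ValidationError(
            f"fate must be one of {FATES}; offending rows: "
            f"{bad_fate['fragment_id'].tolist()[:5]}"
        )

    # a crate lives in exactly one pool
    crate_locs = df.groupby("crate_id")["location"].nunique()
    conflicted = crate_locs[crate_locs > 1]
    if len(conflicted):
        raise CrateLocationError(
            f"crate(s) mapped to more than one location: {conflicted.index.tolist()}"
        )

    for col in ("initial_weight", "final_weight"):
        if col in df.columns:
            neg = df[df[col].notna() & (df[col] < 0)]
            if len(neg):
                raise WeightError(
                    f"negative {col} in rows: {neg['fragment_id'].tolist()[:5]}"
                )

    alive_missing_final = df[(df["fate"] == "alive") & df["final_weight"].isna()]
    if len(alive_missing_final):
        raise ValidationError(
            "surviving fragments must have a final_weight; offending rows: "
            f"{alive_missing_final['fragment_id'].tolist()[:5]}"
        )
    return df


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a fragment-level transplant table.

    Returns a DataFrame with one row per fragment and a ``growth``
    column: ``100 * (final - initial) / initial`` percent buoyant-weight
    increase for survivors, NaN for dead or missing fragments.
    """
    df = pd.read_csv(path, dtype={"fragment_id": str, "colony_id": str, "crate_id": str})
    for col in ("initial_weight", "final_weight", "branch_count"):
        if col not in df.columns:
            df[col] = np.nan
    _check_fragment_frame(df)
    return attach_growth(df)


def attach_growth(df: pd.DataFrame) -> pd.DataFrame:
    """Add the percent buoyant-weight growth column (survivors only)."""
    df = df.copy()
    growth = 100.0 * (df["final_weight"] - df["initial_weight"]) / df["initial_weight"]
    growth[df["fate"] != "alive"] = np.nan
    df["growth"] = growth
    return df


def write_fragment_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FRAGMENT_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV of non-negative integer read counts.

    The first column holds gene IDs (becomes the index); every other
    cell must parse as a non-negative integer.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise CountsError(f"{path}: empty gene set")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicate gene IDs: {dups[:5]}")
    if df.columns.duplicated().any():
        raise DuplicateIdError("duplicate sample IDs in header")
    for sample in df.columns:
        col = df[sample]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = col.index[numeric.isna()]
        if len(bad):
            raise CountsError(f"non-numeric count for gene {bad[0]!r}, sample {sample!r}")
        if (numeric < 0).any():
            gene = numeric.index[numeric < 0][0]
            raise CountsError(f"negative count for gene {gene!r}, sample {sample!r}")
        if (numeric % 1 != 0).any():
            gene = numeric.index[numeric % 1 != 0][0]
            raise CountsError(f"non-integer count for gene {gene!r}, sample {sample!r}")
    return df.astype(np.int64)


def write_counts_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_temperature_table(path: str | Path) -> pd.DataFrame:
    """Read long-format logger records (crate_id, timestamp, temp_c)."""
    df = pd.read_csv(path, dtype={"crate_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def temperature_exceedance(
    timestamps: Iterable,
    temps_c: Iterable[float],
    threshold: float,
) -> tuple[float, float]:
    """Summarize time spent strictly above a temperature threshold.

    Each sample represents one logging interval (the cadence, inferred
    from the median timestamp spacing), so hours above = n_above *
    cadence and the denominator is n_samples * cadence.

    Returns ``(hours_above, percent_of_time)``.
    """
    ts = pd.to_datetime(pd.Series(list(timestamps)))
    temps = np.asarray(list(temps_c), dtype=float)
    if len(ts) < 2:
        raise ValidationError("need at least 2 temperature samples")
    deltas = ts.diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        raise ValidationError("timestamps must be strictly increasing")
    cadence_h = deltas.median().total_seconds() / 3600.0
    n_above = int(np.sum(temps > threshold))
    hours_above = n_above * cadence_h
    total_hours = len(temps) * cadence_h
    percent = 100.0 * hours_above / total_hours
    return hours_above, percent
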