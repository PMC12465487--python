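"""CSV readers/writers for all tabular artifacts.

All writers are deterministic: fixed column order, floats at 17 significant
digits, LF line endings — same inputs give byte-identical files.  Missing
values are written as empty cells and read back as NaN ("nan" is also
accepted on input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import MotionTimeseries

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

METADATA_COLUMNS = (
    "well_id", "strain", "date_yyyymmdd", "plate_id", "rig_id",
    "drug", "dose", "n_worms", "is_bad_well",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wells x features table (index well_id) as CSV."""
    out = table.copy()
    out.index.name = "well_id"
    out.to_csv(path, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_feature_summary(path: str | Path, window_tag: str | None = None) -> pd.DataFrame:
    """Read a Tierpsy-style per-well feature summary CSV.

    Expected layout: header with ``well_id`` first (an optional ``file_id``
    column is ignored), remaining columns numeric feature values; empty cell
    or "nan" means missing.  Duplicate wells or non-numeric cells are errors
    naming the offending location.
    """
    df = pd.read_csv(path, dtype={"well_id": str})
    if "well_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'well_id'")
    if df["well_id"].duplicated().any():
        dup = sorted(df.loc[df["well_id"].duplicated(), "well_id"].unique())
        raise ValueError(f"{path}: duplicate well_id(s): {dup}")
    df = df.set_index("well_id")
    df = df.drop(columns=[c for c in ("file_id",) if c in df.columns])
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                well = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[well, col]!r} in "
                    f"column {col!r}, well {well!r}"
                )
            df[col] = coerced
        else:
            df[col] = df[col].astype(float)
    if window_tag is not None:
        df.attrs["window"] = window_tag
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.reset_index() if metadata.index.name == "well_id" else metadata.copy()
    missing = [c for c in METADATA_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"metadata is missing column(s): {missing}")
    out = out[list(METADATA_COLUMNS)]
    out["is_bad_well"] = out["is_bad_well"].astype(bool)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read well metadata; validates columns, dates and flags."""
    df = pd.read_csv(path, dtype={"well_id": str, "strain": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    if df["well_id"].duplicated().any():
        dup = sorted(df.loc[df["well_id"].duplicated(), "well_id"].unique())
        raise ValueError(f"{path}: duplicate well_id(s): {dup}")
    dates = df["date_yyyymmdd"].astype(str).str.replace(r"\.0$", "", regex=True)
    try:
        pd.to_datetime(dates, format="%Y%m%d")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed date_yyyymmdd: {exc}") from exc
    df["date_yyyymmdd"] = dates.astype(int)
    df["is_bad_well"] = df["is_bad_well"].map(_parse_bool)
    df["n_worms"] = df["n_worms"].astype(int)
    return df


@dataclass
class JoinedDataset:
    """Feature tables inner-joined with metadata on well_id.

    Bad wells (``is_bad_well``) are excluded before the join; unmatched
    well ids are reported both ways.
    """

    tables: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    unmatched_in_tables: list[str] = field(default_factory=list)
    unmatched_in_metadata: list[str] = field(default_factory=list)
    n_bad_wells: int = 0

    @property
    def wells(self) -> list[str]:
        return list(self.metadata["well_id"])

    def strain_of_well(self) -> pd.Series:
        return self.metadata.set_index("well_id")["strain"]

    def day_of_well(self) -> pd.Series:
        return self.metadata.set_index("well_id")["date_yyyymmdd"]


def join_dataset(tables: Mapping[str, pd.DataFrame], metadata: pd.DataFrame) -> JoinedDataset:
    """Inner-join per-window feature tables with well metadata."""
    bad = metadata["is_bad_well"].astype(bool)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("join_dataset: excluding %d bad well(s)", n_bad)
    good = metadata.loc[~bad]
    meta_wells = set(good["well_id"])
    table_wells = set.intersection(*(set(t.index) for t in tables.values()))
    common = sorted(meta_wells & table_wells)
    if not common:
        raise ValueError("no wells shared between feature tables and metadata")
    joined_tables = {tag: t.loc[common] for tag, t in tables.items()}
    joined_meta = good.set_index("well_id").loc[common].reset_index()
    return JoinedDataset(
        tables=joined_tables,
        metadata=joined_meta,
        unmatched_in_tables=sorted(table_wells - meta_wells),
        unmatched_in_metadata=sorted(meta_wells - table_wells),
        n_bad_wells=n_bad,
    )


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[["strain", "feature", "true_effect"]].to_csv(
        path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("strain", "feature", "true_effect") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {missing}")
    return df


def write_test_result(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-feature statistics table (index feature) as CSV."""
    out = table.copy()
    out.index.name = "feature"
    out.to_csv(path, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_motion_timeseries(ts: MotionTimeseries, path: str | Path) -> None:
    """Write one well's timeseries as long CSV (frame, worm, state, speed)."""
    n_frames, n_worms = ts.states.shape
    frames = np.repeat(np.arange(n_frames), n_worms)
    worms = np.tile(np.arange(n_worms), n_frames)
    df = pd.DataFrame({
        "frame": frames,
        "worm": worms,
        "state": ts.states.reshape(-1),
        "speed": ts.speeds.reshape(-1) if ts.speeds is not None else np.nan,
    })
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# well_id={ts.well_id} fps={ts.fps:g}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_motion_timeseries(path: str | Path) -> MotionTimeseries:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# well_id=... fps=...' header line")
        fields = dict(part.split("=", 1) for part in header[1:].split())
        df = pd.read_csv(fh)
    n_frames = int(df["frame"].max()) + 1
    n_worms = int(df["worm"].max()) + 1
    states = df["state"].to_numpy(dtype=np.int8).reshape(n_frames, n_worms)
    speeds = df["speed"].to_numpy(dtype=float).reshape(n_frames, n_worms)
    return MotionTimeseries(well_id=fields["well_id"], fps=float(fields["fps"]),
                            states=states, speeds=speeds)
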