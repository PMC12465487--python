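"""Well-level tracking summaries -> analysis-ready profiles.

Covers skeleton plausibility filtering, per-well averaging, concatenation of
the three stimulus windows into a single phenotypic profile, motion-state
classification of speed traces, pulse-aligned fraction-moving curves with
bootstrap confidence bands, and scalar response-window statistics.

Conventions: time is measured in seconds from the start of the recording,
frames are 0-based at fixed fps, and all windows are half-open
``[start, stop)`` so boundary frames are never double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ResponseWindowSpec,
    SkeletonFilterSpec,
    StimulusProtocol,
    WINDOW_TAGS,
)

# Motion-state codes used throughout.
STATE_FORWARD = 0
STATE_PAUSED = 1
STATE_BACKWARD = 2
STATE_UNDETECTED = 3

STATE_NAMES = {
    STATE_FORWARD: "forward",
    STATE_PAUSED: "paused",
    STATE_BACKWARD: "backward",
    STATE_UNDETECTED: "undetected",
}


@dataclass
class MotionTimeseries:
    """Per-well frame-by-worm motion states and signed midbody speeds.

    ``states`` is an ``(n_frames, n_worms)`` integer array with codes
    forward=0, paused=1, backward=2, undetected=3; ``speeds`` (µm/s, signed,
    NaN = undetected) has the same shape when present.
    """

    well_id: str
    fps: float
    states: np.ndarray
    speeds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (n_frames, n_worms) array")
        bad = ~np.isin(self.states, list(STATE_NAMES))
        if bad.any():
            raise ValueError(f"states contain invalid codes: {np.unique(self.states[bad])}")
        if self.speeds is not None:
            self.speeds = np.asarray(self.speeds, dtype=float)
            if self.speeds.shape != self.states.shape:
                raise ValueError("speeds and states must have the same shape")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_worms(self) -> int:
        return self.states.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def filter_skeleton_records(
    records: pd.DataFrame,
    spec: SkeletonFilterSpec = SkeletonFilterSpec(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep skeletons with plausible length and width (bounds inclusive).

    ``records`` must carry ``length`` and ``width`` columns in µm.  Returns
    the retained rows and rejection counts keyed by reason (``length``,
    ``width``, ``length_and_width``) plus ``retained``.
    """
    for col in ("length", "width"):
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
    length = records["length"].to_numpy(dtype=float)
    width = records["width"].to_numpy(dtype=float)
    if not (np.isfinite(length).all() and np.isfinite(width).all()):
        raise ValueError("skeleton lengths/widths must be finite")
    if (length < 0).any() or (width < 0).any():
        raise ValueError("skeleton lengths/widths must be >= 0")

    llo, lhi = spec.length_bounds
    wlo, whi = spec.width_bounds
    ok_len = (length >= llo) & (length <= lhi)
    ok_wid = (width >= wlo) & (width <= whi)
    keep = ok_len & ok_wid
    counts = {
        "retained": int(keep.sum()),
        "length": int((~ok_len & ok_wid).sum()),
        "width": int((ok_len & ~ok_wid).sum()),
        "length_and_width": int((~ok_len & ~ok_wid).sum()),
    }
    return records.loc[keep], counts


def well_average(
    values: pd.DataFrame,
    by: str = "well_id",
) -> pd.DataFrame:
    """Average per-worm/per-frame values into one vector per well.

    NaN entries are ignored; a well whose feature has no finite value keeps
    NaN for that feature.
    """
    if by not in values.columns:
        raise ValueError(f"grouping column {by!r} not present")
    return values.groupby(by, sort=True).mean(numeric_only=True)


def _check_key_sets(tables: Mapping[str, pd.DataFrame]) -> None:
    tags = list(tables)
    wells = {tag: set(t.index) for tag, t in tables.items()}
    union = set.union(*wells.values())
    missing = {
        tag: sorted(union - wset) for tag, wset in wells.items() if union - wset
    }
    if missing:
        detail = "; ".join(f"{tag}: {m}" for tag, m in missing.items())
        raise ValueError(f"well sets differ across windows — missing wells by window: {detail}")
    feats = {tag: list(t.columns) for tag, t in tables.items()}
    ref = set(feats[tags[0]])
    for tag in tags[1:]:
        diff = ref.symmetric_difference(feats[tag])
        if diff:
            raise ValueError(
                f"feature sets differ between {tags[0]!r} and {tag!r}: {sorted(diff)[:10]}"
            )


def assemble_profiles(
    prestim: pd.DataFrame,
    bluelight: pd.DataFrame,
    poststim: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Concatenate the three window tables into one phenotypic profile.

    Columns are ordered (prestim block, bluelight block, poststim block),
    each preserving its input feature order, and renamed ``<window>_<feature>``.
    The returned ``window_tags`` vector marks each column's origin window
    (the "stim type" barcode).  With 2763 features per window the profile has
    8289 columns.
    """
    tables = dict(zip(WINDOW_TAGS, (prestim, bluelight, poststim)))
    for tag, t in tables.items():
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate well_id in {tag} table: {dup}")
    _check_key_sets(tables)

    order = list(prestim.index)
    blocks = []
    tags = []
    for tag in WINDOW_TAGS:
        t = tables[tag].loc[order]
        # preserve per-window input feature order
        block = t.copy()
        block.columns = [f"{tag}_{c}" for c in t.columns]
        blocks.append(block)
        tags.extend([tag] * t.shape[1])
    profile = pd.concat(blocks, axis=1)
    return profile, np.array(tags)


def split_profiles(
    profile: pd.DataFrame, window_tags: np.ndarray
) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`assemble_profiles` (round-trip exact)."""
    window_tags = np.asarray(window_tags)
    if window_tags.shape[0] != profile.shape[1]:
        raise ValueError("window_tags length must match the profile column count")
    out: dict[str, pd.DataFrame] = {}
    for tag in WINDOW_TAGS:
        cols = profile.columns[window_tags == tag]
        block = profile[cols].copy()
        block.columns = [c[len(tag) + 1:] for c in cols]
        out[tag] = block
    return out


def classify_motion_states(speeds: np.ndarray, v_min: float) -> np.ndarray:
    """Threshold signed speeds into forward / paused / backward states.

    forward iff speed > +v_min, backward iff speed < -v_min, else paused;
    NaN speeds map to the "undetected" code and are excluded from
    denominators downstream.
    """
    if not v_min > 0:
        raise ValueError("v_min must be > 0")
    speeds = np.asarray(speeds, dtype=float)
    states = np.full(speeds.shape, STATE_PAUSED, dtype=np.int8)
    states[speeds > v_min] = STATE_FORWARD
    states[speeds < -v_min] = STATE_BACKWARD
    states[~np.isfinite(speeds)] = STATE_UNDETECTED
    return states


def _mode_mask(states: np.ndarray, mode: str) -> np.ndarray:
    if mode == "forward":
        return states == STATE_FORWARD
    if mode == "backward":
        return states == STATE_BACKWARD
    if mode == "paused":
        return states == STATE_PAUSED
    if mode == "any":
        return (states == STATE_FORWARD) | (states == STATE_BACKWARD)
    raise ValueError(f"unknown mode {mode!r}")


def fraction_trace(ts: MotionTimeseries, mode: str = "forward") -> np.ndarray:
    """Per-frame fraction of detected worms in the given motion mode."""
    detected = (ts.states != STATE_UNDETECTED).sum(axis=1).astype(float)
    moving = _mode_mask(ts.states, mode).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(detected > 0, moving / np.maximum(detected, 1.0), np.nan)
    return frac


def mean_speed_trace(ts: MotionTimeseries, absolute: bool = False) -> np.ndarray:
    """Per-frame mean speed over detected worms (NaN speeds ignored)."""
    if ts.speeds is None:
        raise ValueError(f"well {ts.well_id}: no speed data")
    sp = np.abs(ts.speeds) if absolute else ts.speeds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        return np.nanmean(sp, axis=1)


def fraction_moving_series(
    timeseries: Sequence[MotionTimeseries],
    protocol: StimulusProtocol,
    mode: str = "forward",
    day_of_well: Mapping[str, object] | None = None,
    pulse_index: int = 0,
    align: float | None = None,
    span: tuple[float, float] = (60.0, 80.0),
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Pulse-aligned mean fraction-moving curve with a bootstrap CI band.

    Per frame, each well contributes moving / detected worms; well curves are
    averaged within each biological-replicate day, then across days.  The
    95% band is a percentile bootstrap over wells within day (``n_boot``
    resamples, seeded).  Returns a frame-indexed table with columns ``time``
    (seconds relative to the pulse onset), ``fraction``, ``ci_lower``,
    ``ci_upper`` and ``n_detected_wells``; frames where no well has a
    detected worm are NaN.

    ``align`` overrides the pulse alignment with an absolute time (seconds).
    """
    if not timeseries:
        raise ValueError("no timeseries provided")
    fps = protocol.fps
    if align is None:
        t0 = protocol.pulse_onsets_absolute()[pulse_index]
    else:
        t0 = float(align)
    i0 = int(round(t0 * fps))
    lo = i0 - int(round(span[0] * fps))
    hi = i0 + int(round(span[1] * fps))
    n_frames = min(ts.n_frames for ts in timeseries)
    if lo < 0 or hi > n_frames:
        raise ValueError(
            f"span ({span[0]} s before, {span[1]} s after) does not fit in the "
            f"recording after alignment at {t0} s"
        )

    wells = [ts.well_id for ts in timeseries]
    curves = np.stack([fraction_trace(ts, mode)[lo:hi] for ts in timeseries])
    days = np.array([day_of_well[w] if day_of_well is not None else 0 for w in wells],
                    dtype=object)

    finite = np.isfinite(curves)
    day_levels = pd.unique(days)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        day_means = np.stack([np.nanmean(curves[days == d], axis=0) for d in day_levels])
        mean_curve = np.nanmean(day_means, axis=0)

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    boot_days = np.empty((len(day_levels), n_boot, hi - lo))
    vals0 = np.nan_to_num(curves, nan=0.0)
    for di, d in enumerate(day_levels):
        idx = np.flatnonzero(days == d)
        k = idx.size
        # multinomial well counts <=> resampling wells with replacement
        w = rng.multinomial(k, np.full(k, 1.0 / k), size=n_boot).astype(float)
        num = w @ vals0[idx]
        den = w @ finite[idx].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_days[di] = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot = np.nanmean(boot_days, axis=0)
        ci_lower = np.nanquantile(boot, alpha, axis=0)
        ci_upper = np.nanquantile(boot, 1.0 - alpha, axis=0)

    n_detected = finite.sum(axis=0)
    undefined = n_detected == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} frame(s) have zero detected worms across all wells",
            RuntimeWarning,
        )
    times = (np.arange(lo, hi) - i0) / fps
    return pd.DataFrame(
        {
            "time": times,
            "fraction": mean_curve,
            "ci_lower": ci_lower,
            "ci_upper": ci_upper,
            "n_detected_wells": n_detected,
        }
    )


def _interval_slice(start: float, stop: float, fps: float) -> slice:
    # frames k with k/fps in [start, stop)
    i0 = int(np.ceil(start * fps - 1e-9))
    i1 = int(np.ceil(stop * fps - 1e-9))
    return slice(max(i0, 0), max(i1, 0))


def window_response_features(
    traces: Mapping[str, np.ndarray] | pd.DataFrame,
    protocol: StimulusProtocol,
    spec: ResponseWindowSpec = ResponseWindowSpec(),
    reducer: str = "mean",
    pulse_index: int = 0,
) -> pd.DataFrame:
    """Reduce frame-level traces to (before, response, after) scalars.

    With the default spec and a pulse starting at ``t0`` the half-open
    intervals are ``[t0-10, t0)``, ``[t0+5, t0+15)`` and ``[t0+15, t0+25)``
    seconds.  ``traces`` maps well_id -> 1-D per-frame values (NaN =
    undetected, excluded); a DataFrame is interpreted as wells x frames.
    """
    if reducer not in ("mean", "median"):
        raise ValueError("reducer must be 'mean' or 'median'")
    reduce = np.nanmean if reducer == "mean" else np.nanmedian
    if isinstance(traces, pd.DataFrame):
        items = [(idx, traces.loc[idx].to_numpy(dtype=float)) for idx in traces.index]
    else:
        items = [(k, np.asarray(v, dtype=float)) for k, v in traces.items()]

    t0 = protocol.pulse_onsets_absolute()[pulse_index]
    intervals = spec.intervals(t0)
    if intervals[0][0] < 0:
        raise ValueError("response window precedes the start of the recording")

    rows = {}
    for well, trace in items:
        vals = []
        for (a, b) in intervals:
            sl = _interval_slice(a, b, protocol.fps)
            chunk = trace[sl]
            if chunk.size == 0 or not np.isfinite(chunk).any():
                warnings.warn(
                    f"well {well}: response window [{a}, {b}) has no finite frames",
                    RuntimeWarning,
                )
                vals.append(np.nan)
            else:
                vals.append(float(reduce(chunk)))
        rows[well] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["before", "response", "after"])
    out.index.name = "well_id"
    return out
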