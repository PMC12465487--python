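"""Synthetic behavioural-screen data with known ground truth.

Emulates the statistical structure of a multiwell worm-tracking screen:
wells of 3–5 worms replicated across independent tracking days, one
well-averaged feature vector per recording window (2763 features per window
by default), additive strain effects on a known feature subset, day-block
random effects shared by all wells tracked on the same day, per-window
stimulus shifts, missing entries, and pulse-triggered locomotion produced by
a three-state (forward / paused / backward) Markov chain whose transition
rates are modulated by the blue-light pulses.

A single global seed fans out to per-purpose substreams (baselines, effects,
day effects, noise, NaN mask, worm counts, timeseries) so adding one
generator does not perturb the others, and identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimulationConfig, StimulusProtocol, WINDOW_TAGS
from .features import (
    MotionTimeseries,
    STATE_BACKWARD,
    STATE_FORWARD,
    STATE_PAUSED,
)

_MAX_FRAMES_PER_WELL = 10_000_000

# Tierpsy-style feature names: <base>_<bodypart>_<stat>
_BASES = (
    "speed", "angular_velocity", "relative_to_body_speed", "curvature",
    "d_curvature", "d_speed", "d_angular_velocity", "length", "width",
    "area", "quirkiness", "major_axis", "minor_axis", "motion_mode_forward",
    "motion_mode_paused", "motion_mode_backward", "path_curvature",
    "eigen_projection_1", "eigen_projection_2", "eigen_projection_3",
    "bend_count", "amplitude", "wavelength", "primary_wavelength",
    "radial_velocity",
)
_BODYPARTS = ("head", "neck", "midbody", "hips", "tail", "body")
_STATS = (
    "10th", "25th", "50th", "75th", "90th", "IQR",
    "abs_10th", "abs_25th", "abs_50th", "abs_75th", "abs_90th", "abs_IQR",
    "w_forward_50th", "w_backward_50th", "w_paused_50th", "norm_50th",
    "w_forward_IQR", "w_backward_IQR", "w_paused_IQR", "norm_IQR",
)


def feature_names(n: int) -> list[str]:
    """Canonical per-window feature-name list with exactly ``n`` entries."""
    names: list[str] = []
    for base in _BASES:
        for part in _BODYPARTS:
            for stat in _STATS:
                names.append(f"{base}_{part}_{stat}")
                if len(names) == n:
                    return names
    # overflow: indexed variants keep names unique for any requested count
    i = 0
    while len(names) < n:
        names.append(f"extra_feature_{i:05d}_body_50th")
        i += 1
    return names


def _strain_names(n_strains: int) -> list[str]:
    return ["N2"] + [f"mut-{s:02d}" for s in range(1, n_strains)]


def _draw_effects(rng: np.random.Generator, dist: Mapping, size: int) -> np.ndarray:
    """Standardized strain effects (units of sigma_well)."""
    name = dist["name"]
    if name == "normal":
        return rng.normal(dist.get("mean", 0.0), dist.get("sd", 1.0), size)
    if name == "fixed":
        return np.full(size, float(dist["value"]))
    if name == "student_t":
        return dist.get("scale", 1.0) * rng.standard_t(dist["df"], size)
    raise ValueError(f"unknown effect_size_dist {name!r}")


def _well_plan(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic (strain, day) well layout.

    ``balanced`` gives every strain ``wells_per_strain_per_day`` wells on
    every day.  ``confounded`` keeps the same total per strain but places
    even-indexed strains mostly on early days and odd-indexed strains mostly
    on late days, sharing ``confound_overlap`` of the days — day effects then
    no longer cancel between groups, which is what defeats the naive test.
    """
    D = config.n_days
    rows = []
    if config.day_assignment == "balanced":
        for s in range(config.n_strains):
            for d in range(D):
                rows.append((s, d, config.wells_per_strain_per_day))
    else:
        total = config.wells_per_strain_per_day * D
        shared = max(1, int(round(config.confound_overlap * D)))
        shared = min(shared, D)
        d_end = (D + shared + 1) // 2
        d_start = D - d_end
        early = list(range(0, d_end))
        late = list(range(d_start, D))
        for s in range(config.n_strains):
            days = early if s % 2 == 0 else late
            base, rem = divmod(total, len(days))
            for i, d in enumerate(days):
                rows.append((s, d, base + (1 if i < rem else 0)))
    plan = pd.DataFrame(rows, columns=["strain_idx", "day", "n_wells"])
    return plan[plan["n_wells"] > 0].reset_index(drop=True)


def _metadata_from_plan(config: SimulationConfig, plan: pd.DataFrame,
                        rng_worms: np.random.Generator) -> pd.DataFrame:
    strains = _strain_names(config.n_strains)
    start = pd.Timestamp("2024-01-01")
    records = []
    for _, row in plan.iterrows():
        s, d, k = int(row.strain_idx), int(row.day), int(row.n_wells)
        date = int((start + pd.Timedelta(days=d)).strftime("%Y%m%d"))
        for i in range(k):
            records.append(
                {
                    "well_id": f"{strains[s]}_d{d:02d}_w{i:03d}",
                    "strain": strains[s],
                    "date_yyyymmdd": date,
                    "plate_id": f"P{d:02d}_{i // 8:02d}",
                    "rig_id": f"R{(i % 2) + 1}",
                    "drug": "none",
                    "dose": "none",
                    "n_worms": int(rng_worms.integers(config.worms_per_well[0],
                                                      config.worms_per_well[1] + 1)),
                    "is_bad_well": False,
                }
            )
    meta = pd.DataFrame.from_records(records)
    meta["strain_idx"] = meta["strain"].map({s: i for i, s in enumerate(strains)})
    return meta


def simulate_feature_dataset(
    config: SimulationConfig,
    protocol: StimulusProtocol | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Generate the three per-window feature tables plus metadata and truth.

    Returns ``(tables, metadata, ground_truth)`` where ``tables`` maps each
    window tag to a well x feature DataFrame, ``metadata`` annotates every
    well (strain, tracking day, plate, rig, worm count), and
    ``ground_truth`` lists exactly the (strain, feature) pairs with a
    non-zero injected effect (``true_effect`` in feature units).

    Entries follow ``y = mu_f + beta_{strain,f} + shift_w + delta_{day,f} +
    eps`` with ``delta ~ N(0, sigma_day^2)`` per (day, feature) shared across
    windows and strains, and ``eps ~ N(0, sigma_well^2)`` independent per
    well, feature and window (Student-t with ``noise_df`` degrees of freedom
    scaled to the same SD when the heavy-tail option is on).  NaNs are
    injected uniformly at random at ``nan_rate`` per window.
    """
    del protocol  # window identity is fixed by WINDOW_TAGS; timing not needed here
    ss = np.random.SeedSequence(config.rng_seed)
    kids = ss.spawn(7)
    rng_base, rng_eff, rng_day, rng_noise, rng_nan, rng_worms = (
        np.random.default_rng(k) for k in kids[:6]
    )  # kids[6] is reserved for the motion-timeseries generator

    F = config.n_features_per_window
    S = config.n_strains
    feats = feature_names(F)

    mu = rng_base.normal(0.0, 1.0, F)
    beta = np.zeros((S, F))
    n_aff = int(round(config.affected_fraction * F))
    truth_rows = []
    strains = _strain_names(S)
    for s in range(1, S):
        idx = rng_eff.choice(F, size=n_aff, replace=False) if n_aff else np.array([], int)
        effects = _draw_effects(rng_eff, config.effect_size_dist, idx.size)
        effects = np.where(effects == 0.0, 1e-6, effects)  # truth lists beta != 0
        beta[s, idx] = effects * config.sigma_well
        for j, e in zip(idx, beta[s, idx]):
            truth_rows.append({"strain": strains[s], "feature": feats[j], "true_effect": e})
    ground_truth = pd.DataFrame(truth_rows, columns=["strain", "feature", "true_effect"])

    delta = rng_day.normal(0.0, config.sigma_day, (config.n_days, F)) \
        if config.sigma_day > 0 else np.zeros((config.n_days, F))

    plan = _well_plan(config)
    metadata = _metadata_from_plan(config, plan, rng_worms)
    n_wells = len(metadata)

    per_group = metadata.groupby("strain").size().min()
    if per_group * (1.0 - config.nan_rate) < 2:
        warnings.warn(
            f"nan_rate={config.nan_rate} leaves fewer than 2 finite values per "
            "group in expectation; downstream tests will skip features",
            UserWarning,
        )

    s_idx = metadata["strain_idx"].to_numpy()
    day_pos = metadata["date_yyyymmdd"].rank(method="dense").astype(int).to_numpy() - 1
    base = mu[None, :] + beta[s_idx] + delta[day_pos]

    tables: dict[str, pd.DataFrame] = {}
    for tag in WINDOW_TAGS:
        shift = float(config.window_shift_spec.get(tag, 0.0))
        if config.noise_df is None:
            eps = rng_noise.normal(0.0, config.sigma_well, (n_wells, F))
        else:
            df = config.noise_df
            scale = config.sigma_well * (np.sqrt((df - 2) / df) if df > 2 else 1.0)
            eps = scale * rng_noise.standard_t(df, (n_wells, F))
        y = base + shift + eps
        if config.nan_rate > 0:
            y = np.where(rng_nan.random((n_wells, F)) < config.nan_rate, np.nan, y)
        tables[tag] = pd.DataFrame(y, index=pd.Index(metadata["well_id"], name="well_id"),
                                   columns=feats)
    return tables, metadata.drop(columns="strain_idx"), ground_truth


@dataclass(frozen=True)
class MotionKinetics:
    """Continuous-time kinetics of the 3-state locomotion chain.

    ``baseline_rates`` and ``pulse_rates`` are 3x3 per-second rate matrices
    over (forward, paused, backward); only off-diagonal entries are used.
    During a pulse the rates are the pulse matrix; after pulse end they relax
    back to baseline exponentially with time constant ``relaxation_tau``
    seconds.  Speeds are state-conditional means (µm/s) plus Gaussian noise.
    """

    baseline_rates: tuple = (
        (0.0, 0.20, 0.02),
        (0.25, 0.0, 0.05),
        (0.50, 0.30, 0.0),
    )
    pulse_rates: tuple = (
        (0.0, 0.10, 0.60),
        (1.20, 0.0, 0.40),
        (1.00, 0.10, 0.0),
    )
    relaxation_tau: float = 5.0
    state_speeds: tuple[float, float, float] = (250.0, 0.0, -150.0)
    speed_noise: float = 20.0

    def __post_init__(self) -> None:
        for name in ("baseline_rates", "pulse_rates"):
            q = np.asarray(getattr(self, name), dtype=float)
            if q.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3")
            off = q[~np.eye(3, dtype=bool)]
            if (off < 0).any():
                raise ValueError(f"{name} off-diagonal rates must be >= 0")
        if self.relaxation_tau < 0:
            raise ValueError("relaxation_tau must be >= 0")
        if self.speed_noise < 0:
            raise ValueError("speed_noise must be >= 0")

    def generator_matrix(self, which: str = "baseline") -> np.ndarray:
        q = np.asarray(getattr(self, f"{which}_rates"), dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def _pulse_modulation(protocol: StimulusProtocol, tau: float) -> np.ndarray:
    """Per-frame modulation in [0, 1]: 1 during a pulse, exponential decay
    towards baseline after each pulse end."""
    t = np.arange(protocol.n_frames()) / protocol.fps
    m = np.zeros_like(t)
    for onset in protocol.pulse_onsets_absolute():
        end = onset + protocol.pulse_duration
        m = np.maximum(m, np.where((t >= onset) & (t < end), 1.0, 0.0))
        if tau > 0:
            decay = np.exp(np.minimum(-(t - end) / tau, 0.0))
            m = np.maximum(m, np.where(t >= end, decay, 0.0))
    return m


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix (first unit
    eigenvector; degenerate chains fall back to uniform)."""
    vals, vecs = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, idx])
    pi = np.where(np.abs(pi) < 1e-12, 0.0, pi)
    if pi.sum() == 0 or (pi < -1e-9).any() and (pi > 1e-9).any():
        return np.full(P.shape[0], 1.0 / P.shape[0])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_motion_timeseries(
    config: SimulationConfig,
    kinetics: MotionKinetics,
    protocol: StimulusProtocol,
    wells: pd.DataFrame | None = None,
) -> list[MotionTimeseries]:
    """Simulate per-well, per-worm motion states and speeds.

    Each worm follows the discretized Markov chain (transition matrix
    ``I + Q(t) dt`` at the protocol's frame interval) whose rates blend from
    baseline to the pulse matrix with the pulse modulation; initial states
    are drawn from the baseline chain's stationary distribution.  Speeds are
    the state-conditional means plus Gaussian noise.  ``wells`` (a metadata
    table) fixes well ids and worm counts; by default the config's well plan
    is used.  One :class:`MotionTimeseries` per well.
    """
    n_frames = protocol.n_frames()
    if n_frames > _MAX_FRAMES_PER_WELL:
        raise ValueError(
            f"fps * duration = {n_frames} frames per well exceeds {_MAX_FRAMES_PER_WELL}"
        )
    dt = 1.0 / protocol.fps
    Qb = kinetics.generator_matrix("baseline")
    Qp = kinetics.generator_matrix("pulse")
    max_exit = max((-np.diag(Qb)).max(), (-np.diag(Qp)).max())
    if max_exit * dt > 1.0:
        raise ValueError(
            f"total exit rate {max_exit}/s is too fast for fps={protocol.fps}; "
            "the one-step discretization would leave the simplex"
        )

    root = np.random.SeedSequence(config.rng_seed).spawn(7)[6]
    if wells is None:
        plan = _well_plan(config)
        wells = _metadata_from_plan(config, plan, np.random.default_rng(root.spawn(1)[0]))
    well_ids = list(wells["well_id"])
    n_worms_per_well = list(wells["n_worms"].astype(int))

    m = _pulse_modulation(protocol, kinetics.relaxation_tau)
    # precompute per-frame cumulative transition rows
    P_frames = np.empty((n_frames, 3, 3))
    eye = np.eye(3)
    for f in range(n_frames):
        Q = Qb + m[f] * (Qp - Qb)
        P = eye + Q * dt
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        P_frames[f] = P
    cumP = np.cumsum(P_frames, axis=2)

    pi0 = _stationary(P_frames[0])
    means = np.asarray(kinetics.state_speeds, dtype=float)

    out: list[MotionTimeseries] = []
    for ws, (well_id, n_worms) in zip(root.spawn(len(well_ids)),
                                      zip(well_ids, n_worms_per_well)):
        rng = np.random.default_rng(ws)
        states = np.empty((n_frames, n_worms), dtype=np.int8)
        s = rng.choice(3, size=n_worms, p=pi0)
        states[0] = s
        u = rng.random((n_frames - 1, n_worms))
        for f in range(1, n_frames):
            rows = cumP[f - 1][s]  # (n_worms, 3) cumulative rows
            s = (u[f - 1][:, None] > rows).sum(axis=1)
            states[f] = s
        speeds = means[states]
        if kinetics.speed_noise > 0:
            speeds = speeds + rng.normal(0.0, kinetics.speed_noise, speeds.shape)
        out.append(MotionTimeseries(well_id=well_id, fps=protocol.fps,
                                    states=states, speeds=speeds))
    return out


# state codes re-exported for convenience alongside the generator
__all__ = [
    "feature_names",
    "simulate_feature_dataset",
    "MotionKinetics",
    "simulate_motion_timeseries",
    "STATE_FORWARD",
    "STATE_PAUSED",
    "STATE_BACKWARD",
]
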