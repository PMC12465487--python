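"""Replicate sub-sampling power analysis.

Does a phenotype detected with hundreds of well replicates survive at
drug-screen replicate counts?  Each draw samples ``n_wells`` wells per group
without replacement, runs Student's two-sample t-test per feature, corrects
within the analysed feature subset (Benjamini–Yekutieli), and the detection
fraction is the proportion of draws in which a feature reaches corrected
significance.  Draws deliberately ignore day blocks, matching how a small
screen would be analysed; a blocked variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import StatsConfig
from .stats import block_permutation_ttest, by_adjust

_P_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class SubsampleReport:
    """Outcome of a replicate sub-sampling experiment.

    ``summary`` has one row per feature: detection fraction plus quantiles
    of the raw p-value distribution across draws.  ``draws`` is the per-draw
    long table (draw, feature, p_raw, p_adjusted, significant).
    """

    summary: pd.DataFrame
    draws: pd.DataFrame
    n_wells: int
    n_draws: int
    alpha: float
    correction: str
    test: str


def subsample_power(
    values: pd.DataFrame,
    groups,
    *,
    n_wells: int,
    n_draws: int,
    alpha: float = 0.05,
    correction: str = "BY",
    seed: int = 0,
    features: list[str] | None = None,
    blocks=None,
    blocked: bool = False,
    n_permutations: int = 1000,
) -> SubsampleReport:
    """Estimate per-feature detection fractions at ``n_wells`` replicates.

    ``values`` is a wells x features table, ``groups`` a two-level label
    vector.  ``features`` restricts the analysed subset (and the BY family).
    ``blocked=True`` switches each draw from Student's t to the day-blocked
    permutation test (requires ``blocks``).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if correction not in ("BY", "none"):
        raise ValueError("correction must be 'BY' or 'none'")
    if features is not None:
        values = values[list(features)]
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    idx_a = np.flatnonzero(groups == levels[0])
    idx_b = np.flatnonzero(groups == levels[1])
    for lv, idx in zip(levels, (idx_a, idx_b)):
        if idx.size < n_wells:
            raise ValueError(
                f"group {lv!r} has {idx.size} wells, fewer than n_wells={n_wells}"
            )
    if blocked and blocks is None:
        raise ValueError("blocked draws require day blocks")
    blocks = np.asarray(blocks) if blocks is not None else None

    X = values.to_numpy(dtype=float)
    feats = list(values.columns)
    rng = np.random.default_rng(seed)
    records = []
    for d in range(n_draws):
        sel_a = rng.choice(idx_a, size=n_wells, replace=False)
        sel_b = rng.choice(idx_b, size=n_wells, replace=False)
        if blocked:
            sel = np.concatenate([sel_a, sel_b])
            cfg = StatsConfig(n_permutations=n_permutations,
                              rng_seed=int(rng.integers(2 ** 31)))
            res = block_permutation_ttest(
                values.iloc[sel], groups[sel], blocks[sel], cfg)
            p_raw = res.table["p_raw"].to_numpy()
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p_raw = scipy.stats.ttest_ind(X[sel_a], X[sel_b], axis=0,
                                                 nan_policy="omit")
            p_raw = np.asarray(p_raw, dtype=float)
        p_adj = by_adjust(p_raw) if correction == "BY" else p_raw
        sig = np.where(np.isnan(p_adj), False, p_adj < alpha)
        for j, f in enumerate(feats):
            records.append((d, f, p_raw[j], p_adj[j], bool(sig[j])))

    draws = pd.DataFrame.from_records(
        records, columns=["draw", "feature", "p_raw", "p_adjusted", "significant"]
    )
    grouped = draws.groupby("feature", sort=False)
    summary = pd.DataFrame({
        "detection_fraction": grouped["significant"].mean(),
        "n_wells": n_wells,
        "n_draws": n_draws,
    })
    for q in _P_QUANTILES:
        summary[f"p_q{int(q * 100):02d}"] = grouped["p_raw"].quantile(q)
    summary = summary.loc[feats]
    test = "blocked_permutation_t" if blocked else "student_t"
    return SubsampleReport(
        summary=summary, draws=draws, n_wells=n_wells, n_draws=n_draws,
        alpha=alpha, correction=correction, test=test,
    )
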