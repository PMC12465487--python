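"""Day-blocked permutation t-tests with Benjamini–Yekutieli FDR control.

The screen's unit of replication is the well, but wells tracked on the same
day share day-level variation.  Shuffling group labels only *within*
independent tracking days yields a permutation null that respects that
day-to-day variation; an unblocked test on day-confounded designs is badly
anticonservative.  P-values use the add-one estimator
``(1 + #{|t_perm| >= |t_obs|}) / (1 + B)`` and are corrected per comparison
with the Benjamini–Yekutieli step-up, which controls the FDR under arbitrary
dependence between features.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .config import StatsConfig, WINDOW_TAGS

_REL_TOL = 1e-12  # tie tolerance when comparing |t_perm| with |t_obs|


@dataclass
class PermutationTestResult:
    """Per-feature statistics of one two-group blocked comparison.

    ``table`` is indexed by feature with columns ``t_obs``, ``p_raw``,
    ``p_adjusted``, ``significant`` and ``skip_reason`` (empty string for
    tested features).
    """

    table: pd.DataFrame
    n_permutations: int
    statistic: str
    fdr_q: float
    group_sizes: dict = field(default_factory=dict)
    block_sizes: dict = field(default_factory=dict)

    @property
    def n_tested(self) -> int:
        return int((self.table["skip_reason"] == "").sum())

    @property
    def n_skipped(self) -> int:
        return int((self.table["skip_reason"] != "").sum())

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def by_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    With ``m`` finite inputs sorted ascending and ``c(m) = sum_{i<=m} 1/i``,
    the i-th candidate is ``p_(i) * m * c(m) / i`` and the adjusted value is
    the running minimum of candidates from the largest rank down, capped at
    1.  NaN entries pass through as NaN and do not count towards ``m``.
    """
    p = np.asarray(p_raw, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if pm.size == 0:
        return out
    if (pm <= 0).any() or (pm > 1).any():
        raise ValueError("raw p-values must lie in (0, 1]")
    m = pm.size
    order = np.argsort(pm, kind="stable")
    cm = np.sum(1.0 / np.arange(1, m + 1))
    candidates = pm[order] * m * cm / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(np.minimum.accumulate(candidates[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    out[mask] = adjusted
    return out


def _prepare(values, groups, blocks, levels):
    if isinstance(values, pd.DataFrame):
        X = values.to_numpy(dtype=float)
        feature_names = list(values.columns)
    else:
        X = np.asarray(values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = [f"feature_{j}" for j in range(X.shape[1])]
    n = X.shape[0]
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise ValueError("groups length must match the number of wells")
    if blocks is None:
        blocks = np.zeros(n, dtype=int)
    blocks = np.asarray(blocks)
    if blocks.shape[0] != n:
        raise ValueError("blocks length must match the number of wells")

    if levels is None:
        # sorted for row-order invariance; pass `levels` to fix the t sign
        levels = tuple(sorted(pd.unique(groups), key=str))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {list(levels)}")
    for lv in levels:
        if not (groups == lv).any():
            raise ValueError(f"group {lv!r} is absent from the data")
    extra = set(np.unique(groups).tolist()) - set(levels)
    if extra:
        raise ValueError(f"labels outside the two requested groups: {sorted(map(str, extra))}")
    g = groups == levels[1]
    return X, g, blocks, levels, feature_names


def _canonical_order(X: np.ndarray, g: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Stable well ordering so results are invariant to input row order."""
    block_codes = pd.factorize(pd.Series(blocks).astype(str), sort=True)[0]
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)]
    keys.extend([g.astype(int), block_codes])
    return np.lexsort(tuple(keys))


def _t_from_labels(X0, X0sq, F, G, statistic, min_finite):
    """Two-sample t per feature for each label column of G.

    G: (n_wells, B) float 0/1 matrix assigning wells to group 1.  Returns a
    (n_features, B) array.  Label assignments leaving fewer than
    ``min_finite`` finite values in a group yield +inf (counted as extreme).
    Features constant in both groups yield t = 0.
    """
    nF = F.sum(axis=0)[:, None]
    sX = X0.sum(axis=0)[:, None]
    sXX = X0sq.sum(axis=0)[:, None]

    n1 = F.T @ G
    s1 = X0.T @ G
    ss1 = X0sq.T @ G
    n0 = nF - n1
    s0 = sX - s1
    ss0 = sXX - ss1

    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = s1 / n1
        m0 = s0 / n0
        var1 = np.clip(ss1 - n1 * m1 ** 2, 0.0, None) / np.maximum(n1 - 1, 1)
        var0 = np.clip(ss0 - n0 * m0 ** 2, 0.0, None) / np.maximum(n0 - 1, 1)
        diff = m1 - m0
        if statistic == "pooled_t":
            sp2 = ((n1 - 1) * var1 + (n0 - 1) * var0) / np.maximum(n1 + n0 - 2, 1)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        else:  # welch_t
            se = np.sqrt(var1 / n1 + var0 / n0)
        t = diff / se
    # zero-variance handling: equal means -> 0, separated means -> +/- inf
    zero_se = ~(se > 0)
    t = np.where(zero_se & (diff == 0), 0.0, t)
    t = np.where(zero_se & (diff > 0), np.inf, t)
    t = np.where(zero_se & (diff < 0), -np.inf, t)
    # degenerate assignments count as extreme (conservative)
    t = np.where((n1 < min_finite) | (n0 < min_finite), np.inf, t)
    return t


def _exceeds(t_abs: np.ndarray, t_obs_abs: np.ndarray) -> np.ndarray:
    thresh = t_obs_abs * (1.0 - _REL_TOL) - _REL_TOL
    return t_abs >= thresh[:, None]


def block_permutation_ttest(
    values,
    groups,
    blocks=None,
    config: StatsConfig | None = None,
    levels: tuple | None = None,
) -> PermutationTestResult:
    """Two-group permutation t-test with labels shuffled within day blocks.

    Parameters
    ----------
    values : DataFrame or array, wells x features (NaN = missing).
    groups : two-level labels per well.
    blocks : day labels per well; ``None`` degenerates to an ordinary
        (unblocked) permutation test.
    config : :class:`StatsConfig`; B permutations, statistic, FDR level.
    levels : optional explicit (control, case) pair — required labels; an
        absent level is an error.

    For each of B Monte-Carlo permutations, labels are shuffled uniformly and
    independently within each block (per-block group counts preserved; blocks
    containing one group contribute no exchange).  Two-sided raw
    ``p = (1 + #{|t_perm| >= |t_obs|}) / (1 + B)``; features with fewer than
    ``min_finite_per_group`` finite values in either group are skipped, and
    BY adjustment runs across all tested features of the comparison.
    """
    config = config or StatsConfig()
    X, g, blocks, levels, feature_names = _prepare(values, groups, blocks, levels)

    order = _canonical_order(X, g, blocks)
    X, g, blocks = X[order], g[order], blocks[order]

    F = np.isfinite(X)
    n1f = F[g].sum(axis=0)
    n0f = F[~g].sum(axis=0)
    k = config.min_finite_per_group
    tested = (n1f >= k) & (n0f >= k)
    if not tested.any():
        raise ValueError(
            f"all {X.shape[1]} features skipped: fewer than {k} finite values "
            f"per group (group sizes {int(g.sum())} vs {int((~g).sum())})"
        )

    Xt = X[:, tested]
    Ft = F[:, tested]
    X0 = np.where(Ft, Xt, 0.0)
    X0sq = X0 ** 2

    gcol = g.astype(float)[:, None]
    t_obs = _t_from_labels(X0, X0sq, Ft, gcol, config.statistic, k)[:, 0]
    t_obs_abs = np.abs(t_obs)

    block_labels, block_counts = np.unique(blocks.astype(str), return_counts=True)
    block_idx = [np.flatnonzero(blocks.astype(str) == b) for b in block_labels]

    rng = np.random.default_rng(config.rng_seed)
    B = config.n_permutations
    counts = np.zeros(Xt.shape[1], dtype=np.int64)
    # bound the working set: f x chunk statistics plus the n x chunk labels
    chunk = max(1, min(B, 200_000, int(2.0e7 / max(Xt.shape[1] + X.shape[0], 1))))
    done = 0
    base = g.astype(float)
    while done < B:
        b = min(chunk, B - done)
        G = np.repeat(base[:, None], b, axis=1)
        for idx in block_idx:
            if idx.size < 2 or len(np.unique(g[idx])) < 2:
                continue  # single-group block: nothing to exchange
            sub = np.repeat(base[idx][None, :], b, axis=0)
            G[idx, :] = rng.permuted(sub, axis=1).T
        t_perm = _t_from_labels(X0, X0sq, Ft, G, config.statistic, k)
        counts += _exceeds(np.abs(t_perm), t_obs_abs).sum(axis=1)
        done += b

    p_raw_t = (1.0 + counts) / (1.0 + B)
    p_adj_t = by_adjust(p_raw_t)

    t_full = np.full(X.shape[1], np.nan)
    p_raw = np.full(X.shape[1], np.nan)
    p_adj = np.full(X.shape[1], np.nan)
    t_full[tested] = t_obs
    p_raw[tested] = p_raw_t
    p_adj[tested] = p_adj_t
    skip = np.where(tested, "", "insufficient_finite_data")
    significant = np.where(tested, p_adj < config.fdr_q, False)

    table = pd.DataFrame(
        {
            "t_obs": t_full,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": significant.astype(bool),
            "skip_reason": skip,
        },
        index=pd.Index(feature_names, name="feature"),
    )
    return PermutationTestResult(
        table=table,
        n_permutations=B,
        statistic=config.statistic,
        fdr_q=config.fdr_q,
        group_sizes={str(levels[0]): int((~g).sum()), str(levels[1]): int(g.sum())},
        block_sizes={str(b): int(c) for b, c in zip(block_labels, block_counts)},
    )


def exhaustive_block_permutation_oracle(
    values,
    groups,
    blocks=None,
    statistic: str = "pooled_t",
    max_arrangements: int = 1_000_000,
    levels: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact blocked-permutation p by enumerating every distinct relabelling.

    Enumerates the Cartesian product of within-block label arrangements
    (per-block group counts preserved) and returns, per feature, the exact
    two-sided ``p = #{|t_perm| >= |t_obs|} / total`` together with
    ``t_obs``.  The identity arrangement is included, so p >= 1/total.
    """
    X, g, blocks, levels, _ = _prepare(values, groups, blocks, levels)
    F = np.isfinite(X)
    X0 = np.where(F, X, 0.0)
    X0sq = X0 ** 2

    block_labels = np.unique(blocks.astype(str))
    block_idx = [np.flatnonzero(blocks.astype(str) == b) for b in block_labels]
    per_block: list[list[np.ndarray]] = []
    total = 1
    for idx in block_idx:
        k1 = int(g[idx].sum())
        total *= math.comb(idx.size, k1)
        if total > max_arrangements:
            raise ValueError(
                f"arrangement count exceeds {max_arrangements}; not enumerable"
            )
        per_block.append([np.array(c, dtype=int) for c in
                          itertools.combinations(idx.tolist(), k1)])

    t_obs = _t_from_labels(X0, X0sq, F, g.astype(float)[:, None], statistic, 1)[:, 0]
    t_obs_abs = np.abs(t_obs)

    counts = np.zeros(X.shape[1], dtype=np.int64)
    for combo in itertools.product(*per_block):
        gg = np.zeros(X.shape[0])
        for chosen in combo:
            gg[chosen] = 1.0
        t = _t_from_labels(X0, X0sq, F, gg[:, None], statistic, 1)[:, 0]
        counts += np.abs(t) >= t_obs_abs * (1.0 - _REL_TOL) - _REL_TOL
    return counts / float(total), t_obs


def count_significant(
    result: PermutationTestResult,
    window_tags: Sequence[str] | None = None,
) -> tuple[int, pd.Series]:
    """Total significant features and a per-window breakdown.

    ``window_tags`` gives each feature's origin window; if omitted it is
    inferred from ``<window>_`` feature-name prefixes, with ``"unknown"``
    for unprefixed names.  The breakdown always sums to the total.
    """
    sig = result.table["significant"].to_numpy(dtype=bool)
    if window_tags is None:
        tags = []
        for name in result.table.index:
            head = str(name).split("_", 1)[0]
            tags.append(head if head in WINDOW_TAGS else "unknown")
        window_tags = np.array(tags)
    else:
        window_tags = np.asarray(window_tags)
        if window_tags.shape[0] != sig.shape[0]:
            raise ValueError("window_tags length must match the feature count")
    breakdown = (
        pd.Series(sig, index=pd.Index(window_tags, name="window"))
        .groupby(level=0, sort=True)
        .sum()
        .astype(int)
    )
    return int(sig.sum()), breakdown


@dataclass
class KruskalScreenResult:
    """Per-feature Kruskal–Wallis statistics for a k-group comparison."""

    table: pd.DataFrame  # H, p_raw, p_adjusted, significant, skip_reason
    fdr_q: float
    n_groups: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_tested(self) -> int:
        return int((self.table["skip_reason"] == "").sum())


def kruskal_wallis_screen(
    values,
    labels,
    config: StatsConfig | None = None,
    min_finite_per_group: int | None = None,
) -> KruskalScreenResult:
    """Tie-corrected Kruskal–Wallis test per feature with BY adjustment.

    H is computed from midrank sums with the tie-correction factor and
    referred to a chi-square upper tail with ``k - 1`` degrees of freedom.
    Features constant across all wells, or with fewer than
    ``min_finite_per_group`` finite values in any level, are skipped.
    """
    config = config or StatsConfig()
    k_min = min_finite_per_group or config.min_finite_per_group
    if isinstance(values, pd.DataFrame):
        X = values.to_numpy(dtype=float)
        feature_names = list(values.columns)
    else:
        X = np.asarray(values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = [f"feature_{j}" for j in range(X.shape[1])]
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("at least two condition levels required")
    group_rows = [np.flatnonzero(labels == lv) for lv in levels]

    H = np.full(X.shape[1], np.nan)
    p_raw = np.full(X.shape[1], np.nan)
    skip = np.full(X.shape[1], "", dtype=object)
    for j in range(X.shape[1]):
        samples = []
        ok = True
        for rows in group_rows:
            x = X[rows, j]
            x = x[np.isfinite(x)]
            if x.size < k_min:
                ok = False
                break
            samples.append(x)
        if not ok:
            skip[j] = "insufficient_finite_data"
            continue
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            skip[j] = "zero_variance"
            continue
        h, p = scipy.stats.kruskal(*samples)
        H[j], p_raw[j] = h, p

    p_adj = by_adjust(p_raw)
    tested = skip == ""
    significant = np.where(tested, p_adj < config.fdr_q, False)
    table = pd.DataFrame(
        {
            "H": H,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": significant.astype(bool),
            "skip_reason": skip.astype(str),
        },
        index=pd.Index(feature_names, name="feature"),
    )
    return KruskalScreenResult(table=table, fdr_q=config.fdr_q, n_groups=len(levels))
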