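"""Fingerprints and ordination: z-normalised hierarchical clustering across
strains, PCA trajectories across stimulus windows, and a scalar
stimulus-recovery score.

Z-scores are computed per feature over all wells pooled across strains
(sample SD, denominator n-1).  Residual NaNs are imputed to 0 — the grand
mean on the z scale — for clustering and PCA only; the permutation testing
machinery never imputes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA

from .config import PhenospaceOptions, WINDOW_TAGS

logger = logging.getLogger(__name__)


def znormalise(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each feature over all wells; drop undefined features.

    Features with fewer than 2 finite values or zero SD are dropped with a
    warning naming them.  NaNs are preserved.  Returns the z-scored table
    and a per-feature (mean, sd) table for the retained features.
    """
    means = table.mean(axis=0, skipna=True)
    sds = table.std(axis=0, ddof=1, skipna=True)
    n_finite = table.notna().sum(axis=0)
    bad = (n_finite < 2) | ~(sds > 0)
    if bad.any():
        names = list(table.columns[bad])
        warnings.warn(
            f"dropping {len(names)} constant/underdetermined feature(s): "
            f"{names[:10]}{'...' if len(names) > 10 else ''}",
            UserWarning,
        )
    keep = table.columns[~bad]
    z = (table[keep] - means[keep]) / sds[keep]
    stats = pd.DataFrame({"mean": means[keep], "sd": sds[keep]})
    stats.index.name = "feature"
    return z, stats


@dataclass
class Fingerprint:
    """Strain x feature z-score matrix with row/column linkage trees."""

    matrix: pd.DataFrame          # strain means of z-scores (NaN-imputed to 0)
    row_linkage: np.ndarray       # scipy linkage over strains
    col_linkage: np.ndarray       # scipy linkage over features
    window_tags: np.ndarray | None = None

    @property
    def row_order(self) -> list:
        return [self.matrix.index[i] for i in sch.leaves_list(self.row_linkage)]

    @property
    def col_order(self) -> list:
        return [self.matrix.columns[i] for i in sch.leaves_list(self.col_linkage)]


def hierarchical_fingerprint(
    z: pd.DataFrame,
    strain_of_well: Mapping[str, str] | pd.Series,
    window_tags: Sequence[str] | None = None,
    options: PhenospaceOptions = PhenospaceOptions(),
) -> Fingerprint:
    """Cluster strain-mean z-score profiles (rows) and features (columns).

    Strain rows are NaN-ignoring means over that strain's wells; residual
    NaNs (features never observed for a strain) are imputed to 0 and logged.
    Agglomeration uses the configured linkage (default average) on the
    configured metric (default Euclidean) for both axes.
    """
    strains = pd.Series(strain_of_well)
    missing = z.index.difference(strains.index)
    if len(missing):
        raise ValueError(f"wells without a strain annotation: {list(missing)[:10]}")
    labels = strains.loc[z.index]
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError(f"strain(s) with zero wells: {list(counts[counts == 0].index)}")
    if counts.size < 2:
        raise ValueError("at least 2 strains are required for a fingerprint")

    M = z.groupby(labels).mean()
    n_imputed = int(M.isna().sum().sum())
    if n_imputed:
        logger.info("fingerprint: imputing %d missing strain-mean entries to 0", n_imputed)
        M = M.fillna(0.0)
    row_linkage = sch.linkage(M.to_numpy(), method=options.linkage_method,
                              metric=options.metric)
    col_linkage = sch.linkage(M.to_numpy().T, method=options.linkage_method,
                              metric=options.metric)
    tags = np.asarray(window_tags) if window_tags is not None else None
    return Fingerprint(matrix=M, row_linkage=row_linkage, col_linkage=col_linkage,
                       window_tags=tags)


@dataclass
class PhenospaceProjection:
    """Per-(strain, window) PCA coordinates with dispersion.

    ``centroids`` and ``dispersions`` are indexed by (strain, window) with
    one column per retained principal component; ``well_coords`` keeps the
    per-well scores behind the centroids.
    """

    centroids: pd.DataFrame
    dispersions: pd.DataFrame
    explained_variance_ratio: np.ndarray
    well_coords: pd.DataFrame

    def component_columns(self) -> list[str]:
        return list(self.centroids.columns)


def pca_phenospace(
    tables: Mapping[str, pd.DataFrame],
    strain_of_well: Mapping[str, str] | pd.Series,
    options: PhenospaceOptions = PhenospaceOptions(),
) -> PhenospaceProjection:
    """Project per-window well vectors into a common PCA phenospace.

    The PCA is fitted on all well vectors pooled across strains and windows
    (per-window tables must share one feature space); features are z-scored
    on the pooled set and residual NaNs imputed to 0 before fitting.
    Centroids are per-(strain, window) means of well scores; dispersion is
    the per-axis SD (or SEM) of that stratum's wells.
    """
    missing = [t for t in tables if t not in WINDOW_TAGS]
    if missing:
        raise ValueError(f"unknown window tag(s): {missing}")
    stack = pd.concat({tag: tables[tag] for tag in WINDOW_TAGS if tag in tables},
                      names=["window", "well_id"])
    z, _ = znormalise(stack)
    z0 = z.fillna(0.0)

    max_rank = min(z0.shape)
    n_comp = options.n_components
    if n_comp > max_rank:
        warnings.warn(
            f"n_components={n_comp} exceeds the data rank bound {max_rank}; clamping",
            UserWarning,
        )
        n_comp = max_rank
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    scores = pca.fit_transform(z0.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    coords = pd.DataFrame(scores, index=z0.index, columns=cols)

    strains = pd.Series(strain_of_well)
    well_ids = coords.index.get_level_values("well_id")
    unknown = set(well_ids) - set(strains.index)
    if unknown:
        raise ValueError(f"wells without a strain annotation: {sorted(unknown)[:10]}")
    grouping = [strains.loc[well_ids].to_numpy(),
                coords.index.get_level_values("window")]
    grouped = coords.groupby(grouping)
    centroids = grouped.mean()
    if options.error_bars == "sd":
        dispersions = grouped.std(ddof=1)
    else:
        dispersions = grouped.std(ddof=1) / np.sqrt(grouped.size()).to_numpy()[:, None]
    centroids.index.names = ["strain", "window"]
    dispersions.index.names = ["strain", "window"]
    return PhenospaceProjection(
        centroids=centroids,
        dispersions=dispersions,
        explained_variance_ratio=pca.explained_variance_ratio_,
        well_coords=coords,
    )


def recovery_score(
    projection: PhenospaceProjection,
    strain: str,
    threshold: float = 0.5,
    eps: float = 1e-12,
) -> tuple[float, bool]:
    """Quantify return towards the pre-stimulus phenospace position.

    ``r = ||c_post - c_pre|| / ||c_blue - c_pre||`` over the retained
    components: r = 0 means full recovery to baseline, r = 1 means no
    recovery from the blue-light position.  The strain is flagged
    (non-recovering) when ``r > threshold``.  If the strain barely moves
    under stimulation (denominator < eps) r is undefined (NaN, no flag).
    """
    try:
        c = projection.centroids.loc[strain]
    except KeyError:
        raise ValueError(f"strain {strain!r} not present in the projection")
    for tag in WINDOW_TAGS:
        if tag not in c.index:
            raise ValueError(f"strain {strain!r} is missing the {tag!r} window centroid")
    pre = c.loc["prestim"].to_numpy(dtype=float)
    blue = c.loc["bluelight"].to_numpy(dtype=float)
    post = c.loc["poststim"].to_numpy(dtype=float)
    denom = float(np.linalg.norm(blue - pre))
    if denom < eps:
        warnings.warn(
            f"strain {strain!r}: no measurable stimulus displacement; "
            "recovery score undefined",
            RuntimeWarning,
        )
        return float("nan"), False
    r = float(np.linalg.norm(post - pre)) / denom
    return r, bool(r > threshold)


def recovery_table(
    projection: PhenospaceProjection, threshold: float = 0.5
) -> pd.DataFrame:
    """Recovery score and flag for every strain in the projection."""
    rows = []
    for strain in projection.centroids.index.get_level_values("strain").unique():
        r, flag = recovery_score(projection, strain, threshold)
        rows.append({"strain": strain, "recovery_score": r, "non_recovering": flag})
    return pd.DataFrame(rows).set_index("strain")
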