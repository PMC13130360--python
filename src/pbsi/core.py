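"""Person-based similarity index (PBSI) computation.

For each morphometric measure, a subject's regional profile is rank
correlated (Spearman rho, tie-aware) against the profiles of every other
member of the *same* diagnostic group; the mean of those ``n - 1``
coefficients is the subject's raw PBSI for that measure.  Raw scores are
then z-scored against a reference population and combined into Cortical
(thickness/area/volume) and Total (all four measures) composites.

Lower PBSI means the subject's profile is less like their peers', i.e.
greater inter-individual heterogeneity.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .atlas import CORTICAL_CLASSES, MEASURE_CLASSES
from .errors import GroupTooSmallError, ProfileError

logger = logging.getLogger(__name__)

RAW_COLUMNS = tuple(f"raw_{m}" for m in MEASURE_CLASSES)
Z_COLUMNS = tuple(f"z_{m}" for m in MEASURE_CLASSES) + ("z_cortical", "z_total")

_MIN_GROUP = 3  # below this, the n-1 coefficient average is unreliable


def _as_profile(values, name: str = "profile") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ProfileError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ProfileError(f"{name} contains missing values")
    if arr.size < 3:
        raise ProfileError(f"{name} needs length >= 3, got {arr.size}")
    if np.ptp(arr) == 0:
        raise ProfileError(f"{name} is constant; rank correlation undefined")
    return arr


def spearman_rho(a, b) -> float:
    """Tie-aware Spearman rank correlation between two profiles.

    Computed as the Pearson correlation of average ("fractional") ranks, so
    heavily tied inputs are handled exactly.  Symmetric in its arguments.
    """
    a = _as_profile(a, "a")
    b = _as_profile(b, "b")
    if a.size != b.size:
        raise ProfileError(f"length mismatch: {a.size} vs {b.size}")
    ra = rankdata(a)
    rb = rankdata(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def spearman_matrix(profiles: np.ndarray) -> np.ndarray:
    """All-pairs Spearman correlation for a subjects x regions matrix."""
    profiles = np.asarray(profiles, dtype=float)
    if np.isnan(profiles).any():
        raise ProfileError("profiles contain missing values")
    if np.ptp(profiles, axis=1).min() == 0:
        bad = int(np.argmin(np.ptp(profiles, axis=1)))
        raise ProfileError(f"constant profile at row {bad}")
    ranks = rankdata(profiles, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    np.clip(rho, -1.0, 1.0, out=rho)
    return rho


def pbsi_raw(profiles: Sequence, index: int) -> float:
    """Mean Spearman rho between one group member and all ``n - 1`` others."""
    mat = np.asarray([np.asarray(p, dtype=float) for p in profiles])
    n = mat.shape[0]
    if n < _MIN_GROUP:
        raise GroupTooSmallError(f"group size {n} < {_MIN_GROUP}")
    if not 0 <= index < n:
        raise IndexError(f"subject index {index} out of range for group of {n}")
    rho = spearman_matrix(mat)
    row = np.delete(rho[index], index)
    return float(row.mean())


def pbsi_raw_group(profiles: np.ndarray) -> np.ndarray:
    """Raw PBSI for every member of a group at once (vectorised)."""
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if n < _MIN_GROUP:
        raise GroupTooSmallError(f"group size {n} < {_MIN_GROUP}")
    rho = spearman_matrix(profiles)
    return (rho.sum(axis=1) - np.diag(rho)) / (n - 1)


def compute_pbsi(tables: Mapping[str, "MorphometryTable"],
                 grouping: pd.Series | None = None) -> pd.DataFrame:
    """Raw within-group PBSI per subject for every measure class.

    Subjects missing any region in a measure class are dropped from that
    class only (logged); a group with fewer than three complete members
    raises :class:`GroupTooSmallError`.  Returns a frame indexed by
    subject_id with ``group`` and one ``raw_<measure>`` column per class.
    """
    first = next(iter(tables.values()))
    if grouping is None:
        grouping = first.meta["group"]
    grouping = grouping.astype(str)

    out = pd.DataFrame({"group": grouping})
    out.index.name = "subject_id"
    for measure, table in tables.items():
        col = f"raw_{measure}"
        out[col] = np.nan
        values = table.values
        complete = values.notna().all(axis=1)
        if not complete.all():
            dropped = values.index[~complete].tolist()
            logger.warning("%s: dropping %d subjects with missing regions: %s",
                           measure, len(dropped), dropped)
        for group in grouping.unique():
            ids = values.index[complete & (grouping.loc[values.index] == group)]
            if len(ids) < _MIN_GROUP:
                raise GroupTooSmallError(
                    f"group {group!r} has {len(ids)} complete subjects in "
                    f"{measure}; need >= {_MIN_GROUP}"
                )
            raw = pbsi_raw_group(values.loc[ids].to_numpy())
            out.loc[ids, col] = raw
    return out


def _zscore(series: pd.Series, reference: pd.Index) -> pd.Series:
    ref = series.loc[reference].dropna()
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ProfileError(f"zero/undefined SD in z-score reference for {series.name!r}")
    return (series - ref.mean()) / sd


def aggregate_pbsi(scores: pd.DataFrame, reference: Iterable | None = None,
                   policy: str = "pooled") -> pd.DataFrame:
    """z-score raw PBSI values and build the Cortical and Total composites.

    ``policy='pooled'`` (default) standardises against the full analysed
    sample; ``policy='within-group'`` standardises inside each diagnostic
    group.  Composites average the component z-scores and are re-standardised
    against the same reference.
    """
    if policy not in ("pooled", "within-group"):
        raise ValueError(f"unknown z-score policy {policy!r}")
    scores = scores.copy()

    def standardise(frame: pd.DataFrame, ref: pd.Index) -> None:
        for m in MEASURE_CLASSES:
            frame[f"z_{m}"] = _zscore(frame[f"raw_{m}"], ref)
        cortical = frame[[f"z_{m}" for m in CORTICAL_CLASSES]].mean(axis=1, skipna=False)
        cortical.name = "cortical"
        frame["z_cortical"] = _zscore(cortical, ref)
        total = frame[[f"z_{m}" for m in MEASURE_CLASSES]].mean(axis=1, skipna=False)
        total.name = "total"
        frame["z_total"] = _zscore(total, ref)

    if policy == "pooled":
        ref = pd.Index(reference) if reference is not None else scores.index
        standardise(scores, ref)
    else:
        parts = []
        for _, part in scores.groupby("group", sort=False):
            part = part.copy()
            standardise(part, part.index)
            parts.append(part)
        scores = pd.concat(parts).loc[scores.index]
    return scores
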