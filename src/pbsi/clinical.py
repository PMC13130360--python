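"""Clinical correlations with FDR control.

Within each patient group, every PBSI score is correlated (Pearson) against
seven clinical variables; Benjamini-Hochberg adjustment is applied within
the family of seven tests for each PBSI measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import Z_COLUMNS
from .errors import AnalysisError

#: The seven-variable correlation family.
CLINICAL_VARIABLES = (
    "panss_positive", "panss_negative", "panss_general", "panss_total",
    "fsiq", "mq", "gaf",
)

PBSI_SCORE_COLUMNS = list(Z_COLUMNS)


def pearson_corr(x, y) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with a two-sided t-transform p-value.

    Returns ``(r, p, n)`` where ``n`` is the pairwise-complete count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnalysisError(f"length mismatch: {x.size} vs {y.size}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 4:
        raise AnalysisError(f"need >= 4 pairwise-complete observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("constant input; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0), n


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise AnalysisError("p-values must be a flat family")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def run_clinical_analysis(scores: pd.DataFrame, clinical: pd.DataFrame,
                          group: str,
                          measures: list[str] | None = None,
                          variables: tuple[str, ...] = CLINICAL_VARIABLES,
                          family: str = "per-measure",
                          min_n: int = 4) -> pd.DataFrame:
    """Correlate PBSI scores with clinical variables inside one group.

    ``family='per-measure'`` (default) adjusts across the seven clinical
    variables within each PBSI measure; ``family='per-variable'`` adjusts
    across PBSI measures within each clinical variable.  Returns a tidy
    frame: group, pbsi_measure, clinical_variable, n, r, p_raw, p_fdr.
    """
    if family not in ("per-measure", "per-variable"):
        raise ValueError(f"unknown FDR family policy {family!r}")
    measures = measures or PBSI_SCORE_COLUMNS
    members = scores.index[scores["group"].astype(str) == group]
    if len(members) == 0:
        raise AnalysisError(f"group {group!r} absent from scores")
    joined = scores.loc[members, measures].join(
        clinical.loc[clinical.index.intersection(members), list(variables)],
        how="left",
    )

    rows = []
    for measure in measures:
        for var in variables:
            x = joined[measure].to_numpy(dtype=float)
            y = joined[var].to_numpy(dtype=float) if var in joined else np.full(len(joined), np.nan)
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < min_n or (keep.sum() and
                                      (np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0)):
                r, p, n = np.nan, np.nan, int(keep.sum())
            else:
                r, p, n = pearson_corr(x, y)
            rows.append({"group": group, "pbsi_measure": measure,
                         "clinical_variable": var, "n": n, "r": r, "p_raw": p})
    result = pd.DataFrame(rows)

    family_col = "pbsi_measure" if family == "per-measure" else "clinical_variable"
    result["p_fdr"] = np.nan
    for _, part in result.groupby(family_col, sort=False):
        valid = part.index[part["p_raw"].notna()]
        if len(valid):
            result.loc[valid, "p_fdr"] = fdr_adjust(result.loc[valid, "p_raw"].to_numpy())
    return result
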