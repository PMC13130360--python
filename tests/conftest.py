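"""Shared fixtures and independent oracle helpers.

Oracles here deliberately avoid the package's vectorised code paths: ranks
are assigned by explicit sorting, moments by explicit summation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pbsi.atlas import MEASURE_CLASSES
from pbsi.io import MorphometryTable
from pbsi.synthetic import CohortSpec, SiteEffects, simulate_cohort, spec_presets


# -- independent oracles -----------------------------------------------------

def oracle_ranks(values) -> list[float]:
    """Average (fractional) ranks by explicit sorting, tie-aware."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson_r(x, y) -> float:
    """Pearson correlation by explicit summation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def oracle_spearman(x, y) -> float:
    """Brute-force rank correlation: sort-based ranks, summation Pearson."""
    return oracle_pearson_r(oracle_ranks(x), oracle_ranks(y))


def oracle_bh(p_values) -> list[float]:
    """Benjamini-Hochberg by direct enumeration of the step-up definition:

    adjusted[i] = min over j with p[j] >= p[i] of min(1, m * p[j] / rank(j)).
    """
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for pos, i in enumerate(indexed):
        candidates = []
        for pos2 in range(pos, m):
            j = indexed[pos2]
            candidates.append(min(1.0, m * p_values[j] / (pos2 + 1)))
        adjusted[i] = min(candidates)
    return adjusted


def oracle_iqr_keep(values) -> list[bool]:
    """Tukey-fence keep flags from sorted-order quartiles."""
    srt = sorted(values)
    n = len(srt)

    def quantile(q: float) -> float:
        pos = (n - 1) * q
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return [q1 - 1.5 * iqr <= v <= q3 + 1.5 * iqr for v in values]


def oracle_chi_square(counts) -> float:
    """Pearson chi-square statistic by hand-summed (O-E)^2 / E."""
    counts = [list(row) for row in counts]
    total = sum(sum(row) for row in counts)
    row_sums = [sum(row) for row in counts]
    col_sums = [sum(row[j] for row in counts) for j in range(len(counts[0]))]
    stat = 0.0
    for i, row in enumerate(counts):
        for j, obs in enumerate(row):
            expected = row_sums[i] * col_sums[j] / total
            stat += (obs - expected) ** 2 / expected
    return stat


# -- fixtures ----------------------------------------------------------------

def tiny_spec(seed: int = 0, n_cortical: int = 12, n_subcortical: int = 6,
              group_sizes=None, heterogeneity=None, sites: int = 1,
              **overrides) -> CohortSpec:
    """A small, fast cohort spec for unit tests."""
    rng = np.random.default_rng(99)
    group_sizes = group_sizes or {"HC": 8, "recent": 7, "chronic": 6}
    heterogeneity = heterogeneity or {g: 1.0 for g in group_sizes}
    means = {
        "thickness": rng.uniform(2.0, 3.2, n_cortical),
        "area": rng.uniform(250.0, 1200.0, n_cortical),
        "volume": rng.uniform(800.0, 4000.0, n_cortical),
        "subcortical": rng.uniform(500.0, 8000.0, n_subcortical),
    }
    scales = {m: 0.1 * mu for m, mu in means.items()}
    n_regions = {m: mu.size for m, mu in means.items()}
    site_effects = {}
    for k in range(sites):
        if k == 0:
            site_effects["site0"] = SiteEffects.identity(n_regions)
        else:
            site_effects[f"site{k}"] = SiteEffects(
                shift={m: rng.normal(0, 0.05, mu.size) * mu for m, mu in means.items()},
                scale={m: np.exp(rng.normal(0, 0.05, mu.size)) for m, mu in means.items()},
            )
    spec = CohortSpec(
        group_sizes=group_sizes, region_means=means, region_scales=scales,
        heterogeneity=heterogeneity, site_effects=site_effects,
        n_cortical=n_cortical, n_subcortical=n_subcortical, seed=seed,
        **overrides,
    )
    return spec.validate()


@pytest.fixture
def small_cohort():
    return simulate_cohort(tiny_spec(seed=3))


@pytest.fixture
def paper_like_cohort():
    return simulate_cohort(spec_presets("paper-like", seed=11))


def make_morphometry(values: np.ndarray, groups, sites=None,
                     measure_class: str = "subcortical") -> MorphometryTable:
    """Wrap a raw matrix as a validated-shape morphometry table."""
    n, r = values.shape
    ids = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    prefix = "SUB" if measure_class == "subcortical" else "CTX"
    cols = [f"{prefix}_{i:02d}" for i in range(1, r + 1)]
    rng = np.random.default_rng(5)
    meta = pd.DataFrame({
        "group": list(groups),
        "site": list(sites) if sites is not None else ["site0"] * n,
        "age": rng.uniform(20, 50, n),
        "sex": rng.integers(0, 2, n),
    }, index=ids)
    return MorphometryTable(measure_class, pd.DataFrame(values, index=ids, columns=cols), meta)
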