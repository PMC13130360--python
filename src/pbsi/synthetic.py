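"""Synthetic multi-site, multi-group cohort generator.

The generative model for subject ``s`` in group ``g`` at site ``b``,
region ``r``, measure class ``m`` is::

    value = (mu[m, r] + sigma_g * tau[m, r] * d[s, r]) * scale[b, m, r]
            + shift[b, m, r] + eps

with ``d`` standard-normal subject deviations (optionally sharing a
low-rank factor across regions), ``eps`` proportional measurement noise,
and values clipped at 1% of the region mean so physically positive
measures stay positive without disturbing rank statistics.

Group-specific dispersion multipliers ``sigma_g`` control inter-individual
heterogeneity: larger multipliers push every pairwise profile correlation
down, so the group's expected similarity index falls.  Symptom severity can
optionally be coupled to the magnitude (RMS) of a subject's deviation
vector, giving the generator a planted structure-symptom association.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import CORTICAL_CLASSES, MEASURE_CLASSES, RegionAtlas, default_atlas
from .errors import SpecValidationError

CONTROL_GROUP = "HC"

# PANSS subscale floors (items scored >= 1).
_PANSS_FLOORS = {"panss_positive": 7.0, "panss_negative": 7.0, "panss_general": 16.0}
# How the severity coupling is split across PANSS subscales (sums to 1).
_COUPLING_WEIGHTS = {"panss_positive": 0.35, "panss_negative": 0.15, "panss_general": 0.50}


@dataclass(frozen=True)
class SiteEffects:
    """Additive shift and multiplicative scale vectors per measure class."""

    shift: Mapping[str, np.ndarray]
    scale: Mapping[str, np.ndarray]

    @staticmethod
    def identity(n_regions: Mapping[str, int]) -> "SiteEffects":
        return SiteEffects(
            shift={m: np.zeros(n) for m, n in n_regions.items()},
            scale={m: np.ones(n) for m, n in n_regions.items()},
        )


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a synthetic multi-site cohort."""

    group_sizes: Mapping[str, int]
    region_means: Mapping[str, np.ndarray]
    region_scales: Mapping[str, np.ndarray]
    heterogeneity: Mapping[str, float]
    site_effects: Mapping[str, SiteEffects]
    n_cortical: int = 100
    n_subcortical: int = 14
    site_assignment: Mapping[str, Mapping[str, int]] | None = None
    noise_sd: float = 0.0
    clinical_coupling: float = 0.0
    coupling_measure: str = "all"
    spatial_factor_weight: float = 0.0
    age_range: tuple[float, float] = (20.0, 55.0)
    female_proportion: float = 0.55
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    control_group: str = CONTROL_GROUP
    seed: int = 0

    def n_regions(self, measure_class: str) -> int:
        return self.n_cortical if measure_class in CORTICAL_CLASSES else self.n_subcortical

    def validate(self) -> "CohortSpec":
        for group, size in self.group_sizes.items():
            if size <= 0:
                raise SpecValidationError(f"group_sizes[{group!r}] must be > 0")
        if set(self.heterogeneity) != set(self.group_sizes):
            raise SpecValidationError(
                "heterogeneity keys must equal group_sizes keys"
            )
        for group, sigma in self.heterogeneity.items():
            if sigma < 0:
                raise SpecValidationError(f"heterogeneity[{group!r}] must be >= 0")
        if self.n_cortical <= 0 or self.n_subcortical <= 0:
            raise SpecValidationError("n_cortical and n_subcortical must be > 0")
        for m in MEASURE_CLASSES:
            n = self.n_regions(m)
            if m not in self.region_means or m not in self.region_scales:
                raise SpecValidationError(f"region_means/region_scales missing {m!r}")
            mu = np.asarray(self.region_means[m], dtype=float)
            tau = np.asarray(self.region_scales[m], dtype=float)
            if mu.shape != (n,) or (mu <= 0).any():
                raise SpecValidationError(f"region_means[{m!r}] must be {n} positive reals")
            if tau.shape != (n,) or (tau < 0).any():
                raise SpecValidationError(f"region_scales[{m!r}] must be {n} SDs >= 0")
        for site, eff in self.site_effects.items():
            for m in MEASURE_CLASSES:
                n = self.n_regions(m)
                if np.asarray(eff.scale[m]).shape != (n,) or (np.asarray(eff.scale[m]) <= 0).any():
                    raise SpecValidationError(
                        f"site_effects[{site!r}].scale[{m!r}] must be {n} positives"
                    )
                if np.asarray(eff.shift[m]).shape != (n,):
                    raise SpecValidationError(
                        f"site_effects[{site!r}].shift[{m!r}] must have length {n}"
                    )
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be >= 0")
        if self.coupling_measure not in MEASURE_CLASSES + ("all",):
            raise SpecValidationError(f"coupling_measure {self.coupling_measure!r} unknown")
        if not 0.0 <= self.spatial_factor_weight <= 1.0:
            raise SpecValidationError("spatial_factor_weight must be in [0, 1]")
        if not 0.0 <= self.female_proportion <= 1.0:
            raise SpecValidationError("female_proportion must be in [0, 1]")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise SpecValidationError("age_range must be 0 < lo < hi")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise SpecValidationError(f"missing_rates[{var!r}] must be in [0, 1]")
        if self.site_assignment is not None:
            for group, counts in self.site_assignment.items():
                if group not in self.group_sizes:
                    raise SpecValidationError(f"site_assignment group {group!r} unknown")
                if sum(counts.values()) != self.group_sizes[group]:
                    raise SpecValidationError(
                        f"site_assignment[{group!r}] counts must sum to group size"
                    )
                unknown = set(counts) - set(self.site_effects)
                if unknown:
                    raise SpecValidationError(
                        f"site_assignment[{group!r}] references unknown sites {sorted(unknown)}"
                    )
        return self

    def atlas(self) -> RegionAtlas:
        base = default_atlas()
        if (self.n_cortical, self.n_subcortical) == (base.n_cortical, base.n_subcortical):
            return base
        cortical = tuple(f"CTX_{i:03d}" for i in range(1, self.n_cortical + 1))
        subcortical = tuple(f"SUB_{i:02d}" for i in range(1, self.n_subcortical + 1))
        return RegionAtlas(cortical, subcortical)


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`."""

    tables: dict
    meta: pd.DataFrame
    clinical: pd.DataFrame
    deviation_rms: pd.DataFrame  # per measure class plus "all"
    spec: CohortSpec


def _assign_sites(spec: CohortSpec, groups: pd.Series, rng: np.random.Generator) -> np.ndarray:
    sites = sorted(spec.site_effects)
    if spec.site_assignment is None:
        return rng.choice(sites, size=len(groups))
    out = np.empty(len(groups), dtype=object)
    for group in spec.group_sizes:
        idx = np.flatnonzero(groups.to_numpy() == group)
        labels: list[str] = []
        for site in sites:
            labels.extend([site] * spec.site_assignment[group].get(site, 0))
        out[idx] = labels
    return out


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate morphometry, metadata and clinical tables for one cohort.

    Deterministic given ``spec.seed``: two calls with equal specs produce
    identical tables.
    """
    from .io import MorphometryTable  # local import to avoid cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    atlas = spec.atlas()

    group_col = np.concatenate([
        np.repeat(group, size) for group, size in spec.group_sizes.items()
    ])
    n = len(group_col)
    subject_ids = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="subject_id")
    groups = pd.Series(group_col, index=subject_ids, name="group")

    sites = _assign_sites(spec, groups, rng)
    ages = rng.uniform(*spec.age_range, size=n)
    sex = (rng.random(n) < spec.female_proportion).astype(int)
    meta = pd.DataFrame(
        {"group": groups, "site": sites, "age": ages, "sex": sex}, index=subject_ids
    )

    sigma = groups.map(spec.heterogeneity).to_numpy(dtype=float)

    tables: dict[str, MorphometryTable] = {}
    rms: dict[str, np.ndarray] = {}
    sumsq_all = np.zeros(n)
    n_all = 0
    for m in MEASURE_CLASSES:
        n_regions = spec.n_regions(m)
        mu = np.asarray(spec.region_means[m], dtype=float)
        tau = np.asarray(spec.region_scales[m], dtype=float)

        d = rng.standard_normal((n, n_regions))
        w = spec.spatial_factor_weight
        if w > 0:
            shared = rng.standard_normal((n, 1))
            d = np.sqrt(1.0 - w * w) * d + w * shared

        values = mu + sigma[:, None] * tau * d
        for subj in range(n):
            eff = spec.site_effects[sites[subj]]
            values[subj] = values[subj] * np.asarray(eff.scale[m]) + np.asarray(eff.shift[m])
        if spec.noise_sd > 0:
            values = values + rng.standard_normal((n, n_regions)) * (spec.noise_sd * mu)
        values = np.maximum(values, 0.01 * mu)

        frame = pd.DataFrame(values, index=subject_ids,
                             columns=list(atlas.regions_for(m)))
        tables[m] = MorphometryTable(m, frame, meta).validate(atlas)

        rms[m] = np.sqrt((d ** 2).mean(axis=1))
        sumsq_all += (d ** 2).sum(axis=1)
        n_all += n_regions
    rms["all"] = np.sqrt(sumsq_all / n_all)
    deviation_rms = pd.DataFrame(rms, index=subject_ids)

    clinical = _simulate_clinical(spec, meta, deviation_rms, rng)
    return SimulatedCohort(tables, meta, clinical, deviation_rms, spec)


def _simulate_clinical(spec: CohortSpec, meta: pd.DataFrame,
                       deviation_rms: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = len(meta)
    patient = (meta["group"] != spec.control_group).to_numpy()
    clinical = pd.DataFrame(index=meta.index, dtype=float)

    coupling = spec.clinical_coupling * deviation_rms[spec.coupling_measure].to_numpy()
    subscale_base = {
        "panss_positive": rng.normal(15.0, 4.0, n),
        "panss_negative": rng.normal(16.0, 4.0, n),
        "panss_general": rng.normal(30.0, 6.0, n),
    }
    for name, base in subscale_base.items():
        scores = base + _COUPLING_WEIGHTS[name] * coupling
        scores = np.maximum(scores, _PANSS_FLOORS[name])
        clinical[name] = np.where(patient, scores, np.nan)
    clinical["panss_total"] = (
        clinical["panss_positive"] + clinical["panss_negative"] + clinical["panss_general"]
    )

    clinical["gaf"] = np.where(patient, np.clip(rng.normal(55.0, 13.0, n), 1, 100), np.nan)

    fsiq = np.where(patient, rng.normal(98.0, 15.0, n), rng.normal(118.0, 10.0, n))
    mq = np.where(patient, rng.normal(92.0, 15.0, n), rng.normal(110.0, 12.0, n))
    clinical["fsiq"] = fsiq
    clinical["mq"] = mq

    duration = rng.uniform(0.5, 16.0, n)
    group = meta["group"].to_numpy()
    duration = np.where(group == "recent", rng.uniform(0.5, 5.0, n), duration)
    duration = np.where(group == "chronic", rng.uniform(5.5, 16.0, n), duration)
    clinical["illness_duration"] = np.where(patient, duration, np.nan)
    clinical["antipsychotic_dose"] = np.where(
        patient, np.abs(rng.normal(18.0, 12.0, n)), np.nan
    )

    for var, rate in spec.missing_rates.items():
        if rate > 0 and var in clinical.columns:
            mask = rng.random(n) < rate
            clinical.loc[mask, var] = np.nan
    return clinical


# -- presets -----------------------------------------------------------------

#: Seed of the fixed generator used for region-level population parameters;
#: independent of the cohort seed so every preset shares the same "atlas".
_PARAM_SEED = 20240501

_PRESET_GROUP_SIZES = {"HC": 59, "recent": 41, "chronic": 32}
_PRESET_SITES = {
    "HC": {"AMC1": 20, "AMC2": 39, "AMC3": 0},
    "recent": {"AMC1": 34, "AMC2": 7, "AMC3": 0},
    "chronic": {"AMC1": 0, "AMC2": 11, "AMC3": 21},
}


def default_region_params(n_cortical: int = 100, n_subcortical: int = 14):
    """Fixed, reproducible region means and between-subject SDs."""
    rng = np.random.default_rng(_PARAM_SEED)
    means: dict[str, np.ndarray] = {}
    scales: dict[str, np.ndarray] = {}

    means["thickness"] = rng.uniform(2.0, 3.2, n_cortical)
    scales["thickness"] = np.full(n_cortical, 0.12)

    means["area"] = rng.uniform(250.0, 1200.0, n_cortical)
    scales["area"] = 0.12 * means["area"]

    means["volume"] = rng.uniform(800.0, 4000.0, n_cortical)
    scales["volume"] = 0.12 * means["volume"]

    base = np.array([7500.0, 3700.0, 5200.0, 1800.0, 4200.0, 1700.0, 600.0])
    asym = rng.uniform(0.95, 1.05, base.size)
    sub = np.column_stack([base, base * asym]).ravel()
    sub = np.resize(sub, n_subcortical)
    means["subcortical"] = sub
    scales["subcortical"] = 0.10 * sub
    return means, scales


def _site_effect_draw(rng: np.random.Generator, means: Mapping[str, np.ndarray],
                      shift_frac: float, scale_sd: float) -> SiteEffects:
    shift = {m: rng.normal(0.0, shift_frac, mu.size) * mu for m, mu in means.items()}
    scale = {m: np.exp(rng.normal(0.0, scale_sd, mu.size)) for m, mu in means.items()}
    return SiteEffects(shift=shift, scale=scale)


def spec_presets(name: str, seed: int = 0) -> CohortSpec:
    """Named cohort configurations.

    ``paper-like``
        Group sizes 59/41/32 over three sites with modest batch effects and
        patient groups more heterogeneous than controls.
    ``null``
        Same group sizes, no site effects, all dispersion multipliers 1, no
        clinical coupling — every downstream test statistic is null.
    ``high-heterogeneity``
        Dispersion ordering HC < recent < chronic with a wide spread.
    """
    means, scales = default_region_params()
    n_regions = {m: means[m].size for m in MEASURE_CLASSES}

    if name == "paper-like":
        rng = np.random.default_rng(_PARAM_SEED + 1)
        site_effects = {
            "AMC1": _site_effect_draw(rng, means, 0.03, 0.03),
            "AMC2": _site_effect_draw(rng, means, 0.03, 0.03),
            "AMC3": _site_effect_draw(rng, means, 0.03, 0.03),
        }
        return CohortSpec(
            group_sizes=dict(_PRESET_GROUP_SIZES),
            region_means=means, region_scales=scales,
            heterogeneity={"HC": 1.0, "recent": 1.6, "chronic": 2.0},
            site_effects=site_effects,
            site_assignment={g: dict(c) for g, c in _PRESET_SITES.items()},
            noise_sd=0.01,
            seed=seed,
        ).validate()
    if name == "null":
        site_effects = {"AMC1": SiteEffects.identity(n_regions)}
        return CohortSpec(
            group_sizes=dict(_PRESET_GROUP_SIZES),
            region_means=means, region_scales=scales,
            heterogeneity={"HC": 1.0, "recent": 1.0, "chronic": 1.0},
            site_effects=site_effects,
            noise_sd=0.0,
            seed=seed,
        ).validate()
    if name == "high-heterogeneity":
        site_effects = {"AMC1": SiteEffects.identity(n_regions)}
        return CohortSpec(
            group_sizes=dict(_PRESET_GROUP_SIZES),
            region_means=means, region_scales=scales,
            heterogeneity={"HC": 1.0, "recent": 2.0, "chronic": 3.0},
            site_effects=site_effects,
            noise_sd=0.0,
            seed=seed,
        ).validate()
    raise SpecValidationError(f"unknown preset {name!r}")


def with_overrides(spec: CohortSpec, **kwargs) -> CohortSpec:
    """Return a copy of ``spec`` with the given fields replaced."""
    return dataclasses.replace(spec, **kwargs).validate()
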