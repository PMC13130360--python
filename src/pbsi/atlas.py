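"""Region atlas: the canonical ordering contract for morphometric profiles.

Every profile-valued operation in this package assumes region columns appear
in the order defined by a :class:`RegionAtlas`.  The default atlas mimics a
100-parcel cortical parcellation (hemisphere-prefixed network/parcel names)
plus 14 bilateral subcortical structures.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import TableValidationError

#: Measure classes carried through the whole pipeline, in canonical order.
MEASURE_CLASSES: tuple[str, ...] = ("thickness", "area", "volume", "subcortical")

#: The three cortical measure classes (profiles of length 100 by default).
CORTICAL_CLASSES: tuple[str, ...] = ("thickness", "area", "volume")

# Parcel counts per network and hemisphere for the default 100-parcel atlas.
_NETWORKS_LH = (
    ("Vis", 9), ("SomMot", 6), ("DorsAttn", 8), ("SalVentAttn", 7),
    ("Limbic", 5), ("Cont", 4), ("Default", 11),
)
_NETWORKS_RH = (
    ("Vis", 8), ("SomMot", 8), ("DorsAttn", 7), ("SalVentAttn", 6),
    ("Limbic", 5), ("Cont", 9), ("Default", 7),
)

_SUBCORTICAL_STRUCTURES = (
    "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region identifiers per measure class.

    Parameters
    ----------
    cortical_regions
        Ordered, unique identifiers for the cortical parcels; shared by the
        thickness, area and volume measure classes.
    subcortical_regions
        Ordered, unique identifiers for the subcortical volumes.
    """

    cortical_regions: tuple[str, ...]
    subcortical_regions: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, regions in (("cortical_regions", self.cortical_regions),
                              ("subcortical_regions", self.subcortical_regions)):
            if len(set(regions)) != len(regions):
                raise TableValidationError(f"{name}: duplicate region identifiers")
            if len(regions) == 0:
                raise TableValidationError(f"{name}: empty region list")

    def regions_for(self, measure_class: str) -> tuple[str, ...]:
        """Canonical region order for one measure class."""
        if measure_class in CORTICAL_CLASSES:
            return self.cortical_regions
        if measure_class == "subcortical":
            return self.subcortical_regions
        raise TableValidationError(f"unknown measure class {measure_class!r}")

    @property
    def n_cortical(self) -> int:
        return len(self.cortical_regions)

    @property
    def n_subcortical(self) -> int:
        return len(self.subcortical_regions)


def default_atlas() -> RegionAtlas:
    """The default atlas: 100 cortical parcels and 14 subcortical volumes."""
    cortical: list[str] = []
    for hemi, networks in (("LH", _NETWORKS_LH), ("RH", _NETWORKS_RH)):
        for network, count in networks:
            cortical.extend(
                f"7Networks_{hemi}_{network}_{i}" for i in range(1, count + 1)
            )
    subcortical = [
        f"{side}-{structure}"
        for structure in _SUBCORTICAL_STRUCTURES
        for side in ("Left", "Right")
    ]
    return RegionAtlas(tuple(cortical), tuple(subcortical))
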