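"""Land-cover nomenclature, SELU groups and default per-class parameters.

The default palette is the 16-class nomenclature used for dry-tropical
protected areas in north-western Madagascar (village, rice, sugar cane,
crops, savannah, two dry-forest densities, three mangrove densities,
shrubland, barren land, tan, phragmites, raffia, inland water). Class ids
follow the convention that a sub-class id appends a digit to its parent
land-cover-ecosystem-unit id (e.g. 61 and 62 are densities of forest tree
cover, class 6).

Per-class defaults (greenness weight, carbon densities, NPP) are package
defaults chosen once to be realistic for this landscape; every consumer
accepts an override table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

from .errors import ConfigurationError

# SELU group names double as SELU type labels.
HUMAN = "Human footprint"
AGRI = "Agricultural landscape"
SHRUB = "Shrubland"
FOREST = "Forest landscape"
MANGROVE = "Mangrove Landscape"
WETLAND = "Wetland"
ESTUARY = "Estuary"

SELU_TYPES = (HUMAN, AGRI, SHRUB, FOREST, MANGROVE, WETLAND, ESTUARY)

#: deterministic tie-break for dominant land cover, conservative toward
#: natural classes.
TIE_BREAK_PRIORITY = (FOREST, MANGROVE, WETLAND, SHRUB, AGRI, ESTUARY, HUMAN)


@dataclass(frozen=True)
class LandCoverClass:
    """A land-cover class with its accounting parameters.

    greenness : 0-100 biomass-potential weight used by the GBLI.
    tree : counts toward tree cover in the fragmentation tree ratio.
    habitat : counts as natural habitat for patch/mesh statistics.
    water : open water (lake/reservoir stock in the water account).
    agb : aboveground living biomass carbon density, tC/ha.
    litter_frac : litter+deadwood carbon as a fraction of agb.
    root_shoot : root:shoot ratio (belowground = agb * root_shoot).
    soc : soil organic carbon density, tC/ha.
    npp : net primary production, tC/ha/yr.
    """

    id: int
    name: str
    group: str
    greenness: float
    tree: bool = False
    habitat: bool = False
    water: bool = False
    agb: float = 0.0
    litter_frac: float = 0.1
    root_shoot: float = 0.4
    soc: float = 30.0
    npp: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.greenness <= 100.0:
            raise ConfigurationError(
                f"class {self.id}: greenness weight {self.greenness} outside [0, 100]"
            )
        for attr in ("agb", "litter_frac", "root_shoot", "soc", "npp"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"class {self.id}: {attr} must be >= 0")


DEFAULT_PALETTE: tuple[LandCoverClass, ...] = (
    LandCoverClass(11, "Village", HUMAN, 10, False, False, False, 5, 0.10, 0.30, 20, 2.0),
    LandCoverClass(21, "Rice field", AGRI, 45, False, False, False, 3, 0.10, 0.40, 35, 6.0),
    LandCoverClass(31, "Sugar-cane field", AGRI, 50, False, False, False, 15, 0.10, 0.25, 40, 12.0),
    LandCoverClass(41, "Crops field", AGRI, 55, False, False, False, 8, 0.12, 0.35, 35, 7.0),
    LandCoverClass(51, "Savannah", SHRUB, 65, False, True, False, 10, 0.12, 0.60, 30, 5.0),
    LandCoverClass(61, "Dense dry forest", FOREST, 90, True, True, False, 105, 0.12, 0.45, 45, 9.0),
    LandCoverClass(62, "Sparse dry forest", FOREST, 80, True, True, False, 55, 0.12, 0.50, 40, 7.0),
    LandCoverClass(63, "Dense mangrove", MANGROVE, 95, True, True, False, 130, 0.12, 0.50, 60, 11.0),
    LandCoverClass(64, "Scattered mangrove", MANGROVE, 85, True, True, False, 70, 0.12, 0.55, 50, 8.0),
    LandCoverClass(65, "Stunted mangrove", MANGROVE, 75, True, True, False, 35, 0.10, 0.60, 45, 6.0),
    LandCoverClass(71, "Shrubland", SHRUB, 70, False, True, False, 20, 0.12, 0.55, 30, 5.0),
    LandCoverClass(101, "Barren land", ESTUARY, 5, False, False, False, 0.5, 0.05, 0.20, 10, 0.5),
    LandCoverClass(102, "Tan", ESTUARY, 10, False, False, False, 1, 0.05, 0.20, 15, 1.0),
    LandCoverClass(121, "Phragmites", WETLAND, 60, False, True, False, 12, 0.15, 0.80, 60, 8.0),
    LandCoverClass(122, "Raffia", WETLAND, 75, True, True, False, 40, 0.12, 0.50, 55, 9.0),
    LandCoverClass(131, "Water bodies", WETLAND, 0, False, False, True, 0.5, 0.0, 0.10, 5, 1.0),
)


class Palette:
    """An ordered land-cover nomenclature with fast lookup by class id."""

    def __init__(self, classes=DEFAULT_PALETTE):
        classes = tuple(classes)
        if not classes:
            raise ConfigurationError("palette must contain at least one class")
        ids = [c.id for c in classes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate class ids in palette")
        self.classes = classes
        self._by_id = {c.id: c for c in classes}

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.classes]

    @property
    def names(self) -> dict[int, str]:
        return {c.id: c.name for c in self.classes}

    def __len__(self):
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __contains__(self, class_id: int) -> bool:
        return class_id in self._by_id

    def __getitem__(self, class_id: int) -> LandCoverClass:
        return self._by_id[class_id]

    def grouping(self) -> dict[int, str]:
        """Class id -> SELU group table."""
        return {c.id: c.group for c in self.classes}

    def greenness(self) -> dict[int, float]:
        return {c.id: c.greenness for c in self.classes}

    def to_records(self) -> list[dict]:
        return [asdict(c) for c in self.classes]

    @classmethod
    def from_records(cls, records) -> "Palette":
        return cls(tuple(LandCoverClass(**r) for r in records))

    def with_overrides(self, **per_class) -> "Palette":
        """Return a palette with field overrides, keyed by class id."""
        out = []
        for c in self.classes:
            if c.id in per_class:
                out.append(replace(c, **per_class[c.id]))
            else:
                out.append(c)
        return Palette(tuple(out))


def default_palette() -> Palette:
    return Palette(DEFAULT_PALETTE)
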