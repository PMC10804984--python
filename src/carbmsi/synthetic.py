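"""Seeded generator of paired EDC± co-culture MSI datasets with ground truth.

The generator emulates the published co-culture geometry: two isolated
colony controls (a fungal disk, region ``f``, and a bacterial disk, region
``b``) plus an interaction zone (``i``) on one 60×40 grid at 100 µm per
pixel.  Each panel metabolite carries a spatial archetype — a per-region
abundance multiplier pattern named after the characteristic ion-image
phenotypes (induced in interaction, suppressed, unchanged, ...) — and emits
its M+0/A+2 tagged-ion doublet with envelope-proportional intensities,
ppm-scale m/z jitter, multiplicative lognormal intensity noise, and a
uniform chemical background.

Derivatization chemistry is respected: carboxyl-only members are absent
without EDC; oxocarboxylic acids appear at half intensity without EDC and
plain ketones at twice, mirroring the reported standard spectra.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import APEBA, DerivatizationTag, IsotopeTable, a2_ratio, derivatized_mz
from .metabolites import EdcClass, MetaboliteDB, MetaboliteRecord, demo_db, is_derivatizable
from .msi import MSIDataset, RegionMask

__all__ = [
    "ColonyLayout",
    "SpatialArchetype",
    "PanelMember",
    "GroundTruthPanel",
    "NoiseModel",
    "build_masks",
    "simulate_dataset",
    "simulate_paired",
    "default_scenario",
]


@dataclass(frozen=True)
class ColonyLayout:
    """Grid geometry of the two isolated colonies and the interaction band."""

    width: int = 60
    height: int = 40
    pixel_size_um: float = 100.0
    fungal_center: tuple[int, int] = (14, 20)
    fungal_radius: float = 8.0
    bacterial_center: tuple[int, int] = (46, 20)
    bacterial_radius: float = 8.0
    interaction_x: tuple[int, int] = (25, 35)  # half-open [x0, x1)
    interaction_y: tuple[int, int] = (10, 30)


class SpatialArchetype(enum.Enum):
    """Per-region abundance multipliers for the characteristic ion-image phenotypes."""

    INDUCED_IN_INTERACTION_FUNGUS = ("induced_in_interaction_fungus",
                                     {"f": 0.3, "b": 0.0, "i": 1.0})
    SUPPRESSED_FROM_BACTERIA = ("suppressed_from_bacteria",
                                {"f": 0.0, "b": 1.0, "i": 0.3})
    UNCHANGED = ("unchanged", {"f": 1.0, "b": 1.0, "i": 1.0})
    INDUCED_FROM_BACTERIA = ("induced_from_bacteria",
                             {"f": 0.0, "b": 0.3, "i": 1.0})
    HOTSPOTS_IN_BIOFILM = ("hotspots_in_biofilm",
                           {"f": 0.0, "b": 0.25, "i": 1.0})
    SUPPRESSED_BOTH = ("suppressed_both", {"f": 1.0, "b": 1.0, "i": 0.25})
    INDUCED_BOTH = ("induced_both", {"f": 0.3, "b": 0.3, "i": 1.0})

    def __init__(self, label: str, multipliers: dict[str, float]):
        if any(v < 0 for v in multipliers.values()):
            raise ValueError("archetype multipliers must be non-negative")
        self.label = label
        self.multipliers = multipliers


@dataclass(frozen=True)
class PanelMember:
    record: MetaboliteRecord
    archetype: SpatialArchetype
    base_intensity: float = 1000.0

    def __post_init__(self):
        if self.base_intensity <= 0:
            raise ValueError("base intensity must be positive")


@dataclass(frozen=True)
class GroundTruthPanel:
    """Panel members plus the EDC-dependent derivatization kinetics multipliers.

    Without EDC, oxocarboxylic acids (carboxyl + ketone/aldehyde) react at
    ~50% efficiency while plain ketones react twice as strongly, per the
    standards experiments.
    """

    members: tuple[PanelMember, ...]
    oxoacid_without_edc: float = 0.5
    ketone_without_edc: float = 2.0

    def __post_init__(self):
        if min(self.oxoacid_without_edc, self.ketone_without_edc) <= 0:
            raise ValueError("kinetics multipliers must be positive")

    def kinetics(self, m: MetaboliteRecord, edc_used: bool) -> float:
        if edc_used:
            return 1.0
        if m.has_ketone_or_aldehyde and m.n_carboxyl > 0:
            return self.oxoacid_without_edc
        return self.ketone_without_edc

    def true_edc_class(self, m: MetaboliteRecord) -> EdcClass:
        if m.has_ketone_or_aldehyde:
            return EdcClass.CONTAINS_KETONE_OR_ALDEHYDE
        if m.n_carboxyl > 0:
            return EdcClass.CARBOXYL_ONLY
        return EdcClass.NOT_DERIVATIZABLE_OR_ABSENT


@dataclass(frozen=True)
class NoiseModel:
    mz_jitter_ppm: float = 0.5          # Gaussian sigma of relative m/z error
    intensity_sigma: float = 0.3        # lognormal sigma (mean-1 parametrized)
    background_rate: float = 10.0       # Poisson peaks per pixel
    background_mz_range: tuple[float, float] = (350.0, 700.0)
    background_intensity_median: float = 50.0
    background_intensity_sigma: float = 1.0

    def __post_init__(self):
        if min(self.mz_jitter_ppm, self.intensity_sigma,
               self.background_rate) < 0:
            raise ValueError("noise parameters must be non-negative")


def build_masks(layout: ColonyLayout) -> RegionMask:
    """Disjoint f/b/i masks for a layout; deterministic, errors on empty regions."""
    if layout.fungal_radius <= 0 or layout.bacterial_radius <= 0:
        raise ValueError("degenerate layout: colony radius must be positive")
    f, b, i = set(), set(), set()
    fx, fy = layout.fungal_center
    bx, by = layout.bacterial_center
    for y in range(layout.height):
        for x in range(layout.width):
            if (x - fx) ** 2 + (y - fy) ** 2 <= layout.fungal_radius ** 2:
                f.add((x, y))
            elif (x - bx) ** 2 + (y - by) ** 2 <= layout.bacterial_radius ** 2:
                b.add((x, y))
            elif (layout.interaction_x[0] <= x < layout.interaction_x[1]
                  and layout.interaction_y[0] <= y < layout.interaction_y[1]):
                i.add((x, y))
    if not (f and b and i):
        raise ValueError("degenerate layout: an f/b/i region is empty")
    mask = RegionMask({"f": f, "b": b, "i": i})
    mask.validate_grid(layout.width, layout.height)
    return mask


def _lognormal_factor(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative noise with unit mean: exp(sigma*Z - sigma^2/2)."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(sigma * rng.standard_normal(size) - sigma ** 2 / 2)


def simulate_dataset(layout: ColonyLayout,
                     panel: GroundTruthPanel,
                     noise: NoiseModel,
                     edc_used: bool,
                     tag: DerivatizationTag = APEBA,
                     seed: int = 0,
                     table: IsotopeTable | None = None
                     ) -> tuple[MSIDataset, dict[str, np.ndarray]]:
    """One condition's dataset plus per-member ground-truth abundance maps.

    The truth map holds the noise-free expected M+0 intensity per pixel.
    The RNG stream is keyed by (seed, condition) so the EDC± pair of the
    same seed shares everything but its condition-specific draws.
    """
    if not panel.members:
        pass  # an empty panel is allowed: background-only dataset
    table = table or IsotopeTable.default()
    rng = np.random.default_rng([int(seed), 1 if edc_used else 0])
    masks = build_masks(layout)
    xs, ys, mzs, intens = [], [], [], []
    truth: dict[str, np.ndarray] = {}

    for member in panel.members:
        record = member.record
        truth_map = np.zeros((layout.height, layout.width))
        truth[record.id] = truth_map
        if not is_derivatizable(record, tag, edc_used):
            continue
        mz79 = derivatized_mz(record.neutral_formula, tag, 79, table)
        mz81 = derivatized_mz(record.neutral_formula, tag, 81, table)
        ratio = a2_ratio(record.neutral_formula + tag.cation_formula, table)
        kin = panel.kinetics(record, edc_used)
        for label in ("f", "b", "i"):
            mult = member.archetype.multipliers.get(label, 0.0)
            if mult == 0.0:
                continue
            pixels = sorted(masks[label])
            n = len(pixels)
            expected = member.base_intensity * mult * kin
            i79 = expected * _lognormal_factor(rng, noise.intensity_sigma, n)
            i81 = (expected * ratio
                   * _lognormal_factor(rng, noise.intensity_sigma, n))
            j79 = 1 + 1e-6 * noise.mz_jitter_ppm * rng.standard_normal(n)
            j81 = 1 + 1e-6 * noise.mz_jitter_ppm * rng.standard_normal(n)
            for k, (x, y) in enumerate(pixels):
                truth_map[y, x] += expected
                xs.extend((x, x))
                ys.extend((y, y))
                mzs.extend((mz79 * j79[k], mz81 * j81[k]))
                intens.extend((i79[k], i81[k]))

    # chemical background: Poisson count per pixel, uniform m/z
    lo, hi = noise.background_mz_range
    for y in range(layout.height):
        for x in range(layout.width):
            k = rng.poisson(noise.background_rate)
            if k == 0:
                continue
            bmz = rng.uniform(lo, hi, k)
            bint = (noise.background_intensity_median
                    * np.exp(noise.background_intensity_sigma
                             * rng.standard_normal(k)))
            xs.extend([x] * k)
            ys.extend([y] * k)
            mzs.extend(bmz)
            intens.extend(bint)

    peaks = pd.DataFrame({"x": xs, "y": ys, "mz": mzs, "intensity": intens})
    dataset = MSIDataset(layout.width, layout.height, peaks,
                         pixel_size_um=layout.pixel_size_um,
                         condition="EDC_PLUS" if edc_used else "EDC_MINUS",
                         metadata={"seed": int(seed), "synthetic": True})
    return dataset, truth


def simulate_paired(layout: ColonyLayout,
                    panel: GroundTruthPanel,
                    noise: NoiseModel,
                    tag: DerivatizationTag = APEBA,
                    seed: int = 0,
                    table: IsotopeTable | None = None):
    """Matched EDC+ and EDC− datasets sharing layout, panel and base seed.

    Returns ``(edc_plus, edc_minus, truth)`` where ``truth`` carries the
    per-condition expected abundance maps and each member's true EDC class.
    """
    plus, truth_plus = simulate_dataset(layout, panel, noise, True, tag, seed,
                                        table)
    minus, truth_minus = simulate_dataset(layout, panel, noise, False, tag,
                                          seed, table)
    truth = {
        "EDC_PLUS": truth_plus,
        "EDC_MINUS": truth_minus,
        "classes": {m.record.id: panel.true_edc_class(m.record)
                    for m in panel.members},
    }
    return plus, minus, truth


#: archetype assignment of the default 15-member panel (generator defaults,
#: patterned on the described ion-image phenotypes; not source-data claims)
_DEFAULT_PANEL = (
    ("hexosamine", SpatialArchetype.INDUCED_FROM_BACTERIA),
    ("glcnac", SpatialArchetype.INDUCED_IN_INTERACTION_FUNGUS),
    ("citrate", SpatialArchetype.UNCHANGED),
    ("homocitrate", SpatialArchetype.SUPPRESSED_FROM_BACTERIA),
    ("succinyl_proline", SpatialArchetype.HOTSPOTS_IN_BIOFILM),
    ("glutamate", SpatialArchetype.UNCHANGED),
    ("acetoin", SpatialArchetype.INDUCED_FROM_BACTERIA),
    ("malate", SpatialArchetype.UNCHANGED),
    ("pyruvate", SpatialArchetype.INDUCED_BOTH),
    ("glyoxalate", SpatialArchetype.SUPPRESSED_BOTH),
    ("hydroxyacetone", SpatialArchetype.INDUCED_FROM_BACTERIA),
    ("pentanoate", SpatialArchetype.INDUCED_FROM_BACTERIA),
    ("ffa_c14", SpatialArchetype.SUPPRESSED_BOTH),
    ("ffa_c16", SpatialArchetype.SUPPRESSED_BOTH),
    ("ffa_c18", SpatialArchetype.INDUCED_IN_INTERACTION_FUNGUS),
)


def default_scenario(db: MetaboliteDB | None = None
                     ) -> tuple[ColonyLayout, GroundTruthPanel, NoiseModel]:
    """The shipped co-culture scenario: 15 emitted members, default noise.

    The database additionally holds confounders that are never emitted
    (kinetin: not derivatizable; methionine, butanoate, dehydrothreonate:
    mass-matching alternatives), so isobar resolution is exercised.
    """
    db = db or demo_db()
    members = tuple(PanelMember(db[mid], arch) for mid, arch in _DEFAULT_PANEL)
    return ColonyLayout(), GroundTruthPanel(members), NoiseModel()
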