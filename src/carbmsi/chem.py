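"""Elemental formulas, exact masses, derivatized-ion m/z and isotope envelopes.

The chemistry here is driven by one reagent: 4-APEBA, a carbonyl-reactive
derivatization tag carrying a quaternary ammonium (permanent +1 charge) and a
single bromine atom.  Tagging a neutral metabolite M produces the cation
[M + C18H22N2Br]+, whose two dominant isotopologues — M+0 with 79Br and A+2
with 81Br, almost equally abundant — form the diagnostic doublet used for
annotation verification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ELECTRON_MASS",
    "Isotope",
    "IsotopeTable",
    "ElementalFormula",
    "DerivatizationTag",
    "IsotopePattern",
    "parse_formula",
    "monoisotopic_mass",
    "derivatized_mz",
    "isotope_envelope",
    "a2_ratio",
    "ppm_error",
    "APEBA",
]

#: CODATA electron mass in Da; subtracted once for a singly charged cation.
ELECTRON_MASS = 5.48579909065e-4


class FormulaError(ValueError):
    """Malformed formula text or an element/isotope missing from the table."""


@dataclass(frozen=True)
class Isotope:
    mass_number: int
    mass: float  # Da
    abundance: float  # natural abundance fraction


class IsotopeTable:
    """Isotope masses and natural abundances, keyed by element symbol.

    Shipped as a versioned TSV resource (``data/isotopes.tsv``; masses from
    standard atomic-mass evaluations).  Per element, abundances must sum to 1
    within 1e-6 and masses must be positive.
    """

    _default: "IsotopeTable | None" = None

    def __init__(self, isotopes: Mapping[str, Iterable[Isotope]],
                 electron_mass: float = ELECTRON_MASS):
        self._isotopes: dict[str, tuple[Isotope, ...]] = {
            el: tuple(sorted(iso, key=lambda i: i.mass_number))
            for el, iso in isotopes.items()
        }
        self.electron_mass = electron_mass
        for el, isos in self._isotopes.items():
            if not isos:
                raise ValueError(f"element {el!r} has no isotopes")
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances of {el} sum to {total}, not 1")
            if any(i.mass <= 0 for i in isos):
                raise ValueError(f"non-positive isotope mass for {el}")

    @classmethod
    def default(cls) -> "IsotopeTable":
        if cls._default is None:
            text = (resources.files("carbmsi") / "data/isotopes.tsv").read_text()
            rows: dict[str, list[Isotope]] = {}
            for line in text.splitlines()[1:]:
                if not line.strip():
                    continue
                el, mn, mass, ab = line.split("\t")
                rows.setdefault(el, []).append(
                    Isotope(int(mn), float(mass), float(ab)))
            cls._default = cls(rows)
        return cls._default

    @property
    def elements(self) -> set[str]:
        return set(self._isotopes)

    def isotopes(self, element: str) -> tuple[Isotope, ...]:
        try:
            return self._isotopes[element]
        except KeyError:
            raise FormulaError(f"element {element!r} not in isotope table") from None

    def isotope(self, element: str, mass_number: int) -> Isotope:
        for iso in self.isotopes(element):
            if iso.mass_number == mass_number:
                return iso
        raise FormulaError(
            f"{mass_number} is not a listed isotope of {element}")

    def most_abundant(self, element: str) -> Isotope:
        return max(self.isotopes(element), key=lambda i: i.abundance)


_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Multiset of atoms, with optional whole-element isotope locks.

    ``fixed_isotopes`` maps an element symbol to the mass number that every
    atom of that element carries (e.g. ``{"Br": 81}`` for the A+2
    isotopologue of a singly brominated species).
    """

    counts: Mapping[str, int]
    fixed_isotopes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for el, n in self.counts.items():
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count of {el} must be a non-negative int")
        for el in self.fixed_isotopes:
            if el not in self.counts:
                raise FormulaError(f"fixed isotope for absent element {el}")
        object.__setattr__(self, "counts",
                           {el: n for el, n in self.counts.items() if n > 0})
        object.__setattr__(self, "fixed_isotopes", dict(self.fixed_isotopes))

    def with_fixed(self, element: str, mass_number: int) -> "ElementalFormula":
        fixed = dict(self.fixed_isotopes)
        fixed[element] = mass_number
        return ElementalFormula(dict(self.counts), fixed)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        fixed = dict(self.fixed_isotopes)
        for el, mn in other.fixed_isotopes.items():
            if fixed.get(el, mn) != mn:
                raise FormulaError(f"conflicting fixed isotopes for {el}")
            fixed[el] = mn
        return ElementalFormula(counts, fixed)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        # Hill order: C first, then H, then the rest alphabetically.
        def key(el: str):
            return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

        parts = []
        for el in sorted(self.counts, key=key):
            n = self.counts[el]
            sym = f"[{self.fixed_isotopes[el]}{el}]" if el in self.fixed_isotopes else el
            parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts)


def parse_formula(text: str) -> ElementalFormula:
    """Parse Hill-style formula text like ``"C18H22N2Br"`` or ``"[81Br]"``.

    Counts default to 1; an isotope prefix in brackets locks every atom of
    that element to the given mass number.  Symbols are validated against the
    default isotope table.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    table = IsotopeTable.default()
    counts: dict[str, int] = {}
    fixed: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        pos = m.end()
        if m.group(2):  # [81Br] style
            mn, el, n = int(m.group(1)), m.group(2), m.group(3)
            table.isotope(el, mn)  # validates element and isotope
            if fixed.get(el, mn) != mn:
                raise FormulaError(f"conflicting fixed isotopes for {el}")
            fixed[el] = mn
        else:
            el, n = m.group(4), m.group(5)
            if el not in table.elements:
                raise FormulaError(f"unknown element symbol {el!r}")
        count = int(n) if n else 1
        if count <= 0:
            raise FormulaError(f"zero count for {el}")
        counts[el] = counts.get(el, 0) + count
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r}")
    return ElementalFormula(counts, fixed)


def monoisotopic_mass(f: ElementalFormula,
                      table: IsotopeTable | None = None) -> float:
    """Exact mass using each element's most abundant isotope (Da).

    For every element here the most abundant isotope is also the lightest
    (for Br that is 79Br); a fixed isotope on the formula overrides the
    default selection.
    """
    table = table or IsotopeTable.default()
    total = 0.0
    for el, n in f.counts.items():
        if el in f.fixed_isotopes:
            iso = table.isotope(el, f.fixed_isotopes[el])
        else:
            iso = table.most_abundant(el)
        total += n * iso.mass
    return total


@dataclass(frozen=True)
class DerivatizationTag:
    """A charge-carrying derivatization reagent and its reactivity rules.

    The default is 4-APEBA: the tag cation C18H22N2Br+ attaches to ketones
    and aldehydes directly; carboxylic acids react only after activation by
    the carbodiimide EDC.
    """

    cation_formula: ElementalFormula
    charge: int = 1
    direct_groups: frozenset[str] = frozenset({"ketone", "aldehyde"})
    activated_groups: frozenset[str] = frozenset({"carboxyl"})

    def __post_init__(self):
        if self.charge != 1:
            raise ValueError("only singly charged tags are supported")
        if self.direct_groups & self.activated_groups:
            raise ValueError("direct and activated group sets must be disjoint")

    def reactive_groups(self, edc_used: bool) -> frozenset[str]:
        return self.direct_groups | (self.activated_groups if edc_used else frozenset())


APEBA = DerivatizationTag(parse_formula("C18H22N2Br"))


def derivatized_mz(neutral: ElementalFormula,
                   tag: DerivatizationTag = APEBA,
                   br_mass_number: int = 79,
                   table: IsotopeTable | None = None) -> float:
    """m/z of the singly charged tagged cation [M + tag]+ (Da).

    The tag's bromine is locked to ``br_mass_number`` (79 → M+0, 81 → A+2)
    and one electron mass is subtracted for the +1 charge.
    """
    table = table or IsotopeTable.default()
    if br_mass_number not in (79, 81):
        raise ValueError("br_mass_number must be 79 or 81")
    tag_formula = tag.cation_formula.with_fixed("Br", br_mass_number)
    return (monoisotopic_mass(neutral, table)
            + monoisotopic_mass(tag_formula, table)
            - table.electron_mass * tag.charge)


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided theoretical isotope envelope, base peak normalized to 1."""

    peaks: tuple[tuple[float, float], ...]  # (m/z, relative intensity)
    resolving_power: float

    def __post_init__(self):
        mzs = [p[0] for p in self.peaks]
        ints = [p[1] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("pattern m/z must be strictly increasing")
        if not ints or abs(max(ints) - 1.0) > 1e-12:
            raise ValueError("base peak must be normalized to 1")
        if any(i <= 0 or i > 1 for i in ints):
            raise ValueError("intensities must lie in (0, 1]")

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def intensity(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.peaks)

    def intensity_near(self, mz: float, tol_da: float = 0.3) -> float:
        """Intensity of the pattern peak closest to ``mz`` within ``tol_da``."""
        best = 0.0
        for m, i in self.peaks:
            if abs(m - mz) <= tol_da:
                best = max(best, i)
        return best


def fwhm(mz: float, resolving_power: float, ref_mz: float = 400.0) -> float:
    """Gaussian FWHM of an FTICR peak at ``mz``.

    FTICR resolving power falls off as 1/m, so with R specified at a
    reference m/z the peak width grows quadratically:
    FWHM(m) = m^2 / (R * ref_mz).
    """
    return mz * mz / (resolving_power * ref_mz)


def _element_distribution(isotopes, n: int, prune: float) -> dict[float, float]:
    """Mass distribution of ``n`` atoms of one element (dict m/z→prob)."""
    dist = {0.0: 1.0}
    single = {iso.mass: iso.abundance for iso in isotopes}
    for _ in range(n):
        nxt: dict[float, float] = {}
        for m1, p1 in dist.items():
            for m2, p2 in single.items():
                key = round(m1 + m2, 9)
                nxt[key] = nxt.get(key, 0.0) + p1 * p2
        if len(nxt) > 64:
            cutoff = prune * max(nxt.values())
            nxt = {m: p for m, p in nxt.items() if p >= cutoff}
        dist = nxt
    return dist


def isotope_envelope(f: ElementalFormula,
                     table: IsotopeTable | None = None,
                     resolving_power: float = 110_000.0,
                     max_peaks: int = 10,
                     prune: float = 1e-10) -> IsotopePattern:
    """Theoretical isotope envelope of ``f`` at a given resolving power.

    A full multinomial expansion over isotope placements is computed per
    element by convolution, elements are combined, and centroids closer than
    the instrument FWHM at that m/z are merged (intensity-weighted centroid,
    summed intensity) until all neighbours are resolved.  The result is
    base-peak normalized and truncated to the ``max_peaks`` most intense
    centroids.  Fixed-isotope elements contribute a single exact mass.
    """
    table = table or IsotopeTable.default()
    if resolving_power <= 0:
        raise ValueError("resolving_power must be positive")
    dist = {0.0: 1.0}
    for el, n in f.counts.items():
        if el in f.fixed_isotopes:
            iso = table.isotope(el, f.fixed_isotopes[el])
            part = {round(n * iso.mass, 9): 1.0}
        else:
            part = _element_distribution(table.isotopes(el), n, prune)
        nxt: dict[float, float] = {}
        for m1, p1 in dist.items():
            for m2, p2 in part.items():
                key = round(m1 + m2, 9)
                nxt[key] = nxt.get(key, 0.0) + p1 * p2
        cutoff = prune * max(nxt.values())
        dist = {m: p for m, p in nxt.items() if p >= cutoff}

    peaks = sorted(dist.items())
    peaks = merge_centroids(peaks, resolving_power)
    base = max(p for _, p in peaks)
    peaks = [(m, p / base) for m, p in peaks]
    peaks.sort(key=lambda mp: mp[1], reverse=True)
    peaks = sorted(peaks[:max_peaks])
    return IsotopePattern(tuple(peaks), resolving_power)


def merge_centroids(peaks: list[tuple[float, float]],
                    resolving_power: float) -> list[tuple[float, float]]:
    """Merge centroids closer than the local FWHM, repeating to a fixed point."""
    peaks = sorted(peaks)
    while True:
        merged: list[tuple[float, float]] = []
        changed = False
        for m, p in peaks:
            if merged and (m - merged[-1][0]) <= fwhm(m, resolving_power):
                m0, p0 = merged.pop()
                tot = p0 + p
                merged.append(((m0 * p0 + m * p) / tot, tot))
                changed = True
            else:
                merged.append((m, p))
        peaks = merged
        if not changed:
            return peaks


def a2_ratio(cation: ElementalFormula,
             table: IsotopeTable | None = None,
             resolving_power: float = 110_000.0) -> float:
    """Theoretical A+2 : M+0 intensity ratio of a (singly brominated) species.

    M+0 is the lowest-mass envelope peak; A+2 is the peak nearest
    M+0 + (mass(81Br) − mass(79Br)).  For a single-Br formula the ratio is
    dominated by the 81Br/79Br abundance ratio with a small 13C2 addition.
    """
    table = table or IsotopeTable.default()
    env = isotope_envelope(cation, table, resolving_power=resolving_power)
    m0_mz, m0_int = env.peaks[0]
    delta = table.isotope("Br", 81).mass - table.isotope("Br", 79).mass
    a2_int = env.intensity_near(m0_mz + delta, tol_da=0.5)
    if a2_int == 0.0:
        return 0.0
    return a2_int / m0_int


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
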