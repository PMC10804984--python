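"""Metabolite records, derivatizability rules, and EDC-differential classes.

4-APEBA alone reacts with ketones and aldehydes; with the activator EDC it
additionally reacts with carboxylic acids.  Running the same sample with and
without EDC therefore encodes functional-group information in the
presence/absence pattern of each annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem import DerivatizationTag, ElementalFormula, parse_formula, APEBA

__all__ = [
    "MetaboliteRecord",
    "MetaboliteDB",
    "EdcClass",
    "load_db",
    "demo_db",
    "is_derivatizable",
    "classify_by_edc",
]

_COLUMNS = ["id", "name", "formula", "n_carboxyl", "n_ketone", "n_aldehyde"]


@dataclass(frozen=True)
class MetaboliteRecord:
    """A neutral metabolite with counts of tag-reactive functional groups."""

    id: str
    name: str
    neutral_formula: ElementalFormula
    n_carboxyl: int
    n_ketone: int
    n_aldehyde: int

    def __post_init__(self):
        if min(self.n_carboxyl, self.n_ketone, self.n_aldehyde) < 0:
            raise ValueError("functional-group counts must be non-negative")

    def group_count(self, group: str) -> int:
        return {"carboxyl": self.n_carboxyl,
                "ketone": self.n_ketone,
                "aldehyde": self.n_aldehyde}[group]

    @property
    def has_ketone_or_aldehyde(self) -> bool:
        return (self.n_ketone + self.n_aldehyde) > 0


@dataclass
class MetaboliteDB:
    records: list[MetaboliteRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, metabolite_id: str) -> MetaboliteRecord:
        return self._by_id[metabolite_id]

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self._by_id


class EdcClass(enum.Enum):
    """Functional-group verdict from paired detection with/without EDC."""

    CONTAINS_KETONE_OR_ALDEHYDE = "contains_ketone_or_aldehyde"
    CARBOXYL_ONLY = "carboxyl_only"
    NOT_DERIVATIZABLE_OR_ABSENT = "not_derivatizable_or_absent"
    INCONSISTENT = "inconsistent"


def load_db(path: str | Path, provenance: str | None = None) -> MetaboliteDB:
    """Load a metabolite table from TSV.

    Required columns: id, name, formula, n_carboxyl, n_ketone, n_aldehyde.
    Formulas are validated by the formula parser; duplicate ids are an error.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str})
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"metabolite table missing columns: {missing}")
    records = [
        MetaboliteRecord(
            id=row["id"],
            name=row["name"],
            neutral_formula=parse_formula(row["formula"]),
            n_carboxyl=int(row["n_carboxyl"]),
            n_ketone=int(row["n_ketone"]),
            n_aldehyde=int(row["n_aldehyde"]),
        )
        for _, row in frame.iterrows()
    ]
    if not records:
        raise ValueError("metabolite table is empty")
    return MetaboliteDB(records, provenance or str(path))


def demo_db() -> MetaboliteDB:
    """The packaged demo database: named metabolites of the co-culture study.

    Group counts were audited by hand from the published structures; reducing
    sugars are marked aldehyde=1 under the open-chain interpretation (see the
    notes column of the resource file).
    """
    with resources.as_file(
            resources.files("carbmsi") / "data/demo_metabolites.tsv") as p:
        return load_db(p, provenance="demo panel (KEGG-style subset)")


def is_derivatizable(m: MetaboliteRecord,
                     tag: DerivatizationTag = APEBA,
                     edc_used: bool = False) -> bool:
    """Whether the tag can react with ``m`` under the given condition.

    Without EDC only ketones/aldehydes react; with EDC carboxyls react too.
    """
    groups = tag.reactive_groups(edc_used)
    return sum(m.group_count(g) for g in groups) > 0


def classify_by_edc(detected_without_edc: bool,
                    detected_with_edc: bool) -> EdcClass:
    """Functional-group truth table over a matched EDC± pair of runs.

    Detected in both → at least one ketone/aldehyde; detected only with EDC →
    carboxyls only; detected in neither → absent or unreactive; detected only
    without EDC is kept as an explicit INCONSISTENT flag (ketone kinetics can
    push a borderline species below threshold in the EDC+ run) rather than
    coerced into a chemistry class.
    """
    if detected_without_edc and detected_with_edc:
        return EdcClass.CONTAINS_KETONE_OR_ALDEHYDE
    if detected_with_edc:
        return EdcClass.CARBOXYL_ONLY
    if detected_without_edc:
        return EdcClass.INCONSISTENT
    return EdcClass.NOT_DERIVATIZABLE_OR_ABSENT


def edc_class_consistent(m: MetaboliteRecord, cls: EdcClass) -> bool:
    """Whether a metabolite's functional groups can produce ``cls``."""
    if cls is EdcClass.CONTAINS_KETONE_OR_ALDEHYDE:
        return m.has_ketone_or_aldehyde
    if cls is EdcClass.CARBOXYL_ONLY:
        return m.n_carboxyl > 0 and not m.has_ketone_or_aldehyde
    return True  # absent / inconsistent carry no positive group evidence
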