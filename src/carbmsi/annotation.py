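"""Candidate annotation of derivatized ions with Br verification and decoy FDR.

The annotation pipeline mirrors how a mass-shift ("chemical modifier") search
is reasoned about in derivatization MSI:

1. every metabolite in the database yields two tagged-ion hypotheses, the
   79Br monoisotopic peak (M+0) and the 81Br isotopologue (A+2);
2. hypotheses are matched against the dataset within a ppm window (3 ppm by
   default, the instrument's MS1 confidence);
3. M+0 detections are verified against the bromine doublet: the A+2 partner
   must exist at the envelope-predicted intensity ratio and colocalize;
4. mass-overlapping hypotheses (isobars/isomers/isotopologue collisions) are
   resolved by chemistry (derivatizability under the run's EDC condition),
   Br verification, and — when a matched EDC± pair is available — the
   functional-group truth table;
5. a simplified target-decoy FDR assigns q-values from implausible-modifier
   decoy hypotheses.  This is an explicit, non-equivalent stand-in for the
   METASPACE MSM score (its spatial-chaos term is omitted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (APEBA, DerivatizationTag, ElementalFormula, IsotopeTable,
                   a2_ratio, derivatized_mz, monoisotopic_mass, parse_formula)
from .metabolites import (EdcClass, MetaboliteDB, MetaboliteRecord,
                          classify_by_edc, edc_class_consistent,
                          is_derivatizable)
from .msi import MSIDataset, colocalization, extract_ion_image, window_ppm_errors

__all__ = [
    "AnnotationCandidate",
    "AnnotationResult",
    "generate_candidates",
    "match_candidates",
    "verify_br",
    "resolve_isobars",
    "estimate_fdr",
    "annotate_dataset",
    "result_to_frame",
]

PASS, FAIL, NOT_EVALUATED = "PASS", "FAIL", "NOT_EVALUATED"
ACCEPTED, REJECTED, CANDIDATE = "ACCEPTED", "REJECTED", "CANDIDATE"

#: Fixed decoy-modifier alphabet: bromine-free elemental modifiers with masses
#: bracketing the 4-APEBA shift (~345 Da), chemically implausible as tags.
DECOY_MODIFIERS = (
    "C12H20N5O4P", "C15H24N3O3P", "C13H18N4O5", "C16H28NO4P", "C14H22N2O6",
    "C11H16N6O4", "C17H30O4S", "C13H26N3O3PS", "C15H20N4O3", "C12H24N2O5S",
    "C18H26N2O3", "C10H18N4O6S", "C16H22N2O4", "C14H28N2O2S2", "C11H21N5O3P",
    "C17H24N2O4", "C13H20N6O2", "C15H26O6", "C12H19N3O6", "C19H32N2OS",
)


@dataclass
class AnnotationCandidate:
    """One metabolite × Br-isotopologue hypothesis and its evidence."""

    metabolite: MetaboliteRecord
    br_mass_number: int  # 79 = M+0 hypothesis, 81 = A+2 hypothesis
    theoretical_mz: float
    mean_ppm_error: float = float("nan")
    detection_fraction: float = 0.0
    total_intensity: float = 0.0
    br_verification: str = NOT_EVALUATED
    edc_class: EdcClass | None = None
    status: str = CANDIDATE
    reason: str = ""
    score: float = float("nan")
    q_value: float = float("nan")
    ambiguous: bool = False

    @property
    def metabolite_id(self) -> str:
        return self.metabolite.id

    def reject(self, reason: str) -> None:
        self.status = REJECTED
        self.reason = reason


@dataclass
class AnnotationResult:
    accepted: list[AnnotationCandidate]
    rejected: list[AnnotationCandidate]
    fdr_level: float = 0.20
    decoy_stats: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        both = {id(c) for c in self.accepted} & {id(c) for c in self.rejected}
        if both:
            raise ValueError("a candidate cannot be both accepted and rejected")

    @property
    def accepted_ids(self) -> set[str]:
        return {c.metabolite_id for c in self.accepted}


def generate_candidates(db: MetaboliteDB,
                        tag: DerivatizationTag = APEBA,
                        edc_used: bool = False,
                        table: IsotopeTable | None = None,
                        filter_chemistry: bool = True) -> list[AnnotationCandidate]:
    """M+0 and A+2 hypotheses for every (derivatizable) metabolite.

    With ``filter_chemistry=True`` (the default) metabolites that cannot
    react under the given EDC condition are excluded up front.  The full
    pipeline instead generates permissively (``filter_chemistry=False``) and
    lets isobar resolution eliminate chemistry-impossible mass matches, which
    is how a kinetin-type hypothesis gets rejected *explicitly*.
    """
    if not len(db):
        raise ValueError("metabolite database is empty")
    table = table or IsotopeTable.default()
    out = []
    for record in db:
        if filter_chemistry and not is_derivatizable(record, tag, edc_used):
            continue
        for br in (79, 81):
            out.append(AnnotationCandidate(
                metabolite=record,
                br_mass_number=br,
                theoretical_mz=derivatized_mz(record.neutral_formula, tag, br,
                                              table)))
    return out


def default_intensity_threshold(d: MSIDataset, factor: float = 5.0) -> float:
    """Default total-intensity floor: ``factor`` × median centroid intensity.

    The median over all centroids is dominated by chemical background, so
    this floor rejects windows that caught only a stray background peak.
    """
    if not len(d.peaks):
        return 0.0
    return factor * float(d.peaks["intensity"].median())


def match_candidates(d: MSIDataset,
                     candidates: list[AnnotationCandidate],
                     tol_ppm: float = 3.0,
                     min_detection_fraction: float = 0.01,
                     min_total_intensity: float | None = None) -> list[AnnotationCandidate]:
    """Return the candidates whose ion image clears the detection thresholds.

    A candidate is detected iff its ion image has total intensity at or above
    ``min_total_intensity`` (default: 5× the dataset's median centroid
    intensity) and a nonzero-pixel fraction of at least
    ``min_detection_fraction`` of the grid.  Detection evidence (mean ppm
    error over contributing centroids, detection fraction, total intensity)
    is recorded on the candidate.
    """
    if min_total_intensity is None:
        min_total_intensity = default_intensity_threshold(d)
    detected = []
    for c in candidates:
        img = extract_ion_image(d, c.theoretical_mz, tol_ppm)
        c.total_intensity = img.total()
        c.detection_fraction = img.nonzero_fraction()
        if (c.total_intensity >= min_total_intensity
                and c.detection_fraction >= min_detection_fraction):
            errs = window_ppm_errors(d, c.theoretical_mz, tol_ppm)
            c.mean_ppm_error = float(np.mean(errs)) if errs.size else float("nan")
            detected.append(c)
    return detected


def verify_br(d: MSIDataset,
              c: AnnotationCandidate,
              tag: DerivatizationTag = APEBA,
              table: IsotopeTable | None = None,
              ratio_band: tuple[float, float] = (0.5, 2.0),
              min_coloc: float = 0.7,
              tol_ppm: float = 3.0) -> str:
    """Check the 79Br/81Br doublet of an M+0 detection.

    The observed A+2:M+0 total-intensity ratio must fall within
    ``ratio_band`` × the theoretical envelope ratio, and the two ion images
    must colocalize (cosine ≥ ``min_coloc``).  Both checks are invariant to a
    global intensity scale.
    """
    if c.br_mass_number != 79:
        raise ValueError("Br verification applies to M+0 (79Br) hypotheses")
    table = table or IsotopeTable.default()
    cation = c.metabolite.neutral_formula + tag.cation_formula
    theo_ratio = a2_ratio(cation, table)
    delta = table.isotope("Br", 81).mass - table.isotope("Br", 79).mass
    m0 = extract_ion_image(d, c.theoretical_mz, tol_ppm)
    a2 = extract_ion_image(d, c.theoretical_mz + delta, tol_ppm)
    if m0.total() == 0:
        c.br_verification = FAIL
        c.reason = "no M+0 signal"
        return FAIL
    obs_ratio = a2.total() / m0.total()
    lo, hi = ratio_band
    ratio_ok = lo * theo_ratio <= obs_ratio <= hi * theo_ratio
    coloc_ok = colocalization(m0, a2) >= min_coloc
    c.br_verification = PASS if (ratio_ok and coloc_ok) else FAIL
    return c.br_verification


def _group_by_mz(detections: list[AnnotationCandidate],
                 tol_ppm: float) -> list[list[AnnotationCandidate]]:
    """Cluster detections whose theoretical m/z lie within a mutual 2×tol window."""
    ordered = sorted(detections, key=lambda c: c.theoretical_mz)
    groups: list[list[AnnotationCandidate]] = []
    for c in ordered:
        if groups and (c.theoretical_mz - groups[-1][-1].theoretical_mz
                       <= 2 * tol_ppm * 1e-6 * c.theoretical_mz):
            groups[-1].append(c)
        else:
            groups.append([c])
    return groups


def resolve_isobars(detections: list[AnnotationCandidate],
                    edc_used: bool,
                    tag: DerivatizationTag = APEBA,
                    edc_classes: dict[str, EdcClass] | None = None,
                    tol_ppm: float = 3.0) -> tuple[list[AnnotationCandidate],
                                                   list[AnnotationCandidate]]:
    """Eliminate mass-overlapping hypotheses in a fixed order.

    Within each mutual 2×tol_ppm group: (1) drop metabolites that cannot be
    derivatized under the run's EDC condition; (2) drop M+0 hypotheses whose
    Br doublet failed verification, and A+2 hypotheses whose own M+0 partner
    did not survive; (3) with paired EDC± evidence, drop metabolites whose
    functional groups contradict the EDC class of their window; (4) remaining
    multi-metabolite ties keep the smallest |mean ppm error| and are flagged
    AMBIGUOUS.  Returns (kept, rejected); a hypothesis eliminated at one
    stage is never revisited later.
    """
    rejected: list[AnnotationCandidate] = []
    kept: list[AnnotationCandidate] = []

    # stage 1: chemistry under the run's condition
    stage1 = []
    for c in detections:
        if not is_derivatizable(c.metabolite, tag, edc_used):
            c.reject("not derivatizable under run condition")
            rejected.append(c)
        else:
            stage1.append(c)

    # stage 2: bromine-isotopologue support
    surviving_m0 = {c.metabolite_id for c in stage1
                    if c.br_mass_number == 79 and c.br_verification != FAIL}
    stage2 = []
    for c in stage1:
        if c.br_mass_number == 79 and c.br_verification == FAIL:
            c.reject("Br isotopologue verification failed")
            rejected.append(c)
        elif c.br_mass_number == 81 and c.metabolite_id not in surviving_m0:
            c.reject("A+2 hypothesis without a verified M+0 partner")
            rejected.append(c)
        else:
            stage2.append(c)

    # stage 3: EDC-differential functional-group consistency
    stage3 = []
    for c in stage2:
        cls = (edc_classes or {}).get(c.metabolite_id)
        if cls is not None:
            c.edc_class = cls
        if cls is not None and not edc_class_consistent(c.metabolite, cls):
            c.reject(f"functional groups contradict EDC class {cls.name}")
            rejected.append(c)
        else:
            stage3.append(c)

    # stage 4: ppm tie-break within residual multi-metabolite groups
    for group in _group_by_mz(stage3, tol_ppm):
        ids = {c.metabolite_id for c in group}
        if len(ids) == 1:
            kept.extend(group)
            continue
        best = min(abs(c.mean_ppm_error) for c in group)
        winners = []
        for c in group:
            if abs(abs(c.mean_ppm_error) - best) <= 1e-9:
                c.ambiguous = True
                winners.append(c)
            else:
                c.reject("larger |ppm error| than a co-isobaric hypothesis")
                rejected.append(c)
        if len({c.metabolite_id for c in winners}) == 1:
            for c in winners:
                c.ambiguous = False
        kept.extend(winners)
    kept.sort(key=lambda c: c.theoretical_mz)
    return kept, rejected


def _composite_score(d: MSIDataset, c: AnnotationCandidate,
                     tag: DerivatizationTag, table: IsotopeTable,
                     tol_ppm: float) -> float:
    """Detection fraction × Br-ratio closeness × colocalization, in [0, 1]."""
    table = table or IsotopeTable.default()
    delta = table.isotope("Br", 81).mass - table.isotope("Br", 79).mass
    m0 = extract_ion_image(d, c.theoretical_mz, tol_ppm)
    a2 = extract_ion_image(d, c.theoretical_mz + delta, tol_ppm)
    if m0.total() == 0:
        return 0.0
    cation = c.metabolite.neutral_formula + tag.cation_formula
    theo = a2_ratio(cation, table)
    obs = a2.total() / m0.total()
    if theo <= 0 or obs <= 0:
        closeness = 0.0
    else:
        closeness = min(obs / theo, theo / obs)
    return c.detection_fraction * closeness * colocalization(m0, a2)


def estimate_fdr(target_detections: list[AnnotationCandidate],
                 d: MSIDataset,
                 db: MetaboliteDB,
                 tag: DerivatizationTag = APEBA,
                 n_decoys: int = 20,
                 seed: int = 0,
                 fdr_level: float = 0.20,
                 tol_ppm: float = 3.0,
                 min_detection_fraction: float = 0.01,
                 min_total_intensity: float | None = None,
                 table: IsotopeTable | None = None) -> AnnotationResult:
    """Decoy-based q-values for surviving target detections.

    For every database metabolite, ``n_decoys`` decoy hypotheses are built by
    swapping the tag for a randomly drawn modifier from a fixed bromine-free
    alphabet of similar mass.  Decoys are matched and scored exactly like
    targets; the q-value at a score is (decoy hits ≥ score ÷ n_decoys) ÷
    (target hits ≥ score), made monotone.  Targets with q ≤ ``fdr_level``
    are ACCEPTED.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be at least 1")
    table = table or IsotopeTable.default()
    rng = np.random.default_rng([int(seed), 7919])
    if min_total_intensity is None:
        min_total_intensity = default_intensity_threshold(d)

    for c in target_detections:
        c.score = _composite_score(d, c, tag, table, tol_ppm)

    # decoy hypotheses: metabolite + implausible modifier, M+0-style only
    decoy_scores = []
    modifiers = [monoisotopic_mass(parse_formula(m), table) - table.electron_mass
                 for m in DECOY_MODIFIERS]
    for record in db:
        neutral = monoisotopic_mass(record.neutral_formula, table)
        picks = rng.choice(len(modifiers), size=n_decoys, replace=True)
        for k in picks:
            mz = neutral + modifiers[k]
            img = extract_ion_image(d, mz, tol_ppm)
            if (img.total() < min_total_intensity
                    or img.nonzero_fraction() < min_detection_fraction):
                continue
            dummy = AnnotationCandidate(record, 79, mz,
                                        detection_fraction=img.nonzero_fraction(),
                                        total_intensity=img.total())
            decoy_scores.append(_composite_score(d, dummy, tag, table, tol_ppm))

    decoy_scores = np.sort(np.asarray(decoy_scores))
    target_scores = np.sort(np.asarray([c.score for c in target_detections]))

    def q_value(s: float) -> float:
        n_decoy_ge = decoy_scores.size - np.searchsorted(decoy_scores, s, "left")
        n_target_ge = target_scores.size - np.searchsorted(target_scores, s, "left")
        if n_target_ge == 0:
            return 1.0
        return min(1.0, (n_decoy_ge / n_decoys) / n_target_ge)

    # monotone q: a better score never has a larger q
    order = sorted(target_detections, key=lambda c: c.score, reverse=True)
    running = 0.0
    for c in order:
        running = max(running, q_value(c.score))
        # a score of zero carries no doublet/colocalization evidence at all
        c.q_value = 1.0 if c.score <= 0 else running

    accepted, rejected = [], []
    for c in target_detections:
        if c.q_value <= fdr_level:
            c.status = ACCEPTED
            accepted.append(c)
        else:
            c.reject(f"q-value {c.q_value:.3f} above FDR level {fdr_level}")
            rejected.append(c)
    stats = {"n_decoy_hypotheses": int(len(db) * n_decoys),
             "n_decoy_detections": int(decoy_scores.size),
             "n_targets": len(target_detections),
             "seed": int(seed)}
    return AnnotationResult(accepted, rejected, fdr_level, stats)


def annotate_dataset(d: MSIDataset,
                     db: MetaboliteDB,
                     tag: DerivatizationTag = APEBA,
                     edc_used: bool | None = None,
                     paired: MSIDataset | None = None,
                     tol_ppm: float = 3.0,
                     min_detection_fraction: float = 0.01,
                     min_total_intensity: float | None = None,
                     ratio_band: tuple[float, float] = (0.5, 2.0),
                     min_coloc: float = 0.7,
                     n_decoys: int = 20,
                     seed: int = 0,
                     fdr_level: float = 0.20,
                     table: IsotopeTable | None = None) -> AnnotationResult:
    """Run the full pipeline on one dataset (optionally with its EDC± partner).

    ``paired`` is the matched run of the opposite EDC condition; when given,
    per-metabolite detection flags in both runs feed the EDC truth table and
    the resulting classes participate in isobar resolution.
    """
    table = table or IsotopeTable.default()
    if edc_used is None:
        edc_used = d.edc_used
    candidates = generate_candidates(db, tag, edc_used, table,
                                     filter_chemistry=False)
    detections = match_candidates(d, candidates, tol_ppm,
                                  min_detection_fraction, min_total_intensity)
    for c in detections:
        if c.br_mass_number == 79:
            verify_br(d, c, tag, table, ratio_band, min_coloc, tol_ppm)

    edc_classes = None
    if paired is not None:
        if paired.condition == d.condition:
            raise ValueError("paired dataset must have the opposite EDC condition")
        edc_classes = _edc_classes_from_pair(d, paired, db, tag, tol_ppm,
                                             min_detection_fraction,
                                             min_total_intensity, table)
        for c in detections:
            c.edc_class = edc_classes.get(c.metabolite_id)

    kept, rejected = resolve_isobars(detections, edc_used, tag, edc_classes,
                                     tol_ppm)
    # FDR over the metabolite-level (M+0) survivors; A+2 rows follow their M+0
    m0 = [c for c in kept if c.br_mass_number == 79]
    result = estimate_fdr(m0, d, db, tag, n_decoys, seed, fdr_level, tol_ppm,
                          min_detection_fraction, min_total_intensity, table)
    accepted_ids = result.accepted_ids
    for c in kept:
        if c.br_mass_number == 81:
            if c.metabolite_id in accepted_ids:
                c.status = ACCEPTED
                result.accepted.append(c)
            else:
                c.reject("M+0 partner not accepted")
                result.rejected.append(c)
    result.rejected.extend(rejected)
    result.config = {
        "condition": d.condition, "edc_used": bool(edc_used),
        "tol_ppm": tol_ppm, "min_detection_fraction": min_detection_fraction,
        "ratio_band": list(ratio_band), "min_coloc": min_coloc,
        "n_decoys": n_decoys, "seed": int(seed), "fdr_level": fdr_level,
        "paired": paired.condition if paired is not None else None,
    }
    return result


def _edc_classes_from_pair(d: MSIDataset, paired: MSIDataset,
                           db: MetaboliteDB, tag: DerivatizationTag,
                           tol_ppm, min_detection_fraction,
                           min_total_intensity, table) -> dict[str, EdcClass]:
    """Per-metabolite EDC truth-table classes from matched EDC± detections."""
    runs = {d.condition: d, paired.condition: paired}
    flags: dict[str, dict[str, bool]] = {}
    for cond, ds in runs.items():
        cands = generate_candidates(db, tag, edc_used=True, table=table,
                                    filter_chemistry=False)
        m0 = [c for c in cands if c.br_mass_number == 79]
        detected = match_candidates(ds, m0, tol_ppm, min_detection_fraction,
                                    min_total_intensity)
        ids = {c.metabolite_id for c in detected}
        for record in db:
            flags.setdefault(record.id, {})[cond] = record.id in ids
    return {mid: classify_by_edc(f.get("EDC_MINUS", False),
                                 f.get("EDC_PLUS", False))
            for mid, f in flags.items()}


def result_to_frame(result: AnnotationResult) -> pd.DataFrame:
    """Flatten an AnnotationResult into one row per candidate hypothesis."""
    rows = []
    for c in result.accepted + result.rejected:
        rows.append({
            "metabolite": c.metabolite_id,
            "name": c.metabolite.name,
            "br_mass_number": c.br_mass_number,
            "theoretical_mz": round(c.theoretical_mz, 6),
            "mean_ppm_error": c.mean_ppm_error,
            "detection_fraction": c.detection_fraction,
            "total_intensity": c.total_intensity,
            "br_verification": c.br_verification,
            "edc_class": c.edc_class.name if c.edc_class else "UNKNOWN",
            "score": c.score,
            "q_value": c.q_value,
            "ambiguous": c.ambiguous,
            "status": c.status,
            "reason": c.reason,
        })
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(["status", "theoretical_mz"],
                                  ignore_index=True)
    return frame


def write_result(result: AnnotationResult, tsv_path: str | Path,
                 report_path: str | Path | None = None) -> None:
    result_to_frame(result).to_csv(tsv_path, sep="\t", index=False)
    if report_path is not None:
        report = {"fdr_level": result.fdr_level,
                  "decoy_stats": result.decoy_stats,
                  "config": result.config,
                  "n_accepted": len(result.accepted),
                  "n_rejected": len(result.rejected)}
        Path(report_path).write_text(json.dumps(report, indent=1))
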