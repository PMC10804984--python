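"""Candidate generation, matching, Br verification, isobar resolution, FDR."""

import numpy as np
import pandas as pd
import pytest

from carbmsi import (APEBA, EdcClass, MSIDataset, annotate_dataset,
                     demo_db, derivatized_mz, estimate_fdr,
                     generate_candidates, match_candidates, parse_formula,
                     resolve_isobars, verify_br)
from carbmsi.annotation import FAIL, PASS, result_to_frame
from carbmsi.chem import a2_ratio
from carbmsi.metabolites import MetaboliteDB, MetaboliteRecord
from carbmsi.synthetic import NoiseModel, default_scenario, simulate_dataset

from conftest import make_dataset


def _db_of(*records):
    return MetaboliteDB(list(records))


def _rec(mid, formula, carboxyl=0, ketone=0, aldehyde=0):
    return MetaboliteRecord(mid, mid, parse_formula(formula),
                            carboxyl, ketone, aldehyde)


# -------------------------------------------------------------- candidates
def test_single_ketone_yields_two_hypotheses():
    db = _db_of(_rec("acetoin", "C4H8O2", ketone=1))
    cands = generate_candidates(db, edc_used=False)
    assert len(cands) == 2
    assert {c.br_mass_number for c in cands} == {79, 81}


def test_candidate_chemistry_filter(db):
    minus_ids = {c.metabolite_id for c in generate_candidates(db, edc_used=False)}
    plus_ids = {c.metabolite_id for c in generate_candidates(db, edc_used=True)}
    assert "butanoate" not in minus_ids and "acetoin" in minus_ids
    assert "kinetin" not in plus_ids
    # chemistry subset: EDC− candidates are a subset of EDC+ candidates
    assert minus_ids <= plus_ids


def test_candidate_mz_is_tag_shifted(db):
    c79 = [c for c in generate_candidates(db, edc_used=False)
           if c.metabolite_id == "acetoin" and c.br_mass_number == 79][0]
    assert c79.theoretical_mz == pytest.approx(433.1485, abs=5e-4)


# ---------------------------------------------------------------- matching
def test_match_on_simulated_panel(paired_seed7, db):
    plus, _, _ = paired_seed7
    cands = generate_candidates(db, edc_used=True)
    detected = {c.metabolite_id for c in match_candidates(plus, cands)}
    assert "acetoin" in detected and "malate" in detected
    # methionine's M+0 window catches glutamate's A+2 peaks: detected too
    assert "methionine" in detected


def test_match_empty_dataset(db):
    empty = MSIDataset(4, 4, pd.DataFrame(columns=["x", "y", "mz", "intensity"]))
    cands = generate_candidates(db, edc_used=True)
    assert match_candidates(empty, cands, min_total_intensity=1.0) == []


def test_absent_metabolite_not_detected(db):
    """A quiet dataset with only off-target peaks detects nothing."""
    d = make_dataset([(0, 0, 600.0, 100.0), (1, 1, 601.0, 50.0)])
    cands = generate_candidates(db, edc_used=True)
    assert match_candidates(d, cands) == []


# ------------------------------------------------------------ Br doublet
def _doublet_dataset(neutral, scale=1.0, with_a2=True, ratio=None):
    """Uniform 3×3 image of a tagged metabolite's M+0 (and optional A+2)."""
    f = parse_formula(neutral)
    mz79 = derivatized_mz(f, APEBA, 79)
    mz81 = derivatized_mz(f, APEBA, 81)
    if ratio is None:
        ratio = a2_ratio(f + APEBA.cation_formula)
    peaks = []
    for x in range(3):
        for y in range(3):
            peaks.append((x, y, mz79, 100.0 * scale))
            if with_a2:
                peaks.append((x, y, mz81, 100.0 * ratio * scale))
    return make_dataset(peaks, width=3, height=3, condition="EDC_PLUS")


def _m0_candidate(mid, neutral, **groups):
    db = _db_of(_rec(mid, neutral, **groups))
    return [c for c in generate_candidates(db, edc_used=True)
            if c.br_mass_number == 79][0]


def test_verify_br_pass_at_envelope_ratio():
    d = _doublet_dataset("C5H9NO4")
    c = _m0_candidate("glutamate", "C5H9NO4", carboxyl=2)
    assert verify_br(d, c) == PASS


def test_verify_br_fail_without_partner():
    d = _doublet_dataset("C5H11NO2S", with_a2=False)
    c = _m0_candidate("methionine", "C5H11NO2S", carboxyl=1)
    assert verify_br(d, c) == FAIL


def test_verify_br_fail_wrong_ratio():
    d = _doublet_dataset("C5H9NO4", ratio=0.05)
    c = _m0_candidate("glutamate", "C5H9NO4", carboxyl=2)
    assert verify_br(d, c) == FAIL


def test_verify_br_scale_invariant():
    c1 = _m0_candidate("glutamate", "C5H9NO4", carboxyl=2)
    c2 = _m0_candidate("glutamate", "C5H9NO4", carboxyl=2)
    assert (verify_br(_doublet_dataset("C5H9NO4", scale=1.0), c1)
            == verify_br(_doublet_dataset("C5H9NO4", scale=250.0), c2))


def test_verify_br_zero_m0_fails():
    d = make_dataset([(0, 0, 600.0, 1.0)])
    c = _m0_candidate("glutamate", "C5H9NO4", carboxyl=2)
    assert verify_br(d, c) == FAIL
    assert c.reason == "no M+0 signal"


def test_verify_br_requires_m0_hypothesis():
    db = _db_of(_rec("glutamate", "C5H9NO4", carboxyl=2))
    a2 = [c for c in generate_candidates(db, edc_used=True)
          if c.br_mass_number == 81][0]
    with pytest.raises(ValueError, match="M\\+0"):
        verify_br(_doublet_dataset("C5H9NO4"), a2)


# --------------------------------------------------------- isobar conflicts
def test_kinetin_vs_succinyl_proline(paired_seed7, db):
    """Mass-tied pair at m/z ≈560.175 resolves to the derivatizable isomer."""
    plus, _, _ = paired_seed7
    res = annotate_dataset(plus, db, seed=7)
    assert "succinyl_proline" in res.accepted_ids
    kin = [c for c in res.rejected if c.metabolite_id == "kinetin"]
    assert kin and all("derivatizable" in c.reason for c in kin)


def test_methionine_vs_glutamate_a2(paired_seed7, db):
    """The 494.147 peak is glutamate's A+2, exposed by the missing doublet."""
    plus, _, _ = paired_seed7
    res = annotate_dataset(plus, db, seed=7)
    assert "glutamate" in res.accepted_ids
    met = [c for c in res.rejected
           if c.metabolite_id == "methionine" and c.br_mass_number == 79]
    assert met and met[0].br_verification == FAIL


def test_butanoate_vs_acetoin_needs_edc_pair(paired_seed7, db):
    """Identical-formula isomers resolve through the EDC± presence pattern."""
    plus, minus, _ = paired_seed7
    res = annotate_dataset(plus, db, paired=minus, seed=7)
    assert "acetoin" in res.accepted_ids
    but = [c for c in res.rejected if c.metabolite_id == "butanoate"]
    assert but and any("EDC class" in c.reason for c in but)


def test_resolution_is_staged_and_deterministic(paired_seed7, db):
    plus, minus, _ = paired_seed7
    r1 = annotate_dataset(plus, db, paired=minus, seed=7)
    r2 = annotate_dataset(plus, db, paired=minus, seed=7)
    assert result_to_frame(r1).equals(result_to_frame(r2))
    # nothing rejected at an early stage reappears among the accepted
    assert {id(c) for c in r1.accepted} & {id(c) for c in r1.rejected} == set()


# ------------------------------------------------------------------- FDR
def test_fdr_perfect_signal_accepts_panel(paired_seed7, db):
    plus, _, _ = paired_seed7
    res = annotate_dataset(plus, db, seed=7)
    m0_accepted = [c for c in res.accepted if c.br_mass_number == 79]
    assert all(c.q_value <= 0.05 for c in m0_accepted)


def test_fdr_pure_noise_accepts_nothing(db):
    noise_only = NoiseModel()
    layout, panel, _ = default_scenario()
    from carbmsi.synthetic import GroundTruthPanel
    d, _ = simulate_dataset(layout, GroundTruthPanel(()), noise_only,
                            edc_used=True, seed=11)
    res = annotate_dataset(d, db, seed=11)
    assert len(res.accepted) == 0


def test_fdr_requires_decoys(paired_seed7, db):
    plus, _, _ = paired_seed7
    with pytest.raises(ValueError, match="n_decoys"):
        estimate_fdr([], plus, db, n_decoys=0, seed=1)


def test_fdr_empirical_rate_over_seeds(db):
    """Accepted sets stay clean (empirical FDR ≤ 0.3 at nominal 0.2) across seeds."""
    layout, panel, noise = default_scenario()
    truth_ids = {m.record.id for m in panel.members}
    false_hits = total_hits = 0
    for seed in range(20):
        d, _ = simulate_dataset(layout, panel, noise, edc_used=True, seed=seed)
        res = annotate_dataset(d, db, seed=seed)
        ids = res.accepted_ids
        total_hits += len(ids)
        false_hits += len(ids - truth_ids)
    assert total_hits > 0
    assert false_hits / total_hits <= 0.3


def test_result_export_schema(paired_seed7, db, tmp_path):
    plus, minus, _ = paired_seed7
    res = annotate_dataset(plus, db, paired=minus, seed=7)
    frame = result_to_frame(res)
    assert {"metabolite", "br_mass_number", "theoretical_mz", "status",
            "br_verification", "edc_class", "q_value"} <= set(frame.columns)
    from carbmsi.annotation import write_result
    write_result(res, tmp_path / "r.tsv", tmp_path / "r.json")
    assert (tmp_path / "r.tsv").exists() and (tmp_path / "r.json").exists()
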