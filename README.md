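# carbmsi

Derivatization-aware annotation of carbonyl metabolites in MALDI mass
spectrometry imaging (MSI).

Carboxylic acids, ketones and aldehydes ionize poorly in positive-mode MALDI
and are nearly invisible from agar-grown microbial cultures. On-tissue
chemical derivatization with 4-APEBA — a reagent carrying a permanent
positive charge and a single bromine atom — converts each carbonyl analyte M
into the cation **[M + C₁₈H₂₂N₂Br]⁺** (mass shift +345.0966 Da for the
neutral modifier). The bromine brings a diagnostic isotope doublet: ⁷⁹Br and
⁸¹Br are 50.69 % / 49.31 % abundant, so every genuine derivative shows an
M+0 / A+2 peak pair of nearly equal intensity, 1.9980 Da apart. A second
chemical lever is the activator EDC: 4-APEBA alone derivatizes only ketones
and aldehydes; with EDC it also derivatizes carboxylic acids. Running a
sample with and without EDC therefore encodes functional-group information
in each annotation's presence pattern.

`carbmsi` implements the full reasoning chain for this kind of experiment:

- **`carbmsi.chem`** — elemental-formula parsing, monoisotopic masses from a
  shipped isotope table, tagged-cation m/z (electron mass subtracted for the
  +1 charge), and isotope-envelope simulation with resolution-dependent
  centroid merging (default R = 110,000 at m/z 400, FTICR-style m² scaling).
- **`carbmsi.metabolites`** — metabolite records with carboxyl / ketone /
  aldehyde counts, derivatizability rules under EDC±, and the EDC truth
  table: detected in both runs → contains ketone/aldehyde; only with EDC →
  carboxyl only; neither → absent; only without EDC → flagged inconsistent.
- **`carbmsi.msi`** — pixel-grid datasets of centroid spectra (plain
  JSON + TSV on disk), region masks (`f` isolated fungus, `b` isolated
  bacterium, `i` interaction zone), ion-image extraction in a closed ±ppm
  window, and cosine colocalization.
- **`carbmsi.annotation`** — candidate generation (M+0 and A+2 hypotheses
  per metabolite), 3-ppm matching, Br-doublet verification (observed
  A+2:M+0 ratio within [0.5, 2]× the theoretical envelope ratio and
  colocalization ≥ 0.7), staged isobar/isomer resolution, and a simplified
  target–decoy FDR (default 20 %).
- **`carbmsi.region_stats`** — Mann–Whitney ROC AUC of ion-image intensities
  between region masks: AUC = P(random pixel in A outranks random pixel in
  B), ties credited 0.5.
- **`carbmsi.synthetic`** — a seeded generator of paired EDC± co-culture
  datasets with ground truth (spatial archetypes, Br doublets, EDC kinetics,
  ppm jitter, lognormal intensity noise, chemical background), so the whole
  pipeline is testable without any downloads.
- **`carbmsi.cli` / `carbmsi.spray`** — a `carbmsi` command-line tool
  (`simulate`, `annotate`, `classify-edc`, `discriminate`, `verify`,
  `coverage`) and the sprayer deposition calculator
  coverage = 100 · c·F·n / (v·s) µg/cm².

## Formula grammar

Hill-style element–count text, counts defaulting to 1: `C18H22N2Br`,
`C9H13NO5`, `H2O`. A bracketed isotope prefix locks every atom of that
element to one mass number: `C18H22N2[81Br]` is the A+2 isotopologue of the
tag. The isotope table ships as `carbmsi/data/isotopes.tsv`
(element, mass number, mass, abundance).

## Worked example

```python
import carbmsi as cm

# the two isomer pairs from the worked annotation examples
acetoin = cm.parse_formula("C4H8O2")
print(round(cm.derivatized_mz(acetoin, cm.APEBA, 79), 4))   # 433.1485
malate = cm.parse_formula("C4H6O5")
print(round(cm.derivatized_mz(malate, cm.APEBA, 79), 4))    # 479.1176

# end-to-end on the shipped synthetic co-culture scenario
layout, panel, noise = cm.default_scenario()
plus, minus, truth = cm.simulate_paired(layout, panel, noise, seed=7)
result = cm.annotate_dataset(plus, cm.demo_db(), paired=minus, seed=7)
print(len(result.accepted_ids))                             # 15
print("butanoate" in result.accepted_ids)                   # False
print("acetoin" in result.accepted_ids)                     # True

table = cm.discriminate_all(plus, cm.build_masks(layout), result)
print(table.head(2).to_string(index=False))
# metabolite comparison      auc  n_a  n_b
#    acetoin     b vs i 0.001548  197  200
#    acetoin     f vs i 0.000000  197  200
```

All 15 emitted panel members are accepted; the mass-tied confounders are
rejected for the chemically right reasons (kinetin: no derivatizable
carbonyl; methionine: missing ⁸¹Br partner — the 494.147 peak is glutamate's
A+2; butanoate and dehydrothreonate: contradicted by the EDC± presence
pattern). Acetoin's AUC ≈ 0 for "b vs i" means interaction-zone pixels
dominate the isolated bacterial colony — the induced-in-interaction
phenotype.

The same chain from a shell:

```bash
carbmsi simulate --seed 7 --out run/
carbmsi annotate --dataset run/edc_plus --paired run/edc_minus \
        --out run/plus.tsv --report run/plus.json --seed 7
carbmsi annotate --dataset run/edc_minus --paired run/edc_plus \
        --out run/minus.tsv --seed 7
carbmsi classify-edc --minus run/minus.tsv --plus run/plus.tsv \
        --out run/classes.tsv
carbmsi discriminate --dataset run/edc_plus --masks run/masks.json \
        --annotations run/plus.tsv --out run/auc.tsv
carbmsi coverage -c 40 -f 50 -n 12          # 667
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the installed package alone, the headline desk-scale
quantities: the neutral modifier mass, the kinetin / succinyl-proline
formula-mass gap, five published tagged-cation m/z values, and the two
sprayer coverage figures, and writes them as JSON keyed by target id.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
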