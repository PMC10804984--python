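# Methods

## The measurement being modeled

Positive-mode MALDI imaging of microbial colonies on agar cannot see most
carboxyl-, ketone- and aldehyde-bearing metabolites. Derivatizing the sample
with 4-APEBA attaches a permanently charged, singly brominated tag to each
carbonyl group, so every analyte M appears as the cation [M + C18H22N2Br]+.
Annotation then rests on three independent pieces of evidence:

1. **accurate mass** — the tagged cation's m/z within a ppm window;
2. **the bromine doublet** — ⁷⁹Br/⁸¹Br are 0.5069/0.4931 abundant, so a real
   derivative has an A+2 isotopologue of near-equal intensity 1.9980 Da above
   M+0, colocalized with it;
3. **EDC-differential chemistry** — without the activator EDC only ketones
   and aldehydes react; with it carboxyls react too, so paired EDC± runs
   classify each annotation's functional groups.

`carbmsi` implements each evidence channel and their combination, plus a
synthetic data generator that emits exactly this structure with known truth.

## Mass arithmetic

Monoisotopic mass selects each element's *most abundant* isotope (identical
to the lightest for C/H/N/O/S/Br). Cation m/z subtracts one electron mass
(5.4858e-4 Da); the printed worked examples (433.1485, 479.1176, 492.1492,
494.1471) reproduce only under this convention, so the +345.0966 Da modifier
value is interpreted as the *neutral* formula mass. Isotope masses and
abundances are stored at full published precision in
`carbmsi/data/isotopes.tsv`; rounded views like "51 % / 49 %" are derived,
not stored.

One documented discrepancy: the published figure caption states the
methionine M+0 (C5H11NO2S, ⁷⁹Br) and glutamate A+2 (C5H9NO4, ⁸¹Br) cations
"differ by 0.4 mDa"; recomputation from standard isotope masses gives
≈ 0.06 mDa (494.14714 vs 494.14720). The package computes, it does not
match the 0.4; either way the pair is far inside a 3-ppm window and the
collision is real.

## Isotope envelopes

Envelopes are exact multinomial expansions computed per element by repeated
convolution (pruned at 1e-10 relative probability by default), then merged:
two centroids closer than the local Gaussian FWHM coalesce into their
intensity-weighted centroid, iterated to a fixed point. The FWHM model is
FTICR-like — resolving power falls as 1/m, so FWHM(m) = m²/(R·400) with
R = 110,000 specified at m/z 400. At that resolution the ⁸¹Br peak and the
¹³C₂+⁷⁹Br peak (8.8 mDa apart) merge for cations heavier than ≈ 620 m/z and
stay resolved below; the theoretical A+2:M+0 ratio used for verification is
taken from the same envelope code in both the generator and the verifier, so
the two sides of the check share one definition. The tag's M+0/A+2 peaks
(2 Da apart) can never merge under this model.

Not modeled: fine structure within a nominal mass beyond the merge rule,
multiple charging, and any adduct other than the single tag.

## Detection and verification defaults

| parameter | default | why |
|---|---|---|
| match tolerance | 3 ppm | the instrument's stated MS1 confidence |
| min. detection fraction | 1 % of grid pixels | rejects single stray background hits |
| min. total intensity | 5 × median centroid intensity | the median tracks chemical background |
| A+2:M+0 ratio band | [0.5, 2.0] × theoretical | "similar intensity" made operational |
| min. colocalization | cosine ≥ 0.7 | "same spatial localization" made operational |
| FDR level | 0.20 | the annotation platform's customary level |

The ratio band and colocalization floor are package choices (no numeric
values are published for "similar"); both are exposed as arguments. The ion
image window is closed (boundary peaks at exactly ±3 ppm are included) so
tie behaviour is deterministic.

## Isobar resolution order

Mass-overlapping detections (mutual 2×tol window, so a 1.3-mDa pair at
m/z 560 — 2.3 ppm apart — groups at 3 ppm tolerance) are resolved in a fixed
elimination order: (1) derivatizability under the run's EDC condition,
(2) Br-doublet verification (an A+2 hypothesis also dies with its M+0
partner), (3) consistency with the paired-run EDC class, (4) smallest
|mean ppm error|, with exact ties kept and flagged AMBIGUOUS rather than
silently resolved. A hypothesis eliminated at one stage is never revived.
The pipeline generates hypotheses for *all* database entries (including
non-derivatizable ones) precisely so stage 1 can reject them explicitly —
that is the kinetin-vs-succinyl-proline argument in code form.

## Decoy FDR

The FDR stage is a deliberate simplification of the METASPACE MSM score (no
spatial-chaos term). Decoy hypotheses swap the tag for draws from a fixed
20-member alphabet of bromine-free elemental modifiers with masses
bracketing 345 Da. Targets and decoys are matched and scored identically
(detection fraction × Br-ratio closeness × colocalization, all in [0, 1]);
q = (decoy hits ≥ score / n_decoys) / (target hits ≥ score), made monotone.
A score of exactly 0 (no doublet or colocalization evidence at all) is
assigned q = 1 regardless of decoy counts. Because decoys lack bromine, a
chance decoy detection almost never carries doublet support — the score
composition, not just the mass window, is what separates the populations.

## EDC truth table

(detected without EDC, detected with EDC) maps to: (T,T) contains a
ketone/aldehyde; (F,T) carboxyl only; (F,F) absent or unreactive; (T,F)
INCONSISTENT. The last combination is kept explicit rather than coerced:
ketones react *more strongly* without EDC (the generator models this with a
2× kinetics factor), so a borderline species genuinely can drop below the
detection threshold only in the EDC+ run.

Functional-group counts are database columns, not computed from structures;
a lactone with no free carbonyl is "not derivatizable" in this model, which
is a known limitation. Reducing sugars in the demo database are marked
aldehyde = 1 under the open-chain interpretation (flagged in the resource
file's notes column).

## ROC/AUC

AUC uses the Mann-Whitney formulation via `scipy.stats.mannwhitneyu`
(midranks, ties credited 0.5); the exhaustive pair-counting oracle lives in
the test suite only. Raw intensities are used — no TIC/RMS normalization —
and AUC is invariant to any strictly monotone transform, so this choice only
matters through the detection thresholds. No multiple-testing correction is
applied to AUC tables. Pixels without spectra are excluded from masks at
computation time.

## Synthetic generator: what it does and does not emulate

The default scenario is a 60×40 grid at 100 µm: an isolated fungal disk
(r = 8 px), an isolated bacterial disk (r = 8 px) and a 10×20 interaction
band — each region ≈ 200 pixels. Fifteen panel members drawn from the named
metabolites of the co-culture study each carry a spatial archetype
(per-region multipliers, e.g. induced-in-interaction = {isolated 0.3,
interaction 1.0}); the archetype assignments are generator defaults
patterned on the described phenotypes, not source-data claims. Four
confounders sit in the database but are never emitted (kinetin, methionine,
butanoate, dehydrothreonate), so isobar resolution is exercised for real.

Per pixel and member, the generator emits the M+0 and A+2 centroids at the
exact theoretical m/z (envelope-ratio intensities), multiplies by the
archetype and EDC-kinetics factors (oxoacids 0.5×, plain ketones 2× without
EDC), then applies 0.5-ppm Gaussian m/z jitter and unit-mean lognormal
intensity noise (σ = 0.3). Background is Poisson (10 peaks/pixel) uniform
over m/z 350–700 with lognormal intensities (median 50 against a base
signal of 1000). All draws come from `numpy.random.default_rng([seed,
condition])`, so an EDC± pair shares its base seed and datasets are
bit-reproducible across platforms.

What a green end-to-end test establishes: the pipeline's logic — matching,
doublet verification, EDC classification, isobar elimination, FDR and AUC
directions — is correct on data with exactly the structure the chemistry
predicts. What it does not establish: robustness to matrix effects, ion
suppression, peak-picking artifacts, mass-calibration drift, diffusion of
metabolites through agar, or real-data background correlation structure —
none of which the generator emulates. The 0.5-ppm jitter keeps true peaks
inside the 3-ppm window with probability ≫ 99.9 % (a 6 σ event is required
to escape).

A derived note on recovery fidelity: for observed = truth × L with unit-mean
lognormal L, the expected Pearson correlation between an extracted ion image
and its truth map is √(Var(t)/(Var(t)+cv²·E[t²])) with cv² = e^{σ²}−1 ≈
0.094, i.e. ≈ 0.94 for the default geometry — the tests check this analytic
value rather than a round number.

## Numerical conventions

- Mass comparisons against 4-dp printed values use 0.5 mDa absolute
  tolerance (one printed value, 447.1641, recomputes 0.07 mDa higher).
- Internal dataset format: JSON header + TSV peaks; intensities round-trip
  bitwise (`repr` float serialization, pandas `float_precision="round_trip"`
  parsing), m/z to 1e-9 Da (9 written decimals).
- Coordinates are 0-based, x rightward, y downward, row-major; ion images
  are (height × width) arrays.
- Sprayer coverage = 100·c·F·n/(v·s) µg/cm², printed rounded to integer to
  match protocol-style "~" values; full precision in JSON output.

## Known limitations

- No imzML reader: only the documented internal format is supported (the
  usual imzML libraries are not part of this environment).
- The decoy FDR is not equivalent to METASPACE's MSM; headline annotation
  counts from real datasets are out of reach by design.
- Functional groups are declared, not perceived from structure.
- Double/multiple derivatization is not modeled (none was observed in the
  standards experiments this package mirrors).
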