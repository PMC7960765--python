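# Methods

## Scientific setting

Plant prolyl 4-hydroxylases (P4Hs) convert peptidyl-proline to
4-hydroxyproline (Hyp, +15.9949 Da), the anchor of plant-specific
*O*-glycosylation. On an LC-ESI-MS trace a peptide with n hydroxylations
appears as a ladder of species shifted by n·15.9949/z m/z units; the package
quantifies how the 0..k-Hyp species of a peptide family are distributed,
localizes which prolines carry the oxygen from MS/MS fragments, estimates
Michaelis–Menten parameters of P4H enzymes from endpoint assays, and derives
position-specific sequence motifs of the hydroxylated sites. Because no raw
instrument data are publicly deposited for this system, every analysis runs
against ground-truthed synthetic data produced by generators that emulate
the relevant features of Q-TOF measurements.

## Mass and envelope arithmetic

All masses are monoisotopic and derive from one embedded isotope table
(`data/isotopes.csv`, IUPAC representative masses and abundances). A
peptidoform (sequence + positioned modifications) maps to an elemental
composition (residues + water + modification deltas); two built-in
modifications cover the workflow: oxidation (+O, on Pro) and
carbamidomethylation (+C2H3NO, on Cys, applied as a fixed modification to
every cysteine, matching iodoacetamide alkylation during sample
preparation). Ions are `m/z = (M + z·m_H+ + adduct)/z`; the ammonium adduct
adds 17.026549 Da on top of protonation.

Isotope envelopes use the aggregated (unit-spaced) model: per-element
single-atom patterns keyed on nominal mass offset are convolved by binary
exponentiation, truncated and renormalized. Fine isotope structure is
irrelevant at the four-peak level used for quantification. Aggregated peaks
are spaced by the ¹³C–¹²C mass difference (1.0033548 Da), the dominant
contributor for peptides.

Tryptic digestion cleaves C-terminal to K/R except before P; with m missed
cleavages every union of ≤ m+1 adjacent fragments is emitted with 1-based
inclusive coordinates. Residue numbering is 1-based throughout, so the
untouched IgA1 prolines are positions 4, 6 and 22.

## Synthetic LC-MS1 runs

The generator's defaults are the study conditions, chosen once:

| parameter | default | why |
| --- | --- | --- |
| charge weights | {2+: 0.7, 3+: 0.3} | peptides of this size ionize mainly 2+/3+ |
| retention centers | 3.0 + 0.4·n_ox min | oxidation states chromatographically separated |
| peak width (σ) | 0.06 min | capillary-LC-scale peaks |
| scan interval | 0.02 min | ≥ 5 scans per σ, adequate for trapezoidal areas |
| m/z tolerance | 10 ppm | Q-TOF-plausible; configurable, not a measured value |
| total signal | 10⁶ counts | arbitrary scale; only ratios matter |
| noise | lognormal, unit mean, σ = CV | multiplicative detector noise |

Each species (oxidation count × charge × adduct state) contributes its first
12 isotope peaks (all but ~10⁻⁶ of a 4 kDa peptide's envelope) as Gaussian
elution profiles whose integrated area is fraction × charge weight × adduct
split × envelope abundance. Runs are pure functions of the configuration and
seed. The generator self-checks the adduct-interference geometry: the
[M+NH4]⁺ monoisotopic peak of the n-ox species must lie within the
configured tolerance of the +1 isotope peak of the (n+1)-ox species at 2+
(gap = (17.0265 − 15.9949 − 1.0034)/2 ≈ 0.014 m/z), otherwise simulating an
adduct fraction is refused — interference that cannot happen should not be
silently faked.

What the generator does *not* emulate: profile-mode peaks, resolution-
dependent peak shapes, isotope-dependent ionization, in-source
fragmentation, co-eluting background, retention-time drift. Passing
recovery tests therefore demonstrates correctness of the quantification
arithmetic under clean centroids, not robustness to real chromatographic
pathology.

## Stoichiometry quantification

For each oxidation count the extracted-ion-chromatogram areas of the first
four isotopic peaks are summed over all charge states and normalized to
100%. The m/z ladder of an oxidation state is independent of which proline
is oxidized, so positional isomers pool automatically; resolving them is
the MS/MS localizer's job.

Numerical choice: each species' four-peak sum is divided by the theoretical
envelope share of those four peaks (`envelope_correction=True`). Each
oxidation adds an oxygen and slightly reshapes the envelope, so the
uncorrected shares differ by ~5·10⁻⁴ across the 0..6-Hyp family — harmless
for biology but enough to flip a printed 2-decimal average sitting at a
rounding boundary. With the correction, noiseless recovery is exact to
~10⁻⁶; the uncorrected literal summation remains available as
`envelope_correction=False`.

Ammonium adducts put the [M+NH4]⁺ peak of the n-ox species inside the
instrument window of the (n+1)-ox species' +1 isotope peak, inflating
four-peak abundances of higher oxidation states. The fallback quantifies
monoisotopic peaks only (`n_iso = 1`), which that adduct cannot contaminate.
`detect_adduct_overlap` derives the at-risk (n_ox, charge) pairs from the
mass constants and the tolerance; `--mode auto` switches to the fallback
when overlap is geometrically possible and adduct signal is configured.

Table statistics follow the printing conventions of such reports: the
average Hyp count is Σ n·f_n/100 over the percentages *as printed* (no
renormalization when a row sums to 99.9 or 100.1), rounded to 2 decimals
half away from zero; percent change versus control is computed from
unrounded averages and rounded to the nearest integer. One consequence,
verified in the tests: a published control row whose percentages sum to
100.1 prints an average (1.33) that a measured distribution — which
necessarily sums to 100 — reproduces only as its renormalized value (1.32);
the percent changes, being scale-free ratios, reproduce exactly.

## Site localization

Theoretical fragments are singly charged b/y ions; a placement of n
oxidations over the prolines is scored by the number of observed peaks
greedily matched one-to-one within tolerance, and all C(#Pro, n) placements
are scored. Scoring is intensity-blind: presence of the discriminating
fragment is the evidence, and the simulated uniform-intensity spectra carry
no more information than that. Equal-best placements are returned in
`ambiguous_with` rather than broken arbitrarily — a spectrum missing the
b/y ions between two candidate prolines genuinely cannot distinguish them.
Multiply charged fragments and neutral losses are out of scope.

## Kinetics

Each assay row is one stopped reaction: product formed is
`vmax·S/(Km+S)·t` (initial-rate regime; conversions implied by the
study-scale parameters are ≪ S over 20–30 min, so progress-curve curvature
is negligible). Quantification uses the shared-response-factor assumption:
the internal standard (a 24-mer threonine-rich peptide at fixed
concentration) relates to the substrate exactly as to the product, so
`[P] = S0·A_P/(A_S + A_P)`; the IS-normalized algebraic route reduces to
the same expression and the implementation asserts their agreement at
1e-9 on every call. Velocities are [P]/t with equal weights (no replicate
structure exists to estimate a variance model). Fitting is nonlinear least
squares on v = vmax·S/(Km+S) (scipy `curve_fit`, positivity bounds),
initialized from a Hanes–Woolf linearization (better conditioned than
Lineweaver–Burk when low-S points are sparse); standard errors come from
the Jacobian covariance.

Diagnostic worth stating: the assayed grid spans 22–5610 μM (8 log-spaced
points), so for an enzyme with Km = 8 μM every measurement sits above Km
and the estimate rests on extrapolation; with 2% area noise the median
recovered Km over 100 simulated assays is ~7.8 μM (≈ 2% low), and the
spread grows as min(S)/Km grows. Problem sizes (8 concentrations, 100
seeds) match the assayed design.

## Motifs

A motif is an ordered list of allowed-residue sets over a −1..+3 window
anchored on the modified proline — the five-residue context established for
plant P4H substrates. Consensus is the per-offset union of residues
observed around confirmed sites (sets, not weight matrices: the available
site lists are qualitative). Sites whose window crosses a terminus are
excluded from derivation and reported; matching is strict at termini.
Serialization uses bracket notation (`[STP]-P-[STP]-[TP]-[SP]`), with
`P`/`Pro` marking the anchor. The seven confirmed IgA1 sites yield
[STP]-P-[STP]-[TP]-[SP], matching exactly those seven prolines; the broader
literature variant with V in the −1 set additionally matches P6, a proline
never observed oxidized — the derivation-vs-matching asymmetry the tests
pin down. No enrichment statistics or de-novo discovery are attempted.

## Known limitations

- Centroid positions are exact in simulation; mass-accuracy error is
  expressible only through the matching tolerance, not through peak jitter.
- Stoichiometry recovery tolerances (1e-3 noiseless, 2 points at 2% noise)
  were measured on the simulator and hold for clean centroids only.
- The localizer's score has no probabilistic calibration; ties are the only
  uncertainty it reports.
- Glycoforms (pentose on Hyp, +132.0423 Da) are representable as an EIC
  target but carry no dedicated statistics.
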