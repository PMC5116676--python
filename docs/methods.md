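# Methods

## Overview

`glycotyper` implements a three-stage pipeline for HCD glycoproteomics:
oxonium-based spectrum triage, logistic N/O glycosylation-type
classification, and intact glycopeptide identification by precursor-mass
matching with decoy-based FDR control. This note records the models,
conventions and design choices, what the synthetic data do and do not
emulate, and the problem sizes used by the test suite and the acceptance
script.

## Spectrum preprocessing and the oxonium filter

Spectra are read from mzML 1.1, mzXML 3.x or MGF. MGF parsing goes through
pyteomics; the mzML/mzXML readers are intentionally minimal lxml-based
extractors of MS2 essentials (precursor m/z and charge, retention time,
base64 peak arrays with none/zlib compression at 32- or 64-bit precision).
Precursor charge screening (keep 2+ … 8+, mirroring a typical acquisition
filter) is applied at read time and can be disabled.

Intensity-rank operations use one deterministic tie-break throughout: peaks
rank by (intensity, then m/z) ascending, so among equal intensities the
lowest-m/z peak is dropped first from the bottom fraction and admitted last
to the top fraction. Bottom-fraction removal (default 10% of the peak
*count*, the plain reading of "lowest peaks") uses floor, top-fraction
selection uses ceil, so a nonzero fraction on a nonempty spectrum always
retains at least one top peak.

A spectrum qualifies as oxonium-ion containing when at least 2 of the 10
diagnostic ions (nominal m/z 138, 145, 163, 168, 186, 204, 274, 292, 325,
366) are found among the top 5% of peaks, with the HexNAc ion at 204
mandatory. Ion m/z values are exact monoisotopic masses computed from the
cation elemental formulas (e.g. HexNAc⁺ = C₈H₁₄NO₅⁺ = 204.0867), not the
nominal integers; matching uses the MS2 tolerance of 20 ppm, taking the most
intense peak inside a window. The complex-sample ("serum") preset widens the
top fraction to 10% and waives the intact-peptide-ion rule below.

## Classification model

The 9 features are the intensities of the non-reference ions divided by the
204 intensity — dimensionless ratios, invariant to the instrument's
intensity units. A spectrum without a 204 peak is unclassifiable and is
reported as such rather than silently imputed.

Two classes reduce multinomial logistic regression to the binomial model
p(O | x) = σ(wᵀx + b). The fit (scikit-learn, lbfgs, tolerance 1e-8, ≤ 500
iterations) carries an L2 penalty of strength 1e-4 on the weights: away from
separation this is maximum likelihood for all practical purposes, and under
the perfect or quasi-separation that clean synthetic data produce it keeps
the solution finite and deterministic. The decision threshold is fixed at
0.5 with ties assigned to O (arbitrary but deterministic); every call
returns the probability of the assigned class, which flags gray-zone
spectra. Class imbalance is left unweighted.

Per-feature Wald p-values come from the penalized observed information
X'WX + αI (intercept unpenalized), W = diag(p(1−p)). Caveat: on jointly
separable data the Wald statistic degenerates (coefficients grow, standard
errors grow faster) and the p-values are uninformative — the acceptance
script therefore evaluates the significance of the 186/204 feature under a
configuration where only that feature separates the classes and the test is
calibrated. Cross-validation defaults to stratified 10-fold with a seeded
shuffle; the report pools out-of-fold predictions into an overall accuracy
and per-class true rates. Models serialize to JSON (schema-versioned,
weights at full double precision).

## Peptide and glycan databases

In-silico tryptic digestion cleaves C-terminal to K/R except before P, with
up to 2 missed cleavages, peptide length 5–60 by default (max length is a
config knob, default 70), and 0–2 variable Met oxidations per peptide.
Carbamidomethyl-Cys (+57.021464) is a fixed modification, matching
iodoacetamide alkylation; it is toggleable in principle by editing the
residue table. N-glycosylation sequons are N-X-[S/T/C/V] with X ≠ P,
scanned with overlap. Because only an oxidation *count* is stored, fragment
ions place oxidation on the first n methionines from the N-terminus — a
deterministic convention that affects individual b/y m/z values but not the
peptide mass.

Glycans are compositions (HexNAc/Hex/Fuc/Neu5Ac counts) with canonical form
`N#H#F#S#`; topology and linkage are out of scope. Decoy peptides are built
by concatenating every target sequence, shuffling the pooled residues with a
seeded RNG, and re-cutting into pieces whose lengths are exactly the target
length multiset — amino-acid composition is conserved exactly ("lengths
similar to the targets" is read in its strongest reproducible form). Decoys
carry no motif annotation and are paired with glycans without motif gates:
they exist solely to estimate error rates, and requiring sequons of shuffled
sequences would starve the decoy space and bias the FDR estimate low.

## Scoring and FDR

For a candidate (peptide, glycan) the theoretical ions are all singly
charged b_i/y_i (i = 1..len−1, modifications applied) plus the Y series:
the peptide carrying every sub-composition of the glycan, from Y0 (bare
peptide) upward, capped defensively at 400 sub-compositions. The modified
Morpheus score is

    S = n_matched + matched_fraction

where n_matched counts distinct theoretical ions with an in-tolerance peak
(each ion matches its nearest peak within 20 ppm; a peak's intensity counts
once even if several ions hit it) and matched_fraction is the summed
intensity of matched non-oxonium peaks divided by (total intensity − oxonium
intensity). Excluding oxonium intensity keeps the disproportionately
abundant glycan ions of N-glycopeptide spectra from dominating the
fractional term. The fraction is clamped to just below 1 (1 − 1e-10) so that
floor(S) always recovers the matched-ion count, including at exact full
coverage. Peptides shorter than 11 residues additionally require a matched
Y-series ion (intact peptide with or without partial glycan).

Candidates are generated by precursor neutral-mass matching at 10 ppm:
N-glycan pairings require a sequon, O-glycan pairings an S/T. No ±1 Da
isotope correction is applied to the precursor. Each spectrum contributes
its single best GPSM (ties: decoy preferred — conservative — then smaller
glycan, then lexicographic peptide). A descending-score sweep estimates
FDR = #decoy / max(#target, 1) and accepts the largest target set at or
below the requested level (default 1%).

In pre-classification mode the classifier assigns each oxonium spectrum to
N or O and only that glycan space is searched; the scored candidate volume
is never larger than in conventional mode. Training-set curation keeps
FDR-accepted GPSMs whose peptide overlaps a known glycosite, with intensity
coverage ≥ 10% and total spectrum intensity ≥ 5×10⁵, and restricts O-linked
GPSMs to sequon-free peptides; "intensity coverage" is the matched fraction
of the assigned GPSM.

## Synthetic data

The generator emulates the spectral features the pipeline consumes: the 10
oxonium ions at exact m/z with class-conditional log-normal ratios
(defaults — O: median 186/204 = 0.9, Neu5Ac ions 0.5–0.6, 366 = 0.15, Hex
ions ≈ 0.02; N: 186/204 = 0.12, Hex ions ≈ 0.2, 366 = 0.5, Neu5Ac ions
≈ 0.1; dispersion σ = 0.4 in log space), a Bernoulli-thinned b/y ion set
(inclusion 0.7) and nested Y ladder (0.8) with exponential intensities,
uniform-m/z noise peaks with exponential intensities, Gaussian m/z jitter
truncated at 3σ (5 ppm MS2, 2 ppm MS1), and a base 204 intensity of 10⁶
counts. The ratio medians are plausible settings expressing the qualitative
N/O ordering, not measurements. Non-oxonium peaks are kept out of a 30 ppm
guard band around the table ions so planted ratios stay unambiguous; the
default class split is 872 N / 527 O. Peptides come from ten synthetic
250-residue proteins drawn with K/R- and N/S/T-enriched residue frequencies;
glycan lists are a 12-composition N set (high-mannose plus complex) and a
10-composition O set (mucin-type), both containing the ambiguous N3H3F0S0.

Not emulated: real fragmentation physics (mobile proton, glycan
rearrangement), isotope envelopes, co-isolation, retention-time structure,
and instrument-specific intensity response. Passing tests therefore
demonstrate algorithmic correctness on spectra with known structure — not
classification accuracy on measured data, where class separation is weaker
than the generator's defaults produce (cross-validated accuracy saturates at
100% here precisely because the planted separations are clean).

## Problem sizes and numerical choices

The test suite and acceptance script use: the 1,399-spectrum default
training set for classifier checks; 1,000 spectra per class for
distributional fidelity; 100–300 noiseless spectra for exact-recovery and
search-mode checks; and 10–20 replicate searches of 500 spectra each for
FDR calibration. Scores compare to independent brute-force oracles at 1e-9;
masses assert at 1e-4–1e-6 Da; ion table values at 0.001 Th. All RNG flows
through numpy Generators seeded from explicit arguments; identical
configurations produce byte-identical generator output.

## Known limitations

- Only compositions, not glycan structures, are searched; branch-dependent
  oxonium effects (e.g. the 366 intensity rising with antenna count) are
  outside the model.
- Wald p-values are reported as missing/uninformative under separation
  rather than replaced by a penalized-likelihood-ratio alternative.
- The mzML/mzXML readers cover centroided numeric arrays and MS2 precursor
  metadata only; vendor rawfiles and profile-to-centroid conversion are out
  of scope.
- ETD/EThcD spectra, glycosite localization within multi-site peptides and
  mzIdentML export are not implemented.
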