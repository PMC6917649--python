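# Methods

## The measurement model

The package models a routine reversed-phase UPLC-DAD quantitation
workflow for hop tissues. A single-wavelength chromatogram is treated as

absorbance(t) = Σᵢ Aᵢ · N(t; RTᵢ, σ) + b + ε(t),

a sum of Gaussian peaks on a constant baseline *b* with white detector
noise ε. Each analyte's true peak area is Aᵢ = rᵢ·cᵢ, the product of a
per-channel response factor (mAU·min per mg/ml) and the injected solution
concentration. Quantitation inverts this chain: detect peaks, integrate
the area above a local baseline, convert area to concentration through a
linear calibration curve, and convert concentration to percent of sample
dry weight through the extraction bookkeeping

%dw = 100 · c · D · V / m,

with *c* the measured concentration (mg/ml), *D* the dilution factor, *V*
the pooled extract volume and *m* the extracted mass (mg). Defaults encode
the study's sample prep: cones 0.5 g into 2 × 25 ml, leaves ~200 mg into
2 × 5 ml — so for cones 1 mg/ml corresponds to 10% dw.

Three quantitation conventions are modelled:

* **Prenylchalcones** (370 nm) are quantified as xanthohumol equivalents
  and **leaf flavonols** (350 nm) as quercetin-3-*O*-rutinoside
  equivalents: one calibration curve per family, applied to every member.
  In the forward model all members of a family share the reference
  compound's response factor, so equivalent-scale and true amounts
  coincide and round-trip tests are exact.
* **Bitter acids** (320 nm) are calibrated against the ICE-3 reference
  extract with defined mass fractions (cohumulone 13.88%, n+adhumulone
  30.76%, colupulone 13.44%, n+adlupulone 10.84% w/w): a standard
  injection fixes each analyte's response factor as area divided by its
  known concentration.

Calibration curves are unweighted ordinary least squares of area on
concentration (y = mx + b), fitted to 7 geometric levels spanning
0.001–0.5 mg/ml in three independent series. Responses below the lowest
calibrant are reported and flagged rather than censored, because trace
levels of the cone markers matter for classification; responses above the
calibrated range raise an error advising dilution.

## Trait statistics and chemotype rules

Cone traits: total prenylchalcones = XHU + DXH + XGA + MXH; total alpha
acids Σα = COH + (n+ADH); total beta acids Σβ = COL + (n+ADL); cohumulone
proportion = COH/Σα; alpha ratio Pα = Σα/(Σα + Σβ). Leaf traits: total
flavonol glycosides (sum of the six) and the malonyl proportion
(malonylated kaempferol + quercetin glucosides over the total). Ratios
with zero denominators report NaN and propagate as "unavailable" calls.

Replicates aggregate as mean ± SE with SE = sd(n−1)/√n, undefined for a
single replicate. Group summaries are *unweighted* means over
per-accession means — the convention that reproduces a published
collection average from a table of per-accession values — with SE taken
across accessions.

Chemotype rules:

* cone: XGA > θ and MXH > θ → lupuloides; both ≤ θ → lupulus; exactly one
  above → atypical (the rule is not extrapolated to single-marker cones,
  which the survey never observed). θ defaults to 0.001% dw, a
  concentration floor of the order of the lowest calibration level, so
  integration noise cannot flip a call; it is overridable.
* leaf: malonyl proportion < 0.10 → lupuloides-type, > 0.20 →
  lupulus-type, inside [0.10, 0.20] → indeterminate. The survey's two
  chemotypes never fall in the gap; "indeterminate" is this package's
  convention for it, not an observed category.

Concordance is the fraction of accessions where both rules give definite,
matching calls; atypical/indeterminate/unavailable calls are excluded
from the denominator and reported separately.

## MS annotation

Flavonol glycoside candidates are sums of monoisotopic building blocks:
kaempferol 286.0477, quercetin 302.0427, +hexose 162.0528, +rutinose
308.1107, +malonyl 86.0004 Da. Ion series: positive mode [M+H]⁺ plus the
protonated aglycone (glycoside loss) for non-acylated candidates;
negative mode [M−H]⁻ and [2M−H]⁻, plus the decarboxylation fragment for
malonyl esters, modelled as the deprotonated molecule minus neutral CO₂
(43.9898 Da) — the numeric values printed as "[M−CO₂]⁻" in unit-resolution
ion tables fit this interpretation. Proton mass 1.00728 Da.

Annotation scores a candidate by the fraction of its predicted ions
matched within a tolerance (default 0.5 Da, a unit-resolution tandem
quadrupole; configurable for high-resolution data). Relative abundances
are kept as metadata but never scored — they are tune- and
matrix-dependent. Ties break by λmax proximity (kaempferol glycosides
≈ 347–348 nm, quercetin ≈ 354 nm), then retention time, then name, making
the ranking deterministic. One printed ion in the packaged catalogue —
the kaempferol-3-*O*-rutinoside aglycone fragment at m/z 287.7 — sits
0.645 Da from theory (287.055) and is treated as a transcription outlier;
all 23 other ions, including all twelve base peaks, match within 0.5 Da.

## The synthetic panel generator

The generator emulates the survey's study conditions: 19 *lupuloides* and
11 *lupulus* accessions measured in triplicate. Per-class trait values
(total prenylchalcones, XGA, MXH, Σα, cohumulone proportion, Σβ, leaf
malonyl proportion, total flavonols) are drawn from truncated normal
distributions whose targets are the published class means and whose
truncation bounds are the published per-class column minima/maxima, with
spread set to a quarter of the truncated range. The location parameter is
recentred (by root finding) so the *truncated* mean equals the target —
without this, asymmetric truncation would bias class means by a few
percent. Traits then deterministically decompose into per-compound
concentrations:

* prenylchalcones: XGA and MXH drawn directly (identically zero for
  *lupulus*); the remainder splits 72/28 between xanthohumol and
  desmethylxanthohumol (xanthohumol is the dominant prenylchalcone in all
  samples).
* bitter acids: COH = p·Σα, n+ADH = (1−p)·Σα with p the drawn cohumulone
  proportion; the colupulone share of Σβ uses the same p, since the co-
  analogues derive from the same branched-chain acyl precursor pool.
* leaf flavonols: the malonyl pool splits 5:1 between the kaempferol and
  quercetin esters (the kaempferol ester is about five times more
  abundant); the non-malonyl pool splits in fixed proportions
  (Q-rutinoside 0.35, Q-glucoside 0.25, K-rutinoside 0.15, K-glucoside
  0.25).

Replicate scatter is multiplicative log-normal with unit mean and a 5%
coefficient of variation, matching the few-percent standard errors of
triplicate measurements; the survey does not state a within-replicate
variance model, so the CV is a modelling choice exposed in the
configuration. Calibration-series injections carry 0.5% multiplicative
noise, consistent with sub-percent UPLC injection precision and with
calibration fits achieving r² > 0.999. Every random draw uses an
independent stream derived from (seed, accession, tissue, purpose), so
generation is reproducible element-by-element and order-independent.

With these defaults the two classes' leaf malonyl proportions never enter
the (0.10, 0.20) gap (truncation bounds are 0.063 and 0.221), so the
label-recovery property — both classifiers reproduce the generating
subspecies labels exactly — holds for every seed by construction of the
study conditions, as it did for the real collection.

What the generator does *not* emulate: peak tailing and asymmetry,
retention-time drift between runs, detector saturation, matrix
interferences, between-year variation, and any MS-level signal (only DAD
traces are simulated). Passing round-trip tests therefore demonstrate the
correctness of the integration/calibration/bookkeeping chain, not
robustness to real-world chromatographic pathology.

## Numerical and design choices

* **Peak shape and width.** Gaussian, single σ per method, default
  σ = 0.01 min (~1.4 s FWHM, typical of sub-2-µm UPLC). A wider 0.03 min
  σ was considered but leaves the flavonol peaks (0.10–0.13 min apart)
  only 3–4 σ apart, where valley-delimited integration loses tens of
  percent of area to elevated inter-peak valleys and the noiseless
  round-trip contract cannot be met. At σ = 0.01 min all analytes are
  baseline-resolved except the kaempferol-rutinoside/quercetin-malonyl
  pair (RT 4.18 vs 4.20 min, 2 σ apart), which genuinely co-elutes.
* **Co-elution handling.** Deconvolution is out of scope. The 4.18/4.20
  pair reports as one joint peak flagged `coeluting`; the pipeline
  apportions it by anchoring the quercetin malonyl ester at 1/5 of the
  well-resolved kaempferol malonyl ester (the documented abundance ratio)
  and assigning the remainder to kaempferol-rutinoside, flagging both
  `coeluting-split`. When the generating ratio equals the configured one
  the split is exact; with replicate noise it adds an error of the order
  of the replicate CV to those two analytes only.
* **Peak windows.** Delimited by flanking minima or by the return to
  baseline, whichever is closer to the apex; the baseline-return
  threshold is 3× a MAD-based noise estimate, so noiseless windows hug
  the full peak while noisy windows do not wander across flat stretches.
  Apexes closer than 0.05 min (the RT assignment tolerance) collapse to
  the taller one, so a marginally bimodal co-eluting pair cannot split at
  an arbitrary noise valley. Baseline default is `linear_endpoints`
  (robust to constant offsets); `zero` is available.
* **Peak→compound assignment.** Nearest catalogue RT within ±0.05 min;
  unassigned peaks are retained but not quantified. Published RT spacing
  makes this unambiguous except for the co-eluting pair.
* **Cone retention times** are not published; catalogue defaults follow
  the observed elution order (DXH < XGA < XHU < MXH at 370 nm;
  COH < n+ADH < COL < n+ADL at 320 nm) spaced ≥ 0.4 min inside the 8-min
  gradient. Leaf flavonol RTs are the published values.
* **Integration** is trapezoidal on the sampled grid (20 Hz scan rate →
  1200 points/min, 12 points per σ; trapezoid error ≪ 0.1%). Negative
  net areas clip to zero.
* **Rounding.** Report output rounds to the table's printed precision
  (two decimals for % dw traits and proportions, 3–4 for the malonyl
  proportion); all internal computation keeps full precision. Recomputing
  the alpha ratio from printed per-row alpha/beta values reproduces the
  printed column to within 0.006 — one row (P-WB) rounds the other way
  because the published averages were computed on unrounded data.

## Problem sizes

Tests and the acceptance script run at the survey's own scale: the
30-accession trait table for all desk checks, and synthetic panels of
30 accessions × 2 tissues × 3 replicates × 3 channels (~270 traces of
~10⁴ points) for round-trip checks, which complete in a few seconds.
Generator-convergence checks use 800 accessions.

## Known limitations

* The forward model is deliberately idealized (see generator non-goals);
  the package has not been validated against vendor instrument data, and
  no vendor file readers are provided.
* The equivalents convention reports equivalent-scale amounts, not
  absolute concentrations, for non-reference family members — exactly as
  the underlying assay does.
* The annotator assumes singly charged ions and does not model isotope
  patterns or in-source fragmentation beyond the aglycone and CO₂ losses.
* Group SEs are across-accession dispersions; no inferential statistics
  (hypothesis tests) are provided, since the underlying survey performs
  none.
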