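# hopchem

Chemometric quantitation and chemotaxonomic classification of wild hops
(*Humulus lupulus* L.), built for germplasm surveys that distinguish native
North American *H. lupulus* ssp. *lupuloides* from feral European
*H. lupulus* ssp. *lupulus* by chemical profile alone.

The package covers the full analysis chain for a UPLC-DAD(-MS/MS) survey of
hop cones and leaves:

* **Synthetic study panels** — seeded generation of two-subspecies
  germplasm panels (ground-truth concentrations per accession, tissue and
  replicate) and forward-simulated multi-channel diode-array chromatograms,
  so the whole pipeline is testable without instrument data.
* **Chromatography** — peak detection, baseline-aware trapezoidal
  integration, linear calibration (y = mx + b over 0.001–0.5 mg/ml),
  bitter-acid quantitation against the ICE-3 reference extract of defined
  w/w composition, and conversion to percent of sample dry weight.
* **Chemometrics** — per-accession trait statistics: total
  prenylchalcones (XHU + DXH + XGA + MXH), total alpha and beta acids, the
  cohumulone proportion COH/Σα, the alpha ratio Pα = Σα/(Σα + Σβ), the leaf
  malonyl-flavonol proportion, and unweighted group means ± SE.
* **Chemotaxonomy** — the two marker rules and their concordance:

  - *cone rule*: xanthogalenol (XGA) and 4′-*O*-methyl xanthohumol (MXH)
    both present → *lupuloides*; both absent → *lupulus*; one alone →
    atypical.
  - *leaf rule*: malonyl proportion = (malonyl-kaempferol-glucoside +
    malonyl-quercetin-glucoside)/Σ flavonols; < 0.10 → *lupuloides*-type,
    > 0.20 → *lupulus*-type, between → indeterminate.

* **MS annotation** — monoisotopic masses for flavonol glycoside
  candidates (aglycone + sugar + optional malonyl ester) and their ESI±
  ion series ([M+H]⁺, aglycone fragment, [M−H]⁻, [2M−H]⁻ and the
  diagnostic malonyl decarboxylation fragment [M−H−CO₂]⁻), with a scored
  annotator for observed (RT, λmax, ion list) records.

A 30-accession reference trait table and a six-compound flavonol ion
catalogue ship with the package as plain CSV.

## Worked example

Classify the packaged 30-accession trait table and summarize the classes:

```sh
$ hopchem --quiet classify --out calls.csv
subspecies fractions: lupuloides=0.633, lupulus=0.367
concordance: 1.000 over 30 evaluable accessions
```

63.3% of accessions carry both cone markers (the native chemotype), and
the independent leaf rule agrees with the cone rule for all 30 accessions.
The same numbers from Python, with class trait means:

```python
from hopchem.io import load_table2_fixture, TRAIT_COLUMNS
from hopchem.chemometrics import summarize_trait_table

summary = summarize_trait_table(load_table2_fixture(), TRAIT_COLUMNS)
print(summary[["subspecies", "n", "total_alpha_mean", "prop_coh_mean",
               "malonyl_proportion_mean"]].round(4).to_string(index=False))
```

```
       subspecies  n  total_alpha_mean  prop_coh_mean  malonyl_proportion_mean
       lupuloides 19            6.6489         0.4074                   0.0343
          lupulus 11            4.5791         0.2545                   0.3912
entire collection 30            5.8900         0.3513                   0.1652
```

Native *lupuloides* accessions average 6.65% dw total alpha acids with a
cohumulone proportion of 0.41 and a leaf malonyl proportion of 0.034;
feral *lupulus* accessions average 4.58% dw alpha acids, a lower
cohumulone proportion, and a ten-fold higher malonyl proportion (0.391) —
the bimodal structure both chemotype rules exploit.

A full synthetic study (simulate → calibrate → quantify → profile →
classify → summarize) runs in a few seconds:

```sh
hopchem report --seed 1 --outdir run1/
```

writing `quantitation.csv`, `traits.csv`, `calls.csv`, `summary.csv`,
`calibration.csv` and a plain-text report.

## Layout

```
src/hopchem/
  catalog.py        analyte catalogue (RT, channel, response factors)
  synthetic_data.py panels, forward-simulated traces, calibration series
  chromatography.py peaks, integration, calibration, quantitation
  chemometrics.py   trait statistics and group summaries
  chemotaxonomy.py  chemotype rules and concordance
  ms_annotation.py  glycoside masses, ion series, spectrum annotation
  io.py / cli.py / pipeline.py
  data/             packaged trait table and ion catalogue (CSV)
docs/methods.md     model and design notes
```
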