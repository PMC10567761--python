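# labri — indirect reference intervals for clinical chemistry

`labri` estimates gender- and age-specific **reference intervals** (RIs) for
clinical lab analytes — bundled defaults cover serum creatinine (LOINC
2160-0) and blood urea nitrogen (3094-0), the routine screening markers for
chronic kidney disease — from **unlabeled routine lab results** instead of
vetted healthy volunteers. It is aimed at clinical chemists, epidemiologists
and health-data teams who hold large result archives but no diagnostic
labels.

## Method

Routine data mix healthy and pathological readings. Within one gender/age
segment the healthy values are modeled as Gaussian and the pathological ones
as a wider, shifted overlay, so each segment's distribution is decomposed as
a two-component Gaussian mixture

```
p(x) = a₁·N(x | μ₁, Σ₁) + a₂·N(x | μ₂, Σ₂)
```

fitted by EM (or a variational-Bayes variant). The *principal* component is
taken as the healthy distribution:

* **1D:** the RI is its central 95% range μ ± 1.95996·σ (the 2.5th/97.5th
  percentiles); the other component's weight `a₂` estimates the segment's
  pathological fraction; limit uncertainty comes from a resampling bootstrap
  (100 half-size resamples), and age trends of the limits are fitted by
  linear (adults) and cubic (elderly) least squares.
* **2D:** the RI generalizes to the highest-density ellipse
  (x−μ)ᵀΣ⁻¹(x−μ) ≤ −2·ln(1−0.95); slicing it at a fixed value of one
  analyte gives the conditional ("chord") interval for the other, which can
  be empty when the fixed reading alone is out of range.
* **Continuous abnormal flag:** a reading's percentile is the probability
  mass of the region denser than the reading — the χ²_d CDF of its squared
  Mahalanobis distance — 0 at the population center and exactly 0.95 at the
  RI boundary, turning the classical binary flag into a graded risk measure.

Because the archives such a tool is designed for are licensed and not
redistributable, the package ships a synthetic cohort generator
(`labri.default_spec` / `labri.generate_cohort`) that encodes the documented
structure of real creatinine/urea data — age-widening healthy bands, an
age-ramped pathological fraction, correlated joint values, repeat visits and
occasional unit errors — together with a truth table, so every stage is
testable end to end. See `docs/methods.md` for the model, parameters and
limitations.

## Worked example

```python
import labri

spec = labri.default_spec(n_per_segment=5000, ages=range(28, 33))
table, truth = labri.generate_cohort(spec, seed=7)
table, removed = labri.filter_plausible(table)     # removed == 108 entry errors
cfg = labri.RIConfig(seed=7)

ris = labri.ri_table(table, cfg)
print(ris[ris.age == 30].round(4).to_string(index=False))
```

```
analyte gender  age    n    low    high  outlier_fraction  reliable
 2160-0 female   30 4999 0.4527  0.9153            0.0219      True
 2160-0   male   30 4998 0.5501  1.2273            0.0292      True
 3094-0 female   30 4994 5.9321 18.1045            0.0300      True
 3094-0   male   30 4997 7.0942 21.2214            0.0234      True
```

Each row is one gender/age segment: the estimated healthy 95% interval in
mg/dl and the mixture's pathological fraction (2–3% at age 30, matching the
generator's ramp). Male limits sit above female ones, reflecting the larger
muscle mass encoded in the generating trends.

The same fits, persisted as a population model, drive the continuous
abnormal flag:

```python
model = labri.build_population_model(table, cfg)
res = labri.predict(model, "male", 30, {"2160-0": 1.25, "3094-0": 18.0})
```

```
2160-0: value 1.25  percentile 0.9635  flag True
3094-0: value 18.0  percentile 0.7136  flag False
joint:              percentile 0.8869  flag False
```

The creatinine reading alone is beyond the 95% range (abnormal), the urea
reading is not, and — because the two analytes are positively correlated and
both readings are high together — the pair *jointly* is still inside the
normal range: the joint percentile carries information the two marginal
flags cannot.

The same pipeline is available from the shell:

```bash
labri simulate --seed 7 --n-per-segment 5000 --ages 28:32 -o cohort.csv
labri fit cohort.csv --seed 7 -o ri.csv --bootstrap 100
labri trends ri.csv --limit high -o trends.json
labri model cohort.csv --seed 7 -o model.json
labri predict --model model.json --gender male --age 30 --creatinine 1.25 --urea 18.0
```

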