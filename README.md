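# ppptrace

Partitioning glucose catabolism between **glycolysis** and the **oxidative
pentose phosphate pathway (PPP)** from [1,2-¹³C₂]glucose stable-isotope
tracing, for metabolism labs analyzing GC-MS mass-isotopologue data — e.g.
comparing proneural and mesenchymal glioblastoma brain-tumor-initiating
cells, with or without metformin.

## The model

Glucose labeled at C1 and C2 leaves a pathway-specific signature in
pyruvate and lactate:

* **Glycolysis** splits one glucose into two trioses; the C1–C3 triose
  keeps both labels, so each glucose yields one [2,3-¹³C₂]lactate (m+2)
  and one unlabeled lactate.
* **Oxidative PPP** releases glucose C1 as CO₂, destroying one label per
  molecule. Per three glucose, the non-oxidative rearrangement returns
  products that run down to one [1,3-¹³C₂]lactate, one [3-¹³C₁]lactate
  (m+1, the PPP diagnostic) and three unlabeled lactate.

Writing *p* for the fraction of glucose molecules entering the oxidative
PPP, the expected mass-isotopologue distribution (MID) of the full
lactate/pyruvate backbone ion is

    m0 = 3/(6−p),   m1 = p/(6−p),   m2 = (3−2p)/(6−p)

and of the lactate C2–C3 fragment ion (m/z 117/118/119)

    m0 = 3/(6−p),   m1 = 2p/(6−p),  m2 = (3−3p)/(6−p).

The fragment matters because PPP-derived [1,3-¹³C₂]lactate is m+2 on the
full ion — indistinguishable there from glycolytic [2,3-¹³C₂]lactate — but
m+1 on the C2–C3 ion, which retains only its C3 label. Inverting the
m+1/m+2 ratio *r* gives the PPP fraction: `p = 3r/(2+3r)` (fragment) or
`p = 3r/(1+2r)` (full ion); a bounded least-squares fit over the whole MID
is also provided, with a percentile-bootstrap confidence interval over
replicates.

Measured intensities are first corrected for ¹³C natural abundance
(1.07%/carbon) and tracer lot impurity by solving a non-negative
least-squares system against the binomial measurement operator.

Supporting modules cover isotope-dilution calibration of extracellular
glucose/lactate, glycolysis-stress-test ECAR metrics (glycolysis,
glycolytic capacity, glycolytic reserve), balanced two-way ANOVA with
Tukey HSD, and median-split Kaplan–Meier/log-rank survival comparison —
plus a synthetic-data generator for the whole study design.

## Worked example

```python
import ppptrace as pt

data, truth = pt.simulate_tracing_dataset(pt.SimulationConfig(seed=42))
samples = [s for s in data.sample_id.unique() if s.startswith("BTIC-18-like|control")]
model = pt.PPPFluxModel.from_dataframe(data, fragment_id="lactate_117", sample_ids=samples)
res = model.fit(method="least_squares", n_boot=500, seed=42)
print(res.summary())
```

```
PPP flux partition ([1,2-13C2]glucose tracing)
================================================
analyte:            lactate
fragment:           lactate_117 (C2-C3)
replicates:         3
estimator:          least_squares
f_PPP:              0.2900
f_glycolysis:       0.7100
PPP triose share:   0.2539
95% bootstrap CI:   [0.2854, 0.2984]

bin     corrected   fitted
m+0     0.5236      0.5254
m+1     0.1028      0.1016
m+2     0.3736      0.3730
```

The simulated proneural-like line routes 30% of its glucose through the
oxidative PPP; three replicates at 5% measurement CV recover
f_PPP = 0.29 [0.285, 0.298] — i.e. 29% of glucose via the PPP, 71% via
glycolysis, and 25% of the secreted lactate/pyruvate molecules being
PPP-derived (`PPP triose share` = 5p/(6−p)). The `corrected` column is the
mean natural-abundance/impurity-corrected MID; `fitted` is the model MID at
the estimate.

A command-line interface wraps the same machinery:

```bash
ppptrace run-all --seed 5 --outdir out/       # simulate → correct → estimate → report
ppptrace estimate --data intensities.csv --fragment lactate_117 --out estimates.csv
ppptrace survival --seed 3 --outdir out/surv  # median-split KM + log-rank
```

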