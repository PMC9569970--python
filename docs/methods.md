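# Methods

## Atom-fate model

The core model tracks the carbon fates of glucose labeled with ¹³C at C1
and C2 through two catabolic routes, at the level of product
stoichiometry:

* **Glycolysis.** One glucose yields two trioses. The carbon map is the
  standard aldolase/TPI one: glucose C1→lactate C3, C2→C2, C3→C1 for the
  C1–C3 triose and C6→C3, C5→C2, C4→C1 for the other. With labels on
  C1/C2 only, each glucose yields one [2,3-¹³C₂]lactate and one unlabeled
  lactate.
* **Oxidative PPP (single pass).** 6-phosphogluconate dehydrogenase
  releases C1 as CO₂, destroying one label per molecule. Three glucose
  give three pentoses; transketolase/transaldolase return two
  fructose-6-phosphates and one glyceraldehyde-3-phosphate which, run
  through lower glycolysis, produce five trioses per three glucose: one
  [1,3-¹³C₂]lactate, one [3-¹³C₁]lactate, three unlabeled.

The model parameter `f_ppp` (p) is the fraction of glucose *molecules*
entering the oxidative PPP. Because the PPP yields 5/3 triose per glucose
against glycolysis's 2, the fraction of *triose molecules* that are
PPP-derived is the distinct quantity 5p/(6−p), exposed read-only as
`triose_yield_share`.

**Assumptions (and when they break).** The model is single-pass: no
recycling of PPP-derived fructose-6-phosphate back into the PPP, no
reverse non-oxidative PPP exchange, and no relabeling through
TCA/pyruvate cycling or the Cori-like re-entry of secreted lactate. In
cells with substantial F6P recycling the m+1 signal overstates a
single-pass p; the estimate should then be read as an apparent
(lower-bound-flavored) PPP fraction. Lactate and pyruvate are assumed to
share one labeling distribution (they sit on either side of LDH with no
carbon rearrangement), and ionization efficiency is assumed equal across
isotopologues.

Closed forms with a pure tracer, used both as the estimator's inverse and
as an independent check on the positional enumeration:

| ion | m+0 | m+1 | m+2 |
|---|---|---|---|
| full C1–C3 backbone | 3/(6−p) | p/(6−p) | (3−2p)/(6−p) |
| C2–C3 fragment | 3/(6−p) | 2p/(6−p) | (3−3p)/(6−p) |

Ratio inversions, r = m1/m2: fragment p = 3r/(2+3r); full ion
p = 3r/(1+2r). Inversions falling outside [0,1] (possible on noisy
corrected MIDs) are clamped and flagged rather than raised; m2 = 0 cases
return the boundary value with a `degenerate` flag.

## Estimators

* `ratio` — closed-form inversion of the mean corrected MID. Exact on
  model data; sensitive to m+2 noise at high p.
* `least_squares` — bounded scalar minimization (Brent on [0,1], xatol
  1e-10) of the squared deviation between the mean corrected MID and the
  model MID. The objective is a smooth rational function of p, unimodal on
  [0,1] (asserted on a grid in the tests); no multi-start is needed.
  Agrees with `ratio` to <1e-6 on noiseless data.
* `bootstrap_ci` — percentile (2.5/97.5) interval of the least-squares
  estimate over replicate resampling, deterministic given a seed.
  **Known limitation:** with very few replicates the percentile interval
  undercovers its nominal level — measured ~86% true coverage at six
  replicates and 5% CV against a nominal 95%. This is the usual
  small-sample behavior of percentile bootstraps, not an implementation
  artifact; treat intervals from n ≤ 6 as approximate.

## Isotopologue correction

The measurement operator maps nominal tracer-label counts to measured
isotopologue space. Column j combines (i) binomial thinning of the j
nominal labels at the tracer lot purity π (default 0.99 — a typical lot
value; the actual lot purity should be supplied when known) and (ii)
binomial natural ¹³C labeling of the remaining backbone carbons at
a = 0.0107. The default `carbon_only` mode corrects exactly these two
effects; `full_formula` mode additionally convolves the natural isotope
distributions of all other atoms of a user-supplied ion formula (H, N, O,
Si, S supported) — off by default because the GC derivative, and hence
the formula, is configuration rather than something the pipeline can
assume. Mass beyond m+n is truncated and columns renormalized within the
observed bins; at natural-abundance scales this bias is ≪1e-3.

Correction solves min‖Mx − y‖² s.t. x ≥ 0 (scipy NNLS) and renormalizes,
rather than inverting M: inversion of these near-triangular operators
pushes measurement noise into negative bins, while NNLS guarantees valid
fractions. Round trips (forward-then-correct) are identities to <1e-8 for
every shipped fragment; a condition-number guard (>1e12) raises instead
of returning garbage.

Tracer impurity may equivalently be modeled positionally in the atom map
(each nominal label independently present with probability π) or as the
thinning step of the operator; a property test proves both routes give
the same measured MID. The pipeline uses the operator route, so corrected
MIDs live in nominal-label space and the estimators always invert the
pure-tracer closed forms.

## Fragment registry

Carbon positions are 1-based (C1 = carboxyl of lactate/pyruvate, aldehyde
of glucose). Shipped ions: `lactate_117` retaining C2–C3 (base m/z 117,
the diagnostic fragment that turns PPP [1,3-¹³C₂] into m+1),
`lactate_full` and `pyruvate_full` — the [M−CH₃]⁺ ions of the GC
derivatives (base m/z 219 and 174, standard methoxime/TMS derivative
values supplied as configuration; only the 117 fragment's m/z is inherent
to the method).

## Synthetic data

The generators emulate the study design so that every pipeline stage is
testable without instrument data; they are first-class, tested code.

* **Tracing tables** — per line × treatment × replicate × fragment: model
  MID → measurement operator → random total intensity (log-normal, 30%
  spread around 1e6 counts) → per-bin multiplicative log-normal noise at
  `noise_cv` (default 5%, a typical GC-MS peak-area CV). Log-normal noise
  is chosen because peak areas are positive and roughly CV-stable.
* **Default panel** — two proneural-like lines at f_ppp = 0.30 and two
  mesenchymal-like lines at f_ppp = 0.10, mesenchymal lines consuming
  ~3× more glucose and producing more lactate; metformin arms (0.01, 1,
  10 mM as metadata) raise glucose consumption/lactate output
  (multipliers 1.05–1.5) and lower the PPP share (−0.01 to −0.08). These
  encode the qualitative subtype contrast the pipeline is meant to
  detect, at effect sizes a tracing experiment can resolve.
* **Exometabolome** — linear isotope-dilution response curves (6
  concentration points, duplicate, 2% CV) and 48 h supernatant samples:
  blank 17.5 mM glucose (fresh-medium level) minus consumption, floored
  at zero; lactate accumulating from zero.
* **Survival** — expression drawn log-normally; subjects above the cohort
  median carry `hazard_ratio`-scaled exponential hazard; censoring is
  independent exponential calibrated to the requested censoring fraction.
* **ECAR traces** — piecewise-constant phase means with additive Gaussian
  noise and annotated injection times.

What the generators do **not** emulate: chromatographic peak shape and
integration error, detector saturation, retention-time drift,
between-batch effects, F6P recycling, or correlated replicate noise.
Passing recovery tests therefore demonstrates the correctness of the
estimation machinery under the model's own assumptions, not robustness to
every real-data pathology.

## Assay metrics

Glycolysis-stress metrics follow the standard assay conventions (the
assay names the quantities but not their arithmetic, so the definitions
are an explicit convention choice here): non-glycolytic acidification =
pre-glucose ECAR; glycolysis = post-glucose − pre-glucose; glycolytic
capacity = post-oligomycin − pre-glucose; glycolytic reserve = capacity −
glycolysis. Phase summaries use the mean of all measurements between
injections by default (`phase_stat="last"` selects the last point).
Calibration is ordinary least squares of response ratio on concentration
(≥3 distinct levels); quantitation inverts the line, floors negative
concentrations at zero with a warning (evaporation/matrix effects), and
warns outside the calibrated range. Rates are (blank − sample)/h/µg
protein with the sign convention consumption-positive for substrates and
production-positive for products. All assay computations are
unit-agnostic.

## Statistics

* **Two-way ANOVA** — classical balanced fixed-effects decomposition with
  interaction. Unbalanced input raises rather than silently picking a
  Type I/II/III convention; the study designs this serves are triplicate
  and balanced. Zero residual variance is reported as F = 0, p = 1 with a
  `degenerate` flag.
* **Tukey HSD** — q = |mean_i − mean_j|/√(MSE/n); adjusted p from the
  studentized range distribution (scipy's implementation; the test suite
  cross-checks it against a direct double-quadrature of the range
  distribution to 1e-4). Stars: * p<0.05, ** p<0.01, *** p<0.001,
  **** p<0.0001.
* **Median split** — values strictly above the median are "high"; values
  equal to the median go to "low" (a deterministic tie rule, chosen since
  "above versus below the median" leaves ties unspecified); an impossible
  split (all values identical, or an empty side) raises.
* **Log-rank (Mantel–Cox)** — hypergeometric expectation and variance at
  each distinct event time; (ΣO−ΣE)²/ΣV against χ²₁. Matches lifelines to
  machine precision on random cohorts and holds ~5% type-I error over
  1000 null simulations.
* **Kaplan–Meier** — product-limit estimator, cross-checked against
  lifelines.

## Numerical choices

MID validity tolerance 1e-9 after normalization; least-squares xatol
1e-10; NNLS condition guard 1e12; correction round-trip contract 1e-8;
quadrature in the Tukey test oracle at 1e-8. Problem sizes used by the
recovery and calibration checks — 100 seeded panel runs at n = 3
replicates, 1000 null survival cohorts of 80 subjects — were chosen to
pin the Monte-Carlo estimates (ordering rate, type-I rate) to within a
couple of percentage points while keeping the default suite quick to run.

## Reproducibility

Every simulator is a pure function of (config, seed); the pipeline
records seed, config hash and output list in `manifest.json`, and
rerunning with the same config and seed reproduces byte-identical CSVs.
Ground truth is written to a sidecar file so recovery tests never parse
truth out of the data tables.
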