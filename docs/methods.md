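# Methods

## The growth-linked dissipation model

Repeated application of a pesticide to soil can select for microorganisms
able to use it as a substrate, so the residue disappears faster after each
application ("accelerated degradation").  Standard regulatory kinetics
(single first-order, biphasic) fit each application in isolation and cannot
express this adaptation.  The growth-linked model couples two removal
routes acting on the residue `[Atr]`, expressed as % of one applied dose:

    Atr(t + n) = Atr(t) − Y·n·k1·e^(−k1·tc) − N(t)·n·V·Atr/(Atr + Ks)

advanced by explicit Euler steps of length `n` (default 0.01 day).

* **Chemical route.**  A fraction `Y` (% of dose, 0–100) of each fresh
  application is chemically available and decays first-order at rate `k1`
  (day⁻¹).  `tc` is the time since the most recent application: the clock
  resets at every dosing event because each fresh dose contributes a fresh
  available pool.  A never-resetting clock would extinguish the chemical
  term for later applications, which contradicts its role; the reset is
  therefore the default and only behaviour.
* **Biological route.**  A degrader community of dimensionless size
  `N ∈ [0, Nmax]` (Nmax = 100 by convention) removes residue with
  Monod-type saturation: maximum rate `V` per degrader unit
  (% dose·day⁻¹·unit⁻¹) and half-saturation `Ks` (% of dose).  The
  community grows exponentially on absolute time,
  `N(t) = min(Nmax, N0·e^(μt))`, independent of substrate presence — an
  intentional simplification: adaptation proceeds once soil is exposed,
  and the data that motivated the model do not resolve substrate-gated
  growth.  `N0 = 0` stays 0 (no spontaneous community).  A reading of the
  growth law as `N0^(e^{μt})` is rejected: for `N0 < 1` it would shrink
  the community, which is inconsistent with exponential growth to a cap.

Numerical safeguards: per-step removal is capped at the current residue and
the trajectory is clamped at zero (the raw difference equation can
overshoot at coarse steps).  Each application adds its full dose to the
residue, so non-degrading soils accumulate residue above 100% of one dose.
At re-application times the stored series carries two nodes — pre-dose and
post-dose — so that a sample scheduled "28 days after application 2" (which
is the same calendar day as application 3) reads the pre-dose residue,
while the "day 0" sample of application 3 reads the post-dose residue.

With the biological route off the scheme reproduces `C0·e^(−k1·t)` to
better than 0.05 absolute % at the default step over 60 days; with the
chemical route off and `N = Nmax` it matches the implicit Monod solution
`t(A) = [(A0 − A) + Ks·ln(A0/A)]/(Nmax·V)` to ~0.1% in time.  Both
equivalences are enforced by tests.

`Ks = 75`% of a 6 µg·mL⁻¹-scale dose corresponds to 20.9 µM
(`percent_dose_to_micromolar`), the same scale as the measured Michaelis
constant of the TrzN atrazine chlorohydrolase (20–25 µM).

### Fitting

The original analysis tuned parameters by eye; this package formalises the
fit as bounded nonlinear least squares on the recoveries of **all**
applications simultaneously (`scipy.optimize.least_squares`, TRF).
Defaults:

| parameter | bounds (default)     | scale  | note                           |
|-----------|----------------------|--------|--------------------------------|
| k1        | 0.006 – 1.8 day⁻¹    | linear | reported range 0.06–0.18, ×/÷10|
| Y         | 3 – 100 %            | linear | ceiling is physical (100%)     |
| N0        | 5·10⁻⁶ – 0.3         | log    | spans ≥3 orders of magnitude   |
| μ         | 0.0155 – 2.25 day⁻¹  | linear | reported 0.155–0.225, ×/÷10    |
| V         | 0.06 – 7             | linear | reported 0.6–0.7, ×/÷10        |
| Ks        | fixed at 75          | —      | free via `fix_Ks=None`         |

`Ks` is fixed by default: it was constant across all reported soils and is
poorly identifiable jointly with `V` when all observations live on a single
dose scale.  Multi-start (default 32 starts: bounds midpoint first, then a
seeded Latin-hypercube draw) with early stop once the per-observation SSE
falls below 10⁻⁸ — on noise-free data the midpoint start alone recovers the
generating parameters to ≪0.1%.  Tests and the acceptance script use 4–12
starts, which is ample at the problem sizes they run.

## Regulatory (FOCUS-style) kinetics

Per application window, on day-since-application time, fitted to replicate
day-means (an option for per-replicate fitting is not provided; day-means
match how the χ² statistic is defined):

* **SFO** `C(t) = C0·e^(−kt)`; DT50 = ln2/k, DT90 = ln10/k.  `C0` is
  estimated, not fixed at 100, because day-0 recoveries vary.
* **DFOP** `C(t) = C0·(g·e^(−k_fast·t) + (1−g)·e^(−k_slow·t))`; DT50/DT90
  by bracketed root-finding between the pure-fast and pure-slow half-lives.
  Pools are sorted so `k_fast ≥ k_slow`; a rate ratio < 1.01 is flagged
  SFO-equivalent.  DFOP is the biphasic candidate; hockey-stick and FOMC
  are out of scope.
* **χ² error (%)** — the smallest relative error at which the χ² test on
  the day-mean residuals still passes at α = 0.05:
  `100/mean(obs) · sqrt(Σ(obs−pred)² / χ²₀.₀₅,m−p)`.  The acceptability
  threshold is 15%.
* **Parameter t-tests** — one-sided `estimate/SE` with df = m − p, α =
  0.05; SEs come from the curve-fit covariance.  Zero/undefined SEs mark
  the test undefined; model selection accepts them only when the fit is
  essentially perfect (residuals < 10⁻⁹ of the observation scale).
* **Model selection** — SFO first.  SFO is kept when its χ² < 15%, its
  parameters pass the t-test, and a Wald–Wolfowitz runs test on residual
  signs (one-sided, too-few-runs, α = 0.05) finds no systematic pattern —
  the runs test operationalises the "visual fit" judgement, which cannot be
  automated verbatim.  Otherwise DFOP is chosen if it passes χ² and
  t-tests; failing that the window is flagged "no acceptable fit".

`endpoint_table` assembles soil × application DT50/χ² grids and the two
derived statistics of interest: the per-soil DT50 fold-reduction from first
to second application (the accelerated-degradation signal) and per-soil
persistence ratios against the best other soil.

## Sorption

OECD-106-style batch points: everything leaving solution is assumed sorbed,
`Cs = (c_initial − c_aq)·V/m`.  The Freundlich isotherm `Cs = Kf·Caq^(1/n)`
is fitted by untransformed least squares (matching the spreadsheet-solver
practice the endpoint values derive from); a log-log regression option
exists for comparison but weights low concentrations more heavily.
Duplicate tubes enter as independent points.  Defaults mirror the study
design: 5 g soil : 25 mL solution, nominal 0.02–2.0 µg·mL⁻¹.

## qPCR quantification

Standard curves are OLS of Ct on log₁₀(concentration);
efficiency = (10^(−1/slope) − 1)·100 (100% at slope −3.3219).  Sample
concentrations invert the curve after averaging triplicate Cts on the Ct
scale.  The trzN-carrying fraction of the community is

    %trzN = (trzN conc / 16S conc) · (161 bp / 70 bp) · 100

with the amplicon-length ratio correcting mass-quantified standards to a
per-copy basis; concentrations stay in relative dilution-series units (no
copies-per-gram conversion, no 16S copy-number correction).  Treated vs
control groups are compared by an unpaired two-sided Student t-test (Welch
available as an option).

## Synthetic data

Generators emulate the study design so the whole pipeline runs without any
external data: three applications of one dose at days 0/60/88; sampling
0,1,3,7,14,28,45,60 days after the first application and 0,1,3,7,14,28
after the later two; 4 replicates with multiplicative CV 7% noise (a chosen
default — the source study does not report a numeric replicate CV);
recoveries below 0.33% of dose (the 0.02 µg·mL⁻¹ analytical LOD on the
6 µg·g⁻¹ dose scale) are censored to NaN and dropped by the fitters.
Panels draw adapting-soil parameters uniformly from the reported ranges
(k1 0.06–0.18, Y 30–65, μ 0.155–0.225, V 0.6–0.7; N0 log-uniform
5·10⁻⁵–0.03; Ks = 75); non-adapting soils share the chemistry but have
N0 = 0.  Sorption batches invert the isotherm + mass balance exactly
(bracketed root-finding) before noising c_aq; qPCR plates map true
percentages through ideal curves to Cts with per-triplicate Gaussian noise.

What the generators do **not** emulate: extraction-efficiency drifts,
day-correlated errors, heteroscedastic HPLC noise near the LOD, qPCR
inhibition, or between-soil Ks variation.  Passing round-trip and
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to real-soil artefacts.

## Problem sizes and determinism

Everything is seeded; generators are bit-reproducible given (parameters,
seed).  The test-suite and acceptance-script problem sizes are deliberate
package choices: simulations at step 0.01 day (0.02 for the 9-soil panel,
where the Euler error is far below the 7% replicate noise), 12-start fits
for noise-free recovery, 200-replicate power/selection simulations.
Results are insensitive to the seed at these sizes (spot-checked across
several seeds).

## Known limitations

* The growth-linked fit reports no uncertainty intervals (none were
  reported for the original parameters; the SSE surface is available for
  profiling if needed).
* The (100 − Y)% chemically unavailable fraction is degradable only by the
  biological route; its fate is otherwise unmodelled.
* DT50 values from SFO fits on adapting first applications are effective
  summaries of visibly non-first-order decay; the growth-linked model is
  the mechanistic alternative, not a replacement for the regulatory
  convention.
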