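# atrakin

Quantitative analysis of **accelerated atrazine degradation** in soil.
When atrazine (a chloro-s-triazine herbicide) is applied repeatedly to the
same soil, microbial communities that can use it as a substrate grow, and
later applications dissipate far faster than the first — a DT50 of weeks
collapses to a day or two.  This matters for environmental risk assessment
(regulatory fate models ignore adaptation) and for product efficacy, and it
fails to occur in some soils (notably low-pH ones), where residues instead
accumulate.

The package is for environmental-fate modellers and soil microbiologists.
It provides four analysis stages, each usable on its own, plus generators
that emulate the underlying microcosm design (three applications of
6 µg g⁻¹ at days 0/60/88, sampled 0–60 days after each, 4–12 replicates):

* **Growth-linked model** (`atrakin.growth_model`) — the mechanistic
  dissipation model

  `Atr(t+n) = Atr(t) − Y·n·k1·e^(−k1·tc) − N·n·V·Atr/(Atr+Ks)`,
  `N(t) = min(100, N0·e^(μt))`

  combining a first-order chemical pool (fraction `Y`, rate `k1`) with
  Monod-type biological removal (`V`, `Ks`) by an exponentially growing
  degrader community: forward simulation over a multi-application schedule
  and bounded multi-start least-squares estimation of one parameter set
  across all applications.
* **Regulatory kinetics** (`atrakin.focus`) — per-application SFO
  (`C0·e^(−kt)`) and DFOP (`C0·(g·e^(−k_fast t) + (1−g)·e^(−k_slow t))`)
  fits, DT50/DT90, the FOCUS χ² error statistic with its 15% acceptability
  rule, parameter t-tests, runs-test residual diagnostics, SFO-vs-biphasic
  model selection and soil × application endpoint tables with
  fold-reduction and persistence ratios.
* **Sorption** (`atrakin.sorption`) — OECD-106-style batch mass balance and
  Freundlich isotherm fitting, `Cs = Kf·Caq^(1/n)`.
* **qPCR** (`atrakin.qpcr`) — standard-curve calibration
  (Ct vs log₁₀ concentration), relative quantification, and the
  amplicon-length-corrected percentage of the bacterial community carrying
  the *trzN* atrazine-chlorohydrolase gene:
  `%trzN = (trzN/16S)·(161/70)·100`, with treated-vs-control t-tests.

See `docs/methods.md` for model assumptions, parameter defaults and
numerical choices.

## Worked example

```python
from atrakin import (GrowthLinkedParams, fit_sfo,
                     percent_dose_to_micromolar)
from atrakin.synth import SoilScenario, NoiseModel, generate_dissipation

# an adapting soil: small initial degrader community that grows at 0.19/day
params = GrowthLinkedParams(k1=0.12, Y=45, N0=0.001, mu=0.19, V=0.65, Ks=75)
scen = SoilScenario("demo", params, replicate_cv=0.07, n_replicates=4)
obs = generate_dissipation(scen, noise=NoiseModel(cv=0.07, seed=1))

for a in (1, 2, 3):
    fit = fit_sfo(obs, a)
    print(f"application {a}: DT50 = {fit.dt50:5.2f} d, chi2 = {fit.chi2_err:4.1f}%")
print(f"Ks = 75% of dose = {percent_dose_to_micromolar(75):.1f} uM")
```

prints

```
application 1: DT50 = 26.84 d, chi2 = 11.8%
application 2: DT50 =  1.14 d, chi2 =  3.9%
application 3: DT50 =  1.19 d, chi2 =  4.7%
Ks = 75% of dose = 20.9 uM
```

The first application dissipates slowly (the degrader community is still
tiny), then DT50 drops ~24-fold once the community has grown — the
accelerated-degradation signature.  The fitted half-saturation constant,
75% of the applied dose, converts to 20.9 µM, the same scale as the
measured Michaelis constant of the TrzN enzyme (20–25 µM).

`atrakin.datasets.reference_endpoints()` ships the published nine-soil
endpoint table (DT50 and χ² per application) for cross-checks: the eight
adapting soils show 7–32-fold DT50 reductions, while the one non-adapting
soil (GRS, pH 5.4) stays ≥19× more persistent than any other soil.

A CLI mirrors the library (`atrakin simulate | fit-growth | fit-focus |
fit-sorption | quantify-qpcr | synth | report`), reading/writing plain CSV
and YAML/JSON configs; exit code 2 flags validation errors.

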