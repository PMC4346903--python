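# protospec

Chemical modeling of the proton-binding capacity of soluble bio-organic
substances (SBOs) — humic-like biopolymers recovered from municipal
biowaste — from potentiometric acid–base titration data.

SBOs carry carboxylic, phenolic and nitrogen functional groups spread
heterogeneously over a polydisperse macromolecular pool. Their acid–base
behavior is summarized by a small set of protogenic *site classes*, each
with stepwise protonation constants and a concentration per gram of dry
matter. `protospec` provides the full desk workflow for characterizing
them:

* **speciation** — multi-site protonation models (cumulative
  β<sub>r</sub> vs stepwise K<sub>r</sub> constants), species fractions,
  and a guaranteed-convergent proton mass-balance solver that turns any
  solution composition into a pH and any titrant schedule into a curve;
* **calibrate** — glass-electrode calibration from strong acid/base
  titrations: E = E⁰ − s·pH + j<sub>a</sub>[H⁺], refining any subset of
  {E⁰, j<sub>a</sub>, pK<sub>w</sub>, slope, acid concentration};
* **fit** — weighted nonlinear least squares on EMF readings with
  instrument-resolution error propagation (w = 1/s², s² = σ<sub>E</sub>²
  + (dE/dv)²σ<sub>v</sub>²), reporting the weighted standard deviation of
  the fit and per-parameter uncertainties; structures compared on equal
  footing (shared-concentration "diprotic-like" Models I/II vs the
  discrete all-monoprotic Model III);
* **groups** — the functional-group bookkeeping that merges titration
  with ¹³C NMR band totals and elemental analysis: COY = COOH + CONR and
  N = NR + CONR, with the COOH pool defined as all protonation steps
  with stepwise logK < 7;
* **synthdata** — a generator reproducing the study design (25 mL of
  0.5 g/L SBO in 0.1 M TEACl, acidified to pH 3, titrated with 0.1 M KOH
  to pH 11.5; Gaussian noise at the instrument resolutions 0.1 mV and
  0.001 mL) plus the published reference parameter sets as fixtures;
* **io / pipeline / cli** — text titration files in two metadata
  dialects, YAML model/electrode/composition files, a one-config
  pipeline (`calibrate → fit → compare → breakdown`) and the `protospec`
  command-line tool.

## Worked example

```python
from protospec import (fixtures, breakdown_from_composition, report_round,
                       stepwise_from_cumulative, make_sbo_titration, NoiseSpec,
                       ElectrodeModel, fit_protonation_model, AcidSite)

fx = fixtures()
cvdf = fx["CVDF"]

# stepwise constants of the diprotic-like site from its cumulative ones
print("logK:", stepwise_from_cumulative(cvdf["Model I"].sites[0].cum_logbeta))

# functional-group breakdown from the discrete model + NMR/elemental data
bd = breakdown_from_composition(cvdf.composition, cvdf["Model III"])
print({k: report_round(v) for k, v in bd.as_dict().items()})

# simulate a realistic noisy titration and refit it from shifted guesses
electrode = ElectrodeModel(e0=400.0)
data = make_sbo_titration(cvdf["Model III"], electrode=electrode, noise=NoiseSpec(seed=7))
start = cvdf["Model III"].with_sites(
    [AcidSite(s.site_id, (s.cum_logbeta[0] + 0.2,), s.conc_per_gram * 1.3)
     for s in cvdf["Model III"].sites])
res = fit_protonation_model(data, electrode, start)
print(f"sigma_fit = {res.sigma_fit:.2f}")
print(res.summary()[["site", "logbeta", "sd_logbeta",
                     "conc_mmol_per_g", "sd_conc"]].round(3).to_string(index=False))
```

prints

```
logK: [5.69, 4.14]
{'PhOY': 4.85, 'COY': 4.45, 'CONR': 1.75, 'NR': 1.97, 'COOH': 2.7, 'PhOH': 1.6, 'N_total': 3.71}
sigma_fit = 0.87
  site  logbeta  sd_logbeta  conc_mmol_per_g  sd_conc
Hcvdf1    4.338       0.007            1.695    0.013
Hcvdf2    6.009       0.021            1.008    0.013
Hcvdf3    8.326       0.031            0.695    0.011
Hcvdf4   10.375       0.017            0.887    0.009
```

Reading the output: the CVDF diprotic site's second proton adds with
logK = 4.14; the NMR carboxyl band (COY = 4.45 mmol/g) splits into the
titratable COOH pool (2.7 mmol/g, the two sites with logK < 7) and amide
carbon (CONR = 1.75 mmol/g); and a refit of a synthetic titration at
instrument noise recovers all four generating site parameters
(logK 4.34/6.03/8.33/10.40, concentrations 1.70/1.0/0.7/0.9 mmol/g)
within a few reported standard deviations, with sigma_fit ≈ 1 as
expected when the error model matches the noise.

The same stages are available from the shell:

```sh
protospec synth --sbo CVDF --model III --seed 7 --out titration.csv
protospec calibrate calibration.csv --refine e0,j_a,pKw --out electrode.yaml
protospec fit titration.csv --electrode electrode.yaml --model model3.yaml --report json
protospec breakdown --composition cvdf.yaml --model model3.yaml
protospec run config.yaml
```

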