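# Methods

## Chemical model

Each soluble bio-organic substance (SBO) is represented by a small set
of independent protogenic site classes. A site class `A` binds up to
`n` protons with cumulative constants on the concentration scale,

    A + r H+  <=>  AH_r ,      beta_r = [AH_r] / ([A] [H+]^r) ,

and stepwise constants `logK_r = logbeta_r − logbeta_{r−1}`
(`logK_1 = logbeta_1`). Only the protonation level `r` is tracked; the
absolute charge of the site never enters any computed quantity, so it
is deliberately not modeled. All constants are **conditional** at the
working medium (0.1 mol/L tetraethylammonium chloride, 25 °C): no
activity-coefficient or electrostatic (Debye–Hückel, Donnan, NICA-type)
corrections are applied, and the protonation parameters are assumed
independent of the dissociation degree. pH means −log₁₀[H⁺]
(concentration scale) throughout.

Three named structures are enforced:

* **Model I** — one "diprotic-like" site (two cumulative constants, one
  shared concentration), optionally one extra monoprotic site when the
  fitted pH window is widened into the alkaline range;
* **Model II** — the diprotic site plus one or two monoprotic sites;
* **Model III** — the discrete model: every site monoprotic with an
  independent constant.

Site concentrations are stored in mmol per gram of dry matter and
converted to mol/L through the SBO load (g/L), rediluted at every
titration point.

## Proton balance and solver

Sites enter the balance in the **fully protonated reference state**:
the analytical total proton concentration counts net strong acid (HCl
added minus KOH carried over from dissolving the sample in 1 M KOH —
folded into a single `c_strong_acid`, which the fit may refine) plus
`n_steps` protons per site. The condition solved for pH is

    [H+] − Kw/[H+] + Σ_i C_i · nbar_i(pH) = C_H(total) ,

where `nbar_i` is the mean protons bound per site, computed from the
binding polynomial in log space with max-subtraction so no pH in
[−2, 16] can overflow. The left side is strictly decreasing in pH
(its derivative is −ln10·([H⁺] + [OH⁻] + Σ C_i·var_i), with var_i the
variance of the bound-proton count), so the root is unique. The solver
is a vectorized Newton iteration safeguarded by a maintained bracket on
pH ∈ [−2, 16]: any Newton step leaving the bracket is replaced by its
midpoint, giving guaranteed convergence at Newton speed; iteration
stops at a pH step below 1e−12. A composition with no sign change over
the bracket raises an infeasibility error rather than returning a
boundary value.

`pKw` defaults to 13.78, a standard conditional value at 25 °C and
I = 0.1 mol/L; it is configurable everywhere and refinable in the
calibration stage.

## Electrode model and calibration

The cell response follows the ESAB-style convention

    E (mV) = E0 − s · pH + j_a · [H+] ,

with the Nernst slope fixed at the theoretical 59.16 mV/decade at 25 °C
by default (refinable on request, and guarded: a slope more than 10%
off theoretical is rejected as a configuration error) and an acidic
junction term only — `E_j = j_a[H⁺]` vanishes on the alkaline branch by
construction. The response is monotone provided
`j_a > −s/(ln10·[H⁺]_max)`; the inverse (pH from EMF) is obtained by
bracketed root finding and checked for monotonicity first.

Calibration fits a strong acid (10 mmol/L HCl) vs strong base (0.1 M
KOH) titration by weighted least squares on EMF, with the *same*
weighting stack as the main fit, refining any subset of {E⁰, j_a, pKw,
slope, acid concentration}. Refining pKw without alkaline-branch
readings (pH > 8) is rejected as under-determined. Parameter standard
deviations come from the inverse weighted normal-equations matrix
scaled by the weighted deviation of the fit.

## Weighting and the fit statistic

Each point's variance propagates the two instrument resolutions,

    s_i^2 = sigma_E^2 + (dE/dv)_i^2 · sigma_v^2 ,   w_i = 1/s_i^2 ,

with defaults sigma_E = 0.1 mV and sigma_v = 0.001 mL and the curve
slope estimated from the *observed* readings by centered finite
differences (one-sided at the ends), so weights are model-independent
and equivalence-region points are automatically down-weighted. Unit
weights are available as a mode. The fit quality statistic is

    sigma_fit = sqrt( Σ w_i r_i^2 / (n_points − n_params) ) ,

dimensionless: 0 for a perfect fit, ≈ 1 when residual scatter matches
the error model (verified by a Monte-Carlo χ²-consistency test).

## Refinement

The objective is the weighted EMF residual sum; pH-encoded datasets are
converted to EMF through the electrode model first, which makes the fit
invariant to the input encoding. Parameters are optimized on scales
that build the chemistry in structurally: stepwise logK values directly
(the cumulative series is their running sum) and log₁₀ of the
concentrations (positivity without constraints); the net strong-acid
concentration is refined on its natural scale since it may legitimately
be negative. The optimizer is SciPy's trust-region-reflective
least-squares with finite-difference Jacobians and tolerances at
1e−15, which recovers noise-free generating parameters to ~1e−12.
A deterministic multi-start (joint ±1 shifts of all logK guesses) is
available for rugged cases but off by default. Cumulative-constant
standard deviations are propagated from the full covariance block of
the site's stepwise parameters; concentration uncertainties use the
delta method on the log scale. Sites whose logK falls outside the
observed pH window (±1) are flagged as data-undetermined rather than
silently reported.

A pH-window mask supports the published two-stage diprotic protocol:
fit the diprotic site on the acid branch (pH 2.8–6.5), then widen the
window toward pH 10.5 and add a site — the widened structure is what
the Model II layout encodes. Model comparison fits every candidate
structure on identical data and weights and ranks by `sigma_fit`,
continuing past structures that fail.

Initial guesses are user-supplied or seeded by a deterministic
heuristic: points with below-median |dpH/dv| (buffer plateaus) are
split in pH order into as many chunks as requested sites, each chunk's
median pH becoming a logK guess, with the titrant consumption spread
evenly for concentrations.

## Functional-group bookkeeping

¹³C NMR resolves only band totals — all carboxyl-type carbon COY
(COOH + amide CON, 160–185 ppm) and all O-substituted aromatic carbon
PhOY (140–160 ppm). Band mole fractions convert to mmol/g through
`x·%C/1.20011` (12.011/10), and elemental nitrogen through
`%N·10/14.007` (IUPAC atomic weights). Titrated capacity is split by
stepwise logK: steps below 7 count as COOH, the rest as PhOH, each step
contributing its site concentration once, so the two pools always sum
to the total step capacity regardless of threshold. The threshold is
configurable (the humic-substance literature's logK < 8 convention is
available), and the classification is applied per stepwise constant,
so both steps of a diprotic site with logK < 7 count as carboxylic. The
balances `COY = COOH + CONR` and `N = NR + CONR` then yield the amide
and non-amide nitrogen pools; a negative pool raises an error naming
the violated balance. No attribution of individual constants to named
moieties beyond this split is attempted.

Two numerical conventions worth noting. Report tables round half-even
on the shortest decimal representation (`report_round`), which is how a
two-decimal table entry like 1.015 + 0.67 = 1.685 prints as 1.68; full
precision is kept internally. And applying the band conversion to the
*rounded* published composition table does not exactly reproduce the
published band totals (e.g. a COY of 4.45 vs a printed 4.55 mmol/g) —
the original values were evidently computed from unrounded NMR
fractions. The implementation computes faithfully from its inputs and
makes no attempt to force-match those cells; reconstructed NR values
agree with the printed ones within ±0.03 mmol/g, a pure rounding
artifact.

## Synthetic data

The generator reproduces the study conditions as its defaults: 25 mL of
0.5 g/L SBO in 0.1 mol/L TEACl, net strong acid solved so the curve
starts at pH 3.0, titrated with 0.1 mol/L KOH on a uniform-in-volume
schedule ending where the noise-free curve reaches pH 11.5, 80 points
by default (the study took 50–120). Noise is independent Gaussian per
point with SD equal to the instrument resolution: 0.1 mV on EMF and
0.001 mL on the delivered volume (the nominal volume is recorded, the
equilibrium computed at the perturbed one — the same error structure
the propagated weights assume). Identical seeds give bit-identical
datasets; the generating truth and seed are embedded in the dataset's
provenance metadata for recovery tests.

What the generator does **not** emulate: the forward/reverse titration
hysteresis seen in real SBO curves (a conformational effect with no
quantitative model — reverse schedules reuse the same equilibrium
chemistry and are therefore labeled no-hysteresis), pH drift and slow
equilibration, CO₂ contamination, acid-side precipitation, and any
dependence of the constants on dissociation degree. Passing recovery
tests therefore demonstrate estimator correctness under the stated
error model, not robustness to those real-data effects.

## Problem sizes used in the test suite

Recovery and consistency studies are sized for a laptop-class run:
noise-free self-consistency covers all nine published parameter sets at
60 points each; the stochastic recovery study uses 50 replicates of the
80-point discrete-model design; χ²-consistency uses 200 replicates of a
one-site 40-point design; the speciation solver is checked against an
independent 1e−9 bisection oracle on 1000 random models. The full
suite runs in roughly three minutes.

## Known limitations

* Conditional constants only; results do not transfer to other ionic
  media without recalibration.
* The discrete-site abstraction compresses a continuous acidity
  distribution; site counts are model choices, not molecular counts.
* EMF-space weighting assumes uncorrelated point errors; drift and
  equilibration failures violate this.
* The published weighted fit deviations (1.4–3.0) depend on the
  original raw data and the original software's internals and are
  carried only as reference metadata on the fixtures.
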