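"""Refinement of protonation constants and site concentrations.

Given a titration, an electrode model and a protonation-model template
with initial guesses, the fitter minimizes the weighted sum of squared
EMF residuals

    S = sum_i w_i (E_obs,i - E_calc,i)^2,     w_i = 1 / s_i^2,

where the per-point variance propagates the two instrument resolutions:

    s_i^2 = sigma_E^2 + (dE/dv)_i^2 * sigma_v^2 .

Steep (equivalence-region) points are therefore down-weighted.  The
quality statistic is the weighted standard deviation of the fit,
``sqrt(S / (n_points - n_params))``: zero for a perfect fit, about one
when the residual scatter matches the assumed error model.

Parameters are optimized on scales that make the chemistry structural:
stepwise logK values directly (cumulative constants are their running
sum, so the cumulative series stays increasing as long as the stepwise
values stay positive) and log10 of the site concentrations, so
positivity never needs a constraint.  The optimizer is a trust-region
reflective least-squares solver; the classical Gauss-Newton treatment
of the linearized mass-balance system is honored in spirit, not
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InvalidModelError
from .speciation import (
    AcidSite,
    ProtonationModel,
    SolutionState,
    TitrationDataset,
    cumulative_from_stepwise,
    stepwise_from_cumulative,
    titration_ph,
)

__all__ = [
    "WeightingScheme",
    "FitResult",
    "point_weights",
    "sigma_of_fit",
    "fit_protonation_model",
    "compare_models",
    "auto_initial_guesses",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class WeightingScheme:
    """Per-point weighting of EMF residuals.

    ``sigma_e`` and ``sigma_v`` default to the instrument resolutions
    (0.1 mV potentiometer, 0.001 mL burette).  Mode ``"unit"`` sets
    every weight to one.
    """

    sigma_e: float = 0.1
    sigma_v: float = 0.001
    mode: str = "propagated"

    def __post_init__(self):
        if not (self.sigma_e > 0 and self.sigma_v > 0):
            raise InvalidModelError("weighting sigmas must be > 0")
        if self.mode not in ("propagated", "unit"):
            raise InvalidModelError(f"unknown weighting mode {self.mode!r}")


@dataclass
class FitResult:
    """Outcome of one refinement."""

    model: ProtonationModel
    std_devs: dict[str, float]
    sigma_fit: float
    residuals: np.ndarray  # weighted residuals sqrt(w) * (E_obs - E_calc)
    weights: np.ndarray
    n_points: int
    n_params: int
    c_strong_acid: float
    converged: bool
    message: str = ""
    flagged: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Table-shaped report: one row per protonation step."""
        rows = []
        for site in self.model.sites:
            logk = site.stepwise_logk
            for r, (lb, k) in enumerate(zip(site.cum_logbeta, logk), start=1):
                rows.append(
                    {
                        "site": site.site_id,
                        "step": r,
                        "logbeta": lb,
                        "logK": k,
                        "sd_logbeta": self.std_devs.get(f"{site.site_id}:logbeta{r}", np.nan),
                        "conc_mmol_per_g": site.conc_per_gram,
                        "sd_conc": self.std_devs.get(f"{site.site_id}:conc", np.nan),
                    }
                )
        return pd.DataFrame(rows)


def point_weights(
    data: TitrationDataset,
    electrode,
    weighting: WeightingScheme,
    emf: np.ndarray | None = None,
) -> np.ndarray:
    """Weights w_i = 1/s_i^2 with s_i^2 = sigma_e^2 + (dE/dv)_i^2 sigma_v^2.

    The curve slope dE/dv is estimated from the *observed* readings by
    centered finite differences (one-sided at the ends), so weights do
    not depend on the model being fitted.
    """
    v = data.volume_mL
    if np.any(np.diff(v) <= 0):
        idx = int(np.argmax(np.diff(v) <= 0)) + 1
        raise InvalidModelError(
            f"duplicate or non-increasing volume at point {idx}; "
            "cannot form finite differences"
        )
    if weighting.mode == "unit":
        return np.ones(len(v))
    e = np.asarray(emf if emf is not None else data.observed_emf(electrode), dtype=float)
    dEdv = np.gradient(e, v)
    s2 = weighting.sigma_e**2 + (dEdv * weighting.sigma_v) ** 2
    return 1.0 / s2


def sigma_of_fit(residuals: Sequence[float], weights: Sequence[float], n_params: int) -> float:
    """Weighted standard deviation of the fit.

    ``sqrt( sum_i w_i r_i^2 / (n - p) )`` with raw (unweighted)
    residuals ``r_i``; dimensionless when the weights carry 1/mV^2.
    """
    r = np.asarray(residuals, dtype=float)
    w = np.asarray(weights, dtype=float)
    dof = len(r) - n_params
    if dof <= 0:
        raise InvalidModelError(f"need more points ({len(r)}) than parameters ({n_params})")
    return float(np.sqrt(np.sum(w * r**2) / dof))


# ---------------------------------------------------------------------------
# parameter packing


def _pack(model: ProtonationModel, c_strong_acid: float, refine_strong_acid: bool):
    names, x0 = [], []
    for site in model.sites:
        for r, k in enumerate(site.stepwise_logk, start=1):
            names.append(f"{site.site_id}:logK{r}")
            x0.append(k)
        names.append(f"{site.site_id}:log10conc")
        x0.append(math.log10(site.conc_per_gram))
    if refine_strong_acid:
        names.append("c_strong_acid")
        x0.append(c_strong_acid)
    return names, np.array(x0, dtype=float)


def _unpack(
    x: np.ndarray,
    template: ProtonationModel,
    c_strong_acid: float,
    refine_strong_acid: bool,
):
    sites, i = [], 0
    for site in template.sites:
        logk = x[i : i + site.n_steps]
        i += site.n_steps
        conc = 10.0 ** x[i]
        i += 1
        sites.append(
            AcidSite(site.site_id, tuple(cumulative_from_stepwise(logk)), conc)
        )
    acid = x[i] if refine_strong_acid else c_strong_acid
    return template.with_sites(sites), float(acid)


def _std_devs_from_fit(
    sol, names: list[str], model: ProtonationModel, sigma: float
) -> dict[str, float]:
    """Map optimizer-scale covariances onto chemical parameters.

    Cumulative logbeta_r is the running sum of the stepwise logK, so its
    variance needs the full covariance block of the site's logK values;
    concentration sds come from the log10 scale by the delta method.
    """
    out: dict[str, float] = {}
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.pinv(jtj) * sigma**2
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    i = 0
    for site in model.sites:
        block = cov[i : i + site.n_steps, i : i + site.n_steps]
        for r in range(1, site.n_steps + 1):
            ones = np.ones(r)
            var = float(ones @ block[:r, :r] @ ones)
            out[f"{site.site_id}:logbeta{r}"] = math.sqrt(max(var, 0.0))
            out[f"{site.site_id}:logK{r}"] = float(sd[i + r - 1])
        i += site.n_steps
        out[f"{site.site_id}:conc"] = float(_LN10 * site.conc_per_gram * sd[i])
        i += 1
    if i < len(names):
        out["c_strong_acid"] = float(sd[i])
    return out


# ---------------------------------------------------------------------------
# main refinement


def fit_protonation_model(
    data: TitrationDataset,
    electrode,
    structure: ProtonationModel,
    weighting: WeightingScheme | None = None,
    refine_strong_acid: bool = False,
    ph_min: float | None = None,
    ph_max: float | None = None,
    multistart: int = 0,
) -> FitResult:
    """Refine protonation constants and site concentrations.

    Parameters
    ----------
    structure:
        Model template carrying the initial guesses; its site layout
        (mono/diprotic pattern) is preserved.  A diprotic site carries
        two constants but a single concentration, exactly as a
        shared-concentration H2A/HA pair.
    ph_min, ph_max:
        Optional observed-pH window; points outside are masked before
        fitting (used e.g. to refine a diprotic site on the acid branch
        only, then widen the window and add a site).
    multistart:
        When > 0, rerun from a deterministic grid of logK offsets
        (all-site shifts in {-1, 0, +1}) and keep the best objective.
    """
    if weighting is None:
        weighting = WeightingScheme()
    if not structure.sites:
        raise InvalidModelError("structure must contain at least one site")

    e_obs_full = np.asarray(data.observed_emf(electrode), dtype=float)
    ph_obs_full = electrode.ph(e_obs_full)
    mask = np.ones(len(data), dtype=bool)
    if ph_min is not None:
        mask &= ph_obs_full >= ph_min
    if ph_max is not None:
        mask &= ph_obs_full <= ph_max
    n_points = int(mask.sum())

    names, x0 = _pack(structure, data.state.c_strong_acid, refine_strong_acid)
    n_params = len(names)
    if n_points < n_params + 5:
        raise InvalidModelError(
            f"need at least n_params + 5 = {n_params + 5} points in the "
            f"window, have {n_points}"
        )
    if not np.all(np.isfinite(x0)):
        raise InvalidModelError("initial guesses must be finite")

    w_full = point_weights(data, electrode, weighting, emf=e_obs_full)
    # mask after differencing so edge weights stay consistent
    w = w_full[mask]
    sqw = np.sqrt(w)
    e_obs = e_obs_full[mask]
    volumes = data.volume_mL[mask]

    def residuals(x):
        model, acid = _unpack(x, structure, data.state.c_strong_acid, refine_strong_acid)
        st = replace(data.state, c_strong_acid=acid)
        ph = titration_ph(model, st, volumes)
        return sqw * (e_obs - electrode.emf(ph))

    def solve(x_init):
        return least_squares(
            residuals,
            x_init,
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            x_scale="jac",
            max_nfev=400 * len(x_init),
        )

    sol = solve(x0)
    if multistart > 0:
        for shift in (-1.0, 1.0):
            x_alt = x0.copy()
            i = 0
            for site in structure.sites:
                x_alt[i : i + site.n_steps] += shift
                i += site.n_steps + 1
            try:
                alt = solve(x_alt)
            except Exception:
                continue
            if alt.cost < sol.cost:
                sol = alt

    model, acid = _unpack(sol.x, structure, data.state.c_strong_acid, refine_strong_acid)
    sigma = sigma_of_fit(sol.fun / sqw, w, n_params=n_params)
    std_devs = _std_devs_from_fit(sol, names, model, sigma)

    # flag parameters the data cannot determine: a site whose logK lies
    # outside the observed pH window leaves a near-singular column
    flagged = []
    ph_window = ph_obs_full[mask]
    lo, hi = float(ph_window.min()) - 1.0, float(ph_window.max()) + 1.0
    for site in model.sites:
        for r, k in enumerate(site.stepwise_logk, start=1):
            if not (lo <= k <= hi):
                flagged.append(f"{site.site_id}:logK{r} (= {k:.2f}) outside data window")

    return FitResult(
        model=model,
        std_devs=std_devs,
        sigma_fit=sigma,
        residuals=sol.fun,
        weights=w,
        n_points=n_points,
        n_params=n_params,
        c_strong_acid=acid,
        converged=bool(sol.status > 0),
        message=sol.message,
        flagged=flagged,
    )


def compare_models(
    data: TitrationDataset,
    electrode,
    structures: Sequence[ProtonationModel],
    weighting: WeightingScheme | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[str, "FitResult | Exception"]]:
    """Fit several model structures on identical data and rank by sigma_fit.

    A failing structure is recorded with its exception and the
    comparison continues; the ranking table contains only the fits that
    succeeded.
    """
    if len(structures) < 2:
        raise InvalidModelError("model comparison needs at least two structures")
    results: dict[str, FitResult | Exception] = {}
    rows = []
    for s in structures:
        try:
            res = fit_protonation_model(data, electrode, s, weighting, **fit_kwargs)
        except Exception as err:  # keep ranking the rest
            results[s.name] = err
            continue
        results[s.name] = res
        rows.append(
            {
                "model": s.name,
                "n_params": res.n_params,
                "sigma_fit": res.sigma_fit,
                "converged": res.converged,
            }
        )
    if not rows:
        raise FitError("every candidate structure failed to fit")
    table = (
        pd.DataFrame(rows).sort_values("sigma_fit", kind="stable").reset_index(drop=True)
    )
    return table, results


# ---------------------------------------------------------------------------
# initial-guess heuristic


def auto_initial_guesses(
    data: TitrationDataset,
    electrode,
    n_sites: int,
    name: str = "auto",
) -> ProtonationModel:
    """Deterministic starting model from the shape of the observed curve.

    Buffer plateaus (low |dpH/dv|) mark pH regions where a site is
    half-protonated, so the plateau pH values seed the logK guesses:
    the points with below-median slope are split, in pH order, into
    ``n_sites`` equal chunks whose median pH becomes a logK guess.
    The total base consumed across the fitted window, divided evenly,
    seeds the concentrations.  Crude, but only a starting point.
    """
    ph = np.asarray(data.observed_ph(electrode), dtype=float)
    v = data.volume_mL
    slope = np.abs(np.gradient(ph, v))
    buffered = ph[slope <= np.median(slope)]
    buffered = np.sort(buffered)
    if len(buffered) < n_sites:
        buffered = np.sort(ph)
    chunks = np.array_split(buffered, n_sites)
    logks = sorted(float(np.median(c)) for c in chunks if len(c))
    while len(logks) < n_sites:  # degenerate tiny datasets
        logks.append((logks[-1] if logks else 7.0) + 1.0)
    # total titrant consumed, mmol, spread over sites and per gram of SBO
    mmol_base = data.state.titrant_conc * (v[-1] - v[0])  # mmol (M * mL)
    grams = data.state.sbo_conc * data.state.v0 * 1e-3
    conc_each = max(mmol_base / max(grams, 1e-12) / n_sites, 1e-3)
    sites = [
        AcidSite(f"auto{i+1}", (logk,), conc_each) for i, logk in enumerate(logks)
    ]
    return ProtonationModel(name, tuple(sites))
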