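"""Glass-electrode calibration from strong acid / strong base titrations.

The cell response is modeled with the standard refinement convention of
ESAB-class programs:

    E (mV) = E0 - slope * pH + j_a * [H+]

with ``slope`` the Nernst slope (59.16 mV per decade at 25 C, positive
by this sign convention) and ``j_a`` the acidic junction-potential
coefficient, so the junction term ``E_j = j_a [H+]`` matters only on the
acid branch.  No alkaline junction term is modeled.

Calibration titrates a known HCl solution (default 10 mmol/L, same
ionic medium as the samples) with standard KOH and refines any subset
of {E0, j_a, pKw, slope, acid concentration} by weighted least squares
on the EMF residuals, sharing the weighting stack of the main fit so
the two stages use identical conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import ConfigurationError, UnderdeterminedError
from .speciation import (
    PH_BRACKET,
    ProtonationModel,
    SolutionState,
    TitrationDataset,
    titration_ph,
)

__all__ = ["ElectrodeModel", "emf_from_ph", "ph_from_emf", "calibrate_electrode"]

#: theoretical Nernst slope at 25 C, mV per pH decade
NERNST_SLOPE_25C = 59.16

_LN10 = math.log(10.0)

REFINABLE = ("e0", "j_a", "pKw", "slope", "acid_conc")


@dataclass(frozen=True)
class ElectrodeModel:
    """Electrode parameters: formal potential, slope, junction term, pKw."""

    e0: float
    slope: float = NERNST_SLOPE_25C
    j_a: float = 0.0
    pKw: float = 13.78

    def __post_init__(self):
        if not math.isfinite(self.j_a):
            raise ConfigurationError("j_a must be finite")
        if abs(self.slope - NERNST_SLOPE_25C) > 0.1 * NERNST_SLOPE_25C:
            raise ConfigurationError(
                f"slope {self.slope} deviates more than 10% from the "
                f"theoretical {NERNST_SLOPE_25C} mV/decade; construct with "
                "object.__setattr__ bypass only if you really mean it"
            )

    def emf(self, ph):
        """Cell EMF (mV) at the given pH (scalar or array)."""
        ph = np.asarray(ph, dtype=float)
        out = self.e0 - self.slope * ph + self.j_a * np.power(10.0, -ph)
        return float(out) if out.ndim == 0 else out

    def ph(self, emf):
        """Invert the response numerically (unique by monotonicity)."""
        self._check_monotone()
        emf_arr = np.atleast_1d(np.asarray(emf, dtype=float))
        out = np.array([self._ph_scalar(e) for e in emf_arr])
        return float(out[0]) if np.ndim(emf) == 0 else out

    def _ph_scalar(self, e: float) -> float:
        lo, hi = PH_BRACKET
        if self.j_a == 0.0:
            return (self.e0 - e) / self.slope
        f = lambda p: self.emf(p) - e
        if f(lo) * f(hi) > 0:
            raise ConfigurationError(f"EMF {e} mV outside electrode range")
        return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)

    def _check_monotone(self, ph_min: float = PH_BRACKET[0]) -> None:
        # dE/dpH = -slope - j_a ln10 10^-pH; most positive at the acid end
        d = -self.slope - self.j_a * _LN10 * 10.0 ** (-ph_min)
        if d >= 0:
            raise ConfigurationError(
                f"electrode response not monotone over pH >= {ph_min} "
                f"(slope={self.slope}, j_a={self.j_a})"
            )


def emf_from_ph(electrode: ElectrodeModel, ph):
    """Functional form E = E0 - slope*pH + j_a*10^-pH."""
    return electrode.emf(ph)


def ph_from_emf(electrode: ElectrodeModel, emf):
    return electrode.ph(emf)


def _unsafe_electrode(e0, slope, j_a, pKw) -> ElectrodeModel:
    """Build an ElectrodeModel bypassing the slope guard (optimizer internals)."""
    obj = object.__new__(ElectrodeModel)
    object.__setattr__(obj, "e0", float(e0))
    object.__setattr__(obj, "slope", float(slope))
    object.__setattr__(obj, "j_a", float(j_a))
    object.__setattr__(obj, "pKw", float(pKw))
    return obj


def calibrate_electrode(
    data: TitrationDataset,
    refine: Iterable[str] = ("e0",),
    initial: ElectrodeModel | None = None,
    weighting=None,
) -> tuple[ElectrodeModel, dict[str, float]]:
    """Refine electrode parameters from a strong acid vs strong base titration.

    Parameters
    ----------
    data:
        Strong-acid titration; ``data.state.c_strong_acid`` is the known
        analytical HCl concentration (refined only when ``"acid_conc"``
        is requested).
    refine:
        Subset of ``{"e0", "j_a", "pKw", "slope", "acid_conc"}``.
    initial:
        Starting electrode; defaults to slope 59.16, j_a 0, pKw from the
        solution state and e0 read off the most acidic point.
    weighting:
        A :class:`protospec.fit.WeightingScheme`; defaults to the
        propagated instrument-resolution weights.

    Returns
    -------
    (electrode, std_devs):
        Refined model and asymptotic standard deviations for the
        refined parameters (plus ``"acid_conc"`` when refined; the
        refined acid concentration itself is reported in the std-dev
        dict under ``"acid_conc_value"``).

    Notes
    -----
    Refining pKw requires readings on the alkaline branch: without
    points past neutrality the water term never enters the balance and
    the parameter is unidentifiable.
    """
    from .fit import WeightingScheme, point_weights, sigma_of_fit  # shared stack

    refine = tuple(refine)
    unknown = set(refine) - set(REFINABLE)
    if unknown:
        raise ConfigurationError(f"cannot refine {sorted(unknown)}; allowed {REFINABLE}")
    if len(data) < 10:
        raise UnderdeterminedError("calibration needs at least 10 points")
    if weighting is None:
        weighting = WeightingScheme()

    state = data.state
    if initial is None:
        guess_pkw = state.pKw
        initial = ElectrodeModel(e0=0.0, pKw=guess_pkw)
        # crude e0 from the first (most acidic) point assuming known acid
        ph0 = titration_ph(ProtonationModel("none"), state, data.volume_mL[:1])[0]
        e_obs0 = float(data.observed_emf(_unsafe_electrode(0, NERNST_SLOPE_25C, 0, guess_pkw))[0])
        initial = replace(initial, e0=e_obs0 + NERNST_SLOPE_25C * ph0)

    if "pKw" in refine:
        # identifiability: need points on the alkaline branch
        probe = _unsafe_electrode(initial.e0, initial.slope, initial.j_a, initial.pKw)
        ph_obs = data.observed_ph(probe)
        if not np.any(ph_obs > 8.0):
            raise UnderdeterminedError(
                "pKw refinement requested but no alkaline-branch readings "
                "(pH > 8) are present"
            )

    e_obs = np.asarray(
        data.observed_emf(
            _unsafe_electrode(initial.e0, initial.slope, initial.j_a, initial.pKw)
        ),
        dtype=float,
    )
    w = point_weights(data, electrode=None, weighting=weighting, emf=e_obs)
    sqw = np.sqrt(w)
    no_sites = ProtonationModel("none")

    base = {
        "e0": initial.e0,
        "j_a": initial.j_a,
        "pKw": initial.pKw,
        "slope": initial.slope,
        "acid_conc": state.c_strong_acid,
    }
    x0 = np.array([base[name] for name in refine])

    def unpack(x):
        vals = dict(base)
        vals.update(dict(zip(refine, x)))
        return vals

    def residuals(x):
        v = unpack(x)
        st = replace(state, c_strong_acid=v["acid_conc"], pKw=min(max(v["pKw"], 10.0), 15.0))
        ph = titration_ph(no_sites, st, data.volume_mL)
        ecalc = _unsafe_electrode(v["e0"], v["slope"], v["j_a"], v["pKw"]).emf(ph)
        return sqw * (e_obs - ecalc)

    sol = least_squares(
        residuals, x0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, x_scale="jac"
    )
    v = unpack(sol.x)
    electrode = _unsafe_electrode(v["e0"], v["slope"], v["j_a"], v["pKw"])

    sigma = sigma_of_fit(sol.fun / sqw, w, n_params=len(refine))
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * sigma**2
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sd = np.full(len(refine), np.nan)
    std_devs = dict(zip(refine, (float(s) for s in sd)))
    if "acid_conc" in refine:
        std_devs["acid_conc_value"] = float(v["acid_conc"])
    return electrode, std_devs
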