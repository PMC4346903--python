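"""Multi-site protonation models and the proton mass-balance solver.

The chemistry modeled here is the stepwise protonation of independent
acid site classes carried by a soluble bio-organic polymer (SBO).  Each
site class ``A`` binds up to ``n`` protons,

    A + r H+  <=>  AH_r,      beta_r = [AH_r] / ([A] [H+]^r),

with cumulative constants ``beta_r`` on the concentration scale at fixed
ionic strength (conditional constants; no activity corrections).  Only
the protonation level ``r`` is tracked, never the absolute charge of the
site: every quantity needed downstream (species fractions, bound
protons, titration curves) depends on ``r`` alone.

Proton reference state
----------------------
Sites enter the proton balance **fully protonated**: the analytical
"total proton" concentration of a solution counts the strong acid added
(net of strong base) *plus* ``n_steps`` protons per site.  With that
convention the balance solved by :func:`solve_free_hydrogen` reads

    [H+] - Kw/[H+] + sum_i C_i * nbar_i(pH) = C_H(total)

where ``nbar_i`` is the mean number of protons bound per site of class
``i``.  The left-hand side is strictly decreasing in pH, so the root is
unique and a bracketed Newton iteration with bisection safeguard always
converges.

Units: volumes mL, concentrations mol/L in solution, site loadings
mmol per gram of SBO dry matter, pH = -log10[H+].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InfeasibleCompositionError, InvalidModelError

__all__ = [
    "AcidSite",
    "ProtonationModel",
    "SolutionState",
    "SpeciesDistribution",
    "TitrationDataset",
    "stepwise_from_cumulative",
    "cumulative_from_stepwise",
    "species_fractions",
    "bound_protons_total",
    "solve_free_hydrogen",
    "simulate_titration",
]

_LN10 = math.log(10.0)

#: pH bracket inside which every physically meaningful root must lie.
PH_BRACKET = (-2.0, 16.0)


# ---------------------------------------------------------------------------
# constants conversion


def stepwise_from_cumulative(cum_logbeta: Sequence[float]) -> list[float]:
    """Convert cumulative log(beta_r) to stepwise log(K_r).

    ``K_r`` is the constant of adding the r-th proton to the (r-1)-fold
    protonated species, so ``logK_1 = logbeta_1`` and
    ``logK_r = logbeta_r - logbeta_{r-1}`` for r >= 2.

    Raises
    ------
    InvalidModelError
        If the input is empty or not strictly increasing (a cumulative
        series must grow with every proton added).
    """
    vals = [float(x) for x in cum_logbeta]
    if not vals:
        raise InvalidModelError("cum_logbeta must be non-empty")
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise InvalidModelError(
            f"cumulative logbeta must be strictly increasing, got {vals}"
        )
    return [vals[0]] + [b - a for a, b in zip(vals, vals[1:])]


def cumulative_from_stepwise(logk: Sequence[float]) -> list[float]:
    """Inverse of :func:`stepwise_from_cumulative` (exact involution)."""
    vals = [float(x) for x in logk]
    if not vals:
        raise InvalidModelError("logk must be non-empty")
    out = [vals[0]]
    for k in vals[1:]:
        out.append(out[-1] + k)
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AcidSite:
    """One class of protogenic sites.

    Parameters
    ----------
    site_id:
        Short label, e.g. ``"Hcvdf1"``.
    cum_logbeta:
        Cumulative protonation constants log10(beta_r), r = 1..n_steps,
        strictly increasing.
    conc_per_gram:
        Site concentration in mmol per gram of SBO dry matter.
    """

    site_id: str
    cum_logbeta: tuple[float, ...]
    conc_per_gram: float

    def __post_init__(self):
        object.__setattr__(self, "cum_logbeta", tuple(float(x) for x in self.cum_logbeta))
        if self.n_steps < 1:
            raise InvalidModelError(f"site {self.site_id}: needs >= 1 protonation step")
        # strictly-increasing check (and error) lives in the converter
        logk = stepwise_from_cumulative(self.cum_logbeta)
        if any(b > a + 1e-12 for a, b in zip(logk, logk[1:])):
            warnings.warn(
                f"site {self.site_id}: stepwise logK increases with r "
                f"({logk}); successive protonations are normally weaker",
                stacklevel=2,
            )
        if not self.conc_per_gram > 0:
            raise InvalidModelError(
                f"site {self.site_id}: conc_per_gram must be > 0, got {self.conc_per_gram}"
            )

    @property
    def n_steps(self) -> int:
        return len(self.cum_logbeta)

    @property
    def stepwise_logk(self) -> list[float]:
        return stepwise_from_cumulative(self.cum_logbeta)


@dataclass(frozen=True)
class ProtonationModel:
    """A named collection of acid sites (Model I / II / III or custom).

    The canonical structures:

    * Model I   — one diprotic site, optionally one extra monoprotic site
      (added when the fitted pH window is widened into the alkaline range).
    * Model II  — one diprotic site plus one or two monoprotic sites.
    * Model III — discrete model: every site monoprotic and independent.

    Structure is enforced when ``name`` matches one of those labels.
    """

    name: str
    sites: tuple[AcidSite, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise InvalidModelError(f"duplicate site ids in model {self.name!r}: {ids}")
        self._validate_structure()

    def _validate_structure(self) -> None:
        label = self.name.strip().lower()
        n_di = sum(1 for s in self.sites if s.n_steps == 2)
        n_mono = sum(1 for s in self.sites if s.n_steps == 1)
        n_other = len(self.sites) - n_di - n_mono
        if label == "model i":
            if n_di != 1 or n_mono > 1 or n_other:
                raise InvalidModelError(
                    "Model I requires exactly one diprotic site and at most "
                    f"one monoprotic site, got {self._shape()}"
                )
        elif label == "model ii":
            if n_di != 1 or not (1 <= n_mono <= 2) or n_other:
                raise InvalidModelError(
                    "Model II requires one diprotic site plus 1-2 monoprotic "
                    f"sites, got {self._shape()}"
                )
        elif label == "model iii":
            if self.sites and (n_di or n_other):
                raise InvalidModelError(
                    f"Model III sites must all be monoprotic, got {self._shape()}"
                )

    def _shape(self) -> str:
        return "[" + ", ".join(f"{s.site_id}:{s.n_steps}" for s in self.sites) + "]"

    @property
    def n_params(self) -> int:
        """Number of free chemical parameters (constants + concentrations)."""
        return sum(s.n_steps + 1 for s in self.sites)

    def total_steps_mmol_per_g(self) -> float:
        """Total protonation-step capacity, mmol/g (each step counts once)."""
        return sum(s.n_steps * s.conc_per_gram for s in self.sites)

    def with_sites(self, sites: Sequence[AcidSite]) -> "ProtonationModel":
        return replace(self, sites=tuple(sites))


@dataclass(frozen=True)
class SolutionState:
    """Composition and conditions of the initial titration solution.

    ``c_strong_acid`` is the *net* analytical strong-acid concentration
    (mol/L, referred to ``v0``): HCl added minus KOH carried over from
    sample dissolution.  It may be negative when excess base dominates.
    ``ionic_strength`` and ``temperature_C`` are metadata only; all
    constants are conditional at the working medium.
    """

    v0: float = 25.0
    sbo_conc: float = 0.5
    c_strong_acid: float = 0.0
    titrant_conc: float = 0.1
    titrant_sign: int = 1
    pKw: float = 13.78
    temperature_C: float = 25.0
    ionic_strength: float = 0.1

    def __post_init__(self):
        if not self.v0 > 0:
            raise InvalidModelError(f"v0 must be > 0, got {self.v0}")
        if not self.titrant_conc > 0:
            raise InvalidModelError(f"titrant_conc must be > 0, got {self.titrant_conc}")
        if self.titrant_sign not in (-1, 1):
            raise InvalidModelError(f"titrant_sign must be +-1, got {self.titrant_sign}")
        if not (10.0 <= self.pKw <= 15.0):
            raise InvalidModelError(f"pKw must lie in [10, 15], got {self.pKw}")
        if self.sbo_conc < 0:
            raise InvalidModelError(f"sbo_conc must be >= 0, got {self.sbo_conc}")


@dataclass(frozen=True)
class SpeciesDistribution:
    """Protonation-state fractions of one site at a given pH.

    ``alpha[r]`` is the fraction of sites carrying ``r`` protons,
    ``nbar`` the mean number of bound protons per site.
    """

    site_id: str
    ph: float
    alpha: tuple[float, ...]
    nbar: float


@dataclass
class TitrationDataset:
    """One titration: cumulative titrant volumes with pH and/or EMF readings.

    ``meta`` carries free-form provenance (generator truth, seeds, file
    origin); it never influences computation.
    """

    volume_mL: np.ndarray
    state: SolutionState
    ph: np.ndarray | None = None
    emf_mV: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume_mL = np.asarray(self.volume_mL, dtype=float)
        if self.ph is not None:
            self.ph = np.asarray(self.ph, dtype=float)
        if self.emf_mV is not None:
            self.emf_mV = np.asarray(self.emf_mV, dtype=float)
        if self.ph is None and self.emf_mV is None:
            raise InvalidModelError("dataset needs a pH or an EMF column")
        n = len(self.volume_mL)
        for arr, name in ((self.ph, "ph"), (self.emf_mV, "emf_mV")):
            if arr is not None and len(arr) != n:
                raise InvalidModelError(f"{name} length {len(arr)} != volumes {n}")
        if np.any(np.diff(self.volume_mL) < 0):
            raise InvalidModelError("titrant volumes must be non-decreasing")

    def __len__(self) -> int:
        return len(self.volume_mL)

    def observed_emf(self, electrode) -> np.ndarray:
        """EMF readings, converting from pH via the electrode if needed."""
        if self.emf_mV is not None:
            return self.emf_mV
        return electrode.emf(self.ph)

    def observed_ph(self, electrode=None) -> np.ndarray:
        """pH readings, inverting the electrode response if needed."""
        if self.ph is not None:
            return self.ph
        if electrode is None:
            raise InvalidModelError("EMF-encoded dataset needs an electrode for pH")
        return electrode.ph(self.emf_mV)


# ---------------------------------------------------------------------------
# speciation arithmetic


def _alpha_matrix(cum_logbeta: Sequence[float], ph: np.ndarray) -> np.ndarray:
    """Fractions alpha_r for r = 0..n at each pH; shape (n+1, len(ph)).

    Works in log space and subtracts the per-point maximum before
    exponentiation so extreme pH never overflows.
    """
    logb = np.concatenate(([0.0], np.asarray(cum_logbeta, dtype=float)))
    r = np.arange(len(logb), dtype=float)
    t = _LN10 * (logb[:, None] - r[:, None] * ph[None, :])
    t -= t.max(axis=0, keepdims=True)
    w = np.exp(t)
    return w / w.sum(axis=0, keepdims=True)


def _nbar_and_var(cum_logbeta: Sequence[float], ph: np.ndarray):
    """Mean and variance of the number of bound protons at each pH."""
    a = _alpha_matrix(cum_logbeta, ph)
    r = np.arange(a.shape[0], dtype=float)
    nbar = (r[:, None] * a).sum(axis=0)
    var = (r[:, None] ** 2 * a).sum(axis=0) - nbar**2
    return nbar, var


def species_fractions(site: AcidSite, ph: float) -> SpeciesDistribution:
    """Distribution of protonation states of ``site`` at a single pH."""
    if not math.isfinite(ph):
        raise InvalidModelError(f"pH must be finite, got {ph}")
    pharr = np.array([float(ph)])
    a = _alpha_matrix(site.cum_logbeta, pharr)[:, 0]
    nbar = float(np.dot(np.arange(len(a)), a))
    return SpeciesDistribution(site.site_id, float(ph), tuple(float(x) for x in a), nbar)


def bound_protons_total(
    model: ProtonationModel, site_conc_molar: Sequence[float], ph: float
) -> float:
    """Site-bound proton concentration (mol/L) at a given pH.

    ``site_conc_molar`` gives each site's molar concentration in the
    (diluted) solution, ordered as ``model.sites``.
    """
    conc = np.asarray(site_conc_molar, dtype=float)
    if len(conc) != len(model.sites):
        raise InvalidModelError(
            f"need one concentration per site: {len(conc)} != {len(model.sites)}"
        )
    if np.any(conc < 0):
        raise InvalidModelError("site concentrations must be >= 0")
    pharr = np.array([float(ph)])
    total = 0.0
    for site, c in zip(model.sites, conc):
        nbar, _ = _nbar_and_var(site.cum_logbeta, pharr)
        total += c * nbar[0]
    return float(total)


# ---------------------------------------------------------------------------
# proton-balance solver


def _solve_ph_array(
    logbetas: list[Sequence[float]],
    site_conc: np.ndarray,
    total_proton: np.ndarray,
    pKw: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Vectorized bracketed Newton on the proton balance.

    Parameters
    ----------
    logbetas:
        Per-site cumulative logbeta sequences.
    site_conc:
        Molar site concentrations, shape (n_sites, m).
    total_proton:
        Analytical total proton concentration per point, shape (m,),
        in the fully-protonated-site reference state.
    """
    total_proton = np.asarray(total_proton, dtype=float)
    m = total_proton.shape[0]
    lo = np.full(m, PH_BRACKET[0])
    hi = np.full(m, PH_BRACKET[1])

    def f_fp(ph):
        h = np.power(10.0, -ph)
        oh = np.power(10.0, ph - pKw)
        f = h - oh - total_proton
        fp = -_LN10 * (h + oh)
        for lb, c in zip(logbetas, site_conc):
            nbar, var = _nbar_and_var(lb, ph)
            f = f + c * nbar
            fp = fp - _LN10 * c * var
        return f, fp

    f_lo, _ = f_fp(lo)
    f_hi, _ = f_fp(hi)
    bad = (f_lo < 0) | (f_hi > 0)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise InfeasibleCompositionError(
            f"proton balance has no root in pH {PH_BRACKET} at point {idx} "
            f"(total_proton={total_proton[idx]:.3e})"
        )

    x = 0.5 * (lo + hi)
    for _ in range(max_iter):
        f, fp = f_fp(x)
        # f is strictly decreasing: f > 0 means the root lies above x
        lo = np.where(f > 0, x, lo)
        hi = np.where(f <= 0, x, hi)
        xn = x - f / fp
        outside = (xn <= lo) | (xn >= hi) | ~np.isfinite(xn)
        xn = np.where(outside, 0.5 * (lo + hi), xn)
        if np.all(np.abs(xn - x) < tol) and np.all(hi - lo < 1e-6):
            x = xn
            break
        x = xn
    return x


def solve_free_hydrogen(
    model: ProtonationModel,
    state: SolutionState,
    total_proton: float,
    site_conc_molar: Sequence[float] | None = None,
) -> float:
    """Solve the proton mass balance for pH at a single composition.

    ``total_proton`` is the analytical excess-proton concentration
    (mol/L) with sites counted fully protonated.  When
    ``site_conc_molar`` is omitted the molar site concentrations are
    derived from the model loadings and ``state.sbo_conc`` (undiluted).
    """
    if site_conc_molar is None:
        site_conc_molar = [
            s.conc_per_gram * state.sbo_conc * 1e-3 for s in model.sites
        ]
    conc = np.asarray(site_conc_molar, dtype=float).reshape(len(model.sites), 1)
    ph = _solve_ph_array(
        [s.cum_logbeta for s in model.sites],
        conc,
        np.array([float(total_proton)]),
        state.pKw,
    )
    return float(ph[0])


def _titration_totals(model: ProtonationModel, state: SolutionState, volumes: np.ndarray):
    """Diluted per-point site concentrations and total proton.

    Every initial component is diluted by v0/(v0+v); the titrant
    contributes titrant_conc * v/(v0+v) with its sign (+1 KOH removes
    protons from the total, -1 HCl adds them).
    """
    dil = state.v0 / (state.v0 + volumes)
    site_conc = np.array(
        [s.conc_per_gram * state.sbo_conc * 1e-3 for s in model.sites]
    ).reshape(-1, 1) * dil[None, :]
    titrant = state.titrant_sign * state.titrant_conc * volumes / (state.v0 + volumes)
    total = state.c_strong_acid * dil - titrant
    for s, c in zip(model.sites, site_conc):
        total = total + s.n_steps * c
    return site_conc, total


def titration_ph(
    model: ProtonationModel, state: SolutionState, volumes: np.ndarray
) -> np.ndarray:
    """Noise-free equilibrium pH at each cumulative titrant volume."""
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes < 0):
        raise InvalidModelError("volumes must be non-negative")
    if np.any(np.diff(volumes) < 0):
        raise InvalidModelError("volumes must be non-decreasing")
    site_conc, total = _titration_totals(model, state, volumes)
    try:
        return _solve_ph_array(
            [s.cum_logbeta for s in model.sites], site_conc, total, state.pKw
        )
    except InfeasibleCompositionError as err:
        raise InfeasibleCompositionError(f"titration point failed: {err}") from err


def simulate_titration(
    model: ProtonationModel,
    state: SolutionState,
    volumes: Sequence[float],
    electrode=None,
) -> TitrationDataset:
    """Simulate a noise-free titration curve.

    At each cumulative volume the component totals are rediluted, the
    proton balance solved, and — when an electrode model is supplied —
    the cell EMF evaluated from the solved pH.
    """
    volumes = np.asarray(volumes, dtype=float)
    ph = titration_ph(model, state, volumes)
    emf = electrode.emf(ph) if electrode is not None else None
    return TitrationDataset(
        volume_mL=volumes,
        state=state,
        ph=ph,
        emf_mV=emf,
        meta={"model": model.name, "noise_free": True},
    )
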