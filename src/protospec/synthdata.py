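"""Synthetic titration datasets with realistic instrument noise.

No raw titration tables are deposited for these biopolymers, so every
pipeline stage is exercised on generated data reproducing the reported
experimental design: 25 mL of 0.5 g/L SBO in 0.1 mol/L TEACl, acidified
to pH ~ 3 with HCl, titrated with 0.1 mol/L KOH up to pH 11.5, 50-120
readings per run, potentiometer resolution 0.1 mV and burette
resolution 0.001 mL.

Noise model: independent Gaussian errors per point, SD equal to the
instrument resolution, applied to the EMF reading and to the delivered
volume (the *nominal* volume is recorded, the equilibrium is computed
at the true, perturbed volume — exactly the error structure assumed by
the propagated weighting scheme).  Titration hysteresis is **not**
simulated: reverse schedules reuse the same equilibrium model.

``fixtures()`` exposes the published reference parameterizations (three
SBOs x Models I-III plus the composition records) transcribed
digit-for-digit from the source tables; they drive recovery tests and
the worked examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .calibrate import ElectrodeModel
from .errors import DesignError, InvalidModelError
from .groups import NmrComposition
from .speciation import (
    AcidSite,
    ProtonationModel,
    SolutionState,
    TitrationDataset,
    bound_protons_total,
    titration_ph,
)

__all__ = [
    "NoiseSpec",
    "SboFixture",
    "fixtures",
    "default_design",
    "make_sbo_titration",
    "make_calibration_titration",
]

DEFAULT_ELECTRODE = ElectrodeModel(e0=400.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise: EMF SD (mV), volume SD (mL), RNG seed."""

    sigma_e: float = 0.1
    sigma_v: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.sigma_e < 0 or self.sigma_v < 0:
            raise InvalidModelError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class SboFixture:
    """Published reference record for one SBO: composition + three models."""

    name: str
    composition: NmrComposition
    models: dict
    sigma_fit_reported: dict

    def __getitem__(self, model_name: str) -> ProtonationModel:
        return self.models[model_name]


def _load_tables() -> dict:
    with resources.files("protospec.data").joinpath("reference_tables.json").open() as fh:
        return json.load(fh)


def fixtures() -> dict[str, SboFixture]:
    """The published parameter sets (three SBOs x Models I/II/III)."""
    raw = _load_tables()
    out = {}
    for sbo, comp in raw["compositions"].items():
        models = {}
        sigmas = {}
        for model_name, spec in raw["models"][sbo].items():
            sites = tuple(
                AcidSite(s["id"], tuple(s["logbeta"]), s["conc_mmol_per_g"])
                for s in spec["sites"]
            )
            models[model_name] = ProtonationModel(model_name, sites)
            sigmas[model_name] = spec["sigma_fit_reported"]
        out[sbo] = SboFixture(
            name=sbo,
            composition=NmrComposition(
                name=sbo,
                pct_C=comp["pct_C"],
                pct_N=comp["pct_N"],
                mole_fractions=dict(comp["mole_fractions"]),
                ash_pct=comp["ash_pct"],
                cmc=comp["cmc_g_per_L"],
            ),
            models=models,
            sigma_fit_reported=sigmas,
        )
    return out


# ---------------------------------------------------------------------------
# design helpers


def _acid_for_start_ph(model: ProtonationModel, state: SolutionState, ph_start: float) -> float:
    """Net strong-acid concentration that puts the initial solution at ph_start."""
    h = 10.0**-ph_start
    oh = 10.0 ** (ph_start - state.pKw)
    site_conc = [s.conc_per_gram * state.sbo_conc * 1e-3 for s in model.sites]
    bound = 0.0
    if model.sites:
        bound = bound_protons_total(model, site_conc, ph_start)
    total = h - oh + bound
    return total - sum(s.n_steps * c for s, c in zip(model.sites, site_conc))


def _volume_for_end_ph(model: ProtonationModel, state: SolutionState, ph_end: float) -> float:
    """Cumulative titrant volume at which the curve reaches ph_end."""
    def g(v):
        return float(titration_ph(model, state, np.array([0.0, v]))[1]) - ph_end

    v_hi = 1.0
    while g(v_hi) < 0:
        v_hi *= 2.0
        if v_hi > 40.0 * state.v0:
            raise DesignError(
                f"pH {ph_end} unreachable with titrant {state.titrant_conc} M"
            )
    return brentq(g, 0.0, v_hi, xtol=1e-10)


def default_design(
    model: ProtonationModel,
    n_points: int = 80,
    ph_start: float = 3.0,
    ph_end: float = 11.5,
    v0: float = 25.0,
    sbo_conc: float = 0.5,
    titrant_conc: float = 0.1,
    pKw: float = 13.78,
) -> tuple[SolutionState, np.ndarray]:
    """Reproduce the reference alkalimetric design for a given model.

    The starting strong-acid concentration is solved so the acidified
    solution sits at ``ph_start``; the uniform-in-volume schedule ends
    at the volume where the noise-free curve reaches ``ph_end``.
    """
    if not 2 <= n_points <= 1000:
        raise DesignError(f"n_points {n_points} out of range")
    state = SolutionState(
        v0=v0, sbo_conc=sbo_conc, titrant_conc=titrant_conc, pKw=pKw
    )
    acid = _acid_for_start_ph(model, state, ph_start)
    state = SolutionState(
        v0=v0,
        sbo_conc=sbo_conc,
        c_strong_acid=acid,
        titrant_conc=titrant_conc,
        pKw=pKw,
    )
    v_end = _volume_for_end_ph(model, state, ph_end)
    volumes = np.linspace(0.0, v_end, n_points)
    return state, volumes


# ---------------------------------------------------------------------------
# generators


def _apply_noise(
    model: ProtonationModel,
    state: SolutionState,
    volumes: np.ndarray,
    electrode: ElectrodeModel,
    noise: NoiseSpec,
) -> TitrationDataset:
    rng = np.random.default_rng(noise.seed)
    v_true = volumes + rng.normal(0.0, noise.sigma_v, size=len(volumes)) if noise.sigma_v else volumes
    if noise.sigma_v:
        # keep the physical schedule monotone; resolution-scale noise
        # essentially never violates this for sane spacing
        v_true = np.maximum.accumulate(np.maximum(v_true, 0.0))
    ph_true = titration_ph(model, state, v_true)
    emf = electrode.emf(ph_true)
    if noise.sigma_e:
        emf = emf + rng.normal(0.0, noise.sigma_e, size=len(volumes))
    noiseless = noise.sigma_e == 0 and noise.sigma_v == 0
    return TitrationDataset(
        volume_mL=volumes,
        state=state,
        ph=ph_true if noiseless else None,
        emf_mV=emf,
        meta={
            "model": model.name,
            "noise_free": noiseless,
            "provenance": {
                "seed": noise.seed,
                "sigma_e_mV": noise.sigma_e,
                "sigma_v_mL": noise.sigma_v,
                "true_params": {
                    s.site_id: {
                        "logbeta": list(s.cum_logbeta),
                        "conc_mmol_per_g": s.conc_per_gram,
                    }
                    for s in model.sites
                },
                "electrode": {
                    "e0": electrode.e0,
                    "slope": electrode.slope,
                    "j_a": electrode.j_a,
                    "pKw": electrode.pKw,
                },
                "c_strong_acid": state.c_strong_acid,
            },
        },
    )


def make_sbo_titration(
    model: ProtonationModel,
    state: SolutionState | None = None,
    volumes: np.ndarray | None = None,
    electrode: ElectrodeModel = DEFAULT_ELECTRODE,
    noise: NoiseSpec = NoiseSpec(),
    n_points: int = 80,
) -> TitrationDataset:
    """Generate one alkalimetric SBO titration with instrument noise.

    With ``state``/``volumes`` omitted the reference design is built via
    :func:`default_design`.  The true generating parameters and seed are
    embedded in ``meta["provenance"]`` for recovery tests.
    """
    if state is None or volumes is None:
        state, volumes = default_design(model, n_points=n_points)
    volumes = np.asarray(volumes, dtype=float)
    return _apply_noise(model, state, volumes, electrode, noise)


def make_calibration_titration(
    electrode: ElectrodeModel = DEFAULT_ELECTRODE,
    c_hcl: float = 0.010,
    c_koh: float = 0.1,
    v0: float = 25.0,
    noise: NoiseSpec = NoiseSpec(),
    n_points: int = 50,
    ph_end: float = 11.0,
) -> TitrationDataset:
    """Strong acid vs strong base calibration titration (HCl by KOH)."""
    state = SolutionState(
        v0=v0,
        sbo_conc=0.0,
        c_strong_acid=c_hcl,
        titrant_conc=c_koh,
        pKw=electrode.pKw,
    )
    empty = ProtonationModel("none")
    v_end = _volume_for_end_ph(empty, state, ph_end)
    volumes = np.linspace(0.0, v_end, n_points)
    return _apply_noise(empty, state, volumes, electrode, noise)
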