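"""Speciation arithmetic, the proton-balance solver and titration curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import bisect_ph, direct_alpha, direct_nbar
from protospec import (
    AcidSite,
    ProtonationModel,
    SolutionState,
    bound_protons_total,
    cumulative_from_stepwise,
    simulate_titration,
    solve_free_hydrogen,
    species_fractions,
    stepwise_from_cumulative,
)
from protospec.errors import InfeasibleCompositionError, InvalidModelError

NO_SITES = ProtonationModel("none")


# ---------------------------------------------------------------------------
# cumulative <-> stepwise constants


@pytest.mark.parametrize(
    "cum, step",
    [
        ([5.69, 9.83], [5.69, 4.14]),  # CVDF diprotic site
        ([6.12, 10.32], [6.12, 4.20]),  # FORSUD diprotic site
        ([5.10, 8.61], [5.10, 3.51]),  # CVT230 diprotic site
        ([5.0], [5.0]),  # monoprotic identity
    ],
)
def test_stepwise_from_cumulative(cum, step):
    assert stepwise_from_cumulative(cum) == pytest.approx(step, abs=1e-12)


@pytest.mark.parametrize("bad", [[], [5.0, 5.0], [6.0, 4.0]])
def test_stepwise_rejects_non_increasing(bad):
    with pytest.raises(InvalidModelError):
        stepwise_from_cumulative(bad)


@given(
    st.lists(
        st.floats(min_value=0.05, max_value=6.0, allow_nan=False),
        min_size=1,
        max_size=5,
    )
)
def test_conversion_is_exact_involution(increments):
    """cumulative_from_stepwise inverts stepwise_from_cumulative exactly."""
    cum = list(np.cumsum(increments))
    if any(b <= a for a, b in zip(cum, cum[1:])):  # float-degenerate draw
        return
    step = stepwise_from_cumulative(cum)
    assert cumulative_from_stepwise(step) == pytest.approx(cum, abs=0)
    assert stepwise_from_cumulative(cumulative_from_stepwise(step)) == pytest.approx(
        step, abs=0
    )


# ---------------------------------------------------------------------------
# species fractions


def test_half_protonation_at_ph_equal_logk():
    site = AcidSite("a", (5.0,), 1.0)
    d = species_fractions(site, 5.0)
    assert d.alpha == pytest.approx((0.5, 0.5), abs=1e-12)
    assert d.nbar == pytest.approx(0.5, abs=1e-12)


def test_full_protonation_limit():
    site = AcidSite("a", (5.0,), 1.0)
    assert species_fractions(site, 0.0).alpha[1] == pytest.approx(1.0, abs=1e-5)


def test_diprotic_fractions_match_arbitrary_precision_oracle():
    """Frozen expected values from exact rational arithmetic (sympy):
    alpha_r = beta_r 10^(-r pH) / sum_j beta_j 10^(-j pH) for the
    [5.69, 9.83] site at pH 4.77."""
    site = AcidSite("a", (5.69, 9.83), 1.0)
    d = species_fractions(site, 4.77)
    assert d.alpha[0] == pytest.approx(0.08875097137209104, rel=1e-13)
    assert d.alpha[1] == pytest.approx(0.7381984263747564, rel=1e-13)
    assert d.alpha[2] == pytest.approx(0.17305060225315259, rel=1e-13)
    assert d.nbar == pytest.approx(1.0842996308810616, rel=1e-13)


@given(
    st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=1, max_size=4),
    st.floats(min_value=-2.0, max_value=16.0),
)
@settings(max_examples=200)
def test_fraction_normalization_everywhere(increments, ph):
    """Sum of alpha_r is 1 to 1e-12 at any pH, however extreme the
    constants; the log-space evaluation must never overflow."""
    steps = sorted((float(x) + 2.0 for x in increments), reverse=True)
    cum = tuple(float(x) for x in np.cumsum(steps))
    d = species_fractions(AcidSite("a", cum, 1.0), ph)
    assert sum(d.alpha) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= a <= 1.0 for a in d.alpha)
    assert 0.0 <= d.nbar <= len(cum)


def test_nbar_non_increasing_in_ph():
    site = AcidSite("a", (6.0, 10.0), 1.0)
    phs = np.linspace(-2, 16, 300)
    nbars = [species_fractions(site, p).nbar for p in phs]
    assert np.all(np.diff(nbars) <= 1e-12)


def test_increasing_stepwise_logk_warns_not_raises():
    with pytest.warns(UserWarning, match="stepwise logK increases"):
        AcidSite("odd", (4.0, 9.0), 1.0)  # logK2 = 5 > logK1 = 4


# ---------------------------------------------------------------------------
# bound protons


def test_bound_protons_empty_model_is_zero():
    assert bound_protons_total(NO_SITES, [], 7.0) == 0.0


def test_bound_protons_half_protonation():
    model = ProtonationModel("m", (AcidSite("a", (5.0,), 1.0),))
    assert bound_protons_total(model, [1e-3], 5.0) == pytest.approx(5e-4, rel=1e-12)


def test_bound_protons_matches_independent_sum(fx):
    """CVDF discrete model at pH 7, sites scaled to 0.5 g/L."""
    model = fx["CVDF"]["Model III"]
    conc = [s.conc_per_gram * 0.5e-3 for s in model.sites]
    expected = sum(
        c * direct_nbar(s.cum_logbeta, 7.0) for s, c in zip(model.sites, conc)
    )
    assert bound_protons_total(model, conc, 7.0) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# proton-balance solver


def test_strong_acid_ph():
    state = SolutionState(pKw=13.78)
    assert solve_free_hydrogen(NO_SITES, state, 1e-3) == pytest.approx(3.0, abs=1e-6)


def test_neutral_water_ph_is_half_pkw():
    state = SolutionState(pKw=13.78)
    assert solve_free_hydrogen(NO_SITES, state, 0.0) == pytest.approx(
        13.78 / 2, abs=1e-9
    )


def test_weak_acid_matches_quadratic_and_bisection():
    """Monoprotic logK 5 at 1 mM, fully protonated: the closed-form
    quadratic (water neglected) gives pH 4.02170568645711; the full
    balance must also match a 1e-9 bisection oracle."""
    model = ProtonationModel("m", (AcidSite("a", (5.0,), 1.0),))
    state = SolutionState(pKw=13.78)
    ph = solve_free_hydrogen(model, state, 1e-3, site_conc_molar=[1e-3])
    assert ph == pytest.approx(4.0217056864571119, abs=1e-3)
    oracle = bisect_ph([((5.0,), 1e-3)], 1e-3, 13.78)
    assert ph == pytest.approx(oracle, abs=2e-9)


def test_infeasible_composition_raises():
    with pytest.raises(InfeasibleCompositionError):
        solve_free_hydrogen(NO_SITES, SolutionState(), 1e3)


def test_solver_agrees_with_bisection_on_random_models():
    """Spot check against the independent oracle; the full 1000-model
    sweep runs in the acceptance suite."""
    rng = np.random.default_rng(11)
    for _ in range(60):
        n_sites = rng.integers(1, 6)
        sites, oracle_sites = [], []
        for i in range(n_sites):
            logk = float(rng.uniform(2, 12))
            conc = float(10 ** rng.uniform(-5, -2))
            sites.append(AcidSite(f"s{i}", (logk,), 1.0))
            oracle_sites.append(((logk,), conc))
        model = ProtonationModel("rand", tuple(sites))
        conc = [c for _, c in oracle_sites]
        total = float(rng.uniform(-1e-3, 1e-3)) + sum(conc)
        state = SolutionState(pKw=13.78)
        ph = solve_free_hydrogen(model, state, total, site_conc_molar=conc)
        assert ph == pytest.approx(bisect_ph(oracle_sites, total, 13.78), abs=2e-9)


# ---------------------------------------------------------------------------
# titration simulation


def test_strong_acid_equivalence_inflection():
    """1 mM strong acid in 25 mL vs 0.1 M KOH: steepest pH change at
    v_eq = 0.25 mL."""
    state = SolutionState(v0=25.0, sbo_conc=0.0, c_strong_acid=1e-3)
    vols = np.linspace(0.0, 0.5, 501)
    ds = simulate_titration(NO_SITES, state, vols)
    v_steepest = vols[np.argmax(np.gradient(ds.ph, vols))]
    assert v_steepest == pytest.approx(0.25, abs=2e-3)


def test_weak_acid_buffer_midpoint():
    """pH at half-equivalence approximates logK for a concentrated
    weak monoprotic acid."""
    model = ProtonationModel("m", (AcidSite("a", (5.0,), 1.0),))
    # 10 mmol/g at 2 g/L -> 0.02 M sites, fully protonated, no extra acid
    model = model.with_sites([AcidSite("a", (5.0,), 10.0)])
    state = SolutionState(v0=25.0, sbo_conc=2.0)
    v_eq = 0.02 * 25.0 / 0.1  # 5 mL of 0.1 M KOH
    ds = simulate_titration(model, state, np.array([0.0, v_eq / 2]))
    assert ds.ph[1] == pytest.approx(5.0, abs=0.02)


def test_simulated_ph_strictly_increasing_with_base(fx):
    model = fx["CVDF"]["Model III"]
    state = SolutionState(sbo_conc=0.5, c_strong_acid=1e-3)
    vols = np.linspace(0, 2.0, 100)
    ds = simulate_titration(model, state, vols)
    assert np.all(np.diff(ds.ph) > 0)


def test_titration_curve_matches_pointwise_oracle(fx):
    """CVDF discrete model at 0.5 g/L: point-by-point agreement with an
    independent dense-bisection speciation oracle."""
    model = fx["CVDF"]["Model III"]
    state = SolutionState(v0=25.0, sbo_conc=0.5, c_strong_acid=1e-3)
    vols = np.linspace(0.0, 2.0, 25)
    ds = simulate_titration(model, state, vols)
    for v, ph in zip(vols, ds.ph):
        dil = 25.0 / (25.0 + v)
        oracle_sites = [
            (s.cum_logbeta, s.conc_per_gram * 0.5e-3 * dil) for s in model.sites
        ]
        total = 1e-3 * dil - 0.1 * v / (25.0 + v)
        total += sum(s.n_steps * c for s, (_, c) in zip(model.sites, oracle_sites))
        assert ph == pytest.approx(
            bisect_ph(oracle_sites, total, 13.78, tol=1e-10), abs=1e-6
        )


def test_conservation_of_total_proton(fx):
    """Reconstructing the analytical total proton from the solved
    speciation reproduces the input at every simulated point."""
    model = fx["FORSUD"]["Model III"]
    state = SolutionState(v0=25.0, sbo_conc=0.5, c_strong_acid=1.2e-3)
    vols = np.linspace(0.0, 2.2, 60)
    ds = simulate_titration(model, state, vols)
    for v, ph in zip(vols, ds.ph):
        dil = 25.0 / (25.0 + v)
        conc = [s.conc_per_gram * 0.5e-3 * dil for s in model.sites]
        total_in = (
            1.2e-3 * dil
            - 0.1 * v / (25.0 + v)
            + sum(s.n_steps * c for s, c in zip(model.sites, conc))
        )
        recon = (
            10.0**-ph
            - 10.0 ** (ph - state.pKw)
            + bound_protons_total(model, conc, ph)
        )
        assert abs(recon - total_in) <= 1e-12 + 1e-10 * abs(total_in)


def test_model_structure_validation(fx):
    with pytest.raises(InvalidModelError):
        ProtonationModel("Model III", (AcidSite("d", (5.0, 9.0), 1.0),))
    with pytest.raises(InvalidModelError):
        ProtonationModel("Model I", (AcidSite("m", (5.0,), 1.0),))
    with pytest.raises(InvalidModelError):
        ProtonationModel(
            "x", (AcidSite("a", (5.0,), 1.0), AcidSite("a", (6.0,), 1.0))
        )
    # the published structures themselves must all validate
    for sbo in fx.values():
        assert set(sbo.models) == {"Model I", "Model II", "Model III"}
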