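"""Independent scalar oracles used by the tests.

Deliberately naive implementations — plain Python floats, direct
evaluation of the binding polynomial, interval bisection — kept free of
any code shared with the package so they can arbitrate against it.
"""

from __future__ import annotations


def direct_alpha(logbetas, ph):
    """Species fractions by direct term-by-term evaluation of the
    binding polynomial (beta_0 = 1)."""
    terms = [1.0] + [10.0 ** (lb - (r + 1) * ph) for r, lb in enumerate(logbetas)]
    den = sum(terms)
    return [t / den for t in terms]


def direct_nbar(logbetas, ph):
    a = direct_alpha(logbetas, ph)
    return sum(r * x for r, x in enumerate(a))


def proton_balance(sites, total_proton, pkw, ph):
    """f(pH) for the proton condition; sites = [(logbetas, conc_molar)]."""
    h = 10.0**-ph
    f = h - 10.0 ** (ph - pkw) - total_proton
    for logbetas, conc in sites:
        f += conc * direct_nbar(logbetas, ph)
    return f


def bisect_ph(sites, total_proton, pkw, lo=-2.0, hi=16.0, tol=1e-9):
    """Pure bisection on the proton condition to ``tol`` in pH."""
    assert proton_balance(sites, total_proton, pkw, lo) > 0
    assert proton_balance(sites, total_proton, pkw, hi) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if proton_balance(sites, total_proton, pkw, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
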