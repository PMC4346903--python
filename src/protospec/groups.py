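"""Functional-group bookkeeping: titration pools vs NMR/elemental totals.

13C NMR on these biopolymers resolves only broad band totals: all
carboxyl-type carbon COY (COOH plus amide CON, 160-185 ppm) and all
O-substituted aromatic carbon PhOY (phenol OH plus aryl ethers,
140-160 ppm).  Potentiometric titration, in turn, sees only the
protogenic subset.  Combining the two with the elemental nitrogen
content closes the bookkeeping:

    COY = COOH + CONR        (amide carbon is the non-titratable rest)
    N   = NR + CONR          (organic N splits into amide and the rest)

NMR mole fractions of total organic carbon convert to mmol per gram of
dry matter through the elemental carbon percentage:

    C_i [mmol/g] = x_i * %C / 1.20011

(the factor is 12.011 g/mol divided by 10, turning wt% C into mmol C/g).

Titrated sites are split into the carboxylic and phenolic pools by
their stepwise logK: values below 7 are attributed to -COOH, the rest
to PhOH.  (The humic-substance literature often uses 8; that preset is
available via ``threshold_logk=8``.)  Attribution of individual logK
values to specific moieties beyond this split is deliberately not
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

from .errors import InconsistentBreakdownError, InvalidModelError
from .speciation import ProtonationModel

__all__ = [
    "NmrComposition",
    "FunctionalGroupBreakdown",
    "nmr_to_mmol_per_g",
    "n_total_mmol_per_g",
    "classify_sites",
    "breakdown",
    "breakdown_from_composition",
    "report_round",
]

#: 12.011 / 10 — converts (mole fraction of C) * (wt% C) to mmol/g
CARBON_FACTOR = 1.20011

ATOMIC_WEIGHT_N = 14.007

#: stepwise logK below this is attributed to carboxylic groups
DEFAULT_LOGK_THRESHOLD = 7.0

C_TYPES = ("aliphatic", "NR", "OR", "Ar", "PhOY", "COY")


@dataclass(frozen=True)
class NmrComposition:
    """Elemental and 13C NMR composition of one SBO (dry-matter basis)."""

    name: str
    pct_C: float
    pct_N: float
    mole_fractions: dict = field(default_factory=dict)
    ash_pct: float = 0.0
    cmc: float | None = None

    def __post_init__(self):
        if not (0.0 < self.pct_C < 100.0) or not (0.0 < self.pct_N < 100.0):
            raise InvalidModelError(
                f"{self.name}: %C and %N must lie in (0, 100), "
                f"got {self.pct_C}, {self.pct_N}"
            )
        for key, frac in self.mole_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise InvalidModelError(
                    f"{self.name}: mole fraction {key}={frac} outside [0, 1]"
                )

    def mmol_per_g(self, c_type: str) -> float:
        """Band total for one C type, mmol per g dry matter."""
        return nmr_to_mmol_per_g(self.mole_fractions[c_type], self.pct_C)

    @property
    def n_total_mmol_per_g(self) -> float:
        return n_total_mmol_per_g(self.pct_N)


@dataclass(frozen=True)
class FunctionalGroupBreakdown:
    """COY/PhOY band totals broken into titratable and amide pools (mmol/g)."""

    coy: float
    phoy: float
    cooh: float
    phoh: float
    conr: float
    nr: float
    n_total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "PhOY": self.phoy,
            "COY": self.coy,
            "CONR": self.conr,
            "NR": self.nr,
            "COOH": self.cooh,
            "PhOH": self.phoh,
            "N_total": self.n_total,
        }


def report_round(value: float, ndigits: int = 2) -> float:
    """Round for report tables: half-even on the shortest decimal form.

    Full precision is kept internally everywhere; this is only applied
    when a value is *presented*.  Rounding the shortest decimal
    representation (rather than the binary float) makes e.g.
    1.015 + 0.67 report as 1.68, the half-even decimal result.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, ROUND_HALF_EVEN))


def nmr_to_mmol_per_g(mole_fraction: float, pct_C: float) -> float:
    """Convert an NMR C-type mole fraction to mmol of that C per gram."""
    if not (0.0 <= mole_fraction <= 1.0):
        raise InvalidModelError(f"mole fraction {mole_fraction} outside [0, 1]")
    if not (0.0 < pct_C < 100.0):
        raise InvalidModelError(f"%C {pct_C} outside (0, 100)")
    return mole_fraction * pct_C / CARBON_FACTOR


def n_total_mmol_per_g(pct_N: float) -> float:
    """Total organic nitrogen, mmol/g, from the elemental N percentage."""
    if not (0.0 < pct_N < 100.0):
        raise InvalidModelError(f"%N {pct_N} outside (0, 100)")
    return pct_N * 10.0 / ATOMIC_WEIGHT_N


def classify_sites(
    fit_or_model,
    threshold_logk: float = DEFAULT_LOGK_THRESHOLD,
) -> tuple[float, float]:
    """Split titrated site capacity into (cooh, phoh) pools, mmol/g.

    Every protonation step contributes its site's concentration once;
    steps with stepwise logK strictly below the threshold count as
    carboxylic, the rest as phenolic.  The two pools always sum to the
    total step capacity, whatever the threshold.

    Accepts either a :class:`~protospec.fit.FitResult` or a
    :class:`~protospec.speciation.ProtonationModel`.
    """
    model: ProtonationModel = getattr(fit_or_model, "model", fit_or_model)
    cooh = phoh = 0.0
    for site in model.sites:
        for logk in site.stepwise_logk:
            if logk < threshold_logk:
                cooh += site.conc_per_gram
            else:
                phoh += site.conc_per_gram
    return cooh, phoh


def breakdown(coy: float, n_total: float, cooh: float, phoy: float = float("nan"), phoh: float = float("nan")) -> FunctionalGroupBreakdown:
    """Close the COY/N bookkeeping: CONR = COY - COOH, NR = N - CONR.

    Raises
    ------
    InconsistentBreakdownError
        If a pool goes negative, naming the violated balance.
    """
    conr = coy - cooh
    if conr < 0:
        raise InconsistentBreakdownError(
            f"COY = COOH + CONR violated: COY={coy:.3f} < COOH={cooh:.3f}"
        )
    nr = n_total - conr
    if nr < 0:
        raise InconsistentBreakdownError(
            f"N = NR + CONR violated: N={n_total:.3f} < CONR={conr:.3f}"
        )
    return FunctionalGroupBreakdown(
        coy=coy, phoy=phoy, cooh=cooh, phoh=phoh, conr=conr, nr=nr, n_total=n_total
    )


def breakdown_from_composition(
    composition: NmrComposition,
    fit_or_model,
    threshold_logk: float = DEFAULT_LOGK_THRESHOLD,
) -> FunctionalGroupBreakdown:
    """Full pipeline step: NMR bands + titrated pools -> breakdown."""
    coy = composition.mmol_per_g("COY")
    phoy = composition.mmol_per_g("PhOY")
    cooh, phoh = classify_sites(fit_or_model, threshold_logk)
    return breakdown(
        coy=coy,
        n_total=composition.n_total_mmol_per_g,
        cooh=cooh,
        phoy=phoy,
        phoh=phoh,
    )
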