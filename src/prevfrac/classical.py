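"""Classical attributable-fraction formulas and their validity condition.

The Miettinen formula AF = Pr(A=1 | Y=1) (RR - 1) / RR and the Levin
formula AF = p (RR - 1) / (1 + p (RR - 1)), with p = Pr(A=1) and RR the
crude risk ratio Pr(Y=1|A=1) / Pr(Y=1|A=0), are built from observable
quantities only.  They recover the causal attributable fraction exactly
when partial exchangeability under no exposure holds — Y^0 independent of
A — and in general not otherwise.  The condition is tested structurally on
the counterfactual population (comparing Pr(Y^0=1|A=1) with
Pr(Y^0=1|A=0)); it involves counterfactuals and is untestable from factual
data alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import UndefinedMeasureError
from .population import (
    PopulationSpec,
    counterfactual_risk,
    observed_risk,
    total_measures,
    validate_spec,
)

PARTIAL_EXCH_TOL = 1e-12

__all__ = ["ClassicalAFResult", "classical_af"]


@dataclass(frozen=True)
class ClassicalAFResult:
    rr_crude: float
    af_miettinen: float
    af_levin: float
    af_true: float
    partial_exchangeability_holds: bool


def classical_af(spec: PopulationSpec) -> ClassicalAFResult:
    """Evaluate both classical formulas on the observable margin of a
    counterfactual population, alongside the true attributable fraction."""
    validate_spec(spec)
    p_y1 = observed_risk(spec)
    if p_y1 <= 0.0:
        raise UndefinedMeasureError("Pr(Y=1) = 0")
    risk1 = observed_risk(spec, arm=1)
    risk0 = observed_risk(spec, arm=0)
    if risk0 <= 0.0:
        raise UndefinedMeasureError("Pr(Y=1 | A=0) = 0: crude risk ratio undefined")
    rr = risk1 / risk0
    p_exposed = sum(c.mass for c in spec.cells if c.arm == 1)
    p_exposed_cases = sum(
        c.mass * c.observed_risk for c in spec.cells if c.arm == 1
    ) / p_y1  # Pr(A=1 | Y=1)
    af_miettinen = p_exposed_cases * (rr - 1.0) / rr
    af_levin = p_exposed * (rr - 1.0) / (1.0 + p_exposed * (rr - 1.0))
    af_true = total_measures(spec).af_total
    partial = abs(
        counterfactual_risk(spec, set_to=0, arm=1)
        - counterfactual_risk(spec, set_to=0, arm=0)
    ) < PARTIAL_EXCH_TOL
    return ClassicalAFResult(
        rr_crude=rr,
        af_miettinen=af_miettinen,
        af_levin=af_levin,
        af_true=af_true,
        partial_exchangeability_holds=partial,
    )
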