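"""Stratum decomposition of the total-population impact measures.

Each total measure is a weighted average of stratum-specific measures, with
case-frequency weights Pr(M=m | Y=1) — the share of factual cases in each
stratum — not the population frequencies Pr(M=m).  Strata whose residents
are at higher risk of the outcome therefore contribute more than their
population share.  The same weight vector is exact for the caseload measures
(PF, AF) and for the proportion measures (PP, AP).

Reversing the exposure coding (relabel A: 1<->0, so the treated become the
"unexposed") turns the preventable fraction of the original population into
the attributable fraction of the recoded one, stratum by stratum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from .exceptions import UndefinedMeasureError
from .population import (
    Cell,
    MeasureSet,
    PopulationSpec,
    ResponseTypeDist,
    observed_risk,
    counterfactual_risk,
    total_measures,
    validate_spec,
)

FORM_TOL = 1e-12  # agreement between algebraically equivalent forms

__all__ = [
    "StratumMeasure",
    "Decomposition",
    "stratum_measures",
    "case_weights",
    "decompose",
    "reverse_coding",
    "report_table",
]

MEASURE_NAMES = ("pf", "af", "pp", "ap")


@dataclass(frozen=True)
class StratumMeasure:
    """All four measures for the subpopulation M = m, plus its case weight."""

    stratum: str
    pf_m: float
    af_m: float
    pp_m: float
    ap_m: float
    p_y1_m: float  # Pr(Y=1 | M=m)
    weight: float  # Pr(M=m | Y=1)

    def __getitem__(self, measure: str) -> float:
        return {
            "pf": self.pf_m,
            "af": self.af_m,
            "pp": self.pp_m,
            "ap": self.ap_m,
        }[measure]


@dataclass(frozen=True)
class Decomposition:
    """Per-stratum measures, case weights, their weighted sum, and the
    directly computed total; identity_residual is |weighted - direct| and
    should sit at floating-point noise."""

    measure_name: str
    strata: tuple[StratumMeasure, ...]
    weighted_total: float
    direct_total: float
    identity_residual: float


def _stratum_mass(spec: PopulationSpec, stratum: str) -> float:
    return sum(c.mass for c in spec.cells if c.stratum == stratum)


def _stratum_case_prob(spec: PopulationSpec, stratum: str) -> float:
    """Pr(Y=1, M=m)."""
    return sum(
        c.mass * c.observed_risk for c in spec.cells if c.stratum == stratum
    )


def stratum_measures(spec: PopulationSpec, stratum: str) -> StratumMeasure:
    """Measures for the subpopulation M = stratum.

    PF_m is computed both from its definition (conditional risks given M=m)
    and from the Bayes-rule form
    Pr(A=0, M=m) (Pr(Y=1|A=0,M=m) - Pr(Y^1=1|A=0,M=m)) / Pr(Y=1, M=m);
    the two must agree to floating-point precision (likewise AF_m).
    """
    p_case_m = _stratum_case_prob(spec, stratum)
    if p_case_m <= 0.0:
        raise UndefinedMeasureError(
            f"no cases in stratum {stratum!r}: Pr(Y=1, M={stratum!r}) = 0"
        )
    p_y1_m = observed_risk(spec, stratum=stratum)
    cf1_m = counterfactual_risk(spec, set_to=1, stratum=stratum)
    cf0_m = counterfactual_risk(spec, set_to=0, stratum=stratum)
    pf_m = (p_y1_m - cf1_m) / p_y1_m
    af_m = (p_y1_m - cf0_m) / p_y1_m

    # Bayes-rule forms, accumulated from the untreated (pf) / treated (af)
    # cells only; consistency removes the same-arm terms.
    c0 = spec.cell(stratum, 0)
    c1 = spec.cell(stratum, 1)
    pf_m_bayes = c0.mass * (c0.observed_risk - c0.counterfactual_risk(1)) / p_case_m
    af_m_bayes = c1.mass * (c1.observed_risk - c1.counterfactual_risk(0)) / p_case_m
    if abs(pf_m - pf_m_bayes) > FORM_TOL or abs(af_m - af_m_bayes) > FORM_TOL:
        raise AssertionError(
            f"equivalent stratum-measure forms disagree in stratum {stratum!r}: "
            f"pf {pf_m!r} vs {pf_m_bayes!r}, af {af_m!r} vs {af_m_bayes!r}"
        )

    # Proportion analogues: replace counterfactual caseloads by the factual
    # cases that are also counterfactual cases, all conditional on M=m.
    mass_m = _stratum_mass(spec, stratum)
    joint1 = sum(
        c.mass * c.joint_case_risk(1) for c in spec.cells if c.stratum == stratum
    ) / mass_m
    joint0 = sum(
        c.mass * c.joint_case_risk(0) for c in spec.cells if c.stratum == stratum
    ) / mass_m
    pp_m = (p_y1_m - joint1) / p_y1_m
    ap_m = (p_y1_m - joint0) / p_y1_m

    p_y1 = observed_risk(spec)
    return StratumMeasure(
        stratum=stratum,
        pf_m=pf_m,
        af_m=af_m,
        pp_m=pp_m,
        ap_m=ap_m,
        p_y1_m=p_y1_m,
        weight=p_case_m / p_y1,
    )


def case_weights(spec: PopulationSpec) -> dict[str, float]:
    """Case-frequency weights Pr(M=m | Y=1) = Pr(Y=1, M=m) / Pr(Y=1)."""
    p_y1 = observed_risk(spec)
    if p_y1 <= 0.0:
        raise UndefinedMeasureError("Pr(Y=1) = 0: case weights undefined")
    return {
        m: _stratum_case_prob(spec, m) / p_y1 for m in spec.stratum_labels
    }


def decompose(spec: PopulationSpec, measure_name: str) -> Decomposition:
    """Decompose a total measure into its case-weighted stratum average.

    Strata with no cases get weight 0 and are excluded from the weighted
    sum (their stratum measure is undefined there).
    """
    if measure_name not in MEASURE_NAMES:
        raise ValueError(
            f"unknown measure {measure_name!r}; expected one of {MEASURE_NAMES}"
        )
    validate_spec(spec)
    direct = total_measures(spec)[measure_name]
    strata: list[StratumMeasure] = []
    weighted = 0.0
    for m in spec.stratum_labels:
        if _stratum_case_prob(spec, m) <= 0.0:
            continue
        sm = stratum_measures(spec, m)
        strata.append(sm)
        weighted += sm[measure_name] * sm.weight
    return Decomposition(
        measure_name=measure_name,
        strata=tuple(strata),
        weighted_total=weighted,
        direct_total=direct,
        identity_residual=abs(weighted - direct),
    )


def reverse_coding(spec: PopulationSpec) -> PopulationSpec:
    """Relabel the exposure 1 <-> 0.  Arm labels flip, and the response
    types are remapped so that Y^a keeps its meaning under the new coding:
    helped <-> hurt, doomed and immune unchanged.  Applying it twice gives
    back the original population; the attributable fraction of the recoded
    population equals the preventable fraction of the original.
    """
    cells = []
    for c in spec.cells:
        d = c.response_types
        cells.append(
            Cell(
                stratum=c.stratum,
                arm=1 - c.arm,
                mass=c.mass,
                response_types=ResponseTypeDist(
                    doomed=d.doomed, helped=d.hurt, hurt=d.helped, immune=d.immune
                ),
            )
        )
    return PopulationSpec.from_cells(
        cells, stratum_labels=spec.stratum_labels,
        meta={**spec.meta, "exposure_coding_reversed": True},
    )


def report_table(
    spec: PopulationSpec, measure_name: str = "pf", round_to: int = 2
) -> str:
    """Delimited report mirroring the scenario's stratum/arm layout:
    per cell Pr(A=a, M=m), factual risk, counterfactual risk; per stratum
    Pr(Y=1|M=m), the stratum measure and its case weight; a Total line with
    Pr(Y=1), the counterfactual caseload, and the total measure.

    Numbers are fixed-point with trailing zeros at ``round_to`` decimals;
    stored values are never rounded.
    """
    dec = decompose(spec, measure_name)
    by_stratum = {sm.stratum: sm for sm in dec.strata}
    set_to = 1 if measure_name in ("pf", "pp") else 0

    def fmt(x: float) -> str:
        return f"{x:.{round_to}f}"

    cols = [
        "m", "a", "pr_a_m", "risk_factual", f"risk_set{set_to}",
        "pr_y1_given_m", f"{measure_name}_m", "weight", f"{measure_name}_total",
    ]
    out = io.StringIO()
    out.write("\t".join(cols) + "\n")
    for m in spec.stratum_labels:
        sm = by_stratum.get(m)
        for a in (0, 1):
            c = spec.cell(m, a)
            row = [m, str(a), fmt(c.mass), fmt(c.observed_risk),
                   fmt(c.counterfactual_risk(set_to))]
            if a == 0 and sm is not None:
                row += [fmt(sm.p_y1_m), fmt(sm[measure_name]), fmt(sm.weight), ""]
            else:
                row += ["", "", "", ""]
            out.write("\t".join(row) + "\n")
    ms = total_measures(spec)
    cf = ms.p_cf_treated if set_to == 1 else ms.p_cf_untreated
    out.write(
        "\t".join(
            ["Total", "", fmt(sum(c.mass for c in spec.cells)), fmt(ms.p_y1),
             fmt(cf), "", "", fmt(sum(sm.weight for sm in dec.strata)),
             fmt(dec.weighted_total)]
        )
        + "\n"
    )
    return out.getvalue()
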