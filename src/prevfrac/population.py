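"""Exact counterfactual populations for a binary exposure and binary outcome.

A population is specified per (effect-modifier stratum, exposure arm) cell:
the cell's probability mass Pr(A=a, M=m) and the joint distribution of the
two potential outcomes (Y^0, Y^1) within the cell, parameterized by the four
response types

    doomed  (Y^0=1, Y^1=1)   outcome regardless of exposure
    helped  (Y^0=1, Y^1=0)   outcome prevented by exposure
    hurt    (Y^0=0, Y^1=1)   outcome caused by exposure
    immune  (Y^0=0, Y^1=0)   no outcome regardless

The observed outcome follows by consistency: Y = Y^a for the arm a an
individual actually occupies.  Every factual and counterfactual probability,
and the four total-population impact measures, are exact cell sums:

    PF_total = (Pr(Y=1) - Pr(Y^1=1)) / Pr(Y=1)     preventable fraction (caseload)
    AF_total = (Pr(Y=1) - Pr(Y^0=1)) / Pr(Y=1)     attributable fraction (caseload)
    PP_total = (Pr(Y=1) - Pr(Y=1, Y^1=1)) / Pr(Y=1)  preventable proportion
    AP_total = (Pr(Y=1) - Pr(Y=1, Y^0=1)) / Pr(Y=1)  attributable proportion

The caseload measures contrast a factual against a counterfactual caseload
and may be negative; the proportions count only factual cases removed and
lie in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

from .exceptions import (
    SpecValidationError,
    UndefinedConditionalError,
    UndefinedMeasureError,
)

PROB_TOL = 1e-12  # validation tolerance for probability sums

__all__ = [
    "ResponseTypeDist",
    "Cell",
    "PopulationSpec",
    "MeasureSet",
    "validate_spec",
    "observed_risk",
    "counterfactual_risk",
    "total_measures",
    "load_scenario",
    "scenario_to_dict",
    "dump_scenario",
    "table1",
]


@dataclass(frozen=True)
class ResponseTypeDist:
    """Distribution of the joint potential outcomes within one cell."""

    doomed: float
    helped: float
    hurt: float
    immune: float

    def __post_init__(self) -> None:
        for name, p in self.as_dict().items():
            if not (-PROB_TOL <= p <= 1 + PROB_TOL):
                raise SpecValidationError(
                    f"response-type probability {name}={p!r} outside [0, 1]"
                )
        total = self.doomed + self.helped + self.hurt + self.immune
        if abs(total - 1.0) > PROB_TOL:
            raise SpecValidationError(
                f"response-type probabilities sum to {total!r}, not 1"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "doomed": self.doomed,
            "helped": self.helped,
            "hurt": self.hurt,
            "immune": self.immune,
        }

    def risk(self, set_to: int) -> float:
        """Pr(Y^set_to = 1) within the cell."""
        return self.doomed + (self.hurt if set_to == 1 else self.helped)

    @classmethod
    def from_margins(
        cls, risk_untreated: float, risk_treated: float
    ) -> "ResponseTypeDist":
        """Monotone (Frechet upper bound) completion of the joint from its
        margins: Pr(doomed) = min(r0, r1), so whichever arm has the lower
        risk contributes no one of the opposing harmed/helped type.  This is
        the conventional "no one harmed" coupling for a preventive exposure
        (no 'hurt' type whenever r1 <= r0); all caseload measures depend only
        on the margins and are unaffected by the choice.
        """
        r0, r1 = float(risk_untreated), float(risk_treated)
        doomed = min(r0, r1)
        helped = r0 - doomed
        hurt = r1 - doomed
        immune = 1.0 - doomed - helped - hurt
        return cls(doomed=doomed, helped=helped, hurt=hurt, immune=immune)


@dataclass(frozen=True)
class Cell:
    """One (stratum, arm) cell: Pr(A=arm, M=stratum) and the response-type
    distribution of (Y^0, Y^1) given membership in the cell."""

    stratum: str
    arm: int
    mass: float
    response_types: ResponseTypeDist

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise SpecValidationError(
                f"cell ({self.stratum!r}, arm={self.arm!r}): arm must be 0 or 1"
            )
        if not (-PROB_TOL <= self.mass <= 1 + PROB_TOL):
            raise SpecValidationError(
                f"cell ({self.stratum!r}, arm={self.arm}): mass {self.mass!r} "
                "outside [0, 1]"
            )

    @property
    def observed_risk(self) -> float:
        """Pr(Y=1 | A=arm, M=stratum), via consistency Y = Y^arm."""
        return self.response_types.risk(self.arm)

    def counterfactual_risk(self, set_to: int) -> float:
        """Pr(Y^set_to = 1 | A=arm, M=stratum)."""
        return self.response_types.risk(set_to)

    def joint_case_risk(self, set_to: int) -> float:
        """Pr(Y=1, Y^set_to=1 | cell).  When set_to == arm this is the
        observed risk; otherwise it is Pr(doomed)."""
        if set_to == self.arm:
            return self.observed_risk
        return self.response_types.doomed


@dataclass(frozen=True)
class PopulationSpec:
    """A fully specified counterfactual population: exactly one cell per
    (stratum, arm) pair, masses summing to one."""

    cells: tuple[Cell, ...]
    stratum_labels: tuple[str, ...]
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    @classmethod
    def from_cells(
        cls,
        cells: Iterable[Cell],
        stratum_labels: Iterable[str] | None = None,
        meta: Mapping[str, object] | None = None,
    ) -> "PopulationSpec":
        cells = tuple(cells)
        if stratum_labels is None:
            seen: list[str] = []
            for c in cells:
                if c.stratum not in seen:
                    seen.append(c.stratum)
            stratum_labels = seen
        return validate_spec(
            cls(cells=cells, stratum_labels=tuple(stratum_labels), meta=meta or {})
        )

    def cell(self, stratum: str, arm: int) -> Cell:
        for c in self.cells:
            if c.stratum == stratum and c.arm == arm:
                return c
        raise SpecValidationError(f"no cell for (stratum={stratum!r}, arm={arm})")

    def strata(self) -> tuple[str, ...]:
        return self.stratum_labels


@dataclass(frozen=True)
class MeasureSet:
    """The four total-population measures plus the probabilities they are
    built from."""

    pf_total: float
    af_total: float
    pp_total: float
    ap_total: float
    p_y1: float
    p_cf_treated: float  # Pr(Y^1 = 1)
    p_cf_untreated: float  # Pr(Y^0 = 1)

    def __getitem__(self, measure: str) -> float:
        return {
            "pf": self.pf_total,
            "af": self.af_total,
            "pp": self.pp_total,
            "ap": self.ap_total,
        }[measure]


def validate_spec(spec: PopulationSpec) -> PopulationSpec:
    """Check all structural invariants; return the spec unchanged if valid.

    Raises :class:`SpecValidationError` naming the offending cell otherwise.
    """
    pairs = set()
    for c in spec.cells:
        key = (c.stratum, c.arm)
        if key in pairs:
            raise SpecValidationError(f"duplicate cell for {key!r}")
        pairs.add(key)
        if c.stratum not in spec.stratum_labels:
            raise SpecValidationError(
                f"cell stratum {c.stratum!r} not in declared stratum labels"
            )
    for m in spec.stratum_labels:
        for a in (0, 1):
            if (m, a) not in pairs:
                raise SpecValidationError(
                    f"missing cell for (stratum={m!r}, arm={a}); every stratum "
                    "must appear with both arms (mass may be 0)"
                )
    total = sum(c.mass for c in spec.cells)
    if abs(total - 1.0) > PROB_TOL:
        raise SpecValidationError(f"cell masses sum to {total!r}, not 1")
    return spec


def _conditioning_cells(
    spec: PopulationSpec, arm: int | None, stratum: str | None
) -> list[Cell]:
    if stratum is not None and stratum not in spec.stratum_labels:
        raise SpecValidationError(f"unknown stratum {stratum!r}")
    return [
        c
        for c in spec.cells
        if (arm is None or c.arm == arm) and (stratum is None or c.stratum == stratum)
    ]


def _conditional_risk(
    spec: PopulationSpec,
    risk_of: "callable",
    arm: int | None,
    stratum: str | None,
) -> float:
    cells = _conditioning_cells(spec, arm, stratum)
    mass = sum(c.mass for c in cells)
    if arm is None and stratum is None:
        mass = 1.0  # masses validated to sum to one
    if mass <= 0.0:
        raise UndefinedConditionalError(
            f"conditioning event (arm={arm}, stratum={stratum!r}) has zero probability"
        )
    return sum(c.mass * risk_of(c) for c in cells) / mass


def observed_risk(
    spec: PopulationSpec, arm: int | None = None, stratum: str | None = None
) -> float:
    """Pr(Y=1 | A=arm, M=stratum); omit either argument to marginalize it.

    With both omitted this is the marginal caseload Pr(Y=1)."""
    return _conditional_risk(spec, lambda c: c.observed_risk, arm, stratum)


def counterfactual_risk(
    spec: PopulationSpec,
    set_to: int,
    arm: int | None = None,
    stratum: str | None = None,
) -> float:
    """Pr(Y^set_to = 1 | A=arm, M=stratum), the risk had exposure been set
    to ``set_to`` for everyone in the conditioning event."""
    if set_to not in (0, 1):
        raise ValueError("set_to must be 0 or 1")
    return _conditional_risk(
        spec, lambda c: c.counterfactual_risk(set_to), arm, stratum
    )


def _joint_case_prob(spec: PopulationSpec, set_to: int) -> float:
    """Pr(Y=1, Y^set_to=1), marginally."""
    return sum(c.mass * c.joint_case_risk(set_to) for c in spec.cells)


def total_measures(spec: PopulationSpec) -> MeasureSet:
    """Compute all four total-population measures from first-principles
    cell sums.

    Raises :class:`UndefinedMeasureError` when Pr(Y=1) = 0 (the common
    denominator of every measure).
    """
    p_y1 = observed_risk(spec)
    if p_y1 <= 0.0:
        raise UndefinedMeasureError("Pr(Y=1) = 0: all measures undefined")
    p_cf1 = counterfactual_risk(spec, set_to=1)
    p_cf0 = counterfactual_risk(spec, set_to=0)
    return MeasureSet(
        pf_total=(p_y1 - p_cf1) / p_y1,
        af_total=(p_y1 - p_cf0) / p_y1,
        pp_total=(p_y1 - _joint_case_prob(spec, set_to=1)) / p_y1,
        ap_total=(p_y1 - _joint_case_prob(spec, set_to=0)) / p_y1,
        p_y1=p_y1,
        p_cf_treated=p_cf1,
        p_cf_untreated=p_cf0,
    )


# ---------------------------------------------------------------------------
# Scenario JSON
# ---------------------------------------------------------------------------
#
# Canonical dialect (response types):
#   {"strata": [{"label": "0",
#                "arms": {"0": {"mass": .., "doomed": .., "helped": ..,
#                               "hurt": .., "immune": ..},
#                         "1": {...}}}, ...],
#    "meta": {...}}                                  # optional
#
# Margins dialect (arm 0 gives factual risk and the set-to-1 risk; arm 1
# gives factual risk and optionally the set-to-0 risk, defaulting to the
# arm-0 factual risk, i.e. exchangeability within the stratum):
#   arms: {"0": {"mass": .., "risk_factual": .., "risk_set1": ..},
#          "1": {"mass": .., "risk_factual": .., "risk_set0": ..}}
# The joint is completed with the monotone coupling (see
# ResponseTypeDist.from_margins).


def _cell_from_arm_entry(label: str, arm: int, entry: Mapping) -> tuple[Cell, str]:
    if "doomed" in entry:
        dist = ResponseTypeDist(
            doomed=float(entry["doomed"]),
            helped=float(entry["helped"]),
            hurt=float(entry["hurt"]),
            immune=float(entry["immune"]),
        )
        return Cell(label, arm, float(entry["mass"]), dist), "response_types"
    if "risk_factual" not in entry:
        raise SpecValidationError(
            f"cell ({label!r}, arm={arm}): need either response-type "
            "probabilities or a margins entry with 'risk_factual'"
        )
    raise _MarginsEntry  # handled by caller with access to both arms


class _MarginsEntry(Exception):
    pass


def load_scenario(source) -> PopulationSpec:
    """Load a scenario from a JSON file path, file object, or dict.

    Accepts the response-type dialect and the margins dialect; the dialect
    used is recorded in ``spec.meta['dialect']``.
    """
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)

    try:
        strata = doc["strata"]
    except (KeyError, TypeError):
        raise SpecValidationError("scenario document must have a 'strata' list")

    cells: list[Cell] = []
    labels: list[str] = []
    dialects: set[str] = set()
    for entry in strata:
        label = str(entry["label"])
        labels.append(label)
        arms = entry["arms"]
        if "0" not in arms or "1" not in arms:
            raise SpecValidationError(
                f"stratum {label!r}: both arms '0' and '1' are required"
            )
        a0, a1 = arms["0"], arms["1"]
        if "doomed" in a0 or "doomed" in a1:
            for arm, e in ((0, a0), (1, a1)):
                cell, dialect = _cell_from_arm_entry(label, arm, e)
                cells.append(cell)
                dialects.add(dialect)
        else:
            dialects.add("margins")
            for key, e in (("risk_factual", a0), ("risk_factual", a1)):
                if key not in e:
                    raise SpecValidationError(
                        f"stratum {label!r}: margins dialect requires "
                        "'risk_factual' in both arms"
                    )
            if "risk_set1" not in a0:
                raise SpecValidationError(
                    f"stratum {label!r}: arm 0 margins entry requires 'risk_set1'"
                )
            r0_arm0 = float(a0["risk_factual"])  # Pr(Y^0=1|A=0,m) by consistency
            r1_arm0 = float(a0["risk_set1"])
            r1_arm1 = float(a1["risk_factual"])  # Pr(Y^1=1|A=1,m)
            # Absent risk_set0, exchangeability within the stratum pins
            # Pr(Y^0=1|A=1,m) to the arm-0 factual risk.
            r0_arm1 = float(a1.get("risk_set0", r0_arm0))
            cells.append(
                Cell(label, 0, float(a0["mass"]),
                     ResponseTypeDist.from_margins(r0_arm0, r1_arm0))
            )
            cells.append(
                Cell(label, 1, float(a1["mass"]),
                     ResponseTypeDist.from_margins(r0_arm1, r1_arm1))
            )

    meta = dict(doc.get("meta", {}))
    meta["dialect"] = "margins" if dialects == {"margins"} else (
        "response_types" if dialects == {"response_types"} else "mixed"
    )
    return PopulationSpec.from_cells(cells, stratum_labels=labels, meta=meta)


def scenario_to_dict(spec: PopulationSpec) -> dict:
    """Serialize a spec in the canonical response-type dialect."""
    strata = []
    for label in spec.stratum_labels:
        arms = {}
        for a in (0, 1):
            c = spec.cell(label, a)
            arms[str(a)] = {"mass": c.mass, **c.response_types.as_dict()}
        strata.append({"label": label, "arms": arms})
    doc: dict = {"strata": strata}
    meta = {k: v for k, v in spec.meta.items() if k != "dialect"}
    if meta:
        doc["meta"] = meta
    return doc


def dump_scenario(spec: PopulationSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scenario_to_dict(spec), fh, indent=1)
        fh.write("\n")


def table1() -> PopulationSpec:
    """The packaged six-cell hypothetical-trial scenario: a marginally
    randomized preventive-treatment trial with stratified recruitment and a
    stratum-varying risk difference (three modifier levels)."""
    ref = resources.files("prevfrac.data").joinpath("table1.json")
    with ref.open("r", encoding="utf-8") as fh:
        return load_scenario(fh)


def with_meta(spec: PopulationSpec, **meta) -> PopulationSpec:
    return replace(spec, meta={**spec.meta, **meta})
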