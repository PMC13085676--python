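"""Brute-force finite-enumeration oracle.

Builds an explicit finite population — one row per individual, with arm,
stratum and both potential outcomes — by exact proportional allocation of
the (cell, response type) classes, then measures everything by counting
individuals.  It shares no arithmetic with the package's probability
machinery: every quantity is a census over numpy arrays.
"""

from __future__ import annotations

import math

import numpy as np

from prevfrac.population import Cell, PopulationSpec, ResponseTypeDist

# response type -> (y0, y1)
_TYPE_PO = {"doomed": (1, 1), "helped": (1, 0), "hurt": (0, 1), "immune": (0, 0)}


def round_simplex(probs, denom: int):
    """Largest-remainder rounding of a probability vector onto the grid of
    multiples of 1/denom, preserving the exact sum."""
    probs = np.asarray(probs, dtype=float)
    scaled = probs * denom
    base = np.floor(scaled).astype(int)
    short = int(round(scaled.sum())) - base.sum()
    order = np.argsort(-(scaled - base))
    base[order[:short]] += 1
    return base / denom


def rationalize(spec: PopulationSpec, denom: int = 1000) -> PopulationSpec:
    """Snap all masses and response-type probabilities to multiples of
    1/denom so a population of denom**2 individuals allocates exactly."""
    masses = round_simplex([c.mass for c in spec.cells], denom)
    cells = []
    for c, mass in zip(spec.cells, masses):
        d = c.response_types
        q = round_simplex([d.doomed, d.helped, d.hurt, d.immune], denom)
        cells.append(
            Cell(c.stratum, c.arm, float(mass),
                 ResponseTypeDist(*(float(x) for x in q)))
        )
    return PopulationSpec.from_cells(cells, stratum_labels=spec.stratum_labels)


def enumerate_individuals(spec: PopulationSpec, n: int = 10**6):
    """Arrays (stratum_label, arm, y0, y1), one entry per individual."""
    strata, arms, y0s, y1s = [], [], [], []
    for c in spec.cells:
        for tname, (y0, y1) in _TYPE_PO.items():
            exact = n * c.mass * getattr(c.response_types, tname)
            count = int(round(exact))
            if not math.isclose(exact, count, abs_tol=1e-6):
                raise ValueError(
                    f"non-integer allocation {exact} for "
                    f"({c.stratum}, {c.arm}, {tname})"
                )
            strata.append(np.full(count, c.stratum, dtype=object))
            arms.append(np.full(count, c.arm, dtype=np.int8))
            y0s.append(np.full(count, y0, dtype=np.int8))
            y1s.append(np.full(count, y1, dtype=np.int8))
    m = np.concatenate(strata)
    a = np.concatenate(arms)
    y0 = np.concatenate(y0s)
    y1 = np.concatenate(y1s)
    assert len(m) == n
    return m, a, y0, y1


def oracle_census(spec: PopulationSpec, n: int = 10**6) -> dict:
    """All four total measures and the per-stratum case weights, obtained
    purely by counting individuals in the enumerated population."""
    m, a, y0, y1 = enumerate_individuals(spec, n)
    y = np.where(a == 1, y1, y0)  # consistency
    cases = int(y.sum())
    out = {
        "p_y1": cases / n,
        "pf_total": (cases - int(y1.sum())) / cases,
        "af_total": (cases - int(y0.sum())) / cases,
        "pp_total": (cases - int((y & y1).sum())) / cases,
        "ap_total": (cases - int((y & y0).sum())) / cases,
        "weights": {
            lab: int(y[m == lab].sum()) / cases for lab in spec.stratum_labels
        },
    }
    return out
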