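"""Synthetic trial data from a counterfactual population.

The sampler emulates the scenario's recruitment design directly: each
individual is assigned an (exposure arm, stratum) cell with probability
equal to the cell's mass, then a response type from the cell's joint
potential-outcome distribution; the observed outcome follows by consistency
(y = y1 in the treated arm, y = y0 otherwise), so consistency holds in
every emitted row by construction.

Randomness uses the counter-based Philox bit generator with the caller's
seed, drawing a fixed number of uniforms per row in row order, so row i of
a run is independent of the total sample size n: the first k rows of a
sample of n > k equal the sample of k under the same seed.

``proportional_sample`` is the deterministic counterpart: it allocates
individuals to (cell, response type) classes in exact proportion, so the
empirical distribution equals the population exactly — the no-noise path
used to check that plug-in estimation reproduces population values.

``random_spec`` draws valid random populations for property sweeps, with
optional structural constraints (exchangeability within strata,
monotonicity, a null effect, marginal randomization).  Cell masses are kept
at or above 0.01 and factual risks inside [0.02, 0.98] so that generated
scenarios stay away from positivity failures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import lcm

import numpy as np
import pandas as pd

from .exceptions import SpecValidationError
from .population import Cell, PopulationSpec, ResponseTypeDist, validate_spec

__all__ = ["SimConfig", "sample_population", "proportional_sample", "random_spec"]

# response-type order used for sampling and allocation
_TYPES = ("doomed", "helped", "hurt", "immune")
_Y0 = np.array([1, 1, 0, 0], dtype=np.int8)  # Y^0 by type
_Y1 = np.array([1, 0, 1, 0], dtype=np.int8)  # Y^1 by type

MIN_MASS = 0.01
RISK_LO, RISK_HI = 0.02, 0.98


@dataclass(frozen=True)
class SimConfig:
    spec: PopulationSpec
    n: int
    seed: int
    emit_potential_outcomes: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


def _cell_arrays(spec: PopulationSpec):
    cells = spec.cells
    masses = np.array([c.mass for c in cells], dtype=float)
    type_probs = np.array(
        [[getattr(c.response_types, t) for t in _TYPES] for c in cells], dtype=float
    )
    strata = np.array([c.stratum for c in cells], dtype=object)
    arms = np.array([c.arm for c in cells], dtype=np.int8)
    return masses, type_probs, strata, arms


def _assemble(strata, arms, types, emit_po: bool) -> pd.DataFrame:
    y0 = _Y0[types]
    y1 = _Y1[types]
    y = np.where(arms == 1, y1, y0).astype(np.int8)
    data = {"m": strata, "a": arms.astype(np.int8), "y": y}
    if emit_po:
        data["y0"] = y0
        data["y1"] = y1
    return pd.DataFrame(data)


def sample_population(config: SimConfig) -> pd.DataFrame:
    """Draw ``config.n`` individual records from the population.

    Returns a DataFrame with columns m, a, y (and y0, y1 when
    ``emit_potential_outcomes``).  Identical configs give identical tables.
    """
    spec = validate_spec(config.spec)
    masses, type_probs, strata, arms = _cell_arrays(spec)

    rng = np.random.Generator(np.random.Philox(key=config.seed))
    u = rng.random(2 * config.n).reshape(config.n, 2)  # row-ordered stream

    cum_mass = np.cumsum(masses)
    cum_mass[-1] = 1.0  # guard rounding at the top end
    cell_idx = np.searchsorted(cum_mass, u[:, 0], side="right")

    cum_types = np.cumsum(type_probs, axis=1)
    cum_types[:, -1] = 1.0
    types = (u[:, 1, None] >= cum_types[cell_idx]).sum(axis=1)

    return _assemble(
        strata[cell_idx], arms[cell_idx], types, config.emit_potential_outcomes
    )


def _smallest_feasible_n(spec: PopulationSpec) -> int:
    dens = [1]
    for c in spec.cells:
        for t in _TYPES:
            p = c.mass * getattr(c.response_types, t)
            if p > 0:
                dens.append(Fraction(p).limit_denominator(10**7).denominator)
    return lcm(*dens)


def proportional_sample(
    spec: PopulationSpec, n: int, emit_potential_outcomes: bool = True
) -> pd.DataFrame:
    """Deterministic sample whose empirical distribution equals the
    population exactly: each (cell, response type) class receives
    n * mass * type-probability individuals, which must all be integers.

    Raises ``ValueError`` stating the smallest feasible n otherwise.
    """
    validate_spec(spec)
    masses, type_probs, strata, arms = _cell_arrays(spec)
    counts = n * masses[:, None] * type_probs
    rounded = np.rint(counts)
    if np.max(np.abs(counts - rounded)) > 1e-6:
        raise ValueError(
            f"n={n} does not allocate every (cell, response-type) class an "
            f"integer count; smallest feasible n is {_smallest_feasible_n(spec)}"
        )
    rounded = rounded.astype(np.int64)
    cell_rep = np.repeat(np.arange(len(masses)), rounded.sum(axis=1))
    types = np.concatenate(
        [np.repeat(np.arange(4), row) for row in rounded]
    )
    return _assemble(strata[cell_rep], arms[cell_rep], types, emit_potential_outcomes)


def _bounded_simplex(rng: np.random.Generator, k: int, floor: float) -> np.ndarray:
    if floor * k >= 1.0:
        raise ValueError("too many cells for the mass floor")
    u = rng.random(k)
    return floor + (1.0 - floor * k) * u / u.sum()


def random_spec(
    seed: int,
    n_strata: int,
    exchangeable_within_m: bool = False,
    monotone: bool = False,
    null_effect: bool = False,
    marginal_randomization: bool = False,
) -> PopulationSpec:
    """Seeded random population for property sweeps.

    Constraints:

    - ``exchangeable_within_m``: within each stratum the potential-outcome
      margins do not depend on the arm (Y^a independent of A given M).
    - ``monotone``: no 'hurt' response type anywhere (the treatment never
      causes the outcome); implies r1 <= r0 within each cell.
    - ``null_effect``: Y^0 and Y^1 margins coincide in every cell, so all
      caseload measures are exactly 0.
    - ``marginal_randomization``: A independent of M (equal stratum mix in
      both arms).  Combined with ``exchangeable_within_m`` this yields
      marginal exchangeability, hence partial exchangeability Y^0 ⊥ A.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    rng = np.random.default_rng(seed)

    if marginal_randomization:
        p_a1 = rng.uniform(0.2, 0.8)
        p_m = _bounded_simplex(rng, n_strata, 2 * MIN_MASS)
        mass = {(i, a): p_m[i] * (p_a1 if a == 1 else 1 - p_a1)
                for i in range(n_strata) for a in (0, 1)}
    else:
        flat = _bounded_simplex(rng, 2 * n_strata, MIN_MASS)
        mass = {(i, a): flat[2 * i + a] for i in range(n_strata) for a in (0, 1)}

    def draw_margins() -> tuple[float, float]:
        r0 = rng.uniform(RISK_LO, RISK_HI)
        if null_effect:
            return r0, r0
        if monotone:  # preventive: r1 <= r0, still bounded below
            return r0, rng.uniform(RISK_LO, r0) if r0 > RISK_LO else r0
        return r0, rng.uniform(RISK_LO, RISK_HI)

    def couple(r0: float, r1: float) -> ResponseTypeDist:
        lo, hi = max(0.0, r0 + r1 - 1.0), min(r0, r1)
        doomed = hi if monotone else rng.uniform(lo, hi)
        return ResponseTypeDist(
            doomed=doomed, helped=r0 - doomed, hurt=r1 - doomed,
            immune=1.0 - r0 - r1 + doomed,
        )

    cells = []
    labels = [str(i) for i in range(n_strata)]
    for i, label in enumerate(labels):
        shared = draw_margins() if exchangeable_within_m else None
        for a in (0, 1):
            r0, r1 = shared if shared is not None else draw_margins()
            cells.append(Cell(label, a, mass[(i, a)], couple(r0, r1)))
    return PopulationSpec.from_cells(
        cells,
        stratum_labels=labels,
        meta={
            "generator": "random_spec",
            "seed": seed,
            "constraints": {
                "exchangeable_within_m": exchangeable_within_m,
                "monotone": monotone,
                "null_effect": null_effect,
                "marginal_randomization": marginal_randomization,
            },
        },
    )
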