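"""Plug-in estimation of impact measures from individual-level trial records.

Data are rows (m, a, y) — effect-modifier stratum, binary exposure arm,
binary outcome — optionally with the two potential outcomes (y0, y1) when
the data are synthetic.  The estimator is the plug-in of the population
formulas: empirical cell masses and factual risks, with each cell's
counterfactual risk imputed under a declared identification assumption:

- ``conditional_exchangeability`` (default): Y^a independent of A given M,
  so Pr(Y^1=1 | A=0, M=m) is estimated by the stratum's treated-arm risk
  (g-computation / standardization over M).
- ``marginal_exchangeability``: Y^a independent of A; imputation ignores M.
  Appropriate for a marginally randomized trial, but conditional is the
  default since stratum measures condition on M anyway.
- ``oracle_potential_outcomes``: y0/y1 columns are used directly; the only
  route to the proportion measures (PP/AP) short of a monotonicity
  assumption, under which PP and AP coincide with PF and AF.

Inference is a nonparametric bootstrap — individuals resampled with
replacement, percentile intervals — implemented as multinomial resampling
over the distinct (stratum, arm, outcome) record types, which is exactly
equivalent and vectorizes over replicates.  Replicates that empty a cell
the estimator needs are redrawn up to 100 times, then dropped with a
warning.  The population quantities themselves carry no sampling notion;
all finite-sample machinery here is estimation-layer engineering.

The public surface follows the model/results idiom:
``ImpactFractionModel(data, measure=..., assumption=...).fit(b_reps, seed)``
returns :class:`ImpactFractionResults` with the total-population estimate,
per-stratum estimates, case weights, bootstrap CIs and a ``summary()``
table.  ``estimate``, ``tabulate`` and ``check_positivity`` are thin
functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    NotIdentifiableError,
    PositivityError,
    RecordError,
)
from .population import Cell, PopulationSpec, ResponseTypeDist

__all__ = [
    "ASSUMPTIONS",
    "EstimateResult",
    "ImpactFractionModel",
    "ImpactFractionResults",
    "PositivityReport",
    "read_records",
    "write_records",
    "validate_records",
    "tabulate",
    "check_positivity",
    "estimate",
]

ASSUMPTIONS = (
    "conditional_exchangeability",
    "marginal_exchangeability",
    "oracle_potential_outcomes",
)
_MEASURES = ("pf", "af", "pp", "ap")
_MAX_REDRAWS = 100


# ---------------------------------------------------------------------------
# Records I/O and validation
# ---------------------------------------------------------------------------

def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate codes and (when potential outcomes are present) consistency
    y == y^a for the received arm.  Returns a normalized copy with integer
    a/y columns and string strata."""
    if records is None or len(records) == 0:
        raise RecordError("empty record table")
    missing = {"m", "a", "y"} - set(records.columns)
    if missing:
        raise RecordError(f"missing required columns: {sorted(missing)}")
    out = records.copy()
    out["m"] = out["m"].astype(str)
    if (out["m"].str.len() == 0).any():
        raise RecordError("empty stratum label")
    cols = ["a", "y"] + [c for c in ("y0", "y1") if c in out.columns]
    for col in cols:
        vals = out[col]
        arr = pd.to_numeric(vals, errors="coerce")
        if arr.isna().any() or not np.isin(arr.dropna().unique(), [0, 1]).all():
            bad = vals[~vals.astype(str).isin(["0", "1"])]
            raise RecordError(
                f"column {col!r} must be binary 0/1; found {bad.iloc[0]!r}"
            )
        out[col] = arr.astype(np.int8)
    if "y0" in out.columns and "y1" in out.columns:
        ya = np.where(out["a"] == 1, out["y1"], out["y0"])
        if (out["y"].to_numpy() != ya).any():
            i = int(np.argmax(out["y"].to_numpy() != ya))
            raise RecordError(
                f"consistency violation at row {i}: y != y{out['a'].iloc[i]}"
            )
    return out


def read_records(path) -> pd.DataFrame:
    """Read a records CSV (header m,a,y[,y0,y1]; binaries strictly '0'/'1').

    Other encodings of the binary columns ('TRUE', '1.0', ...) are rejected
    rather than coerced."""
    df = pd.read_csv(path, dtype=str)
    for col in df.columns:
        if col in ("a", "y", "y0", "y1"):
            ok = df[col].isin(["0", "1"])
            if not ok.all():
                bad = df.loc[~ok, col].iloc[0]
                raise RecordError(
                    f"column {col!r} must be encoded strictly as '0'/'1'; "
                    f"found {bad!r}"
                )
    return validate_records(df)


def write_records(records: pd.DataFrame, path) -> None:
    validate_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tabulation and positivity
# ---------------------------------------------------------------------------

def tabulate(records: pd.DataFrame) -> pd.DataFrame:
    """Empirical (stratum, arm) table: counts, masses Pr^(A=a, M=m) and
    factual risks Pr^(Y=1 | A=a, M=m).

    Counterfactual risks are deliberately absent — they are imputed at
    estimation time under the declared assumption, not here."""
    df = validate_records(records)
    n = len(df)
    g = df.groupby(["m", "a"], sort=False).agg(
        n=("y", "size"), cases=("y", "sum")
    )
    g["mass"] = g["n"] / n
    g["risk"] = g["cases"] / g["n"]
    return g.reset_index()


@dataclass(frozen=True)
class PositivityReport:
    counts: pd.DataFrame  # one row per (stratum, arm) with its count
    empty_cells: tuple[tuple[str, int], ...]

    @property
    def ok(self) -> bool:
        return not self.empty_cells


def check_positivity(records: pd.DataFrame) -> PositivityReport:
    """Count every (arm, stratum) cell over the observed strata; flag the
    empty ones.  Never raises (beyond record validation)."""
    df = validate_records(records)
    strata = list(pd.unique(df["m"]))
    rows, empty = [], []
    for m in strata:
        for a in (0, 1):
            cnt = int(((df["m"] == m) & (df["a"] == a)).sum())
            rows.append({"m": m, "a": a, "n": cnt})
            if cnt == 0:
                empty.append((m, a))
    return PositivityReport(pd.DataFrame(rows), tuple(empty))


# ---------------------------------------------------------------------------
# Count engines (vectorized over bootstrap replicates)
# ---------------------------------------------------------------------------

def _counts_3d(df: pd.DataFrame, strata: list[str]) -> np.ndarray:
    """(S, 2, 2) counts over (stratum, arm, y)."""
    idx = df["m"].map({m: i for i, m in enumerate(strata)}).to_numpy()
    c = np.zeros((len(strata), 2, 2), dtype=np.int64)
    np.add.at(c, (idx, df["a"].to_numpy(), df["y"].to_numpy()), 1)
    return c

def _counts_4d(df: pd.DataFrame, strata: list[str]) -> np.ndarray:
    """(S, 2, 4) counts over (stratum, arm, response type)."""
    idx = df["m"].map({m: i for i, m in enumerate(strata)}).to_numpy()
    t = (1 - df["y1"].to_numpy()) + 2 * (1 - df["y0"].to_numpy())
    c = np.zeros((len(strata), 2, 4), dtype=np.int64)
    np.add.at(c, (idx, df["a"].to_numpy(), t), 1)
    return c


def _safe_div(a, b):
    b = np.asarray(b, dtype=float)
    return np.divide(a, b, out=np.zeros(np.broadcast_shapes(np.shape(a), b.shape)),
                     where=b > 0)


def _totals_from_counts(counts: np.ndarray, measure: str, assumption: str):
    """Total-population measure for counts of shape (..., S, 2, 2) under an
    exchangeability assumption (caseload measures only)."""
    n = counts.sum(axis=(-3, -2, -1))
    cases = counts[..., 1]                      # (..., S, 2)
    n_sa = counts.sum(axis=-1)                  # (..., S, 2)
    p_y1 = cases.sum(axis=(-2, -1)) / n
    r_hat = _safe_div(cases, n_sa)              # factual risk per cell
    if assumption == "conditional_exchangeability":
        p_m = n_sa.sum(axis=-1) / n[..., None]
        p_cf = (p_m * r_hat[..., 1 if measure == "pf" else 0]).sum(axis=-1)
    else:  # marginal: counterfactual caseload is the arm's marginal risk
        arm = 1 if measure == "pf" else 0
        p_cf = _safe_div(cases[..., arm].sum(axis=-1), n_sa[..., arm].sum(axis=-1))
    return (p_y1 - p_cf) / p_y1


def _strata_from_counts(counts: np.ndarray, measure: str, assumption: str):
    """Per-stratum measure and case weights, shapes (..., S)."""
    n = counts.sum(axis=(-3, -2, -1))
    cases = counts[..., 1]
    n_sa = counts.sum(axis=-1)
    n_m = n_sa.sum(axis=-1)
    cases_m = cases.sum(axis=-1)
    p_y1_m = _safe_div(cases_m, n_m)
    arm = 1 if measure == "pf" else 0
    if assumption == "conditional_exchangeability":
        cf_m = _safe_div(cases[..., arm], n_sa[..., arm])
    else:
        r_marg = _safe_div(cases[..., arm].sum(axis=-1), n_sa[..., arm].sum(axis=-1))
        # within-stratum plug-in: same-arm cell keeps its factual risk, the
        # other cell is imputed with the marginal arm risk
        cf_m = _safe_div(
            cases[..., arm] + n_sa[..., 1 - arm] * r_marg[..., None], n_m
        )
    meas = _safe_div(p_y1_m - cf_m, p_y1_m)
    weights = _safe_div(cases_m, cases_m.sum(axis=-1)[..., None])
    return meas, weights


def _totals_oracle(c4: np.ndarray, measure: str):
    """Measures from full response-type counts, shape (..., S, 2, 4)."""
    n = c4.sum(axis=(-3, -2, -1))
    t = np.moveaxis(c4, -1, 0)  # (4, ..., S, 2): doomed, helped, hurt, immune
    obs = np.where(
        np.arange(2)[None, :] == 1, t[0] + t[2], t[0] + t[1]
    )  # observed cases per cell
    p_y1 = obs.sum(axis=(-2, -1)) / n
    if measure in ("pf", "af"):
        k = 2 if measure == "pf" else 1
        p_cf = (t[0] + t[k]).sum(axis=(-2, -1)) / n
        return (p_y1 - p_cf) / p_y1
    a_joint = 1 if measure == "pp" else 0
    # Pr(Y=1, Y^set=1): same-arm cells contribute their observed cases,
    # opposite-arm cells only the doomed
    same = (t[0] + (t[2] if a_joint == 1 else t[1]))[..., a_joint]
    other = t[0][..., 1 - a_joint]
    joint = (same + other).sum(axis=-1) / n
    return (p_y1 - joint) / p_y1


def _strata_oracle(c4: np.ndarray, measure: str):
    n_m = c4.sum(axis=(-2, -1))
    t = np.moveaxis(c4, -1, 0)
    obs = np.where(np.arange(2)[None, :] == 1, t[0] + t[2], t[0] + t[1])
    cases_m = obs.sum(axis=-1)
    p_y1_m = _safe_div(cases_m, n_m)
    if measure in ("pf", "af"):
        k = 2 if measure == "pf" else 1
        cf_m = _safe_div((t[0] + t[k]).sum(axis=-1), n_m)
        meas = _safe_div(p_y1_m - cf_m, p_y1_m)
    else:
        a_joint = 1 if measure == "pp" else 0
        same = (t[0] + (t[2] if a_joint == 1 else t[1]))[..., a_joint]
        other = t[0][..., 1 - a_joint]
        joint_m = _safe_div(same + other, n_m)
        meas = _safe_div(p_y1_m - joint_m, p_y1_m)
    weights = _safe_div(cases_m, cases_m.sum(axis=-1)[..., None])
    return meas, weights


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimateResult:
    """A point estimate with its percentile-bootstrap interval."""

    point: float
    ci_low: float
    ci_high: float
    n: int
    assumption: str
    b_reps: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.b_reps > 0 and not (
            np.isnan(self.ci_low)
            or self.ci_low - 1e-12 <= self.point <= self.ci_high + 1e-12
        ):
            raise AssertionError("bootstrap interval does not cover the estimate")


@dataclass(frozen=True)
class ImpactFractionResults:
    """Fitted results: total-population estimate, per-stratum estimates and
    case-frequency weights, all with bootstrap intervals."""

    measure: str
    reported_as: str  # differs from `measure` when monotonicity maps pp->pf
    total: EstimateResult
    strata: Mapping[str, EstimateResult]
    weights: Mapping[str, EstimateResult]
    empirical_spec: PopulationSpec
    n_dropped_replicates: int = 0
    _model: "ImpactFractionModel | None" = field(
        default=None, compare=False, repr=False
    )

    def summary(self, round_to: int = 4) -> str:
        r = self.total
        lines = [
            "Impact fraction estimate (plug-in)",
            "=" * 58,
            f"measure:            {self.reported_as}"
            + (f" (reported as {self.measure} under monotonicity)"
               if self.reported_as != self.measure else ""),
            f"assumption:         {r.assumption}",
            f"n records:          {r.n}",
            f"bootstrap reps:     {r.b_reps} (seed={r.seed}, "
            f"dropped={self.n_dropped_replicates})",
            "-" * 58,
            f"{'':12s}{'estimate':>10s}{'ci_low':>12s}{'ci_high':>12s}",
            f"{'total':12s}{r.point:>10.{round_to}f}"
            f"{r.ci_low:>12.{round_to}f}{r.ci_high:>12.{round_to}f}",
        ]
        for m, s in self.strata.items():
            w = self.weights[m]
            lines.append(
                f"{'m=' + m:12s}{s.point:>10.{round_to}f}"
                f"{s.ci_low:>12.{round_to}f}{s.ci_high:>12.{round_to}f}"
                f"   weight={w.point:.{round_to}f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class ImpactFractionModel:
    """Plug-in impact-fraction model over individual trial records.

    Parameters
    ----------
    data:
        DataFrame with columns m, a, y and optionally y0, y1.
    measure:
        'pf' (preventable fraction), 'af' (attributable fraction),
        'pp'/'ap' (proportion analogues).
    assumption:
        identification assumption; see module docstring.
    monotone:
        declare that the exposure never causes the outcome, identifying
        'pp' with 'pf' and 'ap' with 'af' from factual data alone.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        measure: str = "pf",
        assumption: str = "conditional_exchangeability",
        monotone: bool = False,
    ) -> None:
        if measure not in _MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        if assumption not in ASSUMPTIONS:
            raise ValueError(f"unknown assumption {assumption!r}")
        self.data = validate_records(data)
        self.measure = measure
        self.assumption = assumption
        self.monotone = monotone
        self.strata_labels = list(pd.unique(self.data["m"]))
        self._resolve_identification()
        if self.assumption == "oracle_potential_outcomes":
            if not {"y0", "y1"} <= set(self.data.columns):
                raise NotIdentifiableError(
                    "oracle_potential_outcomes requires y0 and y1 columns"
                )
            self._c = _counts_4d(self.data, self.strata_labels)
        else:
            self._c = _counts_3d(self.data, self.strata_labels)
        self._check_positivity()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ImpactFractionModel":
        return cls(read_records(path), **kwargs)

    def _resolve_identification(self) -> None:
        self.effective_measure = self.measure
        if self.measure in ("pp", "ap") and (
            self.assumption != "oracle_potential_outcomes"
        ):
            if not self.monotone:
                raise NotIdentifiableError(
                    f"{self.measure} is not identifiable from factual data under "
                    f"{self.assumption}; supply potential-outcome columns with "
                    "assumption='oracle_potential_outcomes' or declare "
                    "monotone=True (under which pp ≡ pf and ap ≡ af)"
                )
            self.effective_measure = "pf" if self.measure == "pp" else "af"

    def _check_positivity(self) -> None:
        if int(self.data["y"].sum()) == 0:
            raise PositivityError("no cases observed: measures undefined")
        if self.assumption == "oracle_potential_outcomes":
            return
        n_sa = self._c.sum(axis=-1)
        if self.assumption == "conditional_exchangeability":
            bad = np.argwhere(n_sa == 0)
            if len(bad):
                s, a = bad[0]
                raise PositivityError(
                    f"positivity violation: no subjects in "
                    f"(stratum={self.strata_labels[s]!r}, arm={a})"
                )
        else:
            for a in (0, 1):
                if n_sa[:, a].sum() == 0:
                    raise PositivityError(
                        f"positivity violation: no subjects in arm {a}"
                    )

    # -- point estimates ----------------------------------------------------

    def _point_arrays(self, c):
        if self.assumption == "oracle_potential_outcomes":
            total = _totals_oracle(c, self.measure)
            meas, w = _strata_oracle(c, self.measure)
        else:
            m = self.effective_measure
            total = _totals_from_counts(c, m, self.assumption)
            meas, w = _strata_from_counts(c, m, self.assumption)
        return total, meas, w

    def _bootstrap(self, b_reps: int, seed: int):
        rng = np.random.default_rng(seed)
        n = int(self._c.sum())
        p = self._c.ravel() / n
        shape = self._c.shape
        draws = rng.multinomial(n, p, size=b_reps).reshape((b_reps,) + shape)
        needed = self._c.sum(axis=-1) > 0  # observed (stratum, arm) cells

        def invalid(d):
            if self.assumption == "oracle_potential_outcomes":
                bad = (d.sum(axis=(-2, -1)) == 0).any(axis=-1)  # empty stratum
            else:
                bad = (d.sum(axis=-1)[:, needed] == 0).any(axis=-1)
            return bad | (self._case_count(d) == 0)  # and >= 1 case overall

        dropped = 0
        bad = invalid(draws)
        for _ in range(_MAX_REDRAWS):
            if not bad.any():
                break
            k = int(bad.sum())
            draws[bad] = rng.multinomial(n, p, size=k).reshape((k,) + shape)
            bad = invalid(draws)
        if bad.any():
            dropped = int(bad.sum())
            warnings.warn(
                f"dropping {dropped} bootstrap replicates that left a "
                f"required cell empty after {_MAX_REDRAWS} redraws",
                stacklevel=3,
            )
            draws = draws[~bad]
        return draws, dropped

    def _case_count(self, draws):
        if self.assumption == "oracle_potential_outcomes":
            t = np.moveaxis(draws, -1, 0)
            obs = np.where(np.arange(2)[None, :] == 1, t[0] + t[2], t[0] + t[1])
            return obs.sum(axis=(-2, -1))
        return draws[..., 1].sum(axis=(-2, -1))

    def fit(self, b_reps: int = 1000, seed: int | None = None) -> ImpactFractionResults:
        """Fit and (for ``b_reps > 0``) bootstrap.

        ``seed`` is mandatory whenever bootstrap replicates are requested:
        resampling without a recorded seed is not reproducible."""
        if b_reps > 0 and seed is None:
            raise ValueError("an explicit seed is required when b_reps > 0")
        n = len(self.data)
        total_pt, meas_pt, w_pt = self._point_arrays(self._c)
        total_pt = float(total_pt)

        if b_reps > 0:
            draws, dropped = self._bootstrap(b_reps, seed)
            tot_b, meas_b, w_b = self._point_arrays(draws)
            lo, hi = np.percentile(tot_b, [2.5, 97.5])
            meas_ci = np.percentile(meas_b, [2.5, 97.5], axis=0)
            w_ci = np.percentile(w_b, [2.5, 97.5], axis=0)
        else:
            dropped = 0
            lo = hi = np.nan
            meas_ci = np.full((2, len(self.strata_labels)), np.nan)
            w_ci = np.full((2, len(self.strata_labels)), np.nan)

        def res(pt, l, h):
            return EstimateResult(
                point=float(pt), ci_low=float(l), ci_high=float(h), n=n,
                assumption=self.assumption, b_reps=b_reps, seed=seed,
            )

        return ImpactFractionResults(
            measure=self.measure,
            reported_as=self.effective_measure,
            total=res(total_pt, lo, hi),
            strata={
                m: res(meas_pt[i], meas_ci[0, i], meas_ci[1, i])
                for i, m in enumerate(self.strata_labels)
            },
            weights={
                m: res(w_pt[i], w_ci[0, i], w_ci[1, i])
                for i, m in enumerate(self.strata_labels)
            },
            empirical_spec=self.empirical_spec(),
            n_dropped_replicates=dropped,
            _model=self,
        )

    # -- empirical population ----------------------------------------------

    def empirical_spec(self) -> PopulationSpec:
        """The empirical counterfactual population implied by the data and
        the identification assumption: empirical masses and factual risks,
        counterfactual margins imputed per assumption, joints completed by
        the monotone coupling (oracle counts use the observed joint)."""
        n = int(self._c.sum())
        cells = []
        if self.assumption == "oracle_potential_outcomes":
            for i, m in enumerate(self.strata_labels):
                for a in (0, 1):
                    n_sa = self._c[i, a].sum()
                    if n_sa == 0:
                        dist = ResponseTypeDist(0, 0, 0, 1)
                    else:
                        d, h, u, im = (self._c[i, a] / n_sa).tolist()
                        dist = ResponseTypeDist(d, h, u, im)
                    cells.append(Cell(m, a, n_sa / n, dist))
        else:
            n_sa = self._c.sum(axis=-1)
            r_hat = _safe_div(self._c[..., 1], n_sa)
            r_marg = [
                _safe_div(self._c[:, a, 1].sum(), n_sa[:, a].sum()) for a in (0, 1)
            ]
            for i, m in enumerate(self.strata_labels):
                for a in (0, 1):
                    own = r_hat[i, a]
                    if self.assumption == "conditional_exchangeability":
                        other = r_hat[i, 1 - a]
                    else:
                        other = float(r_marg[1 - a])
                    r0, r1 = (own, other) if a == 0 else (other, own)
                    cells.append(
                        Cell(m, a, n_sa[i, a] / n,
                             ResponseTypeDist.from_margins(r0, r1))
                    )
        return PopulationSpec.from_cells(
            cells, stratum_labels=self.strata_labels,
            meta={"source": "empirical", "assumption": self.assumption, "n": n},
        )


def estimate(
    records: pd.DataFrame,
    measure: str = "pf",
    assumption: str = "conditional_exchangeability",
    b_reps: int = 1000,
    seed: int | None = None,
    monotone: bool = False,
) -> ImpactFractionResults:
    """Functional wrapper: build the model and fit it."""
    return ImpactFractionModel(
        records, measure=measure, assumption=assumption, monotone=monotone
    ).fit(b_reps=b_reps, seed=seed)
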