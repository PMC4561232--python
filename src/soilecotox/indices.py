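"""Biological indices and the pesticide dissipation model.

Four index families quantify how soil biology responds to fungicide
contamination:

* **CD, colony development** -- ``CD = 100 * sum_d p_d / d`` over the
  fractions ``p_d`` of colonies emerging on observation day ``d`` (default
  10-day window).  High CD means fast-appearing r-strategists dominate;
  CD is bounded in ``[100/window, 100]``.
* **EP, ecophysiological diversity** -- Shannon-type evenness
  ``EP = -sum_i p_i log10 p_i`` of the same emergence fractions, in
  ``[0, log10(window)]`` (``[0, 1]`` for the 10-day window).
* **RS, resistance** (Orwin-Wardle) -- ``RS = 1 - 2|D0| / (C0 + |D0|)``
  where ``D0 = C0 - P0`` is the control-minus-disturbed difference at the
  observation time.  RS = 1 means the parameter is unchanged by the
  disturbance; values fall towards -1 as the change grows.
* **RL, resilience** (Orwin-Wardle) -- ``RL = 2|D0| / (|D0| + |Dx|) - 1``
  comparing the initial difference ``D0`` with the difference ``Dx`` at a
  later follow-up time.  RL = 1 is full recovery, RL < 0 means the
  disturbance kept growing.

The predicted environmental concentration (PEC) of the fungicide follows
shared first-order decay, proportional to dose:
``PEC(d, t) = f * d * exp(-k t)`` with initial fraction ``f``, rate ``k``
(1/day) and half-life ``DT50 = ln 2 / k``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "UndefinedIndexError",
    "UnderdeterminedError",
    "MissingControlError",
    "EmergenceProfile",
    "PairedDisturbance",
    "IndexResult",
    "DecayParams",
    "PECFit",
    "EffectDelta",
    "IndexSummary",
    "colony_development_index",
    "ecophysiological_index",
    "resistance_index",
    "resilience_index",
    "resistance_table",
    "resilience_table",
    "fit_pec",
    "predict_pec",
    "dose_linear_prediction",
    "effect_delta",
    "summarize_index",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of an index or model."""


class UndefinedIndexError(DomainError):
    """The index is undefined for this input (e.g. an all-zero profile)."""


class UnderdeterminedError(ValueError):
    """Not enough distinct design points to fit the model."""


class MissingControlError(KeyError):
    """No control (dose 0) series available for the requested comparison."""


# ---------------------------------------------------------------------------
# Emergence profiles: CD and EP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmergenceProfile:
    """Daily new-colony counts over an observation window (default 10 days)."""

    counts: tuple[int, ...]
    window: int = 10

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != self.window:
            raise DomainError(
                f"expected exactly {self.window} daily counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise DomainError("daily colony counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> tuple[float, ...]:
        """Fractions p_i of colonies emerging on each day (sum to 1)."""
        total = self.total
        if total == 0:
            raise UndefinedIndexError(
                "emergence indices are undefined for an all-zero profile"
            )
        return tuple(c / total for c in self.counts)


@dataclass(frozen=True)
class IndexResult:
    """One computed index value with its (variable, dose, time) context."""

    kind: str
    value: float
    context: Mapping[str, object] = field(default_factory=dict)
    note: str = ""

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.value)


def colony_development_index(
    profile: EmergenceProfile, context: Mapping[str, object] | None = None
) -> IndexResult:
    """Colony development index, ``100 * sum_d p_d / d``.

    100 iff every colony appears on day 1; ``100/window`` (10 for the
    default window) iff every colony appears on the last day.
    """
    p = profile.proportions
    value = 100.0 * sum(p_d / day for day, p_d in enumerate(p, start=1))
    return IndexResult("CD", value, dict(context or {}))


def ecophysiological_index(
    profile: EmergenceProfile,
    base: float = 10.0,
    context: Mapping[str, object] | None = None,
) -> IndexResult:
    """Ecophysiological diversity index, ``-sum p_i log_base p_i``.

    Zero-count days contribute nothing.  With the default base 10 and the
    10-day window the index lies in [0, 1]: 0 for emergence concentrated on
    a single day, 1 for perfectly uniform emergence.
    """
    if base <= 1:
        raise DomainError("logarithm base must exceed 1")
    log_base = math.log(base)
    value = -sum(
        p_i * math.log(p_i) / log_base for p_i in profile.proportions if p_i > 0
    )
    return IndexResult("EP", value, dict(context or {}))


# ---------------------------------------------------------------------------
# Paired control/treated series: RS and RL
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedDisturbance:
    """Control/disturbed parameter values at baseline and optional follow-up.

    ``c0``/``p0`` are the control and disturbed values at the baseline time,
    ``cx``/``px`` at the follow-up time (required for resilience only).
    """

    c0: float
    p0: float
    cx: float | None = None
    px: float | None = None

    def __post_init__(self) -> None:
        if not (self.c0 > 0):
            raise DomainError(f"control baseline C0 must be positive, got {self.c0!r}")
        if (self.cx is None) != (self.px is None):
            raise DomainError("follow-up values cx and px must be given together")

    @property
    def d0(self) -> float:
        """Baseline disturbance, C0 - P0."""
        return self.c0 - self.p0

    @property
    def dx(self) -> float:
        """Follow-up disturbance, Cx - Px."""
        if self.cx is None or self.px is None:
            raise DomainError("follow-up values are required for Dx")
        return self.cx - self.px


def resistance_index(
    pair: PairedDisturbance, context: Mapping[str, object] | None = None
) -> IndexResult:
    """Orwin-Wardle resistance, ``RS = 1 - 2|D0| / (C0 + |D0|)``.

    Lies in (-1, 1]; equals 1 iff the disturbed value matches the control,
    0 when the parameter is completely suppressed (``|D0| = C0``), and is
    symmetric in the sign of the change.
    """
    d0 = abs(pair.d0)
    value = 1.0 - 2.0 * d0 / (pair.c0 + d0)
    return IndexResult("RS", value, dict(context or {}))


def resilience_index(
    pair: PairedDisturbance, context: Mapping[str, object] | None = None
) -> IndexResult:
    """Orwin-Wardle resilience, ``RL = 2|D0| / (|D0| + |Dx|) - 1``.

    1 iff the follow-up disturbance vanished, 0 when it is unchanged in
    magnitude, negative when it grew.  When there was no disturbance at
    either time (D0 = Dx = 0) the index is undefined and a flagged-missing
    result (NaN value) is returned rather than a number.  When D0 = 0 but a
    disturbance appeared later, the formula's limit -1 is returned with a
    warning.
    """
    d0 = abs(pair.d0)
    dx = abs(pair.dx)
    ctx = dict(context or {})
    if d0 == 0 and dx == 0:
        return IndexResult(
            "RL", math.nan, ctx, note="undefined: no disturbance at either time"
        )
    if d0 == 0:
        warnings.warn(
            "resilience with zero baseline disturbance: a disturbance emerged "
            "only at follow-up; RL = -1 by convention",
            stacklevel=2,
        )
        return IndexResult("RL", -1.0, ctx, note="new disturbance at follow-up")
    return IndexResult("RL", 2.0 * d0 / (d0 + dx) - 1.0, ctx)


def _mean_lookup(table: pd.DataFrame, variable: str, dose: float, time: int) -> float:
    mask = (
        (table["variable"] == variable)
        & np.isclose(table["dose"].astype(float), dose)
        & (table["time"].astype(int) == time)
    )
    hit = table.loc[mask, "value"]
    if hit.empty:
        raise KeyError(f"no cell for ({variable!r}, dose {dose}, day {time})")
    return float(hit.iloc[0])


def resistance_table(means: pd.DataFrame) -> pd.DataFrame:
    """RS per (variable, treated dose, time) from a tidy means table.

    Each sampling day serves as its own baseline: the control value at that
    day is C0, the treated value is P0.  The input must contain dose-0 rows
    for every (variable, time) present.
    """
    out = []
    doses = sorted(d for d in means["dose"].astype(float).unique() if d > 0)
    for variable in means["variable"].unique():
        for time in sorted(means.loc[means["variable"] == variable, "time"].unique()):
            try:
                c0 = _mean_lookup(means, variable, 0.0, int(time))
            except KeyError as exc:
                raise MissingControlError(
                    f"variable {variable!r} has no control (dose 0) series at day {time}"
                ) from exc
            for dose in doses:
                p0 = _mean_lookup(means, variable, dose, int(time))
                res = resistance_index(PairedDisturbance(c0, p0))
                out.append((dose, int(time), variable, res.value))
    return pd.DataFrame(out, columns=["dose", "time", "variable", "value"])


def resilience_table(means: pd.DataFrame, t0: int = 30, tx: int = 90) -> pd.DataFrame:
    """RL per (variable, treated dose) between baseline day t0 and follow-up tx."""
    if not t0 < tx:
        raise DomainError("baseline time must precede the follow-up time")
    out = []
    doses = sorted(d for d in means["dose"].astype(float).unique() if d > 0)
    for variable in means["variable"].unique():
        try:
            c0 = _mean_lookup(means, variable, 0.0, t0)
            cx = _mean_lookup(means, variable, 0.0, tx)
        except KeyError as exc:
            raise MissingControlError(
                f"variable {variable!r} lacks a control (dose 0) series"
            ) from exc
        for dose in doses:
            pair = PairedDisturbance(
                c0,
                _mean_lookup(means, variable, dose, t0),
                cx,
                _mean_lookup(means, variable, dose, tx),
            )
            out.append((dose, variable, resilience_index(pair).value))
    return pd.DataFrame(out, columns=["dose", "variable", "value"])


# ---------------------------------------------------------------------------
# PEC dissipation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayParams:
    """Shared first-order decay: ``PEC(d, t) = f * d * exp(-k t)``."""

    f: float
    k: float

    def __post_init__(self) -> None:
        if not (self.f > 0):
            raise DomainError("initial concentration fraction f must be positive")
        if not (self.k > 0):
            raise DomainError("decay rate k must be positive")

    @property
    def dt50(self) -> float:
        """Half-life in days, ln 2 / k."""
        return math.log(2.0) / self.k


@dataclass(frozen=True)
class PECFit:
    """Fitted decay parameters plus residual diagnostics (log scale)."""

    params: DecayParams
    log_rmse: float
    n_obs: int
    residuals: pd.DataFrame

    @property
    def f(self) -> float:
        return self.params.f

    @property
    def k(self) -> float:
        return self.params.k

    @property
    def dt50(self) -> float:
        return self.params.dt50


def fit_pec(table: pd.DataFrame) -> PECFit:
    """Least-squares fit of the shared-decay PEC model to a dose x time grid.

    ``table`` is tidy with columns ``dose``, ``time``, ``value``
    (concentrations, mg kg-1).  The fit is the ordinary least-squares line
    ``ln(PEC/dose) = ln f - k t`` pooled over all non-zero doses, so ``f``
    and ``k`` are shared across doses.
    """
    required = {"dose", "time", "value"}
    if not required.issubset(table.columns):
        raise UnderdeterminedError(f"PEC table needs columns {sorted(required)}")
    dose = table["dose"].astype(float).to_numpy()
    time = table["time"].astype(float).to_numpy()
    conc = table["value"].astype(float).to_numpy()
    if np.any(dose <= 0):
        raise DomainError("PEC fitting requires strictly positive doses")
    if np.any(conc <= 0):
        raise DomainError("non-positive concentration in PEC table")
    if np.unique(time).size < 2:
        raise UnderdeterminedError(
            "at least two distinct times are needed to identify the decay rate"
        )
    y = np.log(conc / dose)
    slope, intercept = np.polyfit(time, y, 1)
    params = DecayParams(f=float(np.exp(intercept)), k=float(-slope))
    fitted = intercept + slope * time
    residuals = pd.DataFrame(
        {"dose": dose, "time": time, "log_residual": y - fitted}
    )
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return PECFit(params=params, log_rmse=rmse, n_obs=len(y), residuals=residuals)


def predict_pec(params: DecayParams, dose: float, t: float) -> float:
    """Concentration mg kg-1 at (dose, t); linear in dose, log-linear in time."""
    if dose < 0:
        raise DomainError("dose must be non-negative")
    if t < 0:
        raise DomainError("time must be non-negative")
    return params.f * dose * math.exp(-params.k * t)


def dose_linear_prediction(
    table: pd.DataFrame, from_dose: float, to_dose: float, time: int
) -> float:
    """Predict the concentration at ``to_dose`` by pure dose-proportionality.

    Scales the tabulated concentration at ``(from_dose, time)`` by
    ``to_dose / from_dose``; no decay parameters involved.
    """
    if from_dose <= 0:
        raise DomainError("reference dose must be positive")
    mask = np.isclose(table["dose"].astype(float), from_dose) & (
        table["time"].astype(int) == int(time)
    )
    hit = table.loc[mask, "value"]
    if hit.empty:
        raise KeyError(f"no PEC cell at dose {from_dose}, day {time}")
    return float(hit.iloc[0]) * to_dose / from_dose


# ---------------------------------------------------------------------------
# Mean-table deltas and index summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectDelta:
    """Signed treated-minus-control difference in the variable's unit."""

    variable: str
    dose: float
    time: int
    delta: float  # treated - control

    @property
    def magnitude(self) -> float:
        return abs(self.delta)

    @property
    def direction(self) -> str:
        if self.delta > 0:
            return "increase"
        if self.delta < 0:
            return "reduction"
        return "no change"


def effect_delta(
    table: pd.DataFrame, variable: str, dose: float, time: int
) -> EffectDelta:
    """Treated-minus-control difference at (variable, dose, time).

    The table must contain a dose-0 row for the same variable and time;
    otherwise :class:`MissingControlError` is raised.
    """
    try:
        control = _mean_lookup(table, variable, 0.0, time)
    except KeyError as exc:
        raise MissingControlError(
            f"no control (dose 0) value for {variable!r} at day {time}"
        ) from exc
    treated = _mean_lookup(table, variable, dose, time)
    return EffectDelta(variable=variable, dose=dose, time=int(time), delta=treated - control)


@dataclass(frozen=True)
class IndexSummary:
    """Group means plus global extremes and a descending ranking."""

    group_means: pd.Series
    minimum: float
    maximum: float
    ranking: tuple[str, ...]
    missing_groups: tuple[str, ...] = ()


def summarize_index(
    cells: pd.DataFrame | Sequence[IndexResult], by: str | Sequence[str] = "variable"
) -> IndexSummary:
    """Arithmetic group means, global extremes and a descending ranking.

    ``cells`` is either a tidy frame with a ``value`` column or a sequence
    of :class:`IndexResult` (grouped by their context keys).  Flagged-missing
    values (NaN) are excluded; a group with no usable values is reported
    under ``missing_groups`` rather than as zero.  Ranking ties break by
    label order.
    """
    if not isinstance(cells, pd.DataFrame):
        rows = [{**dict(r.context), "value": r.value} for r in cells]
        cells = pd.DataFrame(rows)
    if cells.empty:
        raise DomainError("cannot summarize an empty index collection")
    keys = [by] if isinstance(by, str) else list(by)
    values = cells.dropna(subset=["value"])
    grouped = values.groupby(keys, sort=True)["value"].mean()
    all_groups = cells.groupby(keys, sort=True)["value"].size()
    missing = tuple(str(g) for g in all_groups.index if g not in grouped.index)
    ranked = sorted(
        grouped.items(), key=lambda item: (-item[1], str(item[0]))
    )
    return IndexSummary(
        group_means=grouped,
        minimum=float(values["value"].min()),
        maximum=float(values["value"].max()),
        ranking=tuple(str(label) for label, _ in ranked),
        missing_groups=missing,
    )
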