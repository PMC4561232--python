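"""Seeded synthetic experiments with the structure the analysis assumes.

The generator emulates the study design: five doses (control, the
recommended rate 0.075, then 2.25, 11.25, 22.50 mg kg-1), sampling on days
30/60/90, nine enzyme replicates and three count replicates per cell.

* Enzyme activity per replicate follows saturating dose inhibition with
  multiplicative log-normal noise:
  ``A = A0(t) * (1 - Imax * d / (d + K50)) * exp(eps)``,
  ``eps ~ N(0, sigma^2)``.  The saturating form mirrors the sub-proportional
  decline of activities at high doses; baselines default to the control
  activities of the real experiment.
* Microbial counts (log10 CFU) are additive in log dose:
  ``y = mu(t) + beta * log10(1 + d/d_ref) + N(0, sigma_c^2)``.
* Colony emergence over a 10-day window is a multinomial draw from a
  mixture of a fast-grower (r-strategist) day distribution and a slow-grower
  (K-strategist) one, with the fast weight declining with dose:
  ``w(d) = w0 * Kw / (Kw + d)``.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .indices import EmergenceProfile
from .io_fixtures import COUNT_UNIT, ENZYME_UNITS

__all__ = [
    "ConfigError",
    "UnidentifiableError",
    "SyntheticConfig",
    "RecoveredParams",
    "generate_experiment",
    "generate_emergence",
    "recover_parameters",
]


class ConfigError(ValueError):
    """Invalid synthetic-experiment configuration."""


class UnidentifiableError(ValueError):
    """The requested parameters cannot be identified from the data."""


# Control-level baselines of the real experiment (per sampling day), used as
# generator defaults so synthetic tables live on a realistic scale.
_ENZYME_BASELINES: dict[str, dict[int, float]] = {
    "dehydrogenases": {30: 5.310, 60: 9.151, 90: 7.255},
    "catalase": {30: 0.360, 60: 0.346, 90: 0.334},
    "urease": {30: 0.175, 60: 0.165, 90: 0.136},
    "acid_phosphatase": {30: 0.910, 60: 0.878, 90: 0.863},
    "alkaline_phosphatase": {30: 1.276, 60: 2.259, 90: 0.470},
}
_COUNT_BASELINES: dict[str, dict[int, float]] = {
    "organotrophic_bacteria": {30: 10.186, 60: 10.474, 90: 10.459},
    "actinomycetes": {30: 9.938, 60: 10.288, 90: 10.293},
    "fungi": {30: 7.153, 60: 7.348, 90: 7.440},
}


def _default_fast_days() -> tuple[float, ...]:
    # r-strategists: colonies appear within the first three days
    return (0.55, 0.30, 0.15, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _default_slow_days() -> tuple[float, ...]:
    # K-strategists: emergence spread evenly over the whole window
    return tuple([0.1] * 10)


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and generative parameters of a synthetic experiment.

    Parameters
    ----------
    doses, times:
        Treatment doses (mg kg-1, control included) and sampling days.
    n_replicates, n_replicates_counts:
        Replicates per cell for enzyme assays (default 9) and plate counts
        (default 3).
    imax:
        Maximal fractional inhibition of enzyme activity, in [0, 1].
    k50:
        Dose of half-maximal inhibition, mg kg-1 (> 0).
    noise_sd:
        Log-scale s.d. of the multiplicative enzyme noise (>= 0).
    count_slope:
        Change of log10 counts per unit log10(1 + d/d_ref); negative for
        inhibition.
    emergence_n:
        Total colonies scored per emergence profile.
    fast_weight, fast_k50:
        Mixture weight of fast growers in uncontaminated soil and the dose
        scale of its decline: ``w(d) = fast_weight * fast_k50 / (fast_k50 + d)``.
    """

    doses: tuple[float, ...] = (0.0, 0.075, 2.25, 11.25, 22.5)
    times: tuple[int, ...] = (30, 60, 90)
    n_replicates: int = 9
    n_replicates_counts: int = 3
    enzyme_baselines: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _ENZYME_BASELINES.items()}
    )
    imax: float = 0.3
    k50: float = 5.0
    noise_sd: float = 0.05
    count_baselines: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _COUNT_BASELINES.items()}
    )
    count_slope: float = -0.3
    count_noise_sd: float = 0.05
    count_dose_ref: float = 1.0
    emergence_n: int = 200
    fast_days: tuple[float, ...] = field(default_factory=_default_fast_days)
    slow_days: tuple[float, ...] = field(default_factory=_default_slow_days)
    fast_weight: float = 0.7
    fast_k50: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) == 0 or len(self.times) == 0:
            raise ConfigError("doses and times must be non-empty")
        if any(d < 0 for d in self.doses):
            raise ConfigError("doses must be non-negative")
        if not 0.0 <= self.imax <= 1.0:
            raise ConfigError("imax must lie in [0, 1]")
        if not self.k50 > 0:
            raise ConfigError("k50 must be positive")
        if self.noise_sd < 0 or self.count_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if not 0.0 <= self.fast_weight <= 1.0:
            raise ConfigError("fast_weight must lie in [0, 1]")
        if not self.fast_k50 > 0:
            raise ConfigError("fast_k50 must be positive")
        if self.emergence_n <= 0:
            raise ConfigError("emergence_n must be positive")
        for name, dist in (("fast_days", self.fast_days), ("slow_days", self.slow_days)):
            arr = np.asarray(dist, dtype=float)
            if arr.size != 10 or (arr < 0).any() or not math.isclose(arr.sum(), 1.0):
                raise ConfigError(
                    f"{name} must be a probability distribution over days 1..10"
                )

    # -- inhibition and mixture weight -------------------------------------
    def inhibition_factor(self, dose: float) -> float:
        """Fraction of baseline activity remaining at ``dose``."""
        return 1.0 - self.imax * dose / (dose + self.k50)

    def fast_weight_at(self, dose: float) -> float:
        """Mixture weight of the fast-grower day distribution at ``dose``."""
        return self.fast_weight * self.fast_k50 / (self.fast_k50 + dose)

    def emergence_day_distribution(self, dose: float) -> np.ndarray:
        w = self.fast_weight_at(dose)
        return w * np.asarray(self.fast_days) + (1 - w) * np.asarray(self.slow_days)

    # -- (de)serialisation ---------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["enzyme_baselines"] = {
            k: {int(t): float(v) for t, v in m.items()}
            for k, m in payload["enzyme_baselines"].items()
        }
        payload["count_baselines"] = {
            k: {int(t): float(v) for t, v in m.items()}
            for k, m in payload["count_baselines"].items()
        }
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(payload, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as handle:
            payload = yaml.safe_load(handle) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        for key in ("doses", "times", "fast_days", "slow_days"):
            if key in payload:
                payload[key] = tuple(payload[key])
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def generate_experiment(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tidy replicate-level experiment table.

    Returns a long frame (dose, time, replicate, variable, value) holding
    enzyme activities for every enzyme in ``config.enzyme_baselines`` and
    log10 counts for every group in ``config.count_baselines``; fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    for enzyme in config.enzyme_baselines:
        baseline = config.enzyme_baselines[enzyme]
        for dose in config.doses:
            factor = config.inhibition_factor(dose)
            for time in config.times:
                if time not in baseline:
                    raise ConfigError(
                        f"no baseline for enzyme {enzyme!r} at day {time}"
                    )
                eps = rng.normal(0.0, config.noise_sd, size=config.n_replicates)
                for i, e in enumerate(eps, start=1):
                    value = baseline[time] * factor * math.exp(e)
                    rows.append((dose, time, f"r{i}", enzyme, value))
    for group in config.count_baselines:
        baseline = config.count_baselines[group]
        for dose in config.doses:
            shift = config.count_slope * math.log10(1.0 + dose / config.count_dose_ref)
            for time in config.times:
                if time not in baseline:
                    raise ConfigError(f"no baseline for group {group!r} at day {time}")
                eps = rng.normal(0.0, config.count_noise_sd, size=config.n_replicates_counts)
                for i, e in enumerate(eps, start=1):
                    rows.append((dose, time, f"r{i}", group, baseline[time] + shift + e))
    frame = pd.DataFrame(rows, columns=["dose", "time", "replicate", "variable", "value"])
    frame.attrs["units"] = {
        **{e: ENZYME_UNITS.get(e, "") for e in config.enzyme_baselines},
        **{g: COUNT_UNIT for g in config.count_baselines},
    }
    return frame


def generate_emergence(config: SyntheticConfig, dose: float) -> EmergenceProfile:
    """Multinomial 10-day emergence profile at ``dose``.

    The day distribution is the fast/slow mixture at ``dose``; the draw is
    seeded from (config.seed, dose) so distinct doses get independent but
    reproducible profiles.
    """
    if dose < 0:
        raise ConfigError("dose must be non-negative")
    p = config.emergence_day_distribution(dose)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(round(dose * 1_000_000))])
    )
    counts = rng.multinomial(config.emergence_n, p / p.sum())
    return EmergenceProfile(tuple(int(c) for c in counts))


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveredParams:
    """Estimated inhibition parameters with optional bootstrap intervals."""

    imax: float
    k50: float
    sigma: float
    baselines: Mapping[int, float]
    ci: Mapping[str, tuple[float, float]] | None = None


def _fit_inhibition(
    doses: np.ndarray, times: np.ndarray, logy: np.ndarray, time_levels: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Least squares of log activity = a_t + log(1 - imax*d/(d+k50))."""
    time_index = np.searchsorted(time_levels, times)

    def unpack(theta):
        a = theta[: time_levels.size]
        imax = 1.0 / (1.0 + np.exp(-theta[-2]))  # logistic: (0, 1)
        k50 = np.exp(theta[-1])
        return a, imax, k50

    def residual(theta):
        a, imax, k50 = unpack(theta)
        pred = a[time_index] + np.log1p(-imax * doses / (doses + k50))
        return pred - logy

    # moment-style start: per-time control means and the strongest observed drop
    a0 = np.array(
        [logy[(time_index == i) & (doses == 0)].mean() if (doses == 0).any()
         else logy[time_index == i].mean() for i in range(time_levels.size)]
    )
    drop = 1.0 - math.exp(
        float(np.min([logy[doses == d].mean() - a0[0] for d in np.unique(doses) if d > 0]))
    )
    imax0 = min(max(drop, 0.05), 0.95)
    theta0 = np.concatenate(
        [a0, [math.log(imax0 / (1 - imax0)), math.log(np.median(doses[doses > 0]))]]
    )
    sol = least_squares(residual, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    a, imax, k50 = unpack(sol.x)
    return float(imax), float(k50), a, sol.fun


def recover_parameters(
    observations: pd.DataFrame,
    variable: str | None = None,
    n_boot: int = 200,
    seed: int | None = None,
) -> RecoveredParams:
    """Estimate (Imax, K50, sigma) of the saturating-inhibition model.

    ``observations`` is a tidy replicate-level table (one variable, or pass
    ``variable`` to select one).  The fit is nonlinear least squares on log
    activity with one free log-baseline per sampling day.  ``n_boot``
    case-resampling rounds within (dose, time) cells give percentile 95 %
    intervals for Imax and K50 (``n_boot=0`` skips them).
    """
    table = observations
    if variable is not None:
        table = table[table["variable"] == variable]
    elif table["variable"].nunique() > 1:
        raise UnidentifiableError(
            "multiple variables present; pass `variable` to select one"
        )
    if table.empty:
        raise UnidentifiableError("no observations to fit")
    doses = table["dose"].astype(float).to_numpy()
    if np.unique(doses[doses > 0]).size < 3:
        raise UnidentifiableError(
            "at least 3 distinct non-zero doses are needed to identify (Imax, K50)"
        )
    times = table["time"].astype(int).to_numpy()
    values = table["value"].astype(float).to_numpy()
    if np.any(values <= 0):
        raise UnidentifiableError("activities must be positive for the log-scale fit")
    logy = np.log(values)
    time_levels = np.unique(times)

    imax, k50, a, res = _fit_inhibition(doses, times, logy, time_levels)
    dof = max(res.size - (time_levels.size + 2), 1)
    sigma = float(np.sqrt(np.sum(res**2) / dof))
    baselines = {int(t): float(np.exp(ai)) for t, ai in zip(time_levels, a)}

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        cells = table.groupby(["dose", "time"], sort=True).indices
        stats_boot = np.empty((n_boot, 2))
        for b in range(n_boot):
            pick = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in cells.values()]
            )
            bi, bk, _, _ = _fit_inhibition(
                doses[pick], times[pick], logy[pick], time_levels
            )
            stats_boot[b] = (bi, bk)
        lo, hi = np.percentile(stats_boot, [2.5, 97.5], axis=0)
        ci = {"imax": (float(lo[0]), float(hi[0])), "k50": (float(lo[1]), float(hi[1]))}

    return RecoveredParams(imax=imax, k50=k50, sigma=sigma, baselines=baselines, ci=ci)
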