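"""Dose-response assessment statistics.

Pearson dose correlations, two-way eta-squared variance partitioning,
Tukey-range compact letter displays, Ward minimum-variance clustering of
standardized response profiles, and PCA explained-variance summaries.

The heavy lifting is delegated to scipy / statsmodels / scikit-learn; this
module fixes the dialects used throughout the pipeline (raw dose scale for
correlations, classic Ward on z-scored features, correlation-matrix PCA)
and the compact-letter-display construction, which is implemented here with
the insert-and-absorb algorithm.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DegenerateDataError",
    "LayoutError",
    "DegreesOfFreedomError",
    "CorrelationResult",
    "VariancePartition",
    "LetterDisplay",
    "WardResult",
    "PCAVariance",
    "dose_correlation",
    "eta_squared",
    "tukey_letters",
    "ward_cluster",
    "pca_variance",
]


class DegenerateDataError(ValueError):
    """Data without the variation the statistic requires."""


class LayoutError(ValueError):
    """The factorial layout is incomplete or malformed."""


class DegreesOfFreedomError(ValueError):
    """Not enough replication for the requested test."""


# ---------------------------------------------------------------------------
# Pearson dose correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    alpha: float
    significant: bool


def dose_correlation(
    doses: Sequence[float], values: Sequence[float], alpha: float = 0.01
) -> CorrelationResult:
    """Pearson correlation between dose and response on the raw dose scale.

    Significance is a two-sided t test at ``alpha`` (default 0.01, the
    conventional threshold for the printed asterisks); the exact p-value is
    always reported alongside the flag.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise DegenerateDataError("doses and values must have equal length")
    if x.size < 3:
        raise DegenerateDataError("at least 3 points are needed for a correlation")
    if np.ptp(y) == 0:
        raise DegenerateDataError("values have zero variance; correlation undefined")
    if np.ptp(x) == 0:
        raise DegenerateDataError("doses have zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), n=int(x.size), p_value=float(p), alpha=alpha,
        significant=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# Two-way eta-squared variance partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariancePartition:
    """Sums of squares and eta-squared shares of a two-way dose x time layout.

    ``ss`` maps factor -> sum of squares; components always include
    ``dose``, ``time`` and ``interaction``, plus ``error`` when the input
    carried replicates.  ``eta_squared`` holds the corresponding fractions
    of the total (they sum to 1).
    """

    ss: Mapping[str, float]
    ss_total: float
    replicated: bool

    @property
    def eta_squared(self) -> dict[str, float]:
        return {k: v / self.ss_total for k, v in self.ss.items()}

    @property
    def eta_squared_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.eta_squared.items()}


def _check_complete(table: pd.DataFrame) -> int:
    counts = table.groupby(["dose", "time"], sort=True)["value"].size()
    n_dose = table["dose"].nunique()
    n_time = table["time"].nunique()
    if len(counts) != n_dose * n_time:
        raise LayoutError(
            f"incomplete factorial layout: {len(counts)} of "
            f"{n_dose * n_time} dose x time cells present"
        )
    if counts.nunique() != 1:
        raise LayoutError("unbalanced layout: cells carry unequal replicate counts")
    return int(counts.iloc[0])


def eta_squared(table: pd.DataFrame) -> VariancePartition:
    """Partition total variance of a complete dose x time layout.

    ``table`` is tidy with ``dose``, ``time`` and ``value`` columns.  With
    one value per cell (a means grid) the partition is the classical
    two-way decomposition without replication: row, column and residual
    (interaction) sums of squares.  With replicated cells a two-way ANOVA
    with interaction (statsmodels OLS) supplies the sums of squares, and an
    ``error`` component appears.  In both cases the components sum to the
    total and each eta-squared share lies in [0, 1].

    Note: a partition computed from a published means grid approximates the
    replicate-level one (it has no error stratum); both modes are exposed.
    """
    required = {"dose", "time", "value"}
    if not required.issubset(table.columns):
        raise LayoutError(f"need columns {sorted(required)}")
    per_cell = _check_complete(table)

    if per_cell == 1:
        grid = table.pivot_table(index="dose", columns="time", values="value")
        values = grid.to_numpy(dtype=float)
        grand = values.mean()
        n_dose, n_time = values.shape
        ss_dose = n_time * float(((values.mean(axis=1) - grand) ** 2).sum())
        ss_time = n_dose * float(((values.mean(axis=0) - grand) ** 2).sum())
        ss_total = float(((values - grand) ** 2).sum())
        ss_inter = ss_total - ss_dose - ss_time
        return VariancePartition(
            ss={"dose": ss_dose, "time": ss_time, "interaction": ss_inter},
            ss_total=ss_total,
            replicated=False,
        )

    frame = table.copy()
    model = ols("value ~ C(dose) * C(time)", data=frame).fit()
    anova = anova_lm(model, typ=2)
    ss = {
        "dose": float(anova.loc["C(dose)", "sum_sq"]),
        "time": float(anova.loc["C(time)", "sum_sq"]),
        "interaction": float(anova.loc["C(dose):C(time)", "sum_sq"]),
        "error": float(anova.loc["Residual", "sum_sq"]),
    }
    return VariancePartition(ss=ss, ss_total=float(sum(ss.values())), replicated=True)


# ---------------------------------------------------------------------------
# Tukey range test and compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display over Tukey HSD pairwise comparisons.

    Two groups share at least one letter iff their comparison is
    non-significant at ``alpha``.
    """

    letters: Mapping[str, str]
    p_values: pd.DataFrame
    alpha: float


def _insert_absorb(labels: Sequence[str], distinct: set[tuple[int, int]]) -> dict[str, str]:
    """Insert-and-absorb compact-letter-display construction.

    ``distinct`` holds index pairs that are significantly different.  Start
    from one column containing every group; for each distinct pair split
    any column containing both; absorb columns that became subsets.
    """
    columns: list[set[int]] = [set(range(len(labels)))]
    for i, j in sorted(distinct):
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
            # absorb: drop any column contained in another
            columns = [
                c for c in columns
                if not any(c < other for other in columns)
            ]
    # deduplicate while keeping deterministic order: by smallest member index
    unique: list[set[int]] = []
    for col in columns:
        if col not in unique:
            unique.append(col)
    unique.sort(key=lambda c: sorted(c))
    alphabet = string.ascii_lowercase
    if len(unique) > len(alphabet):  # pragma: no cover - >26 homogeneous sets
        alphabet = [a + b for a in alphabet for b in alphabet]
    assignment: dict[str, list[str]] = {label: [] for label in labels}
    for letter, col in zip(alphabet, unique):
        for idx in sorted(col):
            assignment[labels[idx]].append(letter)
    return {label: "".join(sorted(ls)) for label, ls in assignment.items()}


def tukey_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.01
) -> LetterDisplay:
    """Homogeneous-group letters from Tukey's range (HSD) test.

    ``groups`` maps group label -> replicate values (>= 2 each).  Pairwise
    p-values come from :func:`scipy.stats.tukey_hsd`; letters are assigned
    to homogeneous sets in group order.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DegenerateDataError("at least two groups are required")
    samples = [np.asarray(groups[label], dtype=float) for label in labels]
    for label, sample in zip(labels, samples):
        if sample.size < 2:
            raise DegreesOfFreedomError(
                f"group {label!r} has {sample.size} replicate(s); "
                "Tukey's test needs at least 2 per group"
            )
    result = sps.tukey_hsd(*samples)
    pmat = pd.DataFrame(result.pvalue, index=labels, columns=labels)
    distinct = {
        (i, j)
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if result.pvalue[i, j] < alpha
    }
    return LetterDisplay(
        letters=_insert_absorb(labels, distinct), p_values=pmat, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Ward clustering of response profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WardResult:
    """Ward minimum-variance merge tree over standardized profiles."""

    linkage: np.ndarray
    labels: tuple[str, ...]
    dropped_features: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """Memberships of the two clusters below the final merge."""
        assignments = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        one = frozenset(l for l, a in zip(self.labels, assignments) if a == 1)
        two = frozenset(l for l, a in zip(self.labels, assignments) if a == 2)
        return one, two


def ward_cluster(
    profiles: pd.DataFrame, standardize: bool = True, method: str = "ward"
) -> WardResult:
    """Hierarchical clustering of profile rows (cases) over feature columns.

    Features are z-scored (sample s.d.) before Euclidean/Ward linkage, the
    classic minimum-variance dialect; ``method`` admits the other scipy
    linkage dialects.  Constant features carry no information after
    standardization and are dropped with a warning.
    """
    if profiles.shape[0] < 2:
        raise DegenerateDataError("at least two profiles are required")
    data = profiles.to_numpy(dtype=float)
    dropped: tuple[str, ...] = ()
    if standardize:
        std = data.std(axis=0, ddof=1)
        keep = std > 0
        if not keep.all():
            dropped = tuple(str(c) for c, k in zip(profiles.columns, keep) if not k)
            warnings.warn(
                f"dropping constant feature(s) before standardization: {dropped}",
                stacklevel=2,
            )
            data = data[:, keep]
            std = std[keep]
            if data.shape[1] == 0:
                raise DegenerateDataError("all features are constant")
        data = (data - data.mean(axis=0)) / std
    linkage = hierarchy.linkage(data, method=method)
    return WardResult(
        linkage=linkage,
        labels=tuple(str(i) for i in profiles.index),
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# PCA explained variance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAVariance:
    """Per-component explained variance of a cases x variables matrix."""

    percent: tuple[float, ...]
    method: str

    @property
    def cumulative_percent(self) -> tuple[float, ...]:
        return tuple(np.cumsum(self.percent))


def pca_variance(matrix: pd.DataFrame | np.ndarray, method: str = "correlation") -> PCAVariance:
    """Explained-variance percentages of principal components.

    ``method='correlation'`` (default) standardizes every variable first,
    i.e. PCA on the correlation matrix; ``method='covariance'`` analyses the
    centred but unscaled data.  Percentages are non-increasing and sum
    to 100.
    """
    if isinstance(matrix, pd.DataFrame):
        names = [str(c) for c in matrix.columns]
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        names = [f"column {i}" for i in range(data.shape[1])]
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise DegenerateDataError("need at least 2 cases and 2 variables")
    if np.isnan(data).any():
        raise DegenerateDataError("missing entries are not allowed")
    std = data.std(axis=0, ddof=1)
    dead = [name for name, s in zip(names, std) if s == 0]
    if dead:
        raise DegenerateDataError(f"zero-variance variable(s): {dead}")
    if method == "correlation":
        data = (data - data.mean(axis=0)) / std
    elif method != "covariance":
        raise ValueError(f"unknown PCA method {method!r}")
    pca = PCA(n_components=min(data.shape[0] - 1, data.shape[1]), svd_solver="full")
    pca.fit(data)
    percent = 100.0 * pca.explained_variance_ratio_
    return PCAVariance(percent=tuple(float(p) for p in percent), method=method)
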