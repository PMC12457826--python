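"""Quantile-threshold discretization of continuous variables.

A continuous measurement is mapped to an ordered set of levels by cutting at
quantiles of a kernel-density-estimated distribution function.  With ``n``
thresholds starting at index ``i`` the cut points ``Q_i, ..., Q_{i+n-1}``
solve ``F(Q_j) = j / (n + 2)``, where ``F`` is the CDF of a Gaussian-kernel
density fit.  The default configuration (``n = i = 2``) cuts at the 50% and
75% points, producing three levels with nominal occupancies 0.5 / 0.25 / 0.25
on tie-free data.  Baseline discretizers (equal-width, equal-frequency,
1-D k-means) and a one-way ANOVA validation of the grouping are also
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "ContinuousSample",
    "QTFModel",
    "OrdinalColumn",
    "AnovaResult",
    "silverman_bandwidth",
    "fit_kde",
    "kde_pdf",
    "kde_cdf",
    "solve_thresholds",
    "discretize",
    "qtf_discretize",
    "anova_validate",
    "equal_width_discretize",
    "equal_frequency_discretize",
    "kmeans_discretize",
]


@dataclass
class ContinuousSample:
    """Raw measurements of one continuous variable."""

    values: np.ndarray
    name: str = "x"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError(
                f"column {self.name!r}: need at least 2 observations for KDE"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"column {self.name!r}: non-finite values present")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class QTFModel:
    """Gaussian-kernel density fit plus (optionally) solved thresholds."""

    sample: ContinuousSample
    bandwidth: float
    thresholds: np.ndarray | None = None
    n_levels: int | None = None
    start_index: int | None = None
    target_fractions: np.ndarray | None = None


@dataclass
class OrdinalColumn:
    """Integer-coded ordinal variable with levels ``0 .. n_levels - 1``."""

    levels: np.ndarray
    n_levels: int
    source: str = "qtf"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.size and (
            self.levels.min() < 0 or self.levels.max() >= self.n_levels
        ):
            raise ValueError("levels outside {0, ..., n_levels-1}")

    def proportions(self) -> np.ndarray:
        """Occupancy of each level; always sums to exactly 1."""
        counts = np.bincount(self.levels, minlength=self.n_levels)
        return counts / self.levels.size


@dataclass
class AnovaResult:
    """One-way ANOVA of the raw values grouped by assigned level."""

    group_means: np.ndarray
    group_sds: np.ndarray
    group_ns: np.ndarray
    F: float
    p: float

    def stars(self) -> str:
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < cut:
                return mark
        return ""


def silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n**(-1/5).

    Falls back to the standard deviation when the IQR is zero (heavy ties);
    returns 0.0 for a constant column, which callers must treat as an error
    unless an explicit bandwidth is supplied.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        return 0.0
    return 0.9 * min(spread_candidates) * n ** (-0.2)


def fit_kde(sample: ContinuousSample, bandwidth: float | None = None) -> QTFModel:
    """Fit a Gaussian-kernel density f(x) = (1/nh) sum K((x - x_i)/h)."""
    if bandwidth is None:
        bandwidth = silverman_bandwidth(sample.values)
        if bandwidth <= 0:
            raise ValueError(
                f"column {sample.name!r} is (nearly) constant; supply an "
                "explicit bandwidth to fit a KDE"
            )
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    return QTFModel(sample=sample, bandwidth=float(bandwidth))


def kde_pdf(model: QTFModel, x) -> np.ndarray | float:
    """Evaluate the fitted kernel density at ``x``."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    h = model.bandwidth
    z = (xs[:, None] - model.sample.values[None, :]) / h
    out = np.exp(-0.5 * z**2).sum(axis=1) / (len(model.sample) * h * np.sqrt(2 * np.pi))
    return out if np.ndim(x) else float(out[0])


def kde_cdf(model: QTFModel, x) -> np.ndarray | float:
    """Evaluate the fitted distribution function F(x) = mean Phi((x-x_i)/h)."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    h = model.bandwidth
    out = ndtr((xs[:, None] - model.sample.values[None, :]) / h).mean(axis=1)
    return out if np.ndim(x) else float(out[0])


def solve_thresholds(
    model: QTFModel,
    n_levels_minus_one: int = 2,
    start_index: int = 2,
) -> QTFModel:
    """Solve the quantile thresholds Q_i .. Q_{i+n-1} of the fitted CDF.

    Each threshold satisfies F(Q_j) = j / (n + 2).  Roots are bracketed in
    [min - 10h, max + 10h] where the kernel CDF provably spans (~0, ~1).
    Thresholds that coincide (possible only under extreme point masses with a
    tiny bandwidth) are collapsed with a warning, reducing the level count.
    """
    n = int(n_levels_minus_one)
    i = int(start_index)
    if n < 1 or i < 1 or i + n - 1 > n + 1:
        raise ValueError(f"invalid QTF parameterization n={n}, i={i}")
    targets = np.array([j / (n + 2) for j in range(i, i + n)])
    vals = model.sample.values
    h = model.bandwidth
    lo, hi = vals.min() - 10 * h, vals.max() + 10 * h
    qs = []
    for t in targets:
        f = lambda x: kde_cdf(model, x) - t  # noqa: E731
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError(
                f"column {model.sample.name!r}: target fraction {t:.4f} not "
                "bracketed within [min-10h, max+10h]"
            )
        qs.append(optimize.brentq(f, lo, hi, xtol=1e-13, rtol=1e-15))
    qs = np.asarray(qs)
    keep = np.concatenate([[True], np.diff(qs) > 1e-12])
    if not keep.all():
        warnings.warn(
            f"column {model.sample.name!r}: {int((~keep).sum())} threshold(s) "
            "coincide; collapsing empty level(s)",
            stacklevel=2,
        )
        qs = qs[keep]
        targets = targets[keep]
    model.thresholds = qs
    model.n_levels = len(qs) + 1
    model.start_index = i
    model.target_fractions = targets
    return model


def discretize(sample: ContinuousSample, thresholds: np.ndarray) -> OrdinalColumn:
    """Map values to levels: level 0 for x <= Q_1, level j for Q_j < x <= Q_{j+1}.

    The boundary belongs to the lower level, and the map is monotone
    nondecreasing in x.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    # number of thresholds strictly below x == ordinal level under the
    # "x <= Q goes down" convention
    levels = np.searchsorted(thresholds, sample.values, side="left")
    return OrdinalColumn(levels=levels, n_levels=len(thresholds) + 1, source="qtf")


def qtf_discretize(
    sample: ContinuousSample,
    n_levels_minus_one: int = 2,
    start_index: int = 2,
    bandwidth: float | None = None,
) -> tuple[OrdinalColumn, QTFModel]:
    """Fit KDE, solve thresholds and discretize in one call."""
    model = fit_kde(sample, bandwidth=bandwidth)
    solve_thresholds(model, n_levels_minus_one, start_index)
    return discretize(sample, model.thresholds), model


def anova_validate(sample: ContinuousSample, column: OrdinalColumn) -> AnovaResult:
    """One-way ANOVA of the raw values across assigned levels.

    Rejecting equality of group means (alpha = 0.05) indicates the grouping
    separates the variable's distribution.
    """
    groups = [
        sample.values[column.levels == lv]
        for lv in range(column.n_levels)
        if np.any(column.levels == lv)
    ]
    if len(groups) < 2:
        raise ValueError(
            f"column {sample.name!r}: classification degenerate "
            "(single occupied level)"
        )
    F, p = stats.f_oneway(*groups)
    return AnovaResult(
        group_means=np.array([g.mean() for g in groups]),
        group_sds=np.array([g.std(ddof=1) if g.size > 1 else 0.0 for g in groups]),
        group_ns=np.array([g.size for g in groups]),
        F=float(F),
        p=float(p),
    )


def _cut_by_edges(values: np.ndarray, inner_edges: np.ndarray, n_levels: int,
                  source: str, metadata: dict | None = None) -> OrdinalColumn:
    levels = np.searchsorted(inner_edges, values, side="left")
    return OrdinalColumn(levels=levels, n_levels=n_levels, source=source,
                         metadata=metadata or {})


def equal_width_discretize(sample: ContinuousSample, n_levels: int) -> OrdinalColumn:
    """Cut [min, max] into ``n_levels`` bins of identical width."""
    lo, hi = sample.values.min(), sample.values.max()
    if hi <= lo:
        raise ValueError(f"column {sample.name!r}: zero range, cannot bin")
    edges = np.linspace(lo, hi, n_levels + 1)[1:-1]
    return _cut_by_edges(sample.values, edges, n_levels, "equal_width")


def equal_frequency_discretize(sample: ContinuousSample, n_levels: int) -> OrdinalColumn:
    """Cut at empirical quantiles so bins hold roughly equal counts.

    Edges come from the empirical quantile function with 'lower'
    interpolation, so identical values are never split across bins; heavy
    ties therefore yield unequal occupancy (warned).
    """
    probs = np.arange(1, n_levels) / n_levels
    edges = np.quantile(sample.values, probs, method="lower")
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        warnings.warn(
            f"column {sample.name!r}: tied quantile edges; fewer than "
            f"{n_levels} distinct bins",
            stacklevel=2,
        )
    col = _cut_by_edges(sample.values, uniq, len(uniq) + 1, "equal_frequency")
    occ = col.proportions()
    if np.abs(occ - 1 / col.n_levels).max() > 0.1:
        warnings.warn(
            f"column {sample.name!r}: heavy ties make equal-frequency bins "
            f"unequal (occupancies {np.round(occ, 3)})",
            stacklevel=2,
        )
    return col


def kmeans_discretize(
    sample: ContinuousSample, n_levels: int, seed: int = 0
) -> OrdinalColumn:
    """1-D k-means binning with clusters relabeled by increasing center.

    Boundaries are data-driven and depend on the random initialization, so
    the seed is recorded in the column metadata.
    """
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_levels, random_state=seed, n_init=10)
    raw = km.fit_predict(sample.values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(n_levels, dtype=int)
    relabel[order] = np.arange(n_levels)
    return OrdinalColumn(
        levels=relabel[raw],
        n_levels=n_levels,
        source="kmeans",
        metadata={"seed": seed, "centers": np.sort(km.cluster_centers_.ravel()),
                  "boundaries_data_dependent": True},
    )
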