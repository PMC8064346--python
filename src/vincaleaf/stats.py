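"""Trait correlation and group comparison.

Two small layers over scipy.stats: a Pearson correlation / ordinary
least-squares fit for trait pairs (e.g. trichome density against stomatal
index across species), and a one-way ANOVA + Tukey HSD comparison for
replicate measurements across groups, annotated with the conventional
star tiers (*** p < 0.0001, ** p <= 0.005, * p <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError

#: Star annotation tiers, checked in order; p <= 0.05 is the significance
#: threshold, anything above it gets "ns".
STAR_TIERS: tuple[tuple[float, str], ...] = (
    (0.0001, "***"),
    (0.005, "**"),
    (0.05, "*"),
)


def significance_stars(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError(f"p-value out of [0, 1]: {p}")
    if p < STAR_TIERS[0][0]:
        return STAR_TIERS[0][1]
    for threshold, stars in STAR_TIERS[1:]:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class TraitVector:
    """Paired values of two traits across the same species."""

    species_ids: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.species_ids) == len(self.x) == len(self.y)):
            raise InvalidInputError("species_ids, x and y must have equal length")
        if len(self.x) < 3:
            raise InvalidInputError("correlation requires at least 3 pairs")
        if any(v is None or not np.isfinite(v) for v in self.x + self.y):
            raise InvalidInputError("missing/non-finite value in trait pair")


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    stars: str


@dataclass(frozen=True)
class GroupComparisonResult:
    """One-way ANOVA across all groups plus Tukey HSD pairwise contrasts."""

    group_labels: tuple[str, ...]
    anova_f: float
    anova_p: float
    anova_stars: str
    pairwise: tuple[PairwiseComparison, ...]


def _check_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and the same length")
    if xa.size < 3:
        raise InvalidInputError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InvalidInputError("correlation undefined: a variable has zero variance")
    return xa, ya


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient, in [-1, 1]."""
    xa, ya = _check_xy(x, y)
    return float(sps.pearsonr(xa, ya).statistic)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFitResult:
    """Ordinary least-squares line y = slope·x + intercept; r² = pearson r²."""
    xa, ya = _check_xy(x, y)
    fit = sps.linregress(xa, ya)
    return LinearFitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=xa.size,
    )


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    design: str = "anova_tukey",
) -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise contrasts and star annotations.

    ``design='pairwise'`` skips the omnibus gate semantics but still uses
    Tukey HSD for the family of pairwise contrasts (the ANOVA row is
    reported either way).  Every group needs at least two replicates.
    """
    if design not in ("anova_tukey", "pairwise"):
        raise InvalidInputError(f"unknown design {design!r}")
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise InvalidInputError(f"group {i} has n={g.size}; every group needs n >= 2")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    elif len(labels) != len(arrays):
        raise InvalidInputError("labels and groups must have equal length")

    f_stat, f_p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)

    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(tukey.pvalue[i, j])
            pairwise.append(
                PairwiseComparison(
                    group_a=str(labels[i]),
                    group_b=str(labels[j]),
                    statistic=float(tukey.statistic[i, j]),
                    p_value=p,
                    stars=significance_stars(p),
                )
            )

    return GroupComparisonResult(
        group_labels=tuple(str(label) for label in labels),
        anova_f=float(f_stat),
        anova_p=float(f_p),
        anova_stars=significance_stars(float(f_p)),
        pairwise=tuple(pairwise),
    )
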