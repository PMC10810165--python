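"""Group statistics for morphometry tables.

The workflow mirrors common practice for small-n morphometry: samples are
screened for normality with the Shapiro-Wilk test; samples that fail and are
strictly positive are natural-log transformed and re-screened; two-group
comparisons use an independent-samples t-test (Welch by default, pooled
variance optional) on the working — possibly transformed — values; more than
two groups use one-way fixed-effects ANOVA; associations use Pearson's
correlation coefficient.  Reported group means and SDs always describe the
untransformed data, whatever transform the test itself used.

Numerical kernels are delegated to :mod:`scipy.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "normality_check",
    "transform_if_needed",
    "compare_groups",
    "one_way_anova",
    "pearson_correlation",
    "holm_adjust",
]


@dataclass
class GroupComparison:
    """A two-group (or k-group) comparison on possibly transformed values.

    Means and SDs are of the untransformed data; ``transform`` records what
    the test statistic was computed on.
    """

    group_names: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]  # untransformed
    sds: tuple[float, ...]  # untransformed, ddof=1
    transform: str  # "none" | "log"
    test: str  # "welch_t" | "pooled_t" | "anova"
    statistic: float
    p_value: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if any(k < 2 for k in self.n):
            raise ValueError(f"every group needs n >= 2, got {self.n}")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if any(s < 0 for s in self.sds):
            raise ValueError("SD must be nonnegative")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


@dataclass
class CorrelationResult:
    """Pearson correlation between two per-islet variables."""

    variables: tuple[str, str]
    n: int
    r: float
    p_value: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"Pearson correlation needs n >= 3, got {self.n}")
        if not -1.0 <= round(self.r, 12) <= 1.0:
            raise ValueError(f"|r| must not exceed 1, got {self.r}")


def _clean(values, name: str = "sample") -> np.ndarray:
    x = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns ``(W, p)``.

    Requires 3 <= n <= 5000 and nonzero variance (each violation is a
    distinct error).
    """
    x = _clean(values)
    if len(x) < 3:
        raise ValueError(f"too few observations for Shapiro-Wilk: n = {len(x)} < 3")
    if len(x) > 5000:
        raise ValueError(f"Shapiro-Wilk supports n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: normality is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def transform_if_needed(values, alpha: float = 0.05) -> tuple[np.ndarray, str]:
    """Return working values and the transform flag (``"none"`` or ``"log"``).

    If the raw sample passes Shapiro-Wilk at ``alpha`` it is used as-is.
    Otherwise, strictly positive samples are natural-log transformed (and
    re-checked, for the record); nonpositive samples raise — no shift is
    silently applied.  Downstream reporting always summarises the raw data.
    """
    x = _clean(values)
    _, p = normality_check(x)
    if p >= alpha:
        return x, "none"
    if np.any(x <= 0):
        raise ValueError(
            "sample fails normality but contains nonpositive values; "
            "log transform is not applicable and no shift is applied"
        )
    logged = np.log(x)
    normality_check(logged)  # re-screen; the flag records the transform either way
    return logged, "log"


def _joint_transform(groups: list[np.ndarray], alpha: float) -> tuple[list[np.ndarray], str]:
    """One transform decision for all groups, so they stay on one scale.

    Log is applied when any group fails the raw normality screen, provided
    every value in every group is positive; groups too small or too uniform
    to screen are left undecided and do not trigger a transform.
    """
    needs = False
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            continue
        _, p = normality_check(g)
        if p < alpha:
            needs = True
    if needs and all(np.all(g > 0) for g in groups):
        return [np.log(g) for g in groups], "log"
    return groups, "none"


def compare_groups(
    a,
    b,
    names: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
    pooled: bool = False,
    transform: str = "auto",
) -> GroupComparison:
    """Two-by-two independent-means comparison.

    Welch's unequal-variance t-test by default; ``pooled=True`` uses the
    classical pooled-variance t-test (whose F = t² duality with one-way
    ANOVA holds exactly).  ``transform="auto"`` applies the log transform to
    both groups when either fails the normality screen (and all values are
    positive); reported means and SDs are always of the raw data.
    """
    xa, xb = _clean(a, "a"), _clean(b, "b")
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(f"each group needs n >= 2, got {len(xa)} and {len(xb)}")
    if transform == "auto":
        (wa, wb), flag = _joint_transform([xa, xb], alpha)
    elif transform == "log":
        if np.any(xa <= 0) or np.any(xb <= 0):
            raise ValueError("log transform requested on nonpositive values")
        (wa, wb), flag = (np.log(xa), np.log(xb)), "log"
    elif transform == "none":
        (wa, wb), flag = (xa, xb), "none"
    else:
        raise ValueError(f"transform must be 'auto', 'none' or 'log', got {transform!r}")
    if np.ptp(wa) == 0 and np.ptp(wb) == 0:
        # degenerate: no within-group variance; identical constants are "equal"
        t_stat, p = (0.0, 1.0) if wa.mean() == wb.mean() else (np.inf, 0.0)
    else:
        res = sps.ttest_ind(wa, wb, equal_var=pooled)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_names=names,
        n=(len(xa), len(xb)),
        means=(float(xa.mean()), float(xb.mean())),
        sds=(float(xa.std(ddof=1)), float(xb.std(ddof=1))),
        transform=flag,
        test="pooled_t" if pooled else "welch_t",
        statistic=t_stat,
        p_value=p,
        alpha=alpha,
    )


def one_way_anova(
    groups,
    names: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    transform: str = "auto",
) -> GroupComparison:
    """One-way fixed-effects ANOVA across two or more groups."""
    gs = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError(f"ANOVA needs at least 2 groups, got {len(gs)}")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        raise ValueError("all observations identical: ANOVA is undefined")
    if transform == "auto":
        ws, flag = _joint_transform(gs, alpha)
    elif transform == "log":
        if any(np.any(g <= 0) for g in gs):
            raise ValueError("log transform requested on nonpositive values")
        ws, flag = [np.log(g) for g in gs], "log"
    else:
        ws, flag = gs, "none"
    res = sps.f_oneway(*ws)
    if names is None:
        names = tuple(f"group{i}" for i in range(len(gs)))
    return GroupComparison(
        group_names=tuple(names),
        n=tuple(len(g) for g in gs),
        means=tuple(float(g.mean()) for g in gs),
        sds=tuple(float(g.std(ddof=1)) for g in gs),
        transform=flag,
        test="anova",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
    )


def pearson_correlation(x, y, variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson's correlation coefficient with a two-sided p-value."""
    xa, ya = _clean(x, "x"), _clean(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got {len(xa)}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for a constant input")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(
        variables=variables, n=len(xa), r=float(res.statistic), p_value=float(res.pvalue)
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
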