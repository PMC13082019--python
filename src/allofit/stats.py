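"""Replicate-level inferential statistics.

Two procedures cover the between-condition comparisons used throughout:
Welch's unequal-variance t-test for two-condition contrasts of fitted
values (e.g. log-cooperativity or gain-in-potency between receptor
variants), and one-way ANOVA followed by Dunnett's many-to-one multiple
comparisons against a control group (e.g. each mutant vs. wild type).
All tests are two-sided. Dunnett adjusted p-values come from the
equicorrelated multivariate-t max-statistic distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSamples", "WelchResult", "DunnettComparison", "DunnettResult",
           "welch_t", "anova_dunnett"]


@dataclass
class GroupSamples:
    """Named groups of replicate values with a designated control group."""

    values: dict[str, np.ndarray]
    control_label: str

    def __post_init__(self):
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        if self.control_label not in self.values:
            raise ValueError(f"control group {self.control_label!r} not present")
        for k, v in self.values.items():
            if v.size < 2:
                raise ValueError(f"group {k!r} needs >= 2 values")

    @property
    def treatment_labels(self) -> list[str]:
        return [k for k in self.values if k != self.control_label]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float  # Welch–Satterthwaite fractional degrees of freedom
    p: float  # two-sided


def welch_t(x, y) -> WelchResult:
    """Welch's two-sample t-test (two-sided, unequal variances).

    Degrees of freedom follow the Welch–Satterthwaite approximation.
    Both groups having zero variance is degenerate and rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise ValueError("zero variance in both groups: Welch's t undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    statistic: float
    p_adjusted: float  # two-sided, familywise over all comparisons


@dataclass
class DunnettResult:
    f_statistic: float
    f_pvalue: float
    comparisons: list[DunnettComparison] = field(default_factory=list)

    def p_adjusted(self, label: str) -> float:
        for c in self.comparisons:
            if c.label == label:
                return c.p_adjusted
        raise KeyError(label)


def anova_dunnett(groups: GroupSamples, seed: int | None = 0) -> DunnettResult:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs. the control.

    The grand F comes from the homoscedastic one-way ANOVA over all groups.
    Each treatment-vs-control adjusted p is two-sided under the
    multivariate-t max-statistic distribution; ``seed`` fixes the
    quasi-random integration so results are reproducible to ~1e-4.
    """
    labels = groups.treatment_labels
    if not labels:
        raise ValueError("need at least one treatment group besides the control")
    control = groups.values[groups.control_label]
    treatments = [groups.values[k] for k in labels]
    f_stat, f_p = sps.f_oneway(control, *treatments)
    res = sps.dunnett(*treatments, control=control, alternative="two-sided", rng=seed)
    comps = [
        DunnettComparison(label=k, statistic=float(s), p_adjusted=float(p))
        for k, s, p in zip(labels, res.statistic, res.pvalue)
    ]
    return DunnettResult(f_statistic=float(f_stat), f_pvalue=float(f_p),
                         comparisons=comps)
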