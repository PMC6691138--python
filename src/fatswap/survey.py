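"""Survey-weighted estimation under a stratified two-PSU design.

Means are weighted ratios; standard errors come from Taylor linearization
of the ratio estimator, with variance accumulated from between-PSU
variation within sampling strata. Subpopulations (e.g. dairy-fat
consumers) are estimated as domains: the full design is retained and
out-of-domain observations contribute zero to the score but still anchor
the PSU structure, which is what distinguishes a domain estimate's SE from
that of a naively filtered dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

#: Normal reference multiplier for 95% confidence intervals.
Z_95 = 1.959963984540054


class SinglePSUError(ValueError):
    """A stratum contributes only one PSU; between-PSU variance is
    undefined. Collapse strata or merge PSUs before estimating."""


@dataclass
class SurveyDesign:
    """Per-participant weight, stratum and PSU labels (aligned indexes)."""

    weight: pd.Series
    stratum: pd.Series
    psu: pd.Series

    def __post_init__(self):
        if (self.weight <= 0).any():
            raise ValueError("survey weights must be positive")
        self.validate()

    @classmethod
    def from_frame(cls, participants: pd.DataFrame) -> "SurveyDesign":
        return cls(
            weight=participants["survey_weight"],
            stratum=participants["stratum"],
            psu=participants["psu"],
        )

    def validate(self) -> None:
        psus = pd.DataFrame({"stratum": self.stratum, "psu": self.psu})
        counts = psus.groupby("stratum")["psu"].nunique()
        bad = counts[counts < 2]
        if len(bad):
            raise SinglePSUError(
                f"strata with a single PSU: {list(bad.index)}; "
                "collapse strata before variance estimation"
            )


@dataclass
class SurveyEstimate:
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def _linearized_variance(z: pd.Series, stratum: pd.Series, psu: pd.Series) -> float:
    """Between-PSU variance of a total from linearized scores ``z``.

    Var = sum_h n_h/(n_h-1) sum_j (t_hj - mean_h)^2 over PSU totals t_hj.
    """
    totals = pd.DataFrame({"z": z, "stratum": stratum, "psu": psu}).groupby(
        ["stratum", "psu"]
    )["z"].sum()
    var = 0.0
    for _, t in totals.groupby(level="stratum"):
        n_h = len(t)
        if n_h < 2:
            raise SinglePSUError(f"stratum {t.index[0][0]!r} has a single PSU")
        var += n_h / (n_h - 1) * float(((t - t.mean()) ** 2).sum())
    return var


def survey_mean_ci(
    values,
    design: SurveyDesign,
    domain: Optional[pd.Series] = None,
) -> SurveyEstimate:
    """Survey-weighted mean with linearized SE and 95% normal CI.

    ``domain``: optional boolean mask defining a subpopulation; the mean is
    computed over the domain while the variance keeps the full design.
    NaN values are excluded from the domain (and counted out of ``n``).
    """
    x = pd.Series(np.asarray(values, dtype=float), index=design.weight.index)
    d = pd.Series(True, index=x.index) if domain is None else domain.astype(bool)
    d = d & x.notna()
    if not d.any():
        raise ValueError("empty domain: no observations to estimate from")
    w = design.weight
    wd = w.where(d, 0.0)
    wsum = float(wd.sum())
    mean = float((wd * x.fillna(0.0)).sum() / wsum)
    # linearized score of the ratio estimator; zero outside the domain
    z = wd * (x.fillna(0.0) - mean) / wsum
    var = _linearized_variance(z, design.stratum, design.psu)
    se = float(np.sqrt(var))
    return SurveyEstimate(
        mean=mean,
        se=se,
        ci_low=mean - Z_95 * se,
        ci_high=mean + Z_95 * se,
        n=int(d.sum()),
    )


def share_above_threshold(
    values,
    design: SurveyDesign,
    threshold: float,
    domain: Optional[pd.Series] = None,
) -> SurveyEstimate:
    """Weighted proportion of persons with value >= threshold."""
    x = pd.Series(np.asarray(values, dtype=float), index=design.weight.index)
    indicator = (x >= threshold).astype(float).where(x.notna())
    return survey_mean_ci(indicator, design, domain=domain)


@dataclass
class RelativeChangeTest:
    relative_change: float
    p_value: float
    significant: bool


def relative_change_test(
    observed: SurveyEstimate,
    modeled: SurveyEstimate,
    margin: float = 0.10,
    alpha: float = 0.05,
) -> RelativeChangeTest:
    """Flag a modeled-vs-observed difference as meaningful.

    Significant only when (a) the relative change strictly exceeds
    ``margin`` (tiny-but-precise differences are never flagged) and (b) a
    Wald test that the absolute difference exceeds margin x |observed mean|
    rejects at ``alpha`` (normal reference, combined SE). An observed mean
    of zero leaves the relative change undefined: not evaluable, returned
    as NaN / not significant.
    """
    if observed.mean == 0:
        return RelativeChangeTest(np.nan, np.nan, False)
    diff = abs(modeled.mean - observed.mean)
    rel = diff / abs(observed.mean)
    se = float(np.hypot(observed.se, modeled.se))
    excess = diff - margin * abs(observed.mean)
    if se == 0:
        p = 0.0 if excess > 0 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(excess) / se))
    significant = rel > margin and excess > 0 and p < alpha
    return RelativeChangeTest(rel, p, significant)
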