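"""Random-effects combination of donor-level confidence distributions.

Each donor CD is reduced to a point estimate (its median m_i) and an
effective standard error s_i = (95% interval width) / 3.92.  Between-
donor heterogeneity tau^2 is estimated by the DerSimonian-Laird moment
estimator; donors are then pooled with inverse-variance weights
w_i = 1 / (s_i^2 + tau^2), giving a normal summary CD with mean
sum(w_i m_i)/sum(w_i) and SE (sum w_i)^(-1/2).  This is a concrete,
standard member of the confidence-distribution-combining family; the
model choice is recorded in the summary metadata.

Ratio statistics (obs/exp) are combined on the log scale and the
summary is back-transformed, because their support is positive and
their intervals asymmetric.

Two CD-based two-tailed tests are provided: a between-group test
(evaluate each group's mean under the other group's summary CD, take
the larger one-tailed p, double it) and a null-divergence test
(2 x the smaller tail of the summary CD at the null value; Q null = 0,
obs/exp null = 1).  The doubling can exceed 1, so p-values are capped
at 1.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cd import ConfidenceDistribution, normal_cd

__all__ = [
    "DonorEstimate",
    "MetaSummary",
    "combine_cds",
    "dersimonian_laird_tau2",
    "between_group_p",
    "null_divergence_p",
]

#: width of a central 95% normal interval in SE units
_Z95_WIDTH = 3.92


@dataclass(frozen=True)
class DonorEstimate:
    """One donor's contribution to a meta-analysis (reporting scale)."""

    donor_id: str
    estimate: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class MetaSummary:
    """Group-level combined CD with point estimate and heterogeneity.

    ``mean``, ``ci_lower``, ``ci_upper`` and the donor estimates are on
    the reporting (natural) scale.  ``summary_cd`` and
    ``internal_mean`` live on the combination scale (log scale when
    ``log_scale`` is set), which is where tail probabilities are
    evaluated.
    """

    group: str
    statistic: str
    mean: float
    ci_lower: float
    ci_upper: float
    se: float
    tau2: float
    donor_estimates: tuple[DonorEstimate, ...]
    summary_cd: ConfidenceDistribution
    model: str = "random_effects"
    log_scale: bool = False
    internal_mean: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.mean <= self.ci_upper:
            raise ValueError("summary mean must lie inside its interval")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")


def dersimonian_laird_tau2(
    means: np.ndarray, ses: np.ndarray
) -> float:
    """DerSimonian-Laird moment estimator of between-donor variance."""
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = means.size
    if k < 2:
        return 0.0
    v = 1.0 / ses**2
    mean_fixed = float(np.sum(v * means) / np.sum(v))
    q_stat = float(np.sum(v * (means - mean_fixed) ** 2))
    denom = float(np.sum(v) - np.sum(v**2) / np.sum(v))
    if denom <= 0:
        return 0.0
    return max(0.0, (q_stat - (k - 1)) / denom)


def _reduce_cd(
    cd: ConfidenceDistribution, log_scale: bool
) -> tuple[float, float, tuple[float, float, float]]:
    """(m_i, s_i, natural-scale (median, lo, hi)) for one donor CD."""
    med = cd.median
    lo, hi = cd.interval(0.95)
    natural = (med, lo, hi)
    if log_scale:
        # Sparse ratio bootstraps can put resamples at 0; floor
        # nonpositive quantiles at half the smallest positive grid value
        # so the log transform stays finite.
        positive = cd.grid[cd.grid > 0]
        if positive.size == 0:
            raise ValueError(
                "cannot log-combine a CD whose support is entirely nonpositive"
            )
        floor = 0.5 * float(positive.min())
        med, lo, hi = (max(x, floor) for x in (med, lo, hi))
        med, lo, hi = math.log(med), math.log(lo), math.log(hi)
    s = (hi - lo) / _Z95_WIDTH
    return med, s, natural


def combine_cds(
    cds: list[ConfidenceDistribution],
    model: str = "random_effects",
    labels: list[str] | None = None,
    group: str = "",
    statistic: str = "",
    log_scale: bool = False,
) -> MetaSummary:
    """Pool donor CDs into a group summary CD.

    ``model`` is ``random_effects`` (DL tau^2) or ``fixed`` (tau^2 = 0).
    Degenerate donor CDs (zero-width intervals) get s_i floored at half
    the smallest nonzero s_i in the group to avoid infinite weight.
    """
    if model not in ("random_effects", "fixed"):
        raise ValueError(f"unknown model {model!r}")
    if not cds:
        raise ValueError("combine_cds requires at least one donor CD")
    if labels is None:
        labels = [f"donor_{i + 1}" for i in range(len(cds))]
    if len(labels) != len(cds):
        raise ValueError("labels and cds must have matching length")

    reduced = [_reduce_cd(cd, log_scale) for cd in cds]
    m = np.array([r[0] for r in reduced])
    s = np.array([r[1] for r in reduced])

    nonzero = s[s > 0]
    if nonzero.size == 0:
        raise ValueError(
            "all donor CDs are degenerate (zero-width intervals); "
            "no spread to combine"
        )
    s = np.where(s > 0, s, 0.5 * nonzero.min())

    tau2 = dersimonian_laird_tau2(m, s) if model == "random_effects" else 0.0
    w = 1.0 / (s**2 + tau2)
    mean_internal = float(np.sum(w * m) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    summary = normal_cd(mean_internal, se)

    lo_i, hi_i = mean_internal - 1.959963984540054 * se, \
        mean_internal + 1.959963984540054 * se
    if log_scale:
        mean_r, lo_r, hi_r = (math.exp(x) for x in (mean_internal, lo_i, hi_i))
    else:
        mean_r, lo_r, hi_r = mean_internal, lo_i, hi_i

    donors = tuple(
        DonorEstimate(lbl, *natural)
        for lbl, (_, _, natural) in zip(labels, reduced)
    )
    return MetaSummary(
        group=group,
        statistic=statistic,
        mean=mean_r,
        ci_lower=lo_r,
        ci_upper=hi_r,
        se=se,
        tau2=float(tau2),
        donor_estimates=donors,
        summary_cd=summary,
        model=model,
        log_scale=log_scale,
        internal_mean=mean_internal,
    )


def _one_tailed(cd: ConfidenceDistribution, value: float) -> float:
    h = cd.probability_at(value)
    return min(h, 1.0 - h)


def between_group_p(summary_a: MetaSummary, summary_b: MetaSummary) -> float:
    """Two-tailed CD-based p for a difference between two group summaries.

    Evaluates each group's meta-analytical mean under the other group's
    summary CD, takes the greater of the two one-tailed p-values and
    doubles it (capped at 1).  Symmetric in its arguments.
    """
    if summary_a.statistic != summary_b.statistic:
        raise ValueError(
            f"statistic mismatch: {summary_a.statistic!r} vs "
            f"{summary_b.statistic!r}"
        )
    if summary_a.log_scale != summary_b.log_scale:
        raise ValueError("summaries combined on different scales")
    p1 = _one_tailed(summary_a.summary_cd, summary_b.internal_mean)
    p2 = _one_tailed(summary_b.summary_cd, summary_a.internal_mean)
    return min(1.0, 2.0 * max(p1, p2))


def null_divergence_p(summary: MetaSummary, null_value: float) -> float:
    """Two-tailed CD-based p for divergence of a group summary from a
    null value (Q null = 0; obs/exp null = 1)."""
    if not math.isfinite(null_value):
        raise ValueError("null value must be finite")
    value = null_value
    if summary.log_scale:
        if null_value <= 0:
            raise ValueError("null value must be positive on the log scale")
        value = math.log(null_value)
    return min(1.0, 2.0 * _one_tailed(summary.summary_cd, value))
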