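"""Chart-review validation machinery and diagnostic performance.

Implements the validation design used to check EHR-derived outcome flags
against manual review: stratified random sampling of flagged-positive and
flagged-negative charts, percent agreement between two reviewers, third-
reviewer adjudication of disagreements, confusion-matrix construction,
and sensitivity/specificity/PPV/NPV with exact (Clopper-Pearson) binomial
confidence intervals.

The Clopper-Pearson interval inverts the binomial tails via beta
quantiles: for ``k`` successes in ``n`` trials at level ``1 - alpha``,

    lower = BetaInv(alpha/2; k, n-k+1)        (0 when k = 0)
    upper = BetaInv(1-alpha/2; k+1, n-k)      (1 when k = n)

Exact intervals are conservative: their coverage is at least the nominal
level for every true proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ReviewSample",
    "ConfusionMatrix",
    "MetricEstimate",
    "DiagnosticPerformance",
    "sample_for_review",
    "percent_agreement",
    "adjudicate",
    "confusion_from_review",
    "confusion_from_predictive_values",
    "clopper_pearson",
    "diagnostic_performance",
]


@dataclass(frozen=True)
class ReviewSample:
    outcome: str
    positive_ids: tuple[Hashable, ...]
    negative_ids: tuple[Hashable, ...]
    seed: int

    @property
    def ids(self) -> tuple[Hashable, ...]:
        return self.positive_ids + self.negative_ids


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact CI; ``defined`` is false when the
    denominator was zero (estimate and CI are then NaN)."""

    estimate: float
    ci_low: float
    ci_high: float
    defined: bool = True

    def contains(self, p: float) -> bool:
        return self.defined and self.ci_low <= p <= self.ci_high


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    level: float = 0.95


def sample_for_review(
    flags: Mapping[Hashable, bool],
    n_pos: int,
    n_neg: int,
    seed: int,
    outcome: str = "",
) -> ReviewSample:
    """Uniform without-replacement sample from each flag stratum.

    Deterministic given ``seed``; raises if a stratum is smaller than the
    requested sample, reporting the stratum sizes.
    """
    pos = sorted((k for k, v in flags.items() if v), key=str)
    neg = sorted((k for k, v in flags.items() if not v), key=str)
    if len(pos) < n_pos or len(neg) < n_neg:
        raise ValueError(
            f"stratum too small: need {n_pos}+/{n_neg}- but have "
            f"{len(pos)}+/{len(neg)}-"
        )
    rng = np.random.default_rng(seed)
    take_pos = tuple(np.array(pos, dtype=object)[
        rng.choice(len(pos), size=n_pos, replace=False)])
    take_neg = tuple(np.array(neg, dtype=object)[
        rng.choice(len(neg), size=n_neg, replace=False)])
    return ReviewSample(outcome=outcome, positive_ids=take_pos,
                        negative_ids=take_neg, seed=seed)


def percent_agreement(
    ratings_a: Mapping[Hashable, Hashable], ratings_b: Mapping[Hashable, Hashable]
) -> float:
    """Fraction of ids with equal labels; id sets must match exactly."""
    if set(ratings_a) != set(ratings_b):
        raise ValueError("ratings cover different id sets")
    if not ratings_a:
        raise ValueError("cannot compute agreement over zero ids")
    agree = sum(ratings_a[k] == ratings_b[k] for k in ratings_a)
    return agree / len(ratings_a)


def adjudicate(
    ratings_a: Mapping[Hashable, Hashable],
    ratings_b: Mapping[Hashable, Hashable],
    ratings_c: Mapping[Hashable, Hashable],
) -> dict[Hashable, Hashable]:
    """Consensus labels: a's label where a and b agree, else c's label.

    The third reviewer must cover every disagreement.
    """
    if set(ratings_a) != set(ratings_b):
        raise ValueError("ratings cover different id sets")
    out: dict[Hashable, Hashable] = {}
    for k in ratings_a:
        if ratings_a[k] == ratings_b[k]:
            out[k] = ratings_a[k]
        elif k in ratings_c:
            out[k] = ratings_c[k]
        else:
            raise ValueError(f"no adjudication for disagreement on id {k!r}")
    return out


def confusion_from_review(
    flags: Mapping[Hashable, bool], adjudicated: Mapping[Hashable, bool]
) -> ConfusionMatrix:
    """Cross-tabulate EHR flags against adjudicated review labels."""
    missing = set(flags) - set(adjudicated)
    if missing:
        raise ValueError(f"labels missing for sampled ids: {sorted(missing, key=str)[:5]}")
    tp = fp = fn = tn = 0
    for k, flag in flags.items():
        truth = bool(adjudicated[k])
        if flag and truth:
            tp += 1
        elif flag and not truth:
            fp += 1
        elif not flag and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_from_predictive_values(
    n_flagged_pos: int, n_flagged_neg: int, ppv: float, npv: float,
    tol: float = 1e-6,
) -> ConfusionMatrix:
    """Back-derive a confusion matrix from stratum sizes and PPV/NPV.

    ``ppv * n_flagged_pos`` and ``npv * n_flagged_neg`` must be integral
    (to within ``tol``) — refusing non-integral products prevents silently
    inventing chart counts.
    """
    tp_f = ppv * n_flagged_pos
    tn_f = npv * n_flagged_neg
    tp, tn = round(tp_f), round(tn_f)
    if abs(tp_f - tp) > tol or abs(tn_f - tn) > tol:
        raise ValueError(
            f"predictive values do not give integral counts: "
            f"ppv*n_pos={tp_f}, npv*n_neg={tn_f}"
        )
    return ConfusionMatrix(tp=tp, fp=n_flagged_pos - tp,
                           fn=n_flagged_neg - tn, tn=tn)


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial CI by beta-quantile tail inversion."""
    if trials < 1:
        raise ValueError("clopper_pearson undefined for zero trials")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def _metric(successes: int, trials: int, level: float) -> MetricEstimate:
    if trials == 0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"),
                              defined=False)
    lo, hi = clopper_pearson(successes, trials, level)
    return MetricEstimate(successes / trials, lo, hi, defined=True)


def diagnostic_performance(
    cm: ConfusionMatrix, level: float = 0.95
) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV and NPV with exact CIs; a metric with
    a zero denominator is flagged undefined rather than raising."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return DiagnosticPerformance(
        sensitivity=_metric(cm.tp, cm.tp + cm.fn, level),
        specificity=_metric(cm.tn, cm.tn + cm.fp, level),
        ppv=_metric(cm.tp, cm.tp + cm.fp, level),
        npv=_metric(cm.tn, cm.tn + cm.fn, level),
        level=level,
    )
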