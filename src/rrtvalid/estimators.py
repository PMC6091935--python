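"""Prevalence estimation under design-induced misclassification.

For a sample of binary responses ``Y`` collected with a questioning design
whose misclassification pair ``(p11, p10)`` is known, the prevalence of
the sensitive answer is estimated by inverting the mixture

    Pr(Y = 1) = p11 * pi + p10 * (1 - pi)

at the sample mean:  pi_hat = (Ybar - p10) / (p11 - p10).  Since pi_hat is
a linear transform of Ybar,

    V(pi_hat) = V(Ybar) / (p11 - p10)^2,   V(Ybar) = Ybar (1 - Ybar) / (n - 1),

and 95% confidence intervals are Wald intervals pi_hat +/- 1.96 se.

Estimates outside [0, 1] are deliberately *not* truncated: a significantly
negative estimate is a diagnostic for non-compliance with the design's
instructions (forced-response designs are prone to this).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .designs import MisclassPair, RRTDesign, misclassification_probs

__all__ = [
    "Z_95",
    "ResponseSample",
    "PrevalenceEstimate",
    "PrevalenceModel",
    "PrevalenceResults",
    "estimate_prevalence",
    "conditional_prevalence",
    "arm_difference",
    "difference_pvalue",
]

#: normal critical value used for all 95% Wald intervals
Z_95 = 1.96


def _resolve_pair(design) -> MisclassPair:
    if isinstance(design, MisclassPair):
        return design
    if isinstance(design, RRTDesign):
        return misclassification_probs(design)
    raise TypeError(f"expected RRTDesign or MisclassPair, got {type(design).__name__}")


def _as_binary(responses) -> np.ndarray:
    y = np.asarray(responses)
    if y.size == 0:
        raise ValueError("responses must be nonempty")
    y = y.astype(float)
    if np.any(np.isnan(y)):
        raise ValueError("responses contain missing values; drop them first")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary (0/1)")
    return y


@dataclass(frozen=True)
class ResponseSample:
    """Binary observed responses for one sensitive item under one design.

    ``responses`` are coded so that 1 is the response that loads on the
    sensitive answer ("yes", or "the same" for the crosswise model), after
    any reverse-coding.  ``design`` may be an :class:`RRTDesign` or a
    pre-resolved :class:`MisclassPair` (useful when respondents faced
    heterogeneous unrelated questions and the arm-average pair is used).
    """

    responses: np.ndarray
    design: RRTDesign | MisclassPair
    item: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", _as_binary(self.responses))
        _resolve_pair(self.design)

    @property
    def pair(self) -> MisclassPair:
        return _resolve_pair(self.design)

    @property
    def n(self) -> int:
        return int(self.responses.size)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point estimate of Pr(Y* = 1) with Wald uncertainty."""

    pi_hat: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    item: str | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if not self.ci_low <= self.pi_hat <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


class PrevalenceModel:
    """Misclassification-corrected prevalence model for one sample.

    Parameters
    ----------
    responses : array-like of 0/1
        Observed responses, recoded so 1 loads on the sensitive answer.
    design : RRTDesign or MisclassPair
        The questioning design (source of ``p11``, ``p10``).
    item : str, optional
        Label of the sensitive item, carried through to results.
    """

    def __init__(self, responses, design, item: str | None = None):
        self.sample = (
            responses
            if isinstance(responses, ResponseSample)
            else ResponseSample(responses, design, item)
        )

    @classmethod
    def from_sample(cls, sample: ResponseSample) -> "PrevalenceModel":
        model = cls.__new__(cls)
        model.sample = sample
        return model

    def fit(self) -> "PrevalenceResults":
        y = self.sample.responses
        n = y.size
        if n < 2:
            raise ValueError(f"need at least 2 responses, got {n}")
        pair = self.sample.pair
        ybar = float(y.mean())
        pi_hat = pair.invert(ybar)
        var = ybar * (1.0 - ybar) / (n - 1) / pair.slope**2
        se = math.sqrt(var)
        return PrevalenceResults(
            pi_hat=float(pi_hat),
            se=se,
            ci_low=float(pi_hat - Z_95 * se),
            ci_high=float(pi_hat + Z_95 * se),
            n=int(n),
            item=self.sample.item,
            ybar=ybar,
            pair=pair,
        )


@dataclass(frozen=True)
class PrevalenceResults(PrevalenceEstimate):
    """Fitted prevalence with the observed mean and design pair attached."""

    ybar: float = float("nan")
    pair: MisclassPair | None = None

    @property
    def bse(self) -> float:  # statsmodels-flavoured alias
        return self.se

    def summary(self) -> str:
        item = self.item or "sensitive item"
        lines = [
            f"Prevalence estimate: {item}",
            "-" * 46,
            f"  n                  {self.n:>10d}",
            f"  observed mean      {self.ybar:>10.4f}",
        ]
        if self.pair is not None:
            lines.append(f"  p11, p10           {self.pair.p11:>10.4f} {self.pair.p10:.4f}")
        lines += [
            f"  pi_hat             {self.pi_hat:>10.4f}",
            f"  std. err.          {self.se:>10.4f}",
            f"  95% CI             [{self.ci_low:.4f}, {self.ci_high:.4f}]",
        ]
        return "\n".join(lines)


def estimate_prevalence(sample: ResponseSample) -> PrevalenceResults:
    """Invert the forward mixture at the sample mean of one arm."""
    return PrevalenceModel.from_sample(sample).fit()


def conditional_prevalence(sample: ResponseSample, mask) -> PrevalenceResults:
    """Prevalence estimate on the subsample selected by a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sample.responses.shape:
        raise ValueError(
            f"mask length {mask.size} does not match responses {sample.n}"
        )
    if not mask.any():
        raise ValueError("mask selects an empty subsample")
    sub = ResponseSample(sample.responses[mask], sample.design, sample.item)
    return estimate_prevalence(sub)


def arm_difference(a: PrevalenceEstimate, b: PrevalenceEstimate) -> PrevalenceEstimate:
    """Difference a - b between two independent arms, with Wald CI."""
    diff = a.pi_hat - b.pi_hat
    se = math.hypot(a.se, b.se)
    item = a.item if a.item == b.item else None
    return PrevalenceEstimate(
        pi_hat=diff,
        se=se,
        ci_low=diff - Z_95 * se,
        ci_high=diff + Z_95 * se,
        n=a.n + b.n,
        item=item,
    )


def difference_pvalue(estimate: PrevalenceEstimate) -> float:
    """Two-sided Wald z-test p-value for H0: the estimated quantity is 0."""
    from scipy.stats import norm

    if estimate.se == 0:
        return 0.0 if estimate.pi_hat != 0 else 1.0
    return float(2.0 * norm.sf(abs(estimate.pi_hat) / estimate.se))
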