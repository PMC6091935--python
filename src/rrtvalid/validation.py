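"""Individual-level validation: true/false-positive and correct-classification rates.

Respondents played a dice game in which they could cheat by claiming an
unearned win, and were later asked (with one of the questioning designs)
whether they cheated.  Writing ``X*`` for a true win, ``X`` for a claimed
win, ``Y*`` for the true answer to the cheating question and ``Y`` for the
observed response, the quantities of interest are

* TPR — proportion of cheaters (``X != X*``) whose corrected response
  admits the cheating,
* FPR — proportion of non-cheaters (``X == X*``) who falsely "admit",
* CCR — overall proportion correctly classified,
  ``CCR = TPR Pr(X != X*) + (1 - FPR) Pr(X = X*)``.

Two regimes are supported:

**Observed truth** (the roll-a-six game): ``X*`` is recorded, so TPR and
FPR are misclassification-corrected conditional prevalences in the cheater
and non-cheater groups.

**Latent truth** (the prediction game): ``X*`` is private, but the win
probability is 1/6 by design.  Under assumption A1 (no false losers:
``X* = 1`` implies ``X = 1``) the cheating rate is identified as
``Pr(X = 1) - 1/6``; adding A2 (true winners and true losers share the
same false positive rate) identifies

    FPR = inv(Pr(Y=1 | X=0)),
    TPR = [Pr(X=1) inv(Pr(Y=1|X=1)) - (1/6) inv(Pr(Y=1|X=0))] / (Pr(X=1) - 1/6),

where ``inv(q) = (q - p10) / (p11 - p10)``.  The alternative assumption
A2' instead sets the false positive rate of true winners to zero, which
drops the winner joint term from the TPR numerator and reweights the
overall FPR onto true losers only:
``FPR' = Pr(X=0) inv(Pr(Y=1|X=0)) / (Pr(X=0) + 1/6)``.

Standard errors propagate the joint sampling covariance of the component
means through the identification formulas with analytic gradients (delta
method); a seeded nonparametric bootstrap is available as a cross-check.
Negative FPR estimates (possible under inversion) are truncated to zero
*only* inside the CCR; the reported ``fpr`` keeps the raw value together
with an ``fpr_truncated`` flag, preserving its diagnostic use.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .designs import MisclassPair, RRTDesign
from .estimators import _as_binary, _resolve_pair

__all__ = [
    "ValidationAssumption",
    "GameOutcomeSample",
    "ValidationResult",
    "BootstrapSE",
    "DiceGameValidationModel",
    "validate_observed_truth",
    "validate_latent_truth",
    "joint_mean_covariance",
    "delta_method_se",
    "bootstrap_se",
]

_STATS = ("tpr", "fpr", "ccr", "cheat_rate")


class ValidationAssumption(str, enum.Enum):
    """Identification assumptions for the latent-truth (prediction) game."""

    A1_A2 = "A1_A2"
    A1_A2PRIME = "A1_A2prime"


@dataclass(frozen=True)
class GameOutcomeSample:
    """Responses, win claims and (optionally) true wins for one arm.

    ``responses`` are recoded so 1 = admits cheating; ``claim`` is 1 for a
    claimed win; ``truth`` (1 = actually won) is present only for the
    observed-truth game.  ``win_prob`` is the design probability of a true
    win (1/6 for both dice games).
    """

    responses: np.ndarray
    claim: np.ndarray
    design: RRTDesign | MisclassPair
    truth: np.ndarray | None = None
    win_prob: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", _as_binary(self.responses))
        object.__setattr__(self, "claim", _as_binary(self.claim))
        if self.claim.shape != self.responses.shape:
            raise ValueError("claim and responses must have equal length")
        if self.truth is not None:
            object.__setattr__(self, "truth", _as_binary(self.truth))
            if self.truth.shape != self.responses.shape:
                raise ValueError("truth and responses must have equal length")
            n_false_losers = int(np.sum((self.claim == 0) & (self.truth == 1)))
            if n_false_losers:
                raise ValueError(
                    f"{n_false_losers} false loser(s) (won but did not claim); "
                    "exclude them before validation"
                )
        if not 0.0 < self.win_prob < 1.0:
            raise ValueError("win_prob must lie in (0, 1)")
        _resolve_pair(self.design)

    @property
    def pair(self) -> MisclassPair:
        return _resolve_pair(self.design)

    @property
    def n(self) -> int:
        return int(self.responses.size)


@dataclass(frozen=True)
class ValidationResult:
    """TPR / FPR / CCR estimates with standard errors and provenance."""

    tpr: float
    fpr: float
    ccr: float
    cheat_rate: float
    se_tpr: float
    se_fpr: float
    se_ccr: float
    se_cheat_rate: float
    fpr_truncated: bool
    assumption: str
    variance_method: str
    n: int
    n_boot: int | None = None
    n_boot_redraws: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "ccr": self.ccr,
            "cheat_rate": self.cheat_rate,
            "se_tpr": self.se_tpr,
            "se_fpr": self.se_fpr,
            "se_ccr": self.se_ccr,
            "se_cheat_rate": self.se_cheat_rate,
        }

    def summary(self) -> str:
        head = (
            f"Individual-level validation  (n={self.n}, "
            f"assumption={self.assumption}, variance={self.variance_method})"
        )
        lines = [head, "-" * len(head)]
        for name, est, se in (
            ("cheat rate", self.cheat_rate, self.se_cheat_rate),
            ("TPR", self.tpr, self.se_tpr),
            ("FPR", self.fpr, self.se_fpr),
            ("CCR", self.ccr, self.se_ccr),
        ):
            lines.append(f"  {name:<11}{est:>9.4f}   (se {se:.4f})")
        if self.fpr_truncated:
            lines.append("  [negative FPR truncated to 0 inside the CCR]")
        return "\n".join(lines)


@dataclass(frozen=True)
class BootstrapSE:
    """Bootstrap standard errors for the four validation statistics."""

    se_tpr: float
    se_fpr: float
    se_ccr: float
    se_cheat_rate: float
    n_boot: int
    n_redraws: int


def joint_mean_covariance(components) -> tuple[np.ndarray, np.ndarray]:
    """Joint means and covariance-of-means of per-respondent components.

    ``components`` is an (n, p) matrix of respondent-level variables; the
    returned covariance is the sample covariance (ddof=1) divided by n,
    i.e. the estimated covariance of the vector of sample means.  For a
    single binary column this reproduces ybar(1-ybar)/(n-1).
    """
    w = np.asarray(components, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 respondents for a covariance")
    means = w.mean(axis=0)
    cov = np.atleast_2d(np.cov(w, rowvar=False, ddof=1)) / n
    return means, cov


def delta_method_se(cov: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """First-order (delta-method) standard errors.

    ``gradients`` has one row per statistic, holding the analytic gradient
    of that statistic with respect to the component means whose covariance
    is ``cov``.
    """
    G = np.atleast_2d(np.asarray(gradients, dtype=float))
    variances = np.einsum("ij,jk,ik->i", G, np.asarray(cov, dtype=float), G)
    if np.any(variances < -1e-12):
        raise ValueError("negative variance from delta propagation")
    return np.sqrt(np.clip(variances, 0.0, None))


# ---------------------------------------------------------------------------
# point estimates and analytic gradients
#
# Both regimes reduce every statistic to a smooth function of three means:
#   observed truth:  m = (c, a, b) with c=1{X!=X*}, a=Y*c, b=Y*(1-c)
#   latent truth:    m = (x, d, e) with x=X,        d=Y*x, e=Y*(1-x)
# ---------------------------------------------------------------------------


def _observed_stats(m, pair: MisclassPair):
    c, a, b = m
    r, p10 = pair.slope, pair.p10
    if c <= 0.0:
        raise ValueError("empty cheater group (no respondents with X != X*)")
    if c >= 1.0:
        raise ValueError("empty non-cheater group (no respondents with X == X*)")
    tpr = (a / c - p10) / r
    fpr = (b / (1.0 - c) - p10) / r
    g_tpr = np.array([-a / (r * c**2), 1.0 / (r * c), 0.0])
    g_fpr = np.array([b / (r * (1.0 - c) ** 2), 0.0, 1.0 / (r * (1.0 - c))])
    truncated = fpr < 0.0
    fpr_c = 0.0 if truncated else fpr
    g_fpr_c = np.zeros(3) if truncated else g_fpr
    ccr = tpr * c + (1.0 - fpr_c) * (1.0 - c)
    g_ccr = (
        c * g_tpr
        + np.array([tpr, 0.0, 0.0])
        - np.array([1.0 - fpr_c, 0.0, 0.0])
        - (1.0 - c) * g_fpr_c
    )
    values = np.array([tpr, fpr, ccr, c])
    grads = np.vstack([g_tpr, g_fpr, g_ccr, [1.0, 0.0, 0.0]])
    return values, grads, truncated


def _latent_stats(m, pair: MisclassPair, win_prob: float, prime: bool):
    x, d, e = m
    r, p10 = pair.slope, pair.p10
    k = win_prob
    if x >= 1.0:
        raise ValueError("empty X = 0 group (every respondent claimed a win)")
    denom = x - k
    if denom <= 0.0:
        raise ValueError(
            "no identifiable cheating mass: Pr(X=1) estimate "
            f"{x:.4f} <= win probability {k:.4f}"
        )
    # loser-conditional inverted prevalence and its gradient
    fpr_loser = (e / (1.0 - x) - p10) / r
    g_fpr_loser = np.array([e / (r * (1.0 - x) ** 2), 0.0, 1.0 / (r * (1.0 - x))])
    # TPR numerator: Pr(Y*=1 and X != X*)
    if prime:
        num = (d - x * p10) / r
        g_num = np.array([-p10 / r, 1.0 / r, 0.0])
    else:
        num = (d - x * p10) / r - k * fpr_loser
        g_num = np.array([-p10 / r, 1.0 / r, 0.0]) - k * g_fpr_loser
    tpr = num / denom
    g_tpr = (g_num * denom - num * np.array([1.0, 0.0, 0.0])) / denom**2
    if prime:
        # overall FPR with winner FPR fixed at 0: true losers reweighted
        u = 1.0 - x + k
        M = (e - (1.0 - x) * p10) / r
        g_M = np.array([p10 / r, 0.0, 1.0 / r])
        fpr = M / u
        g_fpr = (g_M * u + M * np.array([1.0, 0.0, 0.0])) / u**2
    else:
        fpr = fpr_loser
        g_fpr = g_fpr_loser
    truncated = fpr < 0.0
    fpr_c = 0.0 if truncated else fpr
    g_fpr_c = np.zeros(3) if truncated else g_fpr
    u = 1.0 - x + k  # Pr(X = X*) under A1
    ccr = num + (1.0 - fpr_c) * u
    g_ccr = g_num - np.array([1.0 - fpr_c, 0.0, 0.0]) - u * g_fpr_c
    values = np.array([tpr, fpr, ccr, denom])
    grads = np.vstack([g_tpr, g_fpr, g_ccr, [1.0, 0.0, 0.0]])
    return values, grads, truncated


def _components(sample: GameOutcomeSample, observed: bool) -> np.ndarray:
    y = sample.responses
    if observed:
        group = (sample.claim != sample.truth).astype(float)
    else:
        group = sample.claim.astype(float)
    return np.column_stack([group, y * group, y * (1.0 - group)])


class DiceGameValidationModel:
    """Validation model for one dice game x technique arm.

    If ``truth`` is supplied the observed-truth identification is used;
    otherwise an identification assumption (A1+A2 by default, or A1+A2')
    is required.
    """

    def __init__(
        self,
        responses,
        claim,
        design,
        truth=None,
        win_prob: float = 1.0 / 6.0,
    ):
        self.sample = GameOutcomeSample(
            responses=np.asarray(responses),
            claim=np.asarray(claim),
            design=design,
            truth=None if truth is None else np.asarray(truth),
            win_prob=win_prob,
        )

    @classmethod
    def from_sample(cls, sample: GameOutcomeSample) -> "DiceGameValidationModel":
        model = cls.__new__(cls)
        model.sample = sample
        return model

    # -- point estimation ---------------------------------------------------

    def _estimate(self, m, assumption):
        if assumption is None:
            if self.sample.truth is None:
                raise ValueError(
                    "latent truth requires an identification assumption "
                    "(A1_A2 or A1_A2prime)"
                )
            return _observed_stats(m, self.sample.pair)
        prime = ValidationAssumption(assumption) is ValidationAssumption.A1_A2PRIME
        return _latent_stats(m, self.sample.pair, self.sample.win_prob, prime)

    def fit(
        self,
        assumption: str | ValidationAssumption | None = None,
        variance: str = "delta",
        n_boot: int = 2000,
        seed: int | None = None,
    ) -> ValidationResult:
        sample = self.sample
        observed = assumption is None
        if observed and sample.truth is None:
            raise ValueError(
                "no truth vector: supply one or choose an identification assumption"
            )
        w = _components(sample, observed)
        means, cov = joint_mean_covariance(w)
        values, grads, truncated = self._estimate(means, assumption)
        if variance == "delta":
            ses = delta_method_se(cov, grads)
            n_boot_used: int | None = None
            redraws = 0
        elif variance == "bootstrap":
            boot = bootstrap_se(sample, assumption=assumption, B=n_boot, seed=seed)
            ses = np.array(
                [boot.se_tpr, boot.se_fpr, boot.se_ccr, boot.se_cheat_rate]
            )
            n_boot_used = boot.n_boot
            redraws = boot.n_redraws
        else:
            raise ValueError(f"unknown variance method {variance!r}")
        name = (
            "observed_truth"
            if observed
            else ValidationAssumption(assumption).value
        )
        return ValidationResult(
            tpr=float(values[0]),
            fpr=float(values[1]),
            ccr=float(values[2]),
            cheat_rate=float(values[3]),
            se_tpr=float(ses[0]),
            se_fpr=float(ses[1]),
            se_ccr=float(ses[2]),
            se_cheat_rate=float(ses[3]),
            fpr_truncated=bool(truncated),
            assumption=name,
            variance_method=variance,
            n=sample.n,
            n_boot=n_boot_used,
            n_boot_redraws=redraws,
        )


def validate_observed_truth(
    sample: GameOutcomeSample, variance: str = "delta", **kwargs
) -> ValidationResult:
    """TPR/FPR/CCR with individually observed cheating (roll-a-six game)."""
    if sample.truth is None:
        raise ValueError("observed-truth validation requires a truth vector")
    model = DiceGameValidationModel.from_sample(sample)
    return model.fit(assumption=None, variance=variance, **kwargs)


def validate_latent_truth(
    sample: GameOutcomeSample,
    assumption: str | ValidationAssumption = ValidationAssumption.A1_A2,
    variance: str = "delta",
    **kwargs,
) -> ValidationResult:
    """TPR/FPR/CCR with latent cheating (prediction game) under A1+A2(')."""
    model = DiceGameValidationModel.from_sample(sample)
    return model.fit(assumption=assumption, variance=variance, **kwargs)


def bootstrap_se(
    sample: GameOutcomeSample,
    assumption: str | ValidationAssumption | None = None,
    B: int = 2000,
    seed: int | None = None,
) -> BootstrapSE:
    """Nonparametric bootstrap SEs, resampling respondents within the arm.

    Replicates are drawn with replacement; a replicate on which the
    statistics are not computable (an empty conditioning group, or no
    identifiable cheating mass) is redrawn and counted.  Deterministic for
    a given ``seed``.
    """
    if B < 200:
        raise ValueError("B must be at least 200 for stable bootstrap SEs")
    model = DiceGameValidationModel.from_sample(sample)
    observed = assumption is None
    if observed and sample.truth is None:
        raise ValueError("observed-truth bootstrap requires a truth vector")
    w = _components(sample, observed)
    n = sample.n
    rng = np.random.default_rng(seed)
    estimates = np.empty((B, 4))
    redraws = 0
    max_attempts = 100 * B
    attempts = 0
    b = 0
    while b < B:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "bootstrap failed: too many degenerate resamples "
                f"({redraws} redraws in {attempts} attempts)"
            )
        idx = rng.integers(0, n, size=n)
        m = w[idx].mean(axis=0)
        try:
            values, _, _ = model._estimate(m, assumption)
        except ValueError:
            redraws += 1
            continue
        estimates[b] = values
        b += 1
    if redraws > 0.01 * B:
        warnings.warn(
            f"bootstrap redrew {redraws} degenerate resamples "
            f"(> 1% of B={B}); estimates may sit near an identification boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    sds = estimates.std(axis=0, ddof=1)
    return BootstrapSE(
        se_tpr=float(sds[0]),
        se_fpr=float(sds[1]),
        se_ccr=float(sds[2]),
        se_cheat_rate=float(sds[3]),
        n_boot=B,
        n_redraws=redraws,
    )
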