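"""Sensitive-question technique designs and their misclassification parameters.

Each questioning technique — direct questioning (DQ), the crosswise model
(CM), the unrelated-question design (UQ) and the forced-response design
(FR) — maps its randomizing-device parameters to a single pair of
misclassification probabilities

    p11 = Pr(Y = 1 | Y* = 1),   p10 = Pr(Y = 1 | Y* = 0),

where ``Y*`` is the (possibly unobserved) true answer to the sensitive
question and ``Y`` the recorded response ("yes", or "the same" for CM).
Everything downstream (prevalence estimation, individual-level validation)
only needs this pair, which is known by design:

* DQ: no misclassification, ``p11 = 1``, ``p10 = 0``.
* CM: with ``p_z`` the "yes"-probability of the paired non-sensitive
  question, ``p11 = p_z`` and ``p10 = 1 - p_z``.
* UQ: with ``p_u`` the probability of being routed to the non-sensitive
  question, ``p11 = 1 - p_u (1 - p_z)`` and ``p10 = p_u p_z``.
* FR: with forced-answer probabilities ``p_yes`` and ``p_no``,
  ``p11 = 1 - p_no`` and ``p10 = p_yes``.

The module also houses the randomizing devices used in the dice-game
survey this package emulates: Benford-distributed first digits of house
numbers (the UQ routing device) and theoretical "yes"-probabilities for
birthday questions under a uniform-birthday convention.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields
from typing import Mapping

import yaml

__all__ = [
    "Technique",
    "IdentifiabilityError",
    "MisclassPair",
    "RRTDesign",
    "misclassification_probs",
    "benford_first_digit_probability",
    "theoretical_pz",
    "THEORETICAL_PZ",
    "UNRELATED_QUESTIONS",
    "default_catalogue",
    "catalogue_to_config",
    "catalogue_from_config",
    "save_catalogue",
    "load_catalogue",
]


class Technique(str, enum.Enum):
    """The four questioning techniques compared in the survey."""

    DQ = "DQ"
    CM = "CM"
    UQ = "UQ"
    FR = "FR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class IdentifiabilityError(ValueError):
    """Raised when a design's misclassification pair has p11 == p10."""


@dataclass(frozen=True)
class MisclassPair:
    """Misclassification pair (p11, p10) of a questioning design.

    The pair must be identifiable (``p11 != p10``); the difference
    ``p11 - p10`` is the slope of the linear map from true prevalence to
    observed response probability.
    """

    p11: float
    p10: float

    def __post_init__(self) -> None:
        for name in ("p11", "p10"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p11 == self.p10:
            raise IdentifiabilityError(
                f"p11 == p10 == {self.p11}: observed responses carry no "
                "information about the sensitive answer"
            )

    @property
    def slope(self) -> float:
        return self.p11 - self.p10

    def forward(self, pi):
        """Pr(Y = 1) for a population with true prevalence ``pi``."""
        return self.p11 * pi + self.p10 * (1.0 - pi)

    def invert(self, y_mean):
        """True prevalence implied by an observed 'yes' proportion."""
        return (y_mean - self.p10) / self.slope


# fields that are meaningful for each technique kind
_RELEVANT: dict[Technique, tuple[str, ...]] = {
    Technique.DQ: (),
    Technique.CM: ("p_z",),
    Technique.UQ: ("p_z", "p_u"),
    Technique.FR: ("p_yes", "p_no"),
}


@dataclass(frozen=True)
class RRTDesign:
    """A questioning technique with its randomizer parameters.

    Only the fields relevant to ``kind`` may be set:

    ========  =======================================================
    kind      fields
    ========  =======================================================
    DQ        none
    CM        ``p_z`` (unrelated question "yes"-probability, != 1/2)
    UQ        ``p_z`` and ``p_u`` (routing probability, < 1)
    FR        ``p_yes`` and ``p_no`` (forced answers, sum < 1)
    ========  =======================================================

    ``unrelated_question`` optionally records the identifier of the paired
    non-sensitive question (see :data:`THEORETICAL_PZ`).
    """

    kind: Technique
    p_z: float | None = None
    p_u: float | None = None
    p_yes: float | None = None
    p_no: float | None = None
    unrelated_question: str | None = None

    def __post_init__(self) -> None:
        kind = Technique(self.kind)
        object.__setattr__(self, "kind", kind)
        relevant = _RELEVANT[kind]
        for f in ("p_z", "p_u", "p_yes", "p_no"):
            value = getattr(self, f)
            if f in relevant:
                if value is None:
                    raise ValueError(f"{kind.value} design requires {f}")
            elif value is not None:
                raise ValueError(f"{f} is not a parameter of a {kind.value} design")
        if kind is Technique.CM:
            if not 0.0 < self.p_z < 1.0:
                raise ValueError(f"p_z={self.p_z} outside (0, 1)")
            if self.p_z == 0.5:
                raise IdentifiabilityError(
                    "CM with p_z = 1/2 is not identifiable (2*p_z - 1 = 0)"
                )
        elif kind is Technique.UQ:
            if not 0.0 < self.p_z < 1.0:
                raise ValueError(f"p_z={self.p_z} outside (0, 1)")
            if not 0.0 < self.p_u < 1.0:
                raise ValueError(
                    f"p_u={self.p_u} must lie in (0, 1); p_u = 1 would route "
                    "every respondent away from the sensitive question"
                )
        elif kind is Technique.FR:
            if self.p_yes < 0.0 or self.p_no < 0.0:
                raise ValueError("forced-answer probabilities must be >= 0")
            if self.p_yes + self.p_no >= 1.0:
                raise ValueError(
                    f"p_yes + p_no = {self.p_yes + self.p_no} >= 1: some "
                    "respondents must be instructed to answer the question"
                )

    def misclassification_probs(self) -> MisclassPair:
        return misclassification_probs(self)

    def replace_pz(self, p_z: float) -> "RRTDesign":
        """Copy of the design with an overridden unrelated-question p_z."""
        if "p_z" not in _RELEVANT[self.kind]:
            raise ValueError(f"{self.kind.value} design has no p_z parameter")
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs["p_z"] = p_z
        return RRTDesign(**kwargs)


def misclassification_probs(design: RRTDesign) -> MisclassPair:
    """Map a design to its misclassification pair (p11, p10).

    Raises :class:`IdentifiabilityError` if the resulting pair is not
    identifiable, naming the offending parameter.
    """
    kind = design.kind
    if kind is Technique.DQ:
        return MisclassPair(1.0, 0.0)
    if kind is Technique.CM:
        try:
            return MisclassPair(design.p_z, 1.0 - design.p_z)
        except IdentifiabilityError as exc:
            raise IdentifiabilityError(
                f"CM design with p_z={design.p_z} not identifiable"
            ) from exc
    if kind is Technique.UQ:
        return MisclassPair(
            1.0 - design.p_u * (1.0 - design.p_z), design.p_u * design.p_z
        )
    if kind is Technique.FR:
        return MisclassPair(1.0 - design.p_no, design.p_yes)
    raise ValueError(f"unknown design kind {kind!r}")  # pragma: no cover


def benford_first_digit_probability(d_max: int) -> float:
    """Probability that a Benford-distributed first digit is <= ``d_max``.

    First digits of house numbers empirically follow Benford's law,
    Pr(d) = log10(1 + 1/d); the sum over d = 1..d_max telescopes to
    log10(d_max + 1).  Routing respondents on "digit <= 5" therefore
    selects the sensitive question with probability log10(6) ~= 0.778.
    """
    if not isinstance(d_max, (int,)) or isinstance(d_max, bool):
        raise TypeError("d_max must be an integer in 1..9")
    if not 1 <= d_max <= 9:
        raise ValueError(f"d_max={d_max} outside 1..9")
    return math.log10(d_max + 1)


# Theoretical "yes"-probabilities for the birthday questions, assuming
# uniformly distributed birthdays over a 365.25-day year with 12 equal
# months of 30.4375 days.  All values are user-overridable (e.g. with an
# empirically estimated proportion) via RRTDesign.replace_pz.
_DAYS_PER_MONTH = 365.25 / 12.0

THEORETICAL_PZ: dict[str, float] = {
    # crosswise-model pairings
    "jan-feb": 2.0 / 12.0,
    "day-1-6": 72.0 / 365.25,
    # unrelated-question pairings
    "jan-jun": 0.5,
    "even-month": 0.5,
    "first-half-month": 15.0 / _DAYS_PER_MONTH,
    "even-day": 15.0 / _DAYS_PER_MONTH,
    "even-year": 0.5,
}

#: unrelated-question identifiers available to each technique
UNRELATED_QUESTIONS: dict[Technique, tuple[str, ...]] = {
    Technique.CM: ("jan-feb", "day-1-6"),
    Technique.UQ: (
        "jan-jun",
        "even-month",
        "first-half-month",
        "even-day",
        "even-year",
    ),
}


def theoretical_pz(unrelated_question: str) -> float:
    """Theoretical "yes"-probability of a catalogued birthday question."""
    try:
        return THEORETICAL_PZ[unrelated_question]
    except KeyError:
        known = ", ".join(sorted(THEORETICAL_PZ))
        raise KeyError(
            f"unknown unrelated question {unrelated_question!r}; known: {known}"
        ) from None


#: probability that the UQ routing digit is 6..9, i.e. that the respondent
#: answers the unrelated question instead of the sensitive one
DEFAULT_P_U = 1.0 - benford_first_digit_probability(5)


def default_catalogue() -> dict[Technique, RRTDesign]:
    """Default design catalogue mirroring the dice-game survey.

    CM uses the first catalogued birthday question's p_z as its scalar
    template value (per-respondent pairings carry their own p_z in
    simulated data); UQ routes via Benford digits 6-9; FR shows twelve
    fields with 8x "Answer question", 2x "Directly tick yes" and 2x
    "Directly tick no".
    """
    return {
        Technique.DQ: RRTDesign(Technique.DQ),
        Technique.CM: RRTDesign(
            Technique.CM, p_z=THEORETICAL_PZ["jan-feb"], unrelated_question="jan-feb"
        ),
        Technique.UQ: RRTDesign(
            Technique.UQ,
            p_z=0.5,
            p_u=DEFAULT_P_U,
            unrelated_question="jan-jun",
        ),
        Technique.FR: RRTDesign(Technique.FR, p_yes=2.0 / 12.0, p_no=2.0 / 12.0),
    }


def catalogue_to_config(catalogue: Mapping[Technique, RRTDesign]) -> dict[str, object]:
    """Flatten a design catalogue to ``{"cm.p_z": ..., ...}`` keys."""
    flat: dict[str, object] = {}
    for tech, design in catalogue.items():
        prefix = Technique(tech).value.lower()
        flat[f"{prefix}.kind"] = design.kind.value
        for f in ("p_z", "p_u", "p_yes", "p_no", "unrelated_question"):
            value = getattr(design, f)
            if value is not None:
                flat[f"{prefix}.{f}"] = value
    return flat


def catalogue_from_config(flat: Mapping[str, object]) -> dict[Technique, RRTDesign]:
    """Rebuild a design catalogue from flat key-value pairs."""
    grouped: dict[str, dict[str, object]] = {}
    for key, value in flat.items():
        prefix, _, field = key.partition(".")
        if not field:
            raise ValueError(f"malformed catalogue key {key!r}")
        grouped.setdefault(prefix, {})[field] = value
    catalogue: dict[Technique, RRTDesign] = {}
    for prefix, params in grouped.items():
        kind = Technique(str(params.pop("kind", prefix.upper())))
        catalogue[kind] = RRTDesign(kind, **params)  # type: ignore[arg-type]
    return catalogue


def save_catalogue(catalogue: Mapping[Technique, RRTDesign], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalogue_to_config(catalogue), fh, sort_keys=True)


def load_catalogue(path) -> dict[Technique, RRTDesign]:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    return catalogue_from_config(flat)
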