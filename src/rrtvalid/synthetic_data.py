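"""Synthetic dice-game survey generator.

Emulates the data-generating structure the analysis assumes: respondents
are randomized to one of two dice games (*prediction*, where cheating is
latent, and *roll-a-six*, where the roll is recorded and cheating is
observable) and to one of four questioning techniques (DQ 1/8, CM 3/8,
UQ 2/8, FR 2/8).  Die rolls are uniform on 1..6, so the win probability is
1/6 in both games; losers claim an unearned win with a per-game cheating
propensity.  Each respondent then answers four sensitive items
(shoplifting, tax evasion, non-voting, cheating in the dice game) through
their assigned technique's randomizing device:

* CM — an unrelated birthday question (drawn uniformly per respondent from
  the technique's catalogue) with truth ``Z ~ Bernoulli(p_z)``; the honest
  response is "the same" iff the intended answer equals ``Z``.
* UQ — a Benford-distributed first digit routes the respondent to the
  sensitive question (digit 1-5) or to an unrelated birthday question
  (digit 6-9).
* FR — one of twelve fields instructs "Answer question" (8 fields),
  "Directly tick yes" (2) or "Directly tick no" (2).

Response behavior is configurable per game x technique: a cheater's
intended answer is truthful with probability ``p_truthful_cheater`` (the
behavioral TPR*), a non-cheater falsely "admits" with probability
``p_false_admit_noncheater`` (the behavioral FPR*), and two noncompliance
channels reproduce the failure modes observed in practice — instrument
*confusion* (the final response ignores the device and is uniform on the
two options, the mechanism that inflates CM false positives) and
*self-protective* responding (the design's "safe" answer regardless of
instruction: "no" for DQ/UQ/FR; uniform for CM, which has no clear safe
answer).

Randomness is laid out as a fixed-width block of uniforms per respondent
drawn from one master seed, so changing e.g. the arm allocation never
reshuffles any other respondent's draws, and identical seeds give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .designs import (
    RRTDesign,
    Technique,
    THEORETICAL_PZ,
    UNRELATED_QUESTIONS,
    default_catalogue,
    catalogue_to_config,
    catalogue_from_config,
)

__all__ = [
    "GAMES",
    "ITEMS",
    "REVERSE_CODED_ITEMS",
    "BehaviorModel",
    "SimulationConfig",
    "simulate_survey",
    "sample_benford_digit",
    "apply_response_instrument",
    "save_config",
    "load_config",
]

GAMES = ("prediction", "roll_a_six")

#: sensitive items, in questionnaire order; "cheating" refers to the dice game
ITEMS = ("shoplifting", "tax_evasion", "non_voting", "cheating")

#: items whose questionnaire wording has reversed polarity ("Did you vote?",
#: "Did you honestly report?"): raw responses are 1 - sensitive-coded answer
REVERSE_CODED_ITEMS = ("non_voting", "cheating")

_TECH_ORDER = (Technique.DQ, Technique.CM, Technique.UQ, Technique.FR)

# fixed per-respondent uniform layout (columns of the master draw matrix)
_COL_GAME = 0
_COL_DIE = 1
_COL_WIN = 2  # prediction-game predicted value / generic win draw
_COL_CHEAT = 3
_COL_FALSE_LOSER = 4
_COL_TECH = 5
_COL_BEHAVIOR = 6
_COL_COMPLETED = 7
_COL_SCREENER = 8
_COL_ROLL_REC = 9
_ITEM_BLOCK_START = 10
_ITEM_BLOCK_WIDTH = 6  # truth, pairing, device1, device2, intended, response
_N_COLS = _ITEM_BLOCK_START + _ITEM_BLOCK_WIDTH * len(ITEMS)

_BENFORD_CDF = np.log10(np.arange(2, 11))  # Pr(digit <= d) = log10(d + 1)


def _benford_from_uniform(u: np.ndarray) -> np.ndarray:
    return np.searchsorted(_BENFORD_CDF, u, side="right") + 1


def sample_benford_digit(rng=None, size=None):
    """Draw first digits 1..9 from Benford's law by inverse CDF."""
    if rng is None:
        rng = np.random.default_rng()
    digits = _benford_from_uniform(rng.random(size))
    return digits if size is not None else int(digits)


@dataclass(frozen=True)
class BehaviorModel:
    """Response behavior of one game x technique cell.

    All parameters are probabilities; ``p_instrument_confusion`` and
    ``p_self_protective`` must sum to at most 1 (the remainder of the mass
    follows the instrument, truthfully or not).
    """

    p_truthful_cheater: float
    p_false_admit_noncheater: float = 0.0
    p_instrument_confusion: float = 0.0
    p_self_protective: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_truthful_cheater",
            "p_false_admit_noncheater",
            "p_instrument_confusion",
            "p_self_protective",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_instrument_confusion + self.p_self_protective > 1.0:
            raise ValueError("confusion + self-protective probabilities exceed 1")

    def to_dict(self) -> dict[str, float]:
        return {
            "p_truthful_cheater": self.p_truthful_cheater,
            "p_false_admit_noncheater": self.p_false_admit_noncheater,
            "p_instrument_confusion": self.p_instrument_confusion,
            "p_self_protective": self.p_self_protective,
        }


def default_behavior() -> dict[str, dict[Technique, BehaviorModel]]:
    """Behavior defaults emulating the rates observed in the original survey.

    Cheaters admitted far more readily in the verifiable roll-a-six game
    than in the anonymous prediction game; a fixed fraction of CM
    respondents is confused by the crosswise instructions (driving its
    false positive rate to ~10-12%), and a fraction of FR respondents
    answers "no" even when instructed to tick "yes".
    """
    return {
        "prediction": {
            Technique.DQ: BehaviorModel(0.10),
            Technique.CM: BehaviorModel(0.22, p_instrument_confusion=0.21),
            Technique.UQ: BehaviorModel(0.15),
            Technique.FR: BehaviorModel(0.15, p_self_protective=0.10),
        },
        "roll_a_six": {
            Technique.DQ: BehaviorModel(0.70),
            Technique.CM: BehaviorModel(0.44, p_instrument_confusion=0.24),
            Technique.UQ: BehaviorModel(0.50),
            Technique.FR: BehaviorModel(0.50, p_self_protective=0.10),
        },
    }


def _default_arm_probs() -> dict[Technique, float]:
    return {
        Technique.DQ: 1.0 / 8.0,
        Technique.CM: 3.0 / 8.0,
        Technique.UQ: 2.0 / 8.0,
        Technique.FR: 2.0 / 8.0,
    }


def _default_traits() -> dict[str, float]:
    # plausible magnitudes for the non-game items (no truth criterion)
    return {"shoplifting": 0.40, "tax_evasion": 0.15, "non_voting": 0.35}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic survey.

    Defaults reproduce the study conditions: even game split, arm
    allocation 1/8 : 3/8 : 2/8 : 2/8, win probability 1/6, cheating
    propensity among losers 0.30 (prediction) and 0.06 (roll-a-six) so
    overall cheating runs at ~25% and ~5%, and the default behavior and
    design catalogues.  Completion / screener / roll-recording rates
    reproduce the survey's exclusion volumes; ``false_loser_rate``
    defaults to 0 (assumption A1 holds by construction).
    """

    n: int
    seed: int = 0
    game_split: float = 0.5
    arm_probs: Mapping[Technique, float] = field(default_factory=_default_arm_probs)
    win_prob: float = 1.0 / 6.0
    cheat_propensity_prediction: float = 0.30
    cheat_propensity_rollsix: float = 0.06
    behavior: Mapping[str, Mapping[Technique, BehaviorModel]] = field(
        default_factory=default_behavior
    )
    designs: Mapping[Technique, RRTDesign] = field(default_factory=default_catalogue)
    extra_traits: Mapping[str, float] = field(default_factory=_default_traits)
    completion_rate: float = 0.995
    screener_pass_rate: float = 0.97
    roll_record_rate: float = 0.98
    false_loser_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        total = sum(self.arm_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"arm_probs sum to {total}, expected 1")
        probs = {
            "game_split": self.game_split,
            "win_prob": self.win_prob,
            "cheat_propensity_prediction": self.cheat_propensity_prediction,
            "cheat_propensity_rollsix": self.cheat_propensity_rollsix,
            "completion_rate": self.completion_rate,
            "screener_pass_rate": self.screener_pass_rate,
            "roll_record_rate": self.roll_record_rate,
            "false_loser_rate": self.false_loser_rate,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for game in GAMES:
            if game not in self.behavior:
                raise ValueError(f"behavior missing game {game!r}")
            for tech in _TECH_ORDER:
                if tech not in self.behavior[game]:
                    raise ValueError(f"behavior[{game!r}] missing {tech.value}")
        for trait, p in self.extra_traits.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"extra trait {trait!r} prevalence outside [0, 1]")
            if trait == "cheating":
                raise ValueError("'cheating' is generated by the game, not a trait")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "game_split": self.game_split,
            "arm_probs": {t.value: p for t, p in self.arm_probs.items()},
            "win_prob": self.win_prob,
            "cheat_propensity_prediction": self.cheat_propensity_prediction,
            "cheat_propensity_rollsix": self.cheat_propensity_rollsix,
            "behavior": {
                game: {t.value: bm.to_dict() for t, bm in cells.items()}
                for game, cells in self.behavior.items()
            },
            "designs": catalogue_to_config(self.designs),
            "extra_traits": dict(self.extra_traits),
            "completion_rate": self.completion_rate,
            "screener_pass_rate": self.screener_pass_rate,
            "roll_record_rate": self.roll_record_rate,
            "false_loser_rate": self.false_loser_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "arm_probs" in d:
            d["arm_probs"] = {Technique(k): v for k, v in d["arm_probs"].items()}
        if "behavior" in d:
            d["behavior"] = {
                game: {
                    Technique(t): (
                        bm if isinstance(bm, BehaviorModel) else BehaviorModel(**bm)
                    )
                    for t, bm in cells.items()
                }
                for game, cells in d["behavior"].items()
            }
        if "designs" in d and not isinstance(
            next(iter(d["designs"].values()), None), RRTDesign
        ):
            d["designs"] = catalogue_from_config(d["designs"])
        return cls(**d)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# instrument application
# ---------------------------------------------------------------------------


def apply_response_instrument(
    intended,
    design: RRTDesign,
    device: Mapping[str, np.ndarray] | None = None,
    behavior=None,
    u_response=None,
    rng=None,
):
    """Map intended answers to observed responses through a design's device.

    Parameters
    ----------
    intended : array-like of 0/1
        The answer the respondent intends to give to the sensitive question
        (already including any deliberate lying).
    design : RRTDesign
        The questioning design.
    device : mapping of arrays, optional
        Device outcomes: CM needs ``z`` (unrelated-question truth 0/1); UQ
        needs ``digit`` (Benford digit 1..9; digits 6-9 route to the
        unrelated question) or ``routed`` plus ``z``; FR needs
        ``instruction`` (0 = answer, 1 = forced yes, 2 = forced no).
    behavior : array-like of str, optional
        Per-respondent labels among {"honest", "liar", "confused",
        "self_protective"}; honest and liar both *follow* the instrument.
    u_response : array-like of floats, optional
        Uniform draws used for confused (and CM self-protective) responses;
        drawn from ``rng`` if omitted.

    Returns an int array of observed responses (1 = "yes" / "the same").
    """
    intended = np.asarray(intended, dtype=int)
    n = intended.size
    device = {} if device is None else dict(device)
    kind = design.kind

    if kind is Technique.DQ:
        y = intended.copy()
    elif kind is Technique.CM:
        if "z" not in device:
            raise ValueError("CM device outcome requires 'z'")
        z = np.asarray(device["z"], dtype=int)
        if z.size != n:
            raise ValueError("device 'z' length mismatch")
        y = (intended == z).astype(int)
    elif kind is Technique.UQ:
        if "routed" in device:
            routed_sensitive = np.asarray(device["routed"], dtype=bool)
        elif "digit" in device:
            digit = np.asarray(device["digit"], dtype=int)
            if np.any((digit < 1) | (digit > 9)):
                raise ValueError("UQ digits must lie in 1..9")
            routed_sensitive = digit <= 5
        else:
            raise ValueError("UQ device outcome requires 'digit' or 'routed'")
        if "z" not in device:
            raise ValueError("UQ device outcome requires 'z'")
        z = np.asarray(device["z"], dtype=int)
        y = np.where(routed_sensitive, intended, z).astype(int)
    elif kind is Technique.FR:
        if "instruction" not in device:
            raise ValueError("FR device outcome requires 'instruction'")
        instr = np.asarray(device["instruction"], dtype=int)
        if np.any((instr < 0) | (instr > 2)):
            raise ValueError("FR instruction codes must be 0 (answer), 1, or 2")
        y = np.where(instr == 1, 1, np.where(instr == 2, 0, intended)).astype(int)
    else:  # pragma: no cover
        raise ValueError(f"unknown design kind {kind!r}")

    if behavior is None:
        return y
    behavior = np.asarray(behavior)
    confused = behavior == "confused"
    selfprot = behavior == "self_protective"
    if confused.any() or (selfprot.any() and kind is Technique.CM):
        if u_response is None:
            if rng is None:
                rng = np.random.default_rng()
            u_response = rng.random(n)
        u_response = np.asarray(u_response, dtype=float)
    if confused.any():
        y = np.where(confused, (u_response < 0.5).astype(int), y)
    if selfprot.any():
        if kind is Technique.CM:
            # no clear self-protective answer in CM: uniform over the options
            y = np.where(selfprot, (u_response < 0.5).astype(int), y)
        else:
            y = np.where(selfprot, 0, y)
    return y


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------


def _pz_lookup(tech: Technique, design: RRTDesign) -> np.ndarray:
    """p_z values of the technique's unrelated-question catalogue."""
    questions = UNRELATED_QUESTIONS.get(tech, ())
    if questions:
        return np.array([THEORETICAL_PZ[q] for q in questions])
    return np.array([design.p_z if design.p_z is not None else np.nan])


def simulate_survey(config: SimulationConfig) -> pd.DataFrame:
    """Generate one respondent-level survey table.

    Returns a DataFrame with one row per recruited respondent.  Response
    columns ``resp_*`` use the questionnaire's raw polarity (the
    non-voting and cheating items are reverse-coded; see
    :data:`REVERSE_CODED_ITEMS`), while ``true_*`` columns always use the
    sensitive polarity (1 = trait present / cheated).  ``pz_*`` columns
    record the theoretical "yes"-probability of the unrelated question the
    item was paired with (NaN for DQ/FR).
    """
    n = config.n
    rng = np.random.default_rng(config.seed)
    U = rng.random((n, _N_COLS))

    prediction = U[:, _COL_GAME] < config.game_split
    game = np.where(prediction, "prediction", "roll_a_six")
    die = (U[:, _COL_DIE] * 6).astype(int) + 1

    if abs(config.win_prob - 1.0 / 6.0) < 1e-12:
        predicted = (U[:, _COL_WIN] * 6).astype(int) + 1
        won = np.where(prediction, predicted == die, die == 6)
    else:  # non-dice win probability: generic Bernoulli device
        predicted = np.zeros(n, dtype=int)
        won = U[:, _COL_WIN] < config.win_prob
    won = won.astype(bool)

    propensity = np.where(
        prediction,
        config.cheat_propensity_prediction,
        config.cheat_propensity_rollsix,
    )
    cheated = (~won) & (U[:, _COL_CHEAT] < propensity)
    claimed = won | cheated
    false_loser = np.zeros(n, dtype=bool)
    if config.false_loser_rate > 0.0:
        false_loser = won & (U[:, _COL_FALSE_LOSER] < config.false_loser_rate)
        claimed = claimed & ~false_loser

    # technique arm from fixed cumulative allocation (DQ, CM, UQ, FR order)
    cuts = np.cumsum([config.arm_probs[t] for t in _TECH_ORDER])
    arm_idx = np.searchsorted(cuts, U[:, _COL_TECH], side="right")
    arm_idx = np.minimum(arm_idx, len(_TECH_ORDER) - 1)
    technique = np.array([t.value for t in _TECH_ORDER], dtype=object)[arm_idx]

    # per-respondent behavior parameters for their game x technique cell
    t_star = np.empty(n)
    f_star = np.empty(n)
    p_conf = np.empty(n)
    p_self = np.empty(n)
    for g in GAMES:
        for j, tech in enumerate(_TECH_ORDER):
            cell = (game == g) & (arm_idx == j)
            bm = config.behavior[g][tech]
            t_star[cell] = bm.p_truthful_cheater
            f_star[cell] = bm.p_false_admit_noncheater
            p_conf[cell] = bm.p_instrument_confusion
            p_self[cell] = bm.p_self_protective

    u_beh = U[:, _COL_BEHAVIOR]
    confused = u_beh < p_conf
    selfprot = (~confused) & (u_beh < p_conf + p_self)

    completed = U[:, _COL_COMPLETED] < config.completion_rate
    screener = U[:, _COL_SCREENER] < config.screener_pass_rate
    roll_rec = U[:, _COL_ROLL_REC] < config.roll_record_rate

    data: dict[str, np.ndarray] = {
        "respondent_id": np.arange(1, n + 1),
        "completed": completed.astype(int),
        "passed_screener": screener.astype(int),
        "roll_recorded": roll_rec.astype(int),
        "game": game,
        "technique": technique,
        "die_outcome": die,
        "won": won.astype(int),
        "claimed_win": claimed.astype(int),
        "cheated": cheated.astype(int),
        "false_loser": false_loser.astype(int),
    }

    behavior_label = np.full(n, "honest", dtype=object)
    behavior_label[confused] = "confused"
    behavior_label[selfprot] = "self_protective"

    for i, item in enumerate(ITEMS):
        base = _ITEM_BLOCK_START + i * _ITEM_BLOCK_WIDTH
        u_truth, u_pair, u_dev1, u_dev2, u_int, u_resp = (
            U[:, base + j] for j in range(_ITEM_BLOCK_WIDTH)
        )
        if item == "cheating":
            truth = cheated.astype(int)
            p_admit = np.where(cheated, t_star, f_star)
            intended = (u_int < p_admit).astype(int)
            # deliberate lying on the cheating item defines the label
            standard = ~(confused | selfprot)
            liar = standard & (intended != truth)
            behavior_label[liar] = "liar"
        else:
            truth = (u_truth < config.extra_traits[item]).astype(int)
            intended = truth.copy()  # non-game items answered truthfully

        resp = np.zeros(n, dtype=float)
        device_code = np.full(n, -1, dtype=float)
        pz_col = np.full(n, np.nan)
        labels = behavior_label

        for j, tech in enumerate(_TECH_ORDER):
            cell = arm_idx == j
            if not cell.any():
                continue
            design = config.designs[tech]
            m_int = intended[cell]
            m_lab = labels[cell]
            m_resp = u_resp[cell]
            if tech is Technique.DQ:
                device = None
            elif tech is Technique.CM:
                pzs = _pz_lookup(tech, design)
                q_idx = (u_pair[cell] * len(pzs)).astype(int)
                pz = pzs[np.minimum(q_idx, len(pzs) - 1)]
                z = (u_dev1[cell] < pz).astype(int)
                device = {"z": z}
                device_code[cell] = z
                pz_col[cell] = pz
            elif tech is Technique.UQ:
                pzs = _pz_lookup(tech, design)
                q_idx = (u_pair[cell] * len(pzs)).astype(int)
                pz = pzs[np.minimum(q_idx, len(pzs) - 1)]
                digit = _benford_from_uniform(u_dev1[cell])
                z = (u_dev2[cell] < pz).astype(int)
                device = {"digit": digit, "z": z}
                device_code[cell] = digit
                pz_col[cell] = pz
            else:  # FR
                p_answer = 1.0 - design.p_yes - design.p_no
                u = u_dev1[cell]
                instr = np.where(
                    u < p_answer, 0, np.where(u < p_answer + design.p_yes, 1, 2)
                )
                device = {"instruction": instr}
                device_code[cell] = instr
            y = apply_response_instrument(
                m_int, design, device, behavior=m_lab, u_response=m_resp
            )
            resp[cell] = y

        if item in REVERSE_CODED_ITEMS:
            resp = 1.0 - resp  # raw questionnaire polarity
        resp[~completed] = np.nan  # dropped out before the sensitive part

        data[f"true_{item}"] = truth
        data[f"resp_{item}"] = resp
        data[f"device_{item}"] = device_code
        data[f"pz_{item}"] = pz_col

    data["behavior"] = behavior_label
    return pd.DataFrame(data)
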