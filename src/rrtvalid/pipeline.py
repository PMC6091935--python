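"""Three-stage analysis pipeline for dice-game validation surveys.

Reproduces the full analysis workflow from a respondent-level table (real
or synthetic): sample exclusions with a conserving ledger, item recoding,
and the three validation stages —

1. *comparative*: per-item prevalence by technique and differences vs
   direct questioning (the "more-is-better" comparison);
2. *aggregate*: per-game true cheating rates (observed in roll-a-six,
   ``Pr(X=1) - 1/6`` in the prediction game) and each technique's bias;
3. *individual*: TPR / FPR / CCR per technique per game, routed to the
   observed-truth or latent-truth identification as appropriate.

All outputs are tidy tables keyed by (item, technique, game, metric).
The expected input schema is the one written by
:func:`rrtvalid.synthetic_data.simulate_survey`; an external table can be
mapped onto it with a user-editable codebook (column renames / value
recodes) via :func:`load_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .designs import (
    MisclassPair,
    Technique,
    default_catalogue,
    misclassification_probs,
)
from .estimators import (
    PrevalenceEstimate,
    ResponseSample,
    Z_95,
    arm_difference,
    difference_pvalue,
    estimate_prevalence,
)
from .validation import (
    GameOutcomeSample,
    ValidationAssumption,
    validate_latent_truth,
    validate_observed_truth,
)
from .synthetic_data import GAMES, ITEMS, REVERSE_CODED_ITEMS

__all__ = [
    "ExclusionLedger",
    "EXCLUSION_RULES",
    "apply_exclusions",
    "recode_items",
    "comparative_analysis",
    "aggregate_validation",
    "individual_validation",
    "run_analysis",
    "load_table",
    "plot_estimates",
]

#: exclusion rules in the order they are applied; a record failing several
#: rules is attributed to the first
EXCLUSION_RULES = ("screener", "no_roll", "false_loser")

_TECH_ORDER = ("DQ", "CM", "UQ", "FR")
WIN_PROB = 1.0 / 6.0


@dataclass(frozen=True)
class ExclusionLedger:
    """Counts of records removed by each filtering rule; totals conserve."""

    total_recruited: int
    completed_sensitive_part: int
    removed_screener: int
    removed_no_roll: int
    removed_false_loser: int
    final_n: int

    def __post_init__(self) -> None:
        counts = (
            self.total_recruited,
            self.completed_sensitive_part,
            self.removed_screener,
            self.removed_no_roll,
            self.removed_false_loser,
            self.final_n,
        )
        if any(c < 0 for c in counts):
            raise ValueError("ledger counts must be nonnegative")
        expected = (
            self.completed_sensitive_part
            - self.removed_screener
            - self.removed_no_roll
            - self.removed_false_loser
        )
        if expected != self.final_n:
            raise ValueError(
                f"ledger does not conserve counts: {expected} != {self.final_n}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "total_recruited": self.total_recruited,
            "completed_sensitive_part": self.completed_sensitive_part,
            "removed_screener": self.removed_screener,
            "removed_no_roll": self.removed_no_roll,
            "removed_false_loser": self.removed_false_loser,
            "final_n": self.final_n,
        }


def _require_columns(df: pd.DataFrame, columns: Iterable[str], context: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"{context}: missing required column(s) {missing}")


def apply_exclusions(
    df: pd.DataFrame, rules: Sequence[str] = EXCLUSION_RULES
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Filter a raw respondent table, returning the table and a ledger.

    Respondents who did not complete the survey up to the sensitive part
    are dropped first (they enter the ledger as the completed/recruited
    difference); the remaining rules are applied in the given order:
    ``screener`` (failed the attention screener), ``no_roll`` (die roll
    not recorded) and ``false_loser`` (won the roll-a-six game but did not
    claim the bonus).
    """
    unknown = set(rules) - set(EXCLUSION_RULES)
    if unknown:
        raise ValueError(f"unknown exclusion rule(s): {sorted(unknown)}")
    _require_columns(df, ["completed"], "apply_exclusions")
    total = len(df)
    work = df[df["completed"] == 1]
    completed = len(work)
    removed = {rule: 0 for rule in EXCLUSION_RULES}
    for rule in EXCLUSION_RULES:  # fixed order regardless of `rules` order
        if rule not in rules:
            continue
        if rule == "screener":
            _require_columns(work, ["passed_screener"], "rule 'screener'")
            drop = work["passed_screener"] == 0
        elif rule == "no_roll":
            _require_columns(work, ["roll_recorded"], "rule 'no_roll'")
            drop = work["roll_recorded"] == 0
        else:  # false_loser: observable in the roll-a-six game only
            _require_columns(
                work, ["game", "won", "claimed_win"], "rule 'false_loser'"
            )
            drop = (
                (work["game"] == "roll_a_six")
                & (work["won"] == 1)
                & (work["claimed_win"] == 0)
            )
        removed[rule] = int(drop.sum())
        work = work[~drop]
    ledger = ExclusionLedger(
        total_recruited=total,
        completed_sensitive_part=completed,
        removed_screener=removed["screener"],
        removed_no_roll=removed["no_roll"],
        removed_false_loser=removed["false_loser"],
        final_n=len(work),
    )
    return work.reset_index(drop=True), ledger


def recode_items(
    df: pd.DataFrame, items: Sequence[str] = REVERSE_CODED_ITEMS
) -> pd.DataFrame:
    """Flip reverse-coded items so that 1 = sensitive answer.

    The voting and dice-game honesty questions are worded positively
    ("Did you vote?", "Did you honestly report?"), so their raw "yes"
    maps to the *non*-sensitive answer.  Applying the recode twice
    restores the input (involution).
    """
    out = df.copy()
    for item in items:
        if item not in ITEMS:
            raise KeyError(f"unknown item label {item!r}; known items: {ITEMS}")
        col = f"resp_{item}"
        _require_columns(out, [col], "recode_items")
        out[col] = 1.0 - out[col]
    return out


# ---------------------------------------------------------------------------
# arm-level helpers
# ---------------------------------------------------------------------------


def _arm_pair(
    sub: pd.DataFrame, item: str, technique: str, catalogue: Mapping
) -> MisclassPair:
    """Misclassification pair for one arm x item subsample.

    CM and UQ respondents may have faced different unrelated questions;
    because the device outcome is independent of the sensitive answer, the
    arm-average (p11, p10) pair is the correct inversion target, and for
    CM/UQ it equals the pair evaluated at the arm-average p_z.
    """
    tech = Technique(technique)
    design = catalogue[tech]
    pz_col = f"pz_{item}"
    if tech in (Technique.CM, Technique.UQ) and pz_col in sub.columns:
        pz = sub[pz_col].dropna()
        if len(pz):
            design = design.replace_pz(float(pz.mean()))
    return misclassification_probs(design)


def _item_frame(df: pd.DataFrame, item: str) -> pd.DataFrame:
    """Listwise deletion of item nonresponse (negligible by design)."""
    col = f"resp_{item}"
    _require_columns(df, [col, "technique"], f"item {item!r}")
    return df[df[col].notna()]


def _row(item, technique, game, metric, est, se, n, **extra) -> dict:
    return {
        "item": item,
        "technique": technique,
        "game": game,
        "metric": metric,
        "estimate": float(est),
        "se": float(se),
        "ci_low": float(est - Z_95 * se),
        "ci_high": float(est + Z_95 * se),
        "n": int(n),
        **extra,
    }


_TABLE_COLUMNS = [
    "item",
    "technique",
    "game",
    "metric",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "n",
    "p_value",
    "assumption",
    "fpr_truncated",
]


def _finish(rows: list[dict]) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    for col in _TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# stage 1: comparative validation
# ---------------------------------------------------------------------------


def comparative_analysis(
    df: pd.DataFrame,
    catalogue: Mapping | None = None,
    include_differences: bool = True,
) -> pd.DataFrame:
    """Per-item prevalence by technique, plus differences vs DQ.

    Expects a filtered, recoded table.  The three non-game items pool both
    games; the cheating item is analysed per game (the question wording
    differs).  Differences carry two-sided Wald z-test p-values.
    """
    catalogue = default_catalogue() if catalogue is None else catalogue
    _require_columns(df, ["technique", "game"], "comparative_analysis")
    rows: list[dict] = []
    cells: list[tuple[str, str, pd.DataFrame]] = [
        (item, "all", df) for item in ITEMS if item != "cheating"
    ]
    cells += [
        ("cheating", game, df[df["game"] == game])
        for game in GAMES
        if (df["game"] == game).any()
    ]
    for item, game, sub in cells:
        sub = _item_frame(sub, item)
        techniques = [t for t in _TECH_ORDER if (sub["technique"] == t).any()]
        estimates: dict[str, PrevalenceEstimate] = {}
        for tech in techniques:
            arm = sub[sub["technique"] == tech]
            sample = ResponseSample(
                arm[f"resp_{item}"].to_numpy(),
                _arm_pair(arm, item, tech, catalogue),
                item=item,
            )
            est = estimate_prevalence(sample)
            estimates[tech] = est
            rows.append(
                _row(item, tech, game, "prevalence", est.pi_hat, est.se, est.n)
            )
        if include_differences and len(techniques) >= 2:
            if "DQ" not in estimates:
                raise ValueError(
                    f"item {item!r} ({game}): differences vs DQ requested "
                    "but no DQ arm present"
                )
            for tech in techniques:
                if tech == "DQ":
                    continue
                diff = arm_difference(estimates[tech], estimates["DQ"])
                rows.append(
                    _row(
                        item,
                        tech,
                        game,
                        "difference_vs_DQ",
                        diff.pi_hat,
                        diff.se,
                        diff.n,
                        p_value=difference_pvalue(diff),
                    )
                )
    return _finish(rows)


# ---------------------------------------------------------------------------
# stage 2: aggregate-level validation
# ---------------------------------------------------------------------------


def _true_rate(sub: pd.DataFrame, game: str) -> tuple[float, float, int]:
    n = len(sub)
    if n < 2:
        raise ValueError(f"too few respondents in game {game!r}")
    if game == "roll_a_six":
        _require_columns(sub, ["won", "claimed_win"], "aggregate_validation")
        cheat = ((sub["claimed_win"] == 1) & (sub["won"] == 0)).to_numpy(float)
        rate = float(cheat.mean())
        se = float(np.sqrt(rate * (1.0 - rate) / (n - 1)))
    else:
        _require_columns(sub, ["claimed_win"], "aggregate_validation")
        x = sub["claimed_win"].to_numpy(float)
        xbar = float(x.mean())
        rate = xbar - WIN_PROB
        se = float(np.sqrt(xbar * (1.0 - xbar) / (n - 1)))
    return rate, se, n


def aggregate_validation(
    df: pd.DataFrame, catalogue: Mapping | None = None
) -> pd.DataFrame:
    """True cheating rate per game and per-technique estimate and bias.

    The roll-a-six true rate is the observed share of false winners; the
    prediction-game rate is identified as ``Pr(X=1) - 1/6`` with its
    binomially propagated standard error.  Bias rows are estimate minus
    true rate with the two (approximately independent) variances summed.
    """
    catalogue = default_catalogue() if catalogue is None else catalogue
    _require_columns(df, ["game", "technique"], "aggregate_validation")
    rows: list[dict] = []
    for game in GAMES:
        sub_game = df[df["game"] == game]
        if sub_game.empty:
            continue
        rate, rate_se, n_game = _true_rate(sub_game, game)
        rows.append(_row("cheating", "all", game, "true_rate", rate, rate_se, n_game))
        sub_item = _item_frame(sub_game, "cheating")
        for tech in _TECH_ORDER:
            arm = sub_item[sub_item["technique"] == tech]
            if arm.empty:
                continue
            sample = ResponseSample(
                arm["resp_cheating"].to_numpy(),
                _arm_pair(arm, "cheating", tech, catalogue),
                item="cheating",
            )
            est = estimate_prevalence(sample)
            rows.append(
                _row("cheating", tech, game, "prevalence", est.pi_hat, est.se, est.n)
            )
            bias = est.pi_hat - rate
            bias_se = float(np.hypot(est.se, rate_se))
            rows.append(
                _row("cheating", tech, game, "bias", bias, bias_se, est.n)
            )
    return _finish(rows)


# ---------------------------------------------------------------------------
# stage 3: individual-level validation
# ---------------------------------------------------------------------------


def individual_validation(
    df: pd.DataFrame,
    catalogue: Mapping | None = None,
    assumptions: Sequence[str] = ("A1_A2", "A1_A2prime"),
    variance: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """TPR / FPR / CCR per technique per game.

    Roll-a-six arms use the observed-truth identification (the recorded
    roll reveals each cheater); prediction arms use the latent-truth
    identification under each requested assumption set.
    """
    catalogue = default_catalogue() if catalogue is None else catalogue
    _require_columns(
        df, ["game", "technique", "claimed_win", "resp_cheating"], "individual_validation"
    )
    rows: list[dict] = []
    for game in GAMES:
        sub_game = _item_frame(df[df["game"] == game], "cheating")
        if sub_game.empty:
            continue
        for tech in _TECH_ORDER:
            arm = sub_game[sub_game["technique"] == tech]
            if arm.empty:
                continue
            pair = _arm_pair(arm, "cheating", tech, catalogue)
            y = arm["resp_cheating"].to_numpy()
            claim = arm["claimed_win"].to_numpy()
            if game == "roll_a_six":
                _require_columns(arm, ["won"], "individual_validation")
                sample = GameOutcomeSample(
                    y, claim, pair, truth=arm["won"].to_numpy(), win_prob=WIN_PROB
                )
                results = [
                    validate_observed_truth(
                        sample, variance=variance, n_boot=n_boot, seed=seed
                    )
                ]
            else:
                sample = GameOutcomeSample(y, claim, pair, win_prob=WIN_PROB)
                results = [
                    validate_latent_truth(
                        sample,
                        ValidationAssumption(a),
                        variance=variance,
                        n_boot=n_boot,
                        seed=seed,
                    )
                    for a in assumptions
                ]
            for res in results:
                for metric, est, se in (
                    ("TPR", res.tpr, res.se_tpr),
                    ("FPR", res.fpr, res.se_fpr),
                    ("CCR", res.ccr, res.se_ccr),
                    ("cheat_rate", res.cheat_rate, res.se_cheat_rate),
                ):
                    rows.append(
                        _row(
                            "cheating",
                            tech,
                            game,
                            metric,
                            est,
                            se,
                            res.n,
                            assumption=res.assumption,
                            fpr_truncated=res.fpr_truncated,
                        )
                    )
    return _finish(rows)


# ---------------------------------------------------------------------------
# orchestration and I/O
# ---------------------------------------------------------------------------


def run_analysis(
    raw: pd.DataFrame,
    catalogue: Mapping | None = None,
    assumptions: Sequence[str] = ("A1_A2", "A1_A2prime"),
    variance: str = "delta",
    seed: int | None = None,
) -> dict:
    """Exclusions, recoding, and all three analysis stages on a raw table.

    Returns ``{"ledger": ExclusionLedger, "comparative": DataFrame,
    "aggregate": DataFrame, "individual": DataFrame}``.  Deterministic for
    a fixed input table (and fixed seed when ``variance="bootstrap"``).
    """
    filtered, ledger = apply_exclusions(raw)
    recoded = recode_items(filtered)
    return {
        "ledger": ledger,
        "comparative": comparative_analysis(recoded, catalogue),
        "aggregate": aggregate_validation(recoded, catalogue),
        "individual": individual_validation(
            recoded, catalogue, assumptions=assumptions, variance=variance, seed=seed
        ),
    }


def load_table(path, codebook=None) -> pd.DataFrame:
    """Read a respondent table from CSV (or Stata .dta), applying a codebook.

    The codebook (dict or YAML path) may contain ``columns`` (source ->
    schema renames) and ``values`` (per-column value recodes), mapping an
    externally deposited table onto the schema this pipeline expects.
    """
    path = str(path)
    if path.endswith(".dta"):
        df = pd.read_stata(path)
    else:
        df = pd.read_csv(path)
    if codebook is not None:
        if not isinstance(codebook, Mapping):
            with open(codebook) as fh:
                codebook = yaml.safe_load(fh)
        renames = codebook.get("columns", {})
        df = df.rename(columns=renames)
        for col, mapping in codebook.get("values", {}).items():
            df[col] = df[col].map(lambda v: mapping.get(v, v))
    return df


def plot_estimates(
    table: pd.DataFrame, metric: str = "prevalence", ax=None, percent: bool = True
):
    """Simple forest-style plot of one metric from an analysis table."""
    import matplotlib.pyplot as plt

    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows with metric {metric!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * len(sub) + 1.2))
    scale = 100.0 if percent else 1.0
    labels = [
        f"{r.item} | {r.game} | {r.technique}" for r in sub.itertuples(index=False)
    ]
    y = np.arange(len(sub))[::-1]
    est = sub["estimate"].to_numpy() * scale
    err = Z_95 * sub["se"].to_numpy() * scale
    ax.errorbar(est, y, xerr=err, fmt="o", color="k", capsize=2)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y, labels)
    ax.set_xlabel(f"{metric}" + (" (%)" if percent else ""))
    return ax
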