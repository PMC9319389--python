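"""Additive likelihood scoring of presence profiles.

A profile is scored against a weight table by summing relative weights:

    +LR = Σ w(v)  over present variables v          (sum_present mode)
    −LR = 1 − (+LR)

The labels follow the clinical "positive/negative likelihood ratio" usage
of the source tables, but note these are additive scores bounded by the
weight-table total, not sensitivity/specificity-based likelihood ratios.

A second *complement* mode computes +LR = 1 − Σ w(v) over absent variables.
The two modes coincide exactly when the weight table sums to 1; for supplied
tables that sum to more (or less) than 100% they differ by the excess, and
published all-but-one-present rows are typically only reproducible in
complement mode.  Scores outside [0, 1] are never clamped — they indicate a
non-normalized table and are surfaced as warnings instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .dataset_io import DatasetValidationError, PresenceProfile
from .weights import WeightTable, render_percent

__all__ = ["ScoreResult", "score", "score_addends", "explain"]

MODES = ("sum_present", "complement")


@dataclass(frozen=True)
class Contribution:
    """One variable's part in a score."""

    name: str
    present: bool
    weight: Fraction


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one profile.

    ``positive_lr + negative_lr == 1`` exactly, by construction.
    ``contributions`` lists every variable with its status and weight;
    present variables come first, in descending weight order (the
    explanation ranking), followed by absent variables in dataset order.
    """

    positive_lr: Fraction
    negative_lr: Fraction
    contributions: tuple[Contribution, ...]
    mode: str
    warnings: tuple[str, ...] = ()

    @property
    def present_contributions(self) -> tuple[Contribution, ...]:
        return tuple(c for c in self.contributions if c.present)

    def positive_percent(self, precision: int = 1, compact: bool = False) -> str:
        return render_percent(self.positive_lr, precision, compact=compact)

    def negative_percent(self, precision: int = 1, compact: bool = False) -> str:
        return render_percent(self.negative_lr, precision, compact=compact)


def score(
    profile: PresenceProfile,
    weights: WeightTable,
    mode: str = "sum_present",
) -> ScoreResult:
    """Score a presence profile.

    Parameters
    ----------
    profile, weights:
        Must refer to the same dataset (same variable names).
    mode:
        ``"sum_present"`` (default): +LR = Σ weights of present variables.
        ``"complement"``: +LR = 1 − Σ weights of absent variables.

    Returns
    -------
    ScoreResult
        With exact fraction scores and ranked per-variable contributions.
        A warning is attached when +LR falls outside [0, 1], which can only
        happen with a non-normalized supplied table.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if profile.dataset.names != weights.dataset.names:
        raise DatasetValidationError(
            "profile and weight table refer to different datasets"
        )
    present_sum = sum((weights[n] for n in profile.present), Fraction(0))
    absent_sum = sum((weights[n] for n in profile.absent), Fraction(0))
    positive = present_sum if mode == "sum_present" else 1 - absent_sum
    negative = 1 - positive

    ranked_present = sorted(
        (Contribution(n, True, weights[n]) for n in profile.present),
        key=lambda c: (-c.weight, profile.dataset.names.index(c.name)),
    )
    absent = [Contribution(n, False, weights[n]) for n in profile.absent]

    warnings = []
    if not 0 <= positive <= 1:
        warnings.append(
            f"+LR = {float(positive):.4f} lies outside [0, 1]; the weight "
            f"table sums to {float(weights.total):.4f}, not 1"
        )
    return ScoreResult(
        positive_lr=positive,
        negative_lr=negative,
        contributions=tuple(ranked_present) + tuple(absent),
        mode=mode,
        warnings=tuple(warnings),
    )


def score_addends(weights: WeightTable, names: Sequence[str]) -> Fraction:
    """Sum the weights for an explicit list of variable names.

    Unlike :func:`score`, the list is a plain sequence of addends: the same
    name may appear more than once and each occurrence contributes its
    weight again.  This mirrors how clinicians tally a worked example by
    listing percent terms, and reproduces published sums even when a printed
    addend list repeats a variable.
    """
    unknown = [n for n in names if n not in weights.weights]
    if unknown:
        raise DatasetValidationError(f"unknown variable name(s): {unknown}")
    return sum((weights[n] for n in names), Fraction(0))


def explain(result: ScoreResult, precision: int = 1) -> str:
    """Render a ranked, human-readable explanation of a score.

    Present variables are listed top-contributor first with a running
    cumulative +LR column; the footer states +LR/−LR and the scoring mode.
    """
    lines = []
    lines.append(f"{'variable':<40} {'status':<8} {'weight':>8} {'cum +LR':>9}")
    cumulative = Fraction(0)
    for c in result.present_contributions:
        cumulative += c.weight
        lines.append(
            f"{c.name:<40} present  "
            f"{render_percent(c.weight, precision):>8} "
            f"{render_percent(cumulative, precision):>9}"
        )
    if not result.present_contributions:
        lines.append("(no variables present)")
    for c in result.contributions:
        if not c.present:
            lines.append(
                f"{c.name:<40} absent   "
                f"{render_percent(c.weight, precision):>8} {'-':>9}"
            )
    lines.append("")
    lines.append(
        f"+LR = {result.positive_percent(precision)}   "
        f"-LR = {result.negative_percent(precision)}   "
        f"(mode: {result.mode})"
    )
    for w in result.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)
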