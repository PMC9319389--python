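"""Relative and prevalence weights of diagnostic variables.

The importance measure at the heart of the scoring model is the *relative
weight*: a variable's count divided by the sum of counts over all variables,

    w(v) = count(v) / Σ_u count(u),

so that computed weights always sum to exactly 1.  The *prevalence weight*
is the more familiar epidemiological quantity count(v) / N for a cohort of
N patients; it is reported per variable but plays no role in scoring.

Weight tables may also be *supplied*: tabulated percents taken verbatim from
a published source rather than recomputed from counts.  Supplied tables are
loaded without renormalisation — some published tables sum to slightly more
than 100% and silently rescaling them would change every score — and carry a
flag saying whether their sum is within 0.5% of 1.

All weight arithmetic is exact: weights are :class:`fractions.Fraction`
values, so sums, scores and complements carry no floating-point error and
percent rendering is a faithful half-up (or truncating) decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

from .dataset_io import CountingDataset, DatasetValidationError, VariableRecord

__all__ = [
    "WeightTable",
    "relative_weights",
    "prevalence_weight",
    "load_supplied_weights",
    "render_percent",
]

#: supplied tables whose weights sum to within this band of 1 count as
#: normalized; the band tolerates sub-percent rounding drift in printed tables
NORMALIZED_BAND = (Fraction("0.995"), Fraction("1.005"))


@dataclass(frozen=True)
class WeightTable:
    """Per-variable relative weights for one dataset.

    Attributes
    ----------
    dataset:
        The dataset the weights refer to.
    weights:
        Variable name → weight as an exact fraction in [0, 1].
    provenance:
        ``"computed_from_counts"`` or ``"supplied"``.
    display_precision:
        Decimal places used when rendering weights as percents.
    """

    dataset: CountingDataset
    weights: Mapping[str, Fraction]
    provenance: str
    display_precision: int = 1

    def __post_init__(self) -> None:
        if self.provenance not in ("computed_from_counts", "supplied"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if set(self.weights) != set(self.dataset.names):
            raise DatasetValidationError(
                "weight table does not cover exactly the dataset variables"
            )
        object.__setattr__(
            self, "weights", {n: Fraction(self.weights[n]) for n in self.dataset.names}
        )

    @property
    def total(self) -> Fraction:
        """Exact sum of all weights (1 for computed tables)."""
        return sum(self.weights.values(), Fraction(0))

    @property
    def is_normalized(self) -> bool:
        lo, hi = NORMALIZED_BAND
        return lo <= self.total <= hi

    def __getitem__(self, name: str) -> Fraction:
        return self.weights[name]

    def percent(self, name: str, mode: str = "half_up") -> str:
        """Weight of ``name`` rendered as a percent string."""
        return render_percent(self.weights[name], self.display_precision, mode)

    def items(self):
        """(name, weight) pairs in dataset order."""
        return [(n, self.weights[n]) for n in self.dataset.names]


def relative_weights(dataset: CountingDataset) -> WeightTable:
    """Compute relative weights from patient counts.

    Every variable must carry a count and at least one count must be
    positive.  The result sums to exactly 1.

    Examples
    --------
    A 15-symptom cohort whose counts sum to 279 gives the low-grade fever
    variable (46 patients) weight 46/279 ≈ 0.1649, rendered ``"16.5%"``.
    """
    missing = [rec.name for rec in dataset.variables if rec.count is None]
    if missing:
        raise DatasetValidationError(
            f"cannot compute relative weights: no count for {missing[0]!r}"
            + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else "")
        )
    total = sum(rec.count for rec in dataset.variables)  # type: ignore[misc]
    if total == 0:
        raise DatasetValidationError(
            "degenerate dataset: all counts are zero, weights undefined"
        )
    return WeightTable(
        dataset=dataset,
        weights={
            rec.name: Fraction(rec.count, total) for rec in dataset.variables  # type: ignore[arg-type]
        },
        provenance="computed_from_counts",
    )


def prevalence_weight(record: VariableRecord, total_patients: int) -> Fraction:
    """count / cohort size — the fraction of patients showing the variable.

    Distinct from the relative weight: a cohort of 112 patients with 14
    showing abdominal pain gives prevalence 14/112 = 12.5%, while the same
    variable's relative weight divides by the sum of all variable counts.
    """
    if total_patients <= 0:
        raise DatasetValidationError(
            f"total_patients must be positive, got {total_patients}"
        )
    if record.count is None:
        raise DatasetValidationError(f"{record.name!r} has no count")
    if record.count > total_patients:
        raise DatasetValidationError(
            f"{record.name!r}: count {record.count} exceeds "
            f"total_patients {total_patients}"
        )
    return Fraction(record.count, total_patients)


def load_supplied_weights(dataset: CountingDataset) -> WeightTable:
    """Adopt pre-tabulated percent weights verbatim.

    The percents are divided by 100 and kept exactly as printed: a table
    summing to 103.2% loads with total 1.032 and ``is_normalized`` False.
    Zero weights are retained — the variables stay in the table and simply
    contribute nothing to any score.
    """
    missing = [rec.name for rec in dataset.variables if rec.weight_pct is None]
    if missing:
        raise DatasetValidationError(
            f"cannot load supplied weights: no weight_pct for {missing[0]!r}"
        )
    return WeightTable(
        dataset=dataset,
        weights={
            rec.name: Fraction(Decimal(repr(float(rec.weight_pct)))) / 100
            for rec in dataset.variables
        },
        provenance="supplied",
    )


def render_percent(
    fraction, precision: int = 1, mode: str = "half_up", compact: bool = False
) -> str:
    """Render a fraction as a percent string, e.g. ``Fraction(46, 279)`` →
    ``"16.5%"``.

    ``mode`` is ``"half_up"`` (commercial rounding, matches printed clinical
    tables) or ``"truncate"``.  ``compact`` drops a trailing ``.0``/zeros so
    a full weight prints ``"100%"``.
    """
    if precision < 0:
        raise ValueError("precision must be >= 0")
    if mode not in ("half_up", "truncate"):
        raise ValueError(f"unknown rounding mode {mode!r}")
    if isinstance(fraction, float):
        value = Fraction(Decimal(repr(fraction)))
    else:
        value = Fraction(fraction)
    quantum = Decimal(1).scaleb(-precision)
    dec = (
        Decimal(value.numerator * 100) / Decimal(value.denominator)
    ).quantize(quantum, rounding=ROUND_HALF_UP if mode == "half_up" else ROUND_DOWN)
    text = f"{dec:f}"
    if compact and "." in text:
        text = text.rstrip("0").rstrip(".")
    return text + "%"
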