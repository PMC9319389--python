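"""Exhaustive enumeration of all 2^k presence profiles with their scores.

For a dataset with k binary variables there are 2^k presence profiles; the
*explanation table* lists every one with its +LR/−LR.  At k = 19 that is
524,288 rows, so the table is produced as a lazy row stream (O(k) memory)
and written incrementally, never materialised.

Row order is plain binary counting: treating absence as a 1-bit and the
last listed variable as the least-significant bit, explanation number n
(1-based) encodes the bit pattern n − 1.  Explanation 1 is therefore the
all-present profile and explanation 2^k the all-absent one, matching the
end rows of published tables; middle-row numbering is this package's own
convention, so rows should be matched by profile content, not by index.

Scores are exact fractions.  The enumerator keeps a running sum updated by
the bits that flip between consecutive profiles (amortised O(1) flips per
row), so streaming the full 19-variable table takes seconds.
"""

from __future__ import annotations

import csv
import heapq
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence

from .dataset_io import CountingDataset, DatasetValidationError, PresenceProfile
from .scoring import MODES
from .weights import WeightTable, render_percent

__all__ = [
    "ExplanationRow",
    "ExplanationTable",
    "enumerate_profiles",
    "lookup",
    "top_k",
    "write_table",
    "read_table",
]

#: refuse to enumerate beyond 2^24 rows unless forced
DEFAULT_MAX_VARIABLES = 24


@dataclass(frozen=True)
class ExplanationRow:
    """One line of the explanation table."""

    number: int                     # 1-based explanation number
    statuses: tuple[bool, ...]      # presence flags in dataset order
    positive_lr: Fraction
    negative_lr: Fraction

    def percents(self, precision: int = 1, compact: bool = False) -> tuple[str, str]:
        return (
            render_percent(self.positive_lr, precision, compact=compact),
            render_percent(self.negative_lr, precision, compact=compact),
        )


@dataclass
class ExplanationTable:
    """A lazily evaluated explanation table.

    Iterating yields :class:`ExplanationRow` in the requested order.  The
    iterator can be consumed once per call to :func:`enumerate_profiles`.
    """

    dataset: CountingDataset
    weights: WeightTable
    mode: str
    order: str
    rows: Iterator[ExplanationRow]
    total_rows: int

    def __iter__(self) -> Iterator[ExplanationRow]:
        return self.rows


def _check(weights: WeightTable, mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _row_scores(
    present_sum: Fraction, total: Fraction, mode: str
) -> tuple[Fraction, Fraction]:
    if mode == "sum_present":
        positive = present_sum
    else:  # complement: 1 - sum of absent weights
        positive = 1 - (total - present_sum)
    return positive, 1 - positive


def _number_to_statuses(number: int, k: int) -> tuple[bool, ...]:
    """Explanation number → presence flags (absence bits count upward)."""
    bits = number - 1
    return tuple(not (bits >> (k - 1 - j)) & 1 for j in range(k))


def _statuses_to_number(statuses: Sequence[bool]) -> int:
    bits = 0
    for s in statuses:
        bits = (bits << 1) | (0 if s else 1)
    return bits + 1


def enumerate_profiles(
    dataset: CountingDataset,
    weights: WeightTable,
    mode: str = "sum_present",
    order: str = "binary",
    max_variables: int = DEFAULT_MAX_VARIABLES,
    force: bool = False,
) -> ExplanationTable:
    """Stream all 2^k profiles of a dataset with their scores.

    Parameters
    ----------
    order:
        ``"binary"`` — counting order, all-present first (explanation 1),
        all-absent last (explanation 2^k).  ``"by_lr_desc"`` — highest +LR
        first, ties broken by explanation number (requires materialising
        the table, so it is limited to k ≤ 20).
    max_variables, force:
        Datasets beyond ``max_variables`` variables are refused with a size
        estimate unless ``force`` is given.
    """
    _check(weights, mode)
    if dataset.names != weights.dataset.names:
        raise DatasetValidationError(
            "weight table does not cover this dataset's variables"
        )
    k = len(dataset)
    if k > max_variables and not force:
        raise ValueError(
            f"enumeration over {k} variables would produce 2^{k} = {2**k:,} "
            f"rows (limit 2^{max_variables}); pass force=True to proceed"
        )
    if order not in ("binary", "by_lr_desc"):
        raise ValueError(f"unknown order {order!r}")

    if order == "by_lr_desc":
        if k > 20:
            raise ValueError("by_lr_desc order requires k <= 20")
        rows = iter(
            sorted(
                _binary_rows(dataset, weights, mode),
                key=lambda r: (-r.positive_lr, r.number),
            )
        )
    else:
        rows = _binary_rows(dataset, weights, mode)
    return ExplanationTable(
        dataset=dataset,
        weights=weights,
        mode=mode,
        order=order,
        rows=rows,
        total_rows=2**k,
    )


def _binary_rows(
    dataset: CountingDataset, weights: WeightTable, mode: str
) -> Iterator[ExplanationRow]:
    k = len(dataset)
    w = [weights[n] for n in dataset.names]  # dataset order; index j, LSB = j=k-1
    total = weights.total
    statuses = [True] * k
    present_sum = total
    number = 1
    while True:
        positive, negative = _row_scores(present_sum, total, mode)
        yield ExplanationRow(number, tuple(statuses), positive, negative)
        if number == 2**k:
            return
        # binary increment of the absence bits: flip trailing present→absent
        # runs; amortised O(1) flips per row
        j = k - 1
        while not statuses[j]:
            statuses[j] = True
            present_sum += w[j]
            j -= 1
        statuses[j] = False
        present_sum -= w[j]
        number += 1


def lookup(
    profile: PresenceProfile, weights: WeightTable, mode: str = "sum_present"
) -> ExplanationRow:
    """Return the explanation-table row of one profile in O(k)."""
    _check(weights, mode)
    if profile.dataset.names != weights.dataset.names:
        raise DatasetValidationError(
            "profile and weight table refer to different datasets"
        )
    statuses = profile.statuses()
    present_sum = sum(
        (w for s, (n, w) in zip(statuses, weights.items()) if s), Fraction(0)
    )
    positive, negative = _row_scores(present_sum, weights.total, mode)
    return ExplanationRow(
        _statuses_to_number(statuses), statuses, positive, negative
    )


def top_k(
    weights: WeightTable, mode: str = "sum_present", k_rows: int = 1
) -> list[ExplanationRow]:
    """The ``k_rows`` profiles with highest +LR, ties broken by explanation
    number.

    In sum_present mode high +LR means dropping the smallest weights first,
    so the rows are found by lazily enumerating subsets of absent variables
    in increasing weight-sum order (a k-smallest-subset-sums walk) — no full
    enumeration.  In complement mode the ranking is identical because both
    scores decrease by exactly the dropped weights' sum.
    """
    _check(weights, mode)
    if k_rows < 1:
        raise ValueError("k_rows must be >= 1")
    dataset = weights.dataset
    k = len(dataset)
    n_rows = min(k_rows, 2**k)
    total = weights.total
    # absent-subset sums, smallest first; indices sorted by (weight, position)
    order = sorted(range(k), key=lambda j: (weights[dataset.names[j]], j))
    w = [weights[dataset.names[o]] for o in order]

    def number_of(absent: tuple[int, ...]) -> int:
        statuses = [True] * k
        for idx in absent:
            statuses[order[idx]] = False
        return _statuses_to_number(statuses)

    # heap over (absent-sum, explanation number, absent index tuple); ties in
    # sum are collected fully, then cut by number, so equal-weight variables
    # resolve deterministically
    heap: list[tuple[Fraction, int, tuple[int, ...]]] = [
        (Fraction(0), 1, ())
    ]
    popped: list[tuple[Fraction, int, tuple[int, ...]]] = []
    while heap and (
        len(popped) < n_rows or heap[0][0] == popped[n_rows - 1][0]
    ):
        s, num, absent = heapq.heappop(heap)
        popped.append((s, num, absent))
        last = absent[-1] if absent else -1
        if last + 1 < k:
            grown = absent + (last + 1,)
            heapq.heappush(heap, (s + w[last + 1], number_of(grown), grown))
            if absent:
                swapped = absent[:-1] + (last + 1,)
                heapq.heappush(
                    heap, (s - w[last] + w[last + 1], number_of(swapped), swapped)
                )
    popped.sort()
    selected = popped[:n_rows]

    rows = []
    for s, num, absent in selected:
        statuses = _number_to_statuses(num, k)
        positive, negative = _row_scores(total - s, total, mode)
        rows.append(ExplanationRow(num, statuses, positive, negative))
    return rows


# ---------------------------------------------------------------------------
# export / import


def write_table(
    table: ExplanationTable,
    path: str | Path,
    dialect: str = "tsv",
    precision: int = 1,
    compact: bool = False,
) -> Path:
    """Write an explanation table incrementally as delimited text.

    Columns: explanation_number, one ±-status column per variable (in
    dataset order), then +LR(%) and −LR(%).
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    delimiter = "\t" if dialect == "tsv" else ","
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            ["explanation_number", *table.dataset.names, "+LR(%)", "-LR(%)"]
        )
        for row in table:
            pos, neg = row.percents(precision, compact=compact)
            writer.writerow(
                [
                    row.number,
                    *("+" if s else "-" for s in row.statuses),
                    pos.rstrip("%"),
                    neg.rstrip("%"),
                ]
            )
    return path


def read_table(
    path: str | Path, dialect: str = "tsv"
) -> list[tuple[int, tuple[bool, ...], str, str]]:
    """Read back an exported table as (number, statuses, +LR%, −LR%) rows."""
    delimiter = "\t" if dialect == "tsv" else ","
    rows = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader)
        n_vars = len(header) - 3
        for rec in reader:
            rows.append(
                (
                    int(rec[0]),
                    tuple(cell == "+" for cell in rec[1 : 1 + n_vars]),
                    rec[-2],
                    rec[-1],
                )
            )
    return rows
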