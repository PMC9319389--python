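"""Seeded synthetic counting datasets and patient profiles.

Property tests need counting datasets with controlled structure — variable
counts, optional exclusive groups, normalized or deliberately non-normalized
supplied weight tables — without depending on any particular cohort.  This
module generates them reproducibly: one integer seed drives a dedicated
:class:`numpy.random.Generator` per call, so identical spec + seed give
identical output on every platform and no generator state is shared between
operations.

Two count laws are supported:

``uniform``
    independent integer counts drawn uniformly from ``count_range``;
``multinomial``
    a fixed ``total_patients`` allocated across variables with proportions
    drawn from a symmetric Dirichlet with ``concentration`` α — small α
    gives a few dominant variables (like real symptom tables, where a
    handful of findings carry most of the weight), large α near-equal
    counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .dataset_io import CountingDataset, PresenceProfile, VariableRecord
from .weights import WeightTable

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "generate_supplied_weights",
    "sample_profiles",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic counting dataset.

    Attributes
    ----------
    n_variables:
        Number of binary variables.
    total_patients:
        Cohort size (also the multinomial total).
    count_law:
        ``"uniform"`` or ``"multinomial"`` (see module docstring).
    count_range:
        Inclusive (low, high) for the uniform law.
    concentration:
        Dirichlet α for the multinomial law.
    group_sizes:
        Optional sizes of leading exclusive variable families, e.g.
        ``(3, 4)`` marks variables 1–3 as group "g1" and 4–7 as "g2";
        remaining variables are ungrouped.
    seed:
        Integer seed; identical spec + seed → identical dataset.
    """

    n_variables: int
    total_patients: int = 112
    count_law: str = "multinomial"
    count_range: tuple[int, int] = (0, 50)
    concentration: float = 1.0
    group_sizes: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")
        if self.total_patients < 1:
            raise ValueError("total_patients must be >= 1")
        if self.count_law not in ("uniform", "multinomial"):
            raise ValueError(f"unknown count_law {self.count_law!r}")
        if sum(self.group_sizes) > self.n_variables:
            raise ValueError("group_sizes exceed n_variables")


def _group_labels(spec: SyntheticSpec) -> list[str | None]:
    labels: list[str | None] = []
    for gi, size in enumerate(spec.group_sizes, start=1):
        labels.extend([f"g{gi}"] * size)
    labels.extend([None] * (spec.n_variables - len(labels)))
    return labels


def generate_dataset(spec: SyntheticSpec) -> CountingDataset:
    """Draw a counting dataset according to ``spec``.

    At least one count is forced positive so relative weights are always
    defined downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variables
    if spec.count_law == "uniform":
        lo, hi = spec.count_range
        counts = rng.integers(lo, hi + 1, size=n)
    else:
        props = rng.dirichlet(np.full(n, spec.concentration))
        counts = rng.multinomial(spec.total_patients, props)
    counts = counts.astype(int)
    if counts.sum() == 0:
        counts[int(rng.integers(0, n))] = 1
    labels = _group_labels(spec)
    return CountingDataset(
        variables=tuple(
            VariableRecord(name=f"var{i + 1:02d}", group=labels[i], count=int(counts[i]))
            for i in range(n)
        ),
        total_patients=spec.total_patients,
        source_kind="symptoms",
        name=f"synthetic-{spec.seed}",
    )


def generate_supplied_weights(
    spec: SyntheticSpec, normalized: bool = True
) -> WeightTable:
    """Draw a supplied weight table (percents at 1 dp).

    With ``normalized=True`` the percents sum to exactly 100.0; otherwise a
    random off-by-a-few-percent excess or deficit is applied, producing the
    kind of non-normalized published table on which sum-of-present and
    complement scoring disagree and out-of-range warnings fire.
    """
    from .weights import load_supplied_weights

    rng = np.random.default_rng(spec.seed)
    n = spec.n_variables
    props = rng.dirichlet(np.full(n, max(spec.concentration, 0.2)))
    # integer tenths-of-a-percent so the table is exactly representable
    tenths = np.floor(props * 1000).astype(int)
    tenths[0] += 1000 - tenths.sum()  # exact 100.0 total
    if not normalized:
        # perturb by ±(1..50) tenths, keeping each weight in [0, 100]
        offset = int(rng.integers(1, 51)) * (1 if rng.integers(0, 2) else -1)
        top = int(np.argmax(tenths))
        if not 0 <= tenths[top] + offset <= 1000:
            offset = -offset
        tenths[top] += offset
    labels = _group_labels(spec)
    dataset = CountingDataset(
        variables=tuple(
            VariableRecord(
                name=f"var{i + 1:02d}", group=labels[i], weight_pct=int(tenths[i]) / 10
            )
            for i in range(n)
        ),
        total_patients=spec.total_patients,
        source_kind="symptoms",
        name=f"synthetic-weights-{spec.seed}",
    )
    return load_supplied_weights(dataset)


def sample_profiles(
    dataset: CountingDataset,
    prevalences,
    n_patients: int,
    seed: int = 0,
) -> list[PresenceProfile]:
    """Draw presence profiles with independent per-variable prevalence.

    ``prevalences`` is either a single fraction applied to every variable or
    a mapping/sequence of per-variable fractions in [0, 1], aligned to
    dataset order.  Empirical prevalence converges to the stated one as
    ``n_patients`` grows (binomial sampling).
    """
    names = dataset.names
    if isinstance(prevalences, (int, float, Fraction)):
        p = np.full(len(names), float(prevalences))
    elif isinstance(prevalences, dict):
        p = np.array([float(prevalences[n]) for n in names])
    else:
        p = np.asarray([float(x) for x in prevalences], dtype=float)
    if p.shape != (len(names),):
        raise ValueError("prevalences must cover every dataset variable")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("prevalences must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((n_patients, len(names))) < p
    return [
        PresenceProfile(
            dataset=dataset,
            presence={n: bool(row[j]) for j, n in enumerate(names)},
        )
        for row in draws
    ]
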