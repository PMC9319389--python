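# Methods

## Model

`relw` scores presence/absence profiles of binary diagnostic variables with
an additive weight model. For a counting dataset over variables
v₁…v_k with patient counts c₁…c_k, the relative weight of variable i is
wᵢ = cᵢ / Σⱼ cⱼ. A profile P ⊆ {v₁…v_k} of present variables scores

- sum-of-present mode: `+LR(P) = Σ_{v ∈ P} w(v)`, `−LR = 1 − (+LR)`;
- complement mode: `+LR(P) = 1 − Σ_{v ∉ P} w(v)`.

The model assumes variables are binary, that a variable's importance is
proportional to its prevalence among all variable observations in the
cohort, and that contributions add with no interaction terms. It is an
explanation layer over a separate classifier, not a classifier itself: the
"+LR/−LR" labels follow the clinical tables this scheme reproduces, but the
quantities are additive shares of total weight, not Bayesian likelihood
ratios — no sensitivity/specificity enters.

The two modes coincide exactly when Σ wᵢ = 1, which always holds for
computed weights. They matter for *supplied* weight tables: published
percent tables are adopted verbatim (a table summing to 103.2% loads with
total 1.032 and a non-normalized flag). Renormalizing such a table would
silently change every published score, so the package never does;
out-of-range scores (e.g. +LR 103.2% for the all-present profile) are
reported with a warning rather than clamped. All-but-one-present rows of
such tables are only reproducible in complement mode, which is why both
modes are first-class.

A separate *prevalence weight*, count(v)/N for a cohort of N patients, is
reported per variable for epidemiological context; it plays no role in
scoring.

## Numerical choices

- **Exact rational arithmetic.** Weights are `fractions.Fraction`; counts
  give cᵢ/Σc exactly and supplied percents give p/100 via an exact decimal
  conversion. Sums, complements and enumeration are therefore exact:
  `+LR + (−LR) = 1` holds with equality, not to a tolerance.
- **Rounding is display-only.** Percents render at 1 decimal place by
  default with half-up rounding (this reproduces every cell of the bundled
  published weight table from its raw counts); a truncating mode is
  available. Compact rendering drops trailing `.0` ("100%", "0%"), matching
  how published tables print their end rows.
- **Degenerate inputs.** All-zero counts are a hard error (weights
  undefined); zero-weight variables in supplied tables are kept and
  contribute 0. Missing counts are reported by variable name.
- **Tie-breaks.** Contribution ranking orders equal weights by dataset
  position; top-k rows break score ties by ascending explanation number.

## Enumeration

The explanation table over k variables has 2^k rows and is produced as a
lazy stream in binary-counting order: treating absence as a set bit with
the last listed variable least significant, explanation 1 is the
all-present profile and explanation 2^k the all-absent one — matching the
end rows of published tables, whose middle-row ordering is not inferable
and is replaced by this documented convention. The streaming enumerator
updates the running weight sum only at bit flips (amortised O(1) per row)
and uses O(k) memory; the 19-variable table (524,288 rows) streams in a few
seconds. Row lookup for a single profile is O(k). Top-k rows are found with
a lazy k-smallest-subset-sums walk over the dropped-variable lattice, so no
full enumeration is needed. A size guard refuses k > 24 unless forced.

## Bundled cohort and its quirks

`relw.data` bundles a published COVID-19 cohort of 112 patients: a
15-variable symptom counting table (counts summing to 279) with its
published weight table (Σ = 100.0%), and a 19-finding chest-CT weight table
(Σ = 103.2%, supplied verbatim; its derivation from the per-variable
min/max prevalence bounds that accompany it was not published and is not
reconstructed). Known quirks, preserved deliberately:

- The symptom worked example's published addend list contains five percent
  terms for four named symptoms (the dry-cough term appears twice).
  `scoring.score_addends` sums an explicit addend list with repeats allowed
  and reproduces the published 60.3%; scoring the four distinct symptoms as
  a profile gives 43.1% with the published weights (43.0% from raw counts).
- The CT min/max prevalence bounds are stored as ordered (lo, hi) pairs;
  the source prints the two readings in inconsistent column order for some
  variables.
- Fever is represented as three exclusive grade variables. Profiles with
  two grades present exist in the lattice; the opt-in strict group check
  (`PresenceProfile.check_groups_exclusive`) rejects them.

## Synthetic data

The `synthetic` module generates counting datasets for property testing:
counts either uniform on an integer range or multinomial over a fixed
cohort total (default 112, the bundled cohort's size) with
Dirichlet-distributed proportions — concentration α = 1 by default; small α
mimics real symptom tables where a few findings dominate. It also draws
supplied weight tables at 1-dp percent resolution, either summing to
exactly 100.0 or deliberately perturbed off 100 to exercise the
non-normalized warning path, and samples patient profiles with independent
per-variable prevalence. A single integer seed drives a dedicated
`numpy.random.Generator` per call, so identical spec + seed give identical
output and no state leaks between operations.

What the generator does *not* emulate: correlated symptoms, group-exclusive
presence structure in sampled profiles, reader disagreement, or any
disease-status labels. Passing property tests therefore demonstrate the
algebraic contracts of the pipeline (normalization, complementarity,
monotonicity, mode equivalence, oracle agreement), not clinical validity on
real data.

## Problem sizes used in tests

Exhaustive oracle cross-checks run at k ≤ 10 (all 2^k profiles re-summed
independently); the full 2^15 symptom lattice and the streamed 2^19 CT
lattice are exercised once each; lookup-vs-stream agreement is sampled at
500 random rows of the 2^15 table.

## Limitations

- Weight quality is bounded by the counting dataset: reader-dependent image
  findings give reader-dependent weights.
- Additivity ignores symptom interactions and double-counts overlapping
  findings.
- Supplied tables are trusted verbatim; the package flags but cannot repair
  a table that does not sum to 100%.
- The explanation-table row numbering is a package convention; match rows
  by profile content when comparing against externally printed tables.
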