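# Methods

## Setting

The package scores staged one-on-one encounters between two ant workers (or
other dyads) that were coded second by second on an ordinal behaviour scale
from −4 to +5: negative scores are peaceful behaviours (−4 trophallaxis, −3
allogrooming, −2 antennation, −1 sitting next to each other), 0 is ignoring,
and positive scores are aggressive behaviours (1 avoiding, 2 mandible
threatening, 3/4 fighting without/with gaster flexion, 5 killing). The
default scored encounter length is `T_obs = 170` s; an acclimatisation
window is assumed to have been removed before the data reach this package.
Killing is absorbing: once score 5 occurs, all remaining seconds belong to
it and the reader rejects (or, with `repair_kill`, forward-fills)
series that violate this.

Every index depends on the data only through the **duration profile** — the
map from score to total seconds — so `DurationProfile` is the central
in-memory object and all index functions accept either a profile or a raw
per-second series.

## The five indices

For one worker with durations `t_s` at score `s` and `T = Σ_{s≠0} t_s`:

* **AI** (Aggression Index): `AI = Σ_{s≠0} s·t_s / T`, the duration-weighted
  mean score over seconds of interaction. Ignoring (score 0) is excluded
  from numerator and denominator; every other behaviour, including the
  non-contact ones (avoiding, sitting nearby), is included, and killing
  seconds count at score 5. An all-ignoring worker has no AI; the value is
  reported as missing (NaN), never as 0, and missing values are dropped
  from means with a count in the simulation summary.
* **MMAI**: the maximum score displayed for at least one second. Negative
  when only peaceful behaviour occurred.
* **MMPI**: the minimum score displayed for at least one second; the
  peaceful counterpart of MMAI.
* **MBI** at time threshold `t` (integer seconds, `0 ≤ t ≤ T_obs`): with
  `d_agg = Σ_{s>0} t_s` and `d_pcf = Σ_{s<0} t_s`,

  1. killing occurred → 5;
  2. `d_agg > t` and `d_pcf ≤ t` → MMAI (aggression dominated);
  3. `d_pcf > t` and `d_agg ≤ t` → MMPI (peace dominated);
  4. both `> t` → (MMAI + MMPI)/2 (switching between both);
  5. neither `> t` → 0 (ignoring dominated).

  All comparisons are strict (`d = t` does not count as dominating).
  **MBI_agg** and **MBI_pcf** are MBI evaluated at two thresholds chosen
  separately (below).

Aggregation is equal-weight averaging, worker → encounter → pairing mean
over replicates. In the balanced designs this package targets, that order
coincides with a pooled mean.

`near_tie_fraction` reports the fraction of encounters with
`|d_agg − d_pcf| < δ` (default δ = 10 s, strict): the regime where AI is
least informative because aggression and peace cancel.

## Empirical threshold selection

`thresholds.scan` computes the encounter-level MBI for every integer
`t ∈ {0, …, T_obs}`, classifies each encounter by sign (`>0` aggressive,
`<0` peaceful, `0` neutral), and records the two count curves. The
classification happens after worker averaging and before replicate
averaging: the scan counts encounters, not pairings. `thresholds.select`
takes, per class, the lowest `t` attaining the maximum count (first argmax;
ties always resolve toward smaller `t`). Thresholds are meant to be chosen
on internest encounters only — the CLI enforces this filter, the library
leaves the choice of input to the caller. No smoothing or formal
inflection-point estimation is done; the rule is a plain first argmax, and
the curves are not assumed monotone.

Degenerate case: if a class never occurs (no aggressive encounter in a
purely peaceful data set), its maximum count is 0 and every `t` is an
argmax; `select` then returns `t = 0` with a warning. In such data the MBI
is insensitive to the choice for all `t` below the encounter length, so the
convention is inconsequential downstream.

## Encounter simulator

The generator covers eight scenarios defined by which behaviour classes may
occur (P = −4…−1, I = 0, A = 1…4, K = 5): P, P+I, P+I+A, P+I+A+K, I+A,
I+A+K, A, A+K. One encounter is generated by drawing behaviours uniformly
*without replacement* from the allowed scores and assigning each a random
duration until one of three stop rules fires: (i) the 170 s budget is
exhausted (remaining behaviours get 0 s), (ii) only one behaviour is left
(it takes the remainder), (iii) killing is drawn (it immediately absorbs all
remaining seconds, even as the first draw).

The duration draw is governed by `duration_rule`:

* `"remaining"` (default): uniform on `{1, …, seconds still unassigned}`;
* `"capped"`: uniform on `{1, …, T_obs}`, truncated to the remaining budget.

The default was an open design choice; we fixed it by behaviour, not by
formula. Under the capped rule the first behaviour drawn takes on average
half the encounter and frequently all of it, so most encounters contain one
or two behaviours and the per-encounter extremes are badly attenuated
(pure-aggression MMAI ≈ 3.57). The remaining-uniform rule spreads time over
most drawn behaviours and yields the dispersion the extreme-value indices
are supposed to probe (pure-aggression MMAI ≈ 3.94, MMPI ≈ 1.05; the mixed
−4…+4 scenario gives ±3.35). Note that E[AI] is rule-invariant: durations
are assigned exchangeably over scores, so the expected duration-weighted
mean equals the plain mean of the allowed nonzero scores (2.5 for pure
aggression) under *any* rule — this is the generator-robust check used in
the tests.

Batch structure follows the study design: a batch is `n_averaged`
(default 10,000) *averaged encounters*, each the index-wise mean of
`replicates_per_averaged` (default 5) independent single-worker encounters.
Averaging happens on index values, not on profiles, matching the procedure
for observed data. A single seeded `numpy.random.Generator` stream drives
each batch; the same seed reproduces the batch exactly.

What the simulator does *not* emulate: temporal bout structure within an
encounter (indices only need durations), correlation between the two
workers of a real encounter (simulated encounters have one virtual worker),
between-replicate correlation within a colony pairing, and day/observer
effects. Passing simulation checks therefore validates the index algebra
and the generator's marginal behaviour, not ecological realism.

## Statistics

The comparison module is deliberately nonparametric, matching field
practice for index values that are bounded, discrete and skewed:
Anderson-Darling as the normality screen (reported as a p band from the
standard critical-value table), Spearman rank correlation between index
pairs, two-sided Wilcoxon-Mann-Whitney on index means (scipy's policy:
exact for small tie-free samples, tie-corrected normal approximation
otherwise — a choice stated in the report metadata since conventions vary),
and step-down Bonferroni-Holm across the family of all pairwise tests
within one data-set × encounter-type block (m = 10 for five indices; the
family size is logged in the report). Mixed-effect modelling of nest and
day effects is out of scope; pairing means feed ordinary descriptive
comparisons only.

## Numerical and design choices

* Seconds are 1-based integers; scores serialise as ASCII integers and
  typographic minus signs are normalised on input.
* The legacy 0–7 scale translates as {0→0, 1→−1, 2→−2, 3→−3, 4→1, 5→2,
  6→3, 7→4}; its category 3 collapses allogrooming and trophallaxis, so
  adapted −4 is unreachable from translated data.
* Encounters carry 1 or 2 scored workers; other counts are rejected rather
  than averaged silently.
* `mbi` validates `0 ≤ t ≤ total_seconds` and raises otherwise.
* Threshold scan grid: integers 0…T_obs inclusive, vectorised over
  (worker, t); the brute-force double loop exists only as a test oracle.
* Test problem sizes: the full-size simulation checks use the study
  conditions (10,000 × 5 × 170 s); property tests and oracle enumerations
  use small profiles (≤ 12 s totals, ≤ 24 s scan horizons) where
  exhaustiveness matters more than scale.

## Known limitations

* The MBI midrange (case 4) discards everything between the extremes; two
  encounters with very different interiors can share an MBI value.
* The first-argmax threshold rule is sensitive to single-encounter noise in
  small data sets; it was chosen for transparency, not robustness.
* AI treats the ordinal scale as interval-scaled (scores are multiplied by
  durations); this is standard for this index but is an assumption, not a
  property of the data.
* The simulator's uniform draw over behaviours has no ethological content;
  it is a coverage device for comparing indices across behaviour-class
  regimes.
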