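# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic-data tests do and do not establish.

## Carrier types and I/O

A recording is a `CountSeries`: naive-local start timestamp, epoch length
in seconds (1, 5, 10, 15, 30 or 60 — every value divides 60 so blocks align
with clock minutes), three non-negative integer axis-count sequences
(axis 1 vertical) and the per-epoch vector magnitude `vm = √(a1²+a2²+a3²)`.
`vm` is stored for convenience (written with two decimals, a vendor
convention) but always recomputed exactly from the axes on read, so it can
never drift from its definition. Timestamps are naive local time because
day boundaries and the 5:00 AM scoring window are clock-defined; timezone
and daylight-saving arithmetic are out of scope.

## Reintegration

Blocks of `k = target/source` consecutive epochs are summed per axis,
aligned to the series start; a trailing partial block is dropped rather
than padded (no counts are fabricated). Two-stage reintegration with
compatible factors equals one-stage, and totals are conserved up to the
dropped tail. The vector magnitude of a collapsed epoch is recomputed from
the summed axes, **not** summed from fine-epoch magnitudes: the norm of a
sum is not the sum of norms (3-4-5 counterexample in the tests). Whether
vendor software recomputes or sums vm on reintegration is not documented;
recomputation is this package's convention.

## Non-wear detection

All detectors read the vertical axis by default (configurable).

**20-min zero run.** Maximal runs of zero-count epochs spanning ≥ 20 min
are non-wear. No allowance, hence practically epoch-invariant: a run's
span changes only by sub-minute truncation at coarse epochs.

**NHANES.** The detector scans candidates consisting of zero epochs plus
*allowance* epochs, and flags candidates spanning ≥ 60 min. Allowance
semantics, where the interesting behavior lives:

* The allowance is a cumulative per-candidate budget of 120 s of nonzero
  time (the 2-minute variant; 1-minute available via parameters). An
  allowance epoch consumes its own duration: a burst confined to one 10-s
  epoch consumes 10 s, but the same counts reintegrated into a 60-s epoch
  consume 60 s. Whether the budget is per-interval or per-spell is
  ambiguous in the literature's prose; the per-interval reading is the one
  consistent with published allowance-accounting examples.
* An epoch is allowance-eligible when `0 < c ≤ 100 · epoch/60` — the
  0–100 counts-per-minute band *scaled to the epoch length*, i.e. the
  algorithm "converted to match the epoch", which is how practitioners
  apply a 60-s-validated algorithm at other epochs. Scaling is the default
  because it is the only reading under which wear-time estimates *rise* at
  fine epochs, the behavior observed in real cohorts: with the band
  unscaled, fine-epoch terminations are a subset of coarse-epoch
  terminations and fine-epoch budget consumption is never larger, so
  detected non-wear at fine epochs is a superset and wear time could only
  fall. `scale_allowance_band=False` selects the unscaled variant.
* A count above the band, or a nonzero epoch the remaining budget cannot
  cover, terminates the candidate at the previous epoch; the zero run
  before the terminator keeps its candidate membership (maximal-interval
  reading), and a new candidate with a fresh budget starts after the
  terminator. Boundary convention: counts exactly at the band bound are
  eligible; eligibility requires `c > 0`.

**Choi.** The published reference implementation collapses all input to
60-s epochs before scanning, so the scan here runs at minute resolution
whatever the input epoch: maximal runs of *eligible* minutes ≥ 90 min are
non-wear, where a minute is eligible if it is zero or belongs to a nonzero
spell of ≤ 2 consecutive minutes (any magnitude — the definition places no
count band on the spell) whose 30 upstream and 30 downstream minutes are
all zero. At recording edges the truncated flank must still be all zero.
The per-minute mask is broadcast back to the source epoch, making daily
wear minutes bit-identical across epoch lengths by construction; epochs
past the last complete minute stay wear.

Masks record each interval as `(start, end)` epoch indices (end exclusive)
plus the allowance seconds consumed. Intervals crossing midnight contribute
to each day separately; daily wear minutes use the full midnight-to-
midnight day, not the scoring window.

## Intensity classification and summaries

Cut-point sets are band upper bounds in counts per validated epoch
(Evenson 25/573/1002 at 15 s vertical; Treuth 50/1499/2600 at 30 s;
Puyau 799/3199/8199 at 60 s; Mattocks 3580/6129 at 60 s with no SB/LPA
split; Romanzini 180/756/1111 at 15 s on the vector magnitude). Conversion
multiplies bounds by `target/validated` and keeps them real-valued
(Puyau's sedentary bound becomes 199.75 at 15 s); classification uses `≤`
against the scaled bound. Real-valued bounds reproduce the canonical
100 ↔ 50 ↔ 25 counts-per-minute equivalences exactly and avoid
integer-rounding gaps; whether vendor software rounds is undocumented, so
the convention is explicit here. Classification at a mismatched epoch
raises — conversion is always explicit.

Scoring-window membership is decided by the epoch's *start* time, and the
"until 11:59 PM" convention is read as end-of-day, so the last 60-s epoch
scored starts at 23:59:00. Non-wear epochs label `NONWEAR` wherever the
mask says so; wear epochs before 5:00 AM label `OUT_OF_WINDOW`; MVPA is
derived as MPA + VPA at summary time.

Daily summaries report percentages relative to **in-window wear minutes**:
classes are only scored in-window, and this is the denominator under which
the class percentages sum to 100. The literature rarely states its
denominator; minutes are always reported alongside so any other
denominator can be derived. A day is valid when its wear time computed at
**60-s epochs** (same algorithm) is ≥ 360 min; the identical day set is
kept at every epoch length, so epoch contrasts never confound day
selection. The cohort-protocol criterion (3 weekdays + 1 weekend day) is
deliberately not a filter — the analysis rule is per-day only.

## Synthetic cohort

The generator's defaults are a stated world, fixed a priori:

* **Behavior**: a renewal sequence over {SB, LPA, MPA, VPA} with
  exponential dwells (means 120, 25, 10, 6 s — long sedentary spans, brief
  intermittent bursts) and iid segment-state draws with entry probabilities
  `q_s ∝ f_s/m_s`, which gives long-run occupancy `f` = 65/25/7/3% of wear
  time by the renewal-reward theorem. The ±2-point occupancy test follows
  from these long-run proportions, not from tuning.
* **Counts**: per-second vertical counts are zero-inflated lognormal per
  state — zero probability 0.85/0.50/0.05/0.02, median 3/35/55/92, σ
  0.4/0.5/0.25/0.3. Closed-form moments put the within-state 15-s sums
  near 7, 297, 809 and 1415 counts with window SDs of roughly 4, 96, 71
  and 123 — each ≥ 2.7 SDs inside its Evenson band, which is what the
  ≥ 95% band-containment test checks. Lateral axes are Poisson with mean
  `0.5 · axis1`, so vm ≈ 1.22 × vertical on average.
* **Wear**: 24-h wear (children sleep with the device) with one midday
  non-wear episode (15:00, 150 min, probability 0.8 per day) to exercise
  the detectors, plus spurious artifact counts during true non-wear: single
  seconds at 1 event/h with magnitude uniform on {1..100}. These sit inside
  the 0–100 allowance band at a 60-s epoch but above the scaled band at
  fine epochs — the mechanism that makes NHANES wear time epoch-dependent.
* **Seeding**: per-subject generators come from
  `SeedSequence([master_seed, subject_index])`, so streams are
  reproducible, order-independent and collision-free.

What the generator does *not* emulate: diurnal activity rhythms, bouted
MVPA structure, inter-subject heterogeneity in activity level (all
subjects share one behavioral law; between-subject variance arises only
from sampling noise and episode occurrence), autocorrelated counts within
a state, device saturation, or realistic sleep (near-zero but nonzero
movement). Green cohort tests therefore establish that the *algorithms*
interact with epoch length and cut-points as described — not that the
simulated estimates match any particular population's magnitudes, which
are cohort-specific.

## Statistical comparison

Estimates enter comparisons as per-subject means over valid days. The F
test is a one-way fixed-factor ANOVA across levels (epoch lengths, or
cut-point sets at their validated epochs); this matches how such results
are usually presented, though it ignores that subjects repeat across
levels — a repeated-measures variant (`repeated=True`) is provided. Family
significance uses Bonferroni: α = 0.05/11 by epoch (wear time plus five
classes in minutes and percent) and α = 0.05/10 by cut-point. Post-hoc
contrasts are paired t tests on per-subject differences against the
validated epoch (60 s for the wear-time algorithms; the zero-run algorithm
has no derived epoch and uses 60 s by convention), reported raw and judged
against the family α. Degenerate inputs are handled without blow-ups: an
all-identical table returns F = 0, p = 1, and a zero-variance paired
difference reports p = 1 when the mean difference is 0 and p = 0
otherwise. The Mattocks set is excluded from SB and LPA comparisons; when
an exclusion leaves fewer than two comparable sets the estimates are still
reported and the untestable F is skipped. Family-level clustering of
subjects (siblings) is ignored by design.

## Numerical notes

* Detectors are O(n) — the NHANES scan visits only nonzero epochs — so the
  default 50 × 7-day cohort processes through the full grid in ~1.5 s per
  subject on one CPU.
* Daily tallies use `bincount` over day × label keys; results are exact
  integer counts scaled by `epoch/60`.
* All detector masks, summary tables and report CSVs are byte-deterministic
  for a given input and seed.
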