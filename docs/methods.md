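# Methods

This note records the modelling and numerical choices behind `encounterdq`:
what the quality rules compute, how the control-chart and pre-post
statistics are defined, what the synthetic cohort generator does and does
not emulate, and where the design was genuinely open.

## 1. Record model and quality rules

A dataset is one CSV row per clinical encounter (`record_id`, `user_id`,
`profession`, `encounter_type` ∈ {initial, follow_up}, `appointment_date`,
`entry_date`, `referral_date`, `referral_source`, `visit_reason`,
`no_show`). Dates are ISO-8601 only; empty strings denote missing optional
values. The referral date `1900-01-01` is a *sentinel*, not missingness: it
is what the source system stores when a user selects "I do not know the
referral date", and the I/O layer preserves it verbatim because the
completeness analysis hinges on it.

The three predicates are deterministic functions of a single record:

- **same_day**: `entry_date == appointment_date`.
- **complete**: every required field non-missing, `visit_reason != "other"`,
  and for initial encounters a non-missing referral source *and* a known
  (non-sentinel) referral date. The default required set is
  {user_id, encounter_type, appointment_date, entry_date, visit_reason};
  it is configurable because real reporting forms carry more fields than
  this schema.
- **valid**: (1) `appointment_date <= entry_date`; (2) appointment strictly
  after 2008-01-01; (3) `entry_date < appointment_date + 4 months`;
  (4) if a known referral date exists,
  `appointment_date <= referral_date + 6 months`.

Three readings deserve justification:

- Rule (1) is non-strict. Same-day entry dominates these systems (half to
  three-quarters of entries) while validity runs ≈99%; a strict "before"
  would classify every same-day entry invalid, which is self-contradictory
  for a system that counts same-day entry as its timeliness goal.
- Rule (2) is strict: an appointment on exactly 2008-01-01 is invalid.
- Rules (3) and (4) use calendar-month advancement (add N to the month,
  clamp the day to the target month's length — `2016-10-31 + 4 months =
  2017-02-28`), strict for the 4-month rule and non-strict for the 6-month
  rule. Month-based wording of clinical rules has no canonical day count;
  calendar arithmetic is deterministic and matches clinical usage. The
  6-month rule is skipped for sentinel referral dates: an unknown date
  cannot be evaluated, and penalizing it would double-count the
  completeness rule.

Aggregation emits percentages (100 × flagged / n) per user, per calendar
month of the *appointment* date, or per (user, pre/post window). Windows
are `[intervention − 56 d, intervention)` and `[intervention,
intervention + 56 d)` — eight weeks each — assigned by appointment date,
because the measures describe encounters rather than data-entry events.
Groups with zero records are omitted rather than emitted as 0/0.

## 2. XmR charts

For values x with moving ranges mRᵢ = |xᵢ₊₁ − xᵢ|: center X̄, limits
X̄ ± 2.66·m̄R on the X chart and 3.267·m̄R on the mR chart. The constants
are the standard individuals-chart factors 3/d₂ (d₂ = 1.128 for subgroups
of two) and D₄ (n = 2). Signals are points *strictly* outside the limits —
a point exactly on a limit is chance variation. Only the beyond-limits rule
is implemented; run/zone rules are deliberately out of scope because the
analysis this package supports uses control-limit crossings only.

Numerical choices: limits are not clamped to [0, 100] for percentage data
(a negative LCL means no lower signal is reachable, which is standard
practice); all points feed the limit statistics by default (retrospective
analysis of a closed study window), with `baseline_n` available to freeze
limits on an initial segment for prospective monitoring; a constant series
collapses X̄ = UCL = LCL with no signals. Because m̄R depends on adjacency,
limits are order-dependent — reordering a series changes them, which is a
property of the method, not a bug.

## 3. Paired pre-post statistics

Per-user paired differences D (post − pre window averages) give
t = D̄/(s_D/√n) with the n−1 standard deviation, two-sided p on n−1 degrees
of freedom, and Cohen's d = D̄/s_D, so t = d·√n identically. Zero-variance
differences raise a degenerate-variance error instead of returning NaN.
Users with records in only one window are excluded from pairing and
counted.

Achieved power is the two-sided normal approximation

    power = Φ(|d|·√n − z_{1−α/2}),

which treats |d|·√n as the noncentrality and drops the far-tail term
Φ(−|d|·√n − z); at d = 0 it equals α/2. An exact noncentral-t power
(`method="nct"`) is provided for comparison; the normal approximation is
the default because it is the convention this package standardizes on for
reporting achieved power alongside paired t tests at n ≈ 50, where the two
differ by under 0.02. Two-sided tests and α = .05 throughout; no
multiplicity correction is applied across the three measures.

The volume comparison applies the same machinery to per-user entry counts
per window, as a check that a quality change is not an artifact of changed
workload.

## 4. Synthetic cohort generator

The generator produces record-level data whose aggregate behavior matches
what the pipeline is designed to detect. Per user and Monday-started week,
an encounter count is drawn Poisson(`entries_per_user_week`), scaled by the
fraction of the week's weekdays inside the date range; appointments fall
uniformly on weekdays (cosmetic realism — clinics run weekdays). Entry is
same-day with a per-user probability, else delayed by 1 + Geometric
(`delay_geom_p`) days — the simplest one-parameter positive delay; only the
same-day indicator feeds the headline measure, so the delay tail shape is
inconsequential. Initial encounters (probability `p_initial`) get a
referral source and a referral date uniform within 180 days before the
appointment, replaced by the 1900-01-01 sentinel with a time-varying
probability. Visit reason is `"other"` with configurable pre/post
probability, otherwise a uniform draw from five clinical labels.

Intervention structure:

- **Timeliness step**: each user's same-day probability is drawn once from
  a Beta distribution with mean `p_same_day_pre` and concentration
  `heterogeneity_concentration` (default 60 pseudo-counts — visible
  between-user spread without bimodality; real per-user heterogeneity is
  unconstrained by published aggregates, so this is a modelling choice, not
  an empirical claim). The intervention shifts every user additively by
  `p_same_day_post − p_same_day_pre` (clipped to [0, 1]), so the expected
  per-user change equals the configured step.
- **Completeness drop-and-recovery**: the sentinel probability jumps from
  `p_referral_unknown_pre` to `p_referral_unknown_spike` at the
  intervention and decays *linearly* back over `spike_duration_days`.
  Linearity is the generator's choice of the simplest recovery shape; only
  "drop then recover within about three months" is the behavior being
  emulated.
- **Validity noise**: with probability `p_validity_error` a record gets one
  uniformly chosen violation — entry before appointment, appointment moved
  into 2000–2007, entry pushed past the 4-month limit, or referral pushed
  past the 6-month gap. Violations are injected independently of other
  behaviors; observed validity shifts in real systems are too small to
  constrain anything richer, so the rate is constant across the
  intervention.
- **Quarter-end seasonality**: in the 14 days before each calendar-quarter
  end, the same-day probability is multiplied by
  `1 − quarter_end_delay_boost` (peak reporting pressure delays entry).

Determinism: one `numpy` Generator seeded from `seed` drives every draw in
a fixed order; identical config + seed yields byte-identical CSV output.

**`scenario_paper_like()`** is calibrated so the *window means* of the
generated measures sit at the reference study-scale values: 53 users,
≈42 entries/user/week (≈336 per 8-week window), same-day 0.628 → 0.732,
completeness ≈86.3% pre / ≈81.6% post, validity ≈99%. Completeness
calibration: with P(complete) = (1 − p_other)(1 − p_initial·p_unknown),
choosing p_other = 0.10 and p_initial = 0.20 fixes p_unknown_pre = 0.206
from the 86.3% pre mean, and the 81.6% post-window mean then pins the spike
at 0.585 with a 90-day linear recovery. The quarter-end dip is *off* (0.0)
in this preset: the calibrated window means already absorb any seasonality
of the system being emulated, and stacking an extra December dip on top
would push the post window below its calibrated mean. The dip is exercised
with nonzero values in its own tests. `scenario_null()` equalizes all
pre/post parameters (no effect) and reduces volume to 12 entries/user/week —
per-user window averages still pool ≈100 records, and replicate calibration
studies stay fast.

What the generator does **not** emulate: feedback dynamics between users
and the intervention (badge thresholds, social comparison), correlation
between timeliness and completeness behavior within a user, drift or
autocorrelation in the baseline, profession-level effects, and real
referral-pattern seasonality. Passing tests therefore show the *pipeline*
recovers known structure from realistic-scale data — not that real
organizational data satisfies the generator's independence assumptions.

## 5. Verification design

- The rule engine is pinned by a committed 12-record fixture whose flag
  table was derived by hand, covering every clause boundary (±1 day around
  the 4- and 6-month limits, the 2008 floor, the sentinel, the "other"
  reason, initial-encounter referral requirements).
- XmR limits and signals are checked against an independent brute-force
  recomputation (stdlib statistics over 1,000 random series, 1e-12
  relative tolerance) plus a hand-worked 3-point example.
- The paired t test is cross-checked against `scipy.stats.ttest_rel`; the
  t = d·√n identity is property-tested.
- Effect recovery: 200 study-scenario replicates must recover the
  simulated +10.4-point same-day step within 3 Monte-Carlo standard errors,
  with >95% rejection at α = .05; 100-seed chart emulation must show
  post-intervention above-UCL timeliness months in >90% of seeds and the
  completeness below-LCL-then-recovery pattern for the documented seed;
  500 null replicates must hold the type-I error of all four comparisons
  within 2 binomial standard errors of .05.

Problem sizes in the test and acceptance runs (replicate counts, the null
scenario's reduced volume) were chosen to make Monte-Carlo bands tight
enough to be meaningful while keeping a full run in the low minutes on one
core.

## 6. Known limitations

- Calendar-month validity arithmetic differs from day-count rules some
  warehouses use (e.g. "<122 days"); boundary records can classify
  differently.
- The completeness rule treats the required-field set as configuration;
  fields outside the schema cannot be checked.
- Only the beyond-limits SPC rule is implemented; shifts smaller than
  2.66·m̄R that would trip run rules go undetected.
- The normal-approximation power is slightly anticonservative versus
  noncentral-t at small n; both are reported achieved (post-hoc) power,
  with the usual caveats about interpreting it.
- The generator's independence assumptions (see §4) make it a structural
  test bed, not a simulator of any specific organization.
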