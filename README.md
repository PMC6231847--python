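# encounterdq

Data-quality analytics for clinical encounter reporting systems: rule-based
scoring of encounter records on **timeliness**, **completeness** and
**validity**, **XmR statistical-process-control charts** of the monthly
measures, and **paired pre-post analysis** of an intervention — plus a
synthetic cohort generator so the whole pipeline runs end-to-end without any
organizational data.

It is aimed at quality-improvement analysts in primary-care organizations
(e.g. family health teams whose allied health professionals — nurses,
dietitians, social workers, pharmacists — record encounter data), and at
researchers evaluating interventions intended to change data-entry behavior.

## The measures and the statistics

Each encounter record carries an appointment date, an entry date (when it was
typed into the system), and — for initial encounters — a referral source and
referral date, where the literal date `1900-01-01` is the system's sentinel
for *"I do not know the referral date"*. Three record-level predicates are
aggregated to percentages per user, per month, or per pre/post window:

- **same-day entry** — entry date equals appointment date;
- **complete** — all required fields populated, visit reason ≠ `"other"`,
  and (for initial encounters) referral source present and referral date
  known (the sentinel counts as missing);
- **valid** — appointment ≤ entry, appointment strictly after 2008-01-01,
  entry within 4 calendar months of the appointment, and any known referral
  date at most 6 calendar months before the appointment.

**XmR chart.** For a monthly series *x₁…xₖ* with moving ranges
*mRᵢ = |xᵢ₊₁ − xᵢ|*, the individuals chart has center line X̄ and limits
X̄ ± 2.66·m̄R; the moving-range chart has upper limit 3.267·m̄R. Points
strictly outside the limits are assignable-cause signals; everything else is
chance variation. By default all points feed the limits (retrospective
charting); a frozen baseline is available for prospective monitoring.

**Paired pre-post.** Per-user measures averaged over the 8 weeks before and
after the intervention give paired differences *D*; the package reports the
paired *t* = D̄/(s_D/√n), two-sided *p*, Cohen's *d* = D̄/s_D (so *t* = *d*·√n),
and achieved power Φ(|d|·√n − z₀.₉₇₅).

## Worked example

```python
from encounterdq import (aggregate, compare_prepost, generate_cohort,
                         scenario_paper_like, score_frame)

cfg = scenario_paper_like()          # 53 users, Apr 2016 – Feb 2017,
data = generate_cohort(cfg)          # intervention on 2016-11-28
windows = aggregate(score_frame(data.frame), data, "by_user_and_window",
                    intervention_date=cfg.intervention_date)
print(compare_prepost(windows, "same_day"))
```

Running `python examples/prepost_analysis.py` prints (default seed):

```
 measure     pre    post  change       t  p_value  power  cohen_d  n_pairs
same_day  62.652  73.865  11.213  27.099    0.000  1.000    3.722       53
complete  86.563  81.808  -4.756 -10.459    0.000  1.000   -1.437       53
   valid  99.356  99.316  -0.040  -0.471    0.640  0.068   -0.065       53
  volume 333.566 331.415  -2.151  -0.764    0.448  0.116   -0.105       53
```

The same-day share rises ~11 points after the intervention (highly
significant), completeness dips ~5 points (users trading referral detail for
speed), validity is unchanged, and entry volume stays level — so the quality
changes are not explained by workload. `examples/xmr_chart.py` builds the
monthly XmR chart and flags Dec 2016 – Feb 2017 as above the upper control
limit (assignable cause), and `examples/generate_and_score.py` shows the raw
monthly measures.

A command-line interface mirrors the workflow (`encounterdq simulate /
score / xmr / prepost / report`); `encounterdq report --scenario paper-like
--out out/` runs every stage and writes CSV tables, SVG charts and a
reproducibility manifest.

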