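# nciwear

Wear/nonwear classification of minute-epoch accelerometer counts, with a
full audit of the National Cancer Institute's rule-based nonwear
classifier (NCINW) and of the hourly count allowance built into it.

## The problem

Physical-activity monitors keep recording whether or not they are worn, so
every analysis of counts-per-minute (CPM), sedentary time or
moderate-to-vigorous activity first has to decide, minute by minute,
whether the device was on the body. The NCI classifier — used to process
the NHANES 2003–2004 physical activity monitor data and shipped with SAS,
ActiLife and R tooling — defines nonwear as:

> an interval of **≥ 60 consecutive minutes of zero counts**, allowing up
> to **2 consecutive minutes with 1–100 counts**, terminated by any minute
> **above 100 counts** or by **3 consecutive minutes in the 1–100 band**.

That allowance has a counterintuitive reach. Because an hour may contain up
to 40 nonzero minutes of ≤ 100 counts each (never 3 in a row), a nonwear
hour can legally carry **4,000 counts**; conversely three 1-count minutes
per hour are enough to keep a day of otherwise-zero data classified 100%
wear. `nciwear` reimplements the classifier, constructs the two extreme
corner-case scenarios exactly, scans cohorts for naturally occurring
"A-type" (high-count nonwear) and "B-type" (low-count wear) clock hours,
and sweeps the reclassification threshold *T* at which fully-nonwear clock
hours with ≥ *T* counts are re-designated wear, reporting valid days
(≥ 10 h wear from midnight), pooled CPM over valid-day wear time, and
minutes at or above the 2,020 counts/min cut-point.

It is aimed at physical-activity epidemiologists and methods researchers
who need a transparent, testable implementation of the rule and of its
sensitivity analysis, without the original SAS/ActiLife binaries.

## Worked example

```sh
nciwear scenarios
```

prints the corner-case audit (Scenario A repeats the hourly pattern
`0,100,100`; Scenario B repeats `1,1,1` then 57 zeros):

```
                                      Scenario A      Scenario B
Before classification
  Duration (HH:MM)                         24:00           24:00
  Counts-per-minute                        66.67            0.05
  Counts (total)                          96,000              72
After classification
  Duration wear (HH:MM)             00:02 (0.1%)  24:00 (100.0%)
  Counts wear (total)                        200              72
  Duration excluded (HH:MM)        23:58 (99.9%)    00:00 (0.0%)
  Counts excluded (total)                 95,800               0
```

A day carrying 96,000 counts is 99.9% nonwear (only the final two
100-count minutes fall outside the single bout), while a day carrying 72
counts is 100% wear — the two boundary behaviours of the rule.

The same pipeline runs on data: simulate a cohort (or read your own
per-minute count table; `participant_id, day_index, minute_of_day, counts,
calibration_ok`), then sweep the reclassification threshold:

```sh
nciwear simulate --participants 50 --days 7 --seed 1 --out cohort.csv
nciwear sensitivity --input cohort.csv --out sensitivity.tsv
nciwear prevalence  --input cohort.csv --out prevalence.tsv
```

`sensitivity.tsv` holds one row per threshold (baseline first) with
participant counts, mean CPM and mean cut-point minutes for the ≥ 1 and
≥ 4 valid-day strata, plus signed absolute and percent differences from
baseline. As *T* falls, wear time can only grow, so stratum sizes rise and
mean CPM falls. From Python the same objects are available directly:

```python
from nciwear import (build_pattern, build_scenario, classify_wear,
                     max_nonwear_hour_counts)
labels = classify_wear(build_scenario(build_pattern("A")))
labels.wear_minutes        # 2
labels.bouts               # ((0, 1438),)
max_nonwear_hour_counts()  # 4000
```

The NHANES 2003–2004 PAXRAW per-minute file (SAS transport format) can be
ingested with `read_count_table(path, dialect="nhanes-xpt")`; the
survey-scale tests activate automatically when that download is present
(`NCIWEAR_PAXRAW_C` or `data/paxraw_c.xpt`).

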