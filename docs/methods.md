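# Methods

## The nonwear rule and the bout contract

`classify_wear` labels each 1-minute epoch wear or nonwear. A candidate
nonwear bout starts at a zero-count minute and extends over minutes that
are either zero or *allowance* minutes (counts in
`[allowance_min_counts, allowance_max_counts]`, default 1–100), with never
more than `max_consecutive_allowance` (default 2) allowance minutes in a
row. The candidate stops before any minute above
`terminate_above_counts` (strictly greater than 100 at defaults) and
before the first minute of a too-long allowance run; it then **ends at the
last zero-count minute it reached** — trailing allowance minutes are wear.
Candidates shorter than `window_minutes` (default 60) are discarded.

The trailing-zero endpoint rule is the load-bearing choice. A day of the
repeating `0,100,100` pattern has no zero after minute 1437, so the bout is
`[0, 1438)` and exactly the last two 100-count minutes are wear; any
convention that kept trailing allowance minutes inside the bout would
classify the whole day nonwear and change every downstream tally. The
allowance band is inclusive at both ends (a 100-count minute is allowance,
not a terminator, because termination requires *exceeding* 100), and a run
of `max_consecutive_allowance + 1` allowance minutes ends the candidate at
the last zero before the run, leaving the run itself wear. Counts that are
nonzero yet below `allowance_min_counts` cannot occur at defaults; if the
parameters are changed so they can, they terminate the candidate.

Series start and end receive no special treatment: a bout may begin at
index 0 or end at the last index provided those minutes are zeros. Some
deployed implementations behave inconsistently in the first and last study
hours; that quirk is not modelled here.

The scan is linear time: after a candidate ends at its last zero, no zero
exists between that point and the terminating minute, so scanning resumes
at the candidate's end without revisiting minutes.

### Oracle

`nonwear_oracle` is a deliberately naive quadratic reference: for every
zero-count start index it enumerates every admissible interval (zero
endpoints, no terminator, no over-long allowance run, length ≥ window) and
takes the union of all of them as nonwear. It shares no maximality or
resumption logic with the scanner. Equivalence holds because admissible
intervals cannot cross a terminator or an over-long allowance run, so
within each barrier-free zone the union of admissible intervals is either
empty or the single maximal interval the scanner finds. The test suite
asserts equality on thousands of randomized and pattern-spliced series,
under default and perturbed parameters.

## Hourly reclassification

`reclassify_nonwear` implements the sensitivity analysis's edit: for
threshold T ≥ 1, every complete clock hour (aligned to the hour via the
series' minute-of-day offset) whose 60 minutes are all nonwear and whose
pre-classification counts total ≥ T is relabelled wear. Partial-hour
nonwear is never touched. T = 0 is the degenerate "no nonwear exclusion"
limit: all minutes become wear. Reclassification edits labels only — bout
detection is not re-run — and resulting bouts are recomputed as plain
False-runs with no minimum length, since an edited hour can leave a
sub-window nonwear remnant. Wear minutes are monotone: lowering T only
adds wear. T = 4,001 is the identity at default parameters because of the
hourly ceiling below.

## The 4,000-count hourly ceiling

`max_nonwear_hour_counts` finds the maximum count total of a clock hour
lying wholly inside a nonwear bout by dynamic programming over the 60
minutes, with state = length of the trailing nonzero run. Each minute is
zero or an allowance minute at the per-minute cap (smaller values are
dominated, so the cap loses no generality), and no run may exceed
`max_consecutive_allowance`. Runs touching the hour boundary are
admissible because the hour can always be embedded in a longer bout padded
with zeros on both sides. At defaults the optimum is 40 minutes of 100
counts in the `0,100,100` arrangement: 4,000 counts. The value is searched,
not hard-coded, so it tracks parameter changes (e.g. a 50-count cap gives
2,000; allowance run length 0 gives 0).

## Clock-hour pattern scan

Only hourly clock intervals are scanned (1:00–1:59, never 1:30–2:29),
and an hour "classified nonwear/wear" means all 60 minutes share the
label; mixed hours qualify as neither. This strict reading matches the
reclassification's own "full hours" unit — the alternative (hours merely
overlapped by a bout) would double-count boundary hours that the
reclassification can never act on. A-type hours are fully-nonwear hours
with ≥ T pre-classification counts (surveyed for T in 10–500); B-type
hours are fully-wear hours with 1–T counts, inclusive at 1 (surveyed for T
in 1–60). Prevalence counts each participant once per threshold
(≥ 1 qualifying hour), with the full evaluated cohort as denominator.

## Valid days, CPM and the sweep

Days are calendar days beginning at midnight; only complete 1,440-minute
days are scored (partial first/last days are dropped — how the original
survey handled them is unstated, and strict complete-day scoring is the
reproducible choice). A day is valid with ≥ 600 wear minutes. Per
participant, CPM is the **pooled ratio** — total counts during wear over
valid days divided by total wear minutes over valid days — rather than a
mean of daily ratios; the pooled form is what "average CPM during valid
day wear time" computes and is the established practice for this metric.
Minutes at or above the 2,020 counts/min cut-point (inclusive) are
averaged over valid days, then averaged unweighted across participants, as
is the CPM. No survey weights are applied anywhere: the analysis reports
raw participant counts. Cohort entry requires ≥ 1,440 recorded minutes and
a passing calibration flag.

`sensitivity_table` classifies each series once, then for each threshold
in the sweep (default 500, 400, 350, 300, 250, 200, 150, 100, 90, 80, 75,
70, 60, 50, 25, 10, 5, 3, 1, 0) applies the reclassification edit and
re-tallies. The baseline (no reclassification) row comes first; every
other row carries signed absolute and percent differences from it.
Stratum sizes are nondecreasing and mean CPM nonincreasing as T falls,
because wear minutes only grow and the added minutes carry ≤ 100 counts
each, far below typical wear-time CPM.

## Synthetic cohort

The generator emulates the structure the survey analysis assumes:
midnight-aligned multi-day 1-minute series with one contiguous daytime
wear period per day (start drawn uniformly in 06:00–09:00, end in
20:00–23:00). Wear counts come from a three-part mixture over exactly the
strata the rule distinguishes — zero (probability 0.10), low 1–100 uniform
(0.30), high > 100 as 101 plus an exponential with scale 500 (0.60) —
because the classifier's behaviour depends only on these strata, not on a
realistic count spectrum. The mixture puts wear-time CPM near 400,
comparable to adult population means. Nonwear is zero-count with sparse
isolated 1–100-count noise (expected 0.1 noisy minutes per nonwear hour).
Defaults are 200 participants × 7 days.

Corner-case hours are planted at known clock hours so detection can be
scored exactly. A planted A-type hour is the `0,100,100` pattern inserted
strictly inside a nonwear span with the following minute forced to zero:
the bout then runs past the hour boundary and the whole hour is classified
nonwear with 4,000 counts. (An A-pattern hour bordered by high-count wear
would *not* work: its trailing two 100-count minutes fall outside the
bout, leaving the hour mixed.) A planted B-type hour replaces the last
nonwear hour before a day's wear onset with the `1,1,1` + 57-zeros
pattern: the leading triple breaks any bout arriving from the night, and
the wear period terminates the 57-zero tail below the window, so the hour
is classified entirely wear with 3 counts. A-type hours are never planted
directly before a B-type hour, whose leading allowance minutes would
otherwise merge with the A hour's trailing run and break its bout.
Planted hours never overlap, ground truth marks A hours as true wear and
B hours as true nonwear, and per-participant random substreams are
spawned from one global seed, so output is reproducible and independent
of cohort size ordering.

What the generator does **not** model: within-day wear gaps, day-to-day
activity correlation, demographic heterogeneity, device-axis or
epoch-length variation, and naturally occurring near-threshold patterns
other than the planted shapes. Passing tests therefore demonstrate
correctness of the rule, the scan and the sweep mechanics — not that
real-data prevalence estimates would match any particular survey.

## Numerical and formatting choices

All computation is in integer minutes and integer counts; durations are
rendered HH:MM only at the reporting edge. Bout intervals are half-open
`[start, end)`; minute-of-day indexing is 0-based. Reports format
participant counts as integers, CPM to one decimal, minutes and percent
differences to two decimals. Empty strata report NaN means rather than
zero. Series that do not start on a known clock minute cannot be
represented (the offset is validated into [0, 1439]), so hour and day
alignment is never guessed.

## Problem sizes

The default test and verification runs use a 200-participant × 7-day
cohort for the monotonicity audit, a 30-participant × 4-day noise-free
cohort for planted-pattern recovery, and 1,000+ randomized series of up to
300 minutes for oracle equivalence; these sizes give exact, reproducible
checks of every rule mechanism while keeping the whole suite fast.

## Known limitations

The boundary-hour inconsistency reported for a handful of NHANES
participants in the original implementations is intentionally not
reproduced. The SAS-transport reader expects the PAXRAW variable layout
and is exercised against real data only when the external download is
present. The alternative nonwear algorithm of Choi et al. and bout-based
activity summaries are out of scope.
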