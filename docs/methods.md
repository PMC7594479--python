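# Methods

## Problem and data model

Administrative health collections ask the Indigenous-status question at
every encounter, so a person linked across collections carries many
independent reports. The package derives one person-level status from
those reports and validates each derivation rule at the *record* level:
every APDC or EDDC record with a usable flag is one confusion-matrix
unit, its predicted label is the person's derived status (for the
as-recorded baseline, the record's own flag), and its truth is the
person's self-reported reference status. Record-level evaluation is the
natural frame because enhancement re-labels records: a rule that flips
one heavily-admitted person changes many records.

Two tables carry the data: a records table (person id, source
collection, event date, facility id for hospital records, reported
flag, sampled-record marker) and a per-person reference table
(reference status, age group, optional sex and remoteness). Reference
status is strictly binary; record flags may be `missing`. CSV is the
interchange format and dates are ISO-8601 so chronological rules are
unambiguous.

## Derivation rules

A *unit of information* is one linked record with a non-missing flag.
The weight-of-evidence (ERA) rule declares a person Aboriginal when
they have ≥ 3 units of which ≥ 2 indicate Aboriginal, or 1–2 units of
which ≥ 1 does. The multi-stage (MSM) rule applies ERA within each
collection and then across the per-collection results, so a
record-rich collection cannot dominate the evidence; when all records
lie in one collection MSM reduces exactly to ERA. The remaining rules
are: ever/always reported, index/most-recent record, Aboriginal-flagged
at ≥ 2 distinct hospital facilities (APDC/EDDC only), and
Aboriginal-flagged on ≥ 50% of public-hospital (APDC) records.

Decisions taken where the rules are underspecified:

* **Granularity.** ERA's units are individual records. This is the
  choice under which MSM — defined as collapsing records *within each
  collection* first — differs from ERA at all; counting one unit per
  episode or per collection would make the two rules coincide.
* **Missing flags** carry no evidence for any rule and reduce the unit
  count, mirroring the upstream exclusion of persons with missing
  reference status.
* **Zero-evidence persons** derive non-Aboriginal (not "unknown"),
  matching the binary record-level evaluation; such persons are logged.
* **Same-date ties** for the chronological rules break by fixed
  collection priority (APDC > EDDC > PDC > RBDM > CODURF), then by
  Aboriginal flag first, then by input row order — deterministic and
  documented rather than order-sensitive.
* **Scope of the hospital rules.** *Two hospitals* counts distinct
  facility ids among APDC/EDDC records only; *majority* is restricted
  to APDC. The chronological rules use all five collections by default
  (the per-person functions operate on whatever records they are
  given, so a hospital-only variant is a pre-filter away).
* The **sampled record** counts as an ordinary evidence unit for the
  enhancement rules; the survey response itself is never evidence.

The vectorised whole-dataset deriver (`derive_all`) and the per-person
rule functions are two independent implementations of the same
contracts; the test suite checks them against each other on simulated
cohorts.

## Validity measures

Sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP),
PPV = 100·TP/(TP+FP), NPV = 100·TN/(TN+FN); the F score is the harmonic
mean of sensitivity and PPV on the unit scale,
𝓕 = 2·Se·PPV/(Se+PPV). F is defined this way because it balances the
sensitivity gain of an enhancement against its PPV cost, and because
every published total-row F cell is reproduced by this formula to two
decimals (one age-stratified cell differs by 0.01, attributable to the
published inputs themselves being rounded to one decimal). Measures
with zero denominators are undefined and propagate as NaN — never as 0
or 100. Display rounding is one decimal for rates and two for F;
internal computation is full precision. Evaluation defaults to
`all_records` mode; `sampled_only` mode (only the originally sampled
record of each person contributes) is provided because the baseline is
defined through the sampled record, and neither mode is asserted to be
the published table's exact construction.

## Synthetic cohort generator

No generative model is published, so the generator invents the minimal
structure that exercises every rule: a person-level never-identified
stratum plus independent per-record flagging. Per person it draws
reference status (prevalence 0.039), a never-identified indicator
(0.164 of reference-Aboriginal persons), an age group / sex /
remoteness from the published status-specific marginals, and a linked
record count from the status-specific distribution over {1, 2, 3+}
with a left-truncated geometric tail. The tail means (16.84 Aboriginal,
11.74 non-Aboriginal) are fixed so the per-status records-per-person
match the published totals (75,041/5,102 and 1,190,758/125,412,
i.e. ~9.7 overall). Records are assigned to collections by the
published shares (56.5/40.8/1.1/1.3/0.3%), dated uniformly over
2011–2016, and given one of 200 hospital facilities (roughly the NSW
public-hospital count) when in APDC/EDDC.

Flags: records of identifiable (not never-identified) Aboriginal
persons are flagged Aboriginal independently with a per-collection
sensitivity — defaults APDC 1.00, EDDC 0.93, minor collections 0.95,
chosen once so that the record-level as-recorded sensitivities
approximate the published ones under this model ((1−f)·s with
f = 0.164) and APDC exceeds EDDC as published. Never-identified
persons' records are all non-Aboriginal. A fraction 0.005 of
non-Aboriginal persons are misreporters: one record is forced
Aboriginal and the rest are Aboriginal independently at rate 0.5,
producing both once-only and consistently misreported persons. A
MISSING overlay (rate 0.01, a small plausible item-nonresponse rate;
not published) is applied to all but the forced record. Exactly one
APDC/EDDC record per person (when any exists) is marked as sampled.
Misreporting is modelled as collection-independent; whether it
clusters by collection is not published.

All draws come from per-stage child streams of one
`numpy.random.SeedSequence`, so one integer seed reproduces the cohort
byte-for-byte and adding draws to one stage cannot shift another.

**What the generator does not emulate.** Record counts are independent
of the never-identified indicator, so never-identified persons hold
~16.4% of Aboriginal-person records, whereas in the real cohort they
hold only 8–11% (they are lighter users of hospital services). Under
this simplification the simulated as-recorded sensitivities land near
(1−0.164)·s ≈ 83.6% (APDC) and 77.7% (EDDC) — close to, but by
construction not above, the published 84.4%/77.4% pattern. Likewise,
with APDC flagging set to 1.0 there is no within-APDC inconsistency
for identifiable persons, so the sensitivity gain of ERA over
as-recorded on APDC is smaller in simulation than published. Passing
tests therefore demonstrate the correctness and ordering behaviour of
the rules and the evaluation machinery under a faithful cohort
*structure*, not a reproduction of the confidential data's exact
accuracy figures. There is no false-link noise, family/household
structure, or collection-clustered misreporting.

## Evaluation sizes and numerics

The cohort-level checks run at the published cohort size
(130,514 persons, ~1.27M records; the whole pipeline takes well under a
minute), structural property checks use 20 cohorts of 1,000 persons,
and unit tests use hand-built fixtures of ≤ 5 persons. Monte-Carlo
comparisons of record-level proportions use a person-clustered standard
error (records of one person share its latent attributes), and
parameter-recovery checks require agreement within three such SEs.
Realised cohort fractions are compared with their configured targets in
the calibration report with binomial SEs; the observable
never-identified fraction slightly exceeds the latent one whenever some
flag sensitivity is below one, which the report makes visible by
showing both.

## Known limitations

* The reference standard is treated as perfect; reference
  misclassification is outside the model.
* Probabilistic linkage is out of scope — person ids are taken as
  ground truth; no false-link simulation is provided.
* Age groups come from the reference table throughout (age at survey),
  including for EDDC strata.
* No confidence intervals are reported for the validity measures,
  matching the published presentation; the clustered-SE helper exists
  for parameter-recovery checks only.
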