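# Methods

## Task model

A session is a sequence of choice events. The deck holds all 64
color×shape×number combinations twice (128 cards), shuffled by a seeded
generator; a config flag can exclude the four cards identical to a key
card (off by default, leaving the standard 128). The four key cards are
fixed — (red, triangle, 1), (green, star, 2), (yellow, cross, 3),
(blue, circle, 4) — so every level of every dimension appears on exactly
one pile and the correct pile under any rule is unique. A consequence used
throughout the tests: a uniformly random responder is correct with
probability exactly 1/4 per trial.

The starting rule is drawn uniformly from {color, shape, number} using
`start_rule_seed`; subsequent rules follow a fixed configurable cycle
(default color → shape → number, entered at the random start). "Ten cards
successfully matched" is read as ten *consecutive* correct responses — the
standard convention for this task family, and the only reading under which
90 trials is a best case rather than a typical case; the counter resets on
any error and at every rule change. The session ends at 9 completed
categories or deck exhaustion. Trials are purely choice events (no
response times), trial indexing is 1-based, and rule changes are silent:
the policy interface exposes only the key cards, the current card, and the
feedback history. The oracle policy is a declared test-harness exception
that receives the active rule.

## Scoring

A response is *perseverative* iff a previous set exists and the chosen
pile is the correct pile under that previous set's rule. The perseverative
dimension updates at every rule change. This single-clause criterion is
deliberately liberal (the multi-clause Heaton-manual rules are out of
scope): whether the response is also correct under the active rule does
not block the flag, so correct perseverative responses exist and raw PR
can exceed raw TE. Set 1 contributes no perseverative responses, which has
a measurement consequence discussed below.

Range scoring counts flags over an inclusive 1-based trial range;
percentages divide by the number of trials in the range (64 for the short
form, trials actually taken for the full form). Categories are attributed
to the trial on which a set's criterion-th consecutive correct response
occurs, re-derived from the trial stream itself so that logs read from
disk score identically; a set in progress at a range boundary counts for
neither side, which makes raw counts exactly additive over disjoint
ranges — a property test enforces this.

## The respondent model

The parametric agent is a minimal win-stay/lose-shift learner, chosen as
the simplest mechanism that produces the qualitative signatures seen in
human protocols: perseverative runs after rule switches, one or two
non-perseverative search errors while discovering a new rule, and less
perseveration as the test progresses.

State: an *intended* dimension, the last *reinforced* dimension, and a
set of dimensions ruled out in the current search episode.

- Positive feedback reinforces the intended dimension and clears the
  ruled-out set. Ambiguous positive feedback (pile consistent with more
  than one dimension) reinforces the intended dimension only — the agent
  cannot observe which dimension the task rewarded.
- Negative feedback: with probability `persev_prob` the agent re-intends
  the reinforced dimension (a perseverative response); otherwise it rules
  out the intended dimension and shifts uniformly to a dimension not yet
  ruled out (lose-shift without replacement). With `persev_prob = 0` and
  no lapses this bounds every run of consecutive errors at two, matching
  the one-or-two-search-errors signature.
- With probability `lapse_prob` a trial is an attentional slip: a uniform
  random pile with *no* credit assignment. Attributing slip outcomes to
  the intended dimension would let rare lapses corrupt the search state
  and blur the `persev_prob = 0` elimination bound; a slip that leaves
  beliefs untouched is the cleaner and defensible reading.
- The agent tracks its own run of correct feedback; each time it reaches
  the criterion length (a completed set, which the agent can infer even
  though rule changes are silent) `persev_prob` is multiplied by
  `learning_rate`.

All randomness comes from the agent's seed; re-running a session with the
same seeds is bit-identical (policies are reset at session start).

A maximal perseverator (`persev_prob = 1`, no lapses) never abandons its
first reinforced dimension, exhausts the deck, and completes at most one
category — exactly one when it reinforced the true set-1 rule, zero when
ambiguous feedback reinforced a wrong dimension first.

### A measurement artifact worth knowing about

Mean perseverative-response percent in trials 65..end is generally *not*
lower than in trials 1..64, even for agents whose perseveration tendency
decays (`learning_rate < 1`). No trial in set 1 can be perseverative, so
the first 64 trials include a block with a structural PR of zero, while
the second half is fully PR-eligible (including a coincidental baseline:
a correct response is flagged perseverative whenever the old and new rules
map the card to the same pile, about a quarter of the time). At
`persev_prob = 0.8, learning_rate = 0.5` the simulated means are ≈28%
(first half) vs ≈32% (second half). The learning mechanism itself is
verified the unconfounded way: holding all seeds fixed, switching decay on
(`learning_rate = 0.7` vs `1.0`) lowers mean second-half PR% from ≈57% to
≈33%. Human datasets show the same half-contrast artifact in raw PR; this
package does not attempt to separate artifact from behavior, it only
measures what the scoring rule defines.

## Cohort analysis

A cohort draws n respondents' parameters from configurable distributions —
defaults `persev_prob ~ Beta(2,3)`, `lapse_prob ~ Beta(1,20)`,
`learning_rate ~ Uniform(0.7,1.0)`, chosen to give plausible error and
perseveration levels (grand means near 20–30% with substantial
between-subject spread) — and gives each subject an individually shuffled
deck and starting rule, all derived from one master seed via spawned seed
sequences, so cohort → report is bit-stable. Each session is scored
full-length / first-64 / remaining, and for each measure (TE%, PR%, PE%,
categories completed) two Pearson correlations are computed across
subjects: short vs long and first half vs second half, with p-values from
the standard t transform, df = n − 2, two-sided, no multiplicity
correction. An optional grouping labels subjects and computes per-group
batteries; groups with fewer than three members are skipped with a
warning.

If any measure has zero between-subject variance its correlations are
undefined; the cohort is flagged degenerate and the report prints
"undefined" rather than propagating NaN silently. The headline human
correlation magnitudes of the original validation sample are sample
statistics of real participants and are not reproducible by simulation;
the quantity the simulation can and does check is the ordinal pattern —
short-vs-long r above half-vs-half r for every measure — which follows
structurally from part–whole containment.

## Numerical and design choices

- Pearson's r is delegated to `scipy.stats.pearsonr` behind a thin
  contract layer (length/constancy checks); tests cross-check a
  hand-computed value and an independent matrix computation.
- Seeds: every stochastic component (deck shuffle, starting rule, agent
  RNG, parameter draws) has an explicit integer seed; derived seeds are
  taken modulo 2³¹. CLI manifests record version, config hash and seeds.
- Degenerate inputs: constant vectors raise a dedicated undefined-
  correlation error; empty/inverted score ranges and sessions shorter
  than 65 trials raise argument/invalid-session errors; policies
  returning non-integers or out-of-range piles abort the session with the
  offending trial identified.
- Problem sizes: the validation property is checked on 20 independent
  cohorts of n = 200 (≈4,000 sessions, a few seconds); scorer equivalence
  uses 1,000 random-policy sessions. These sizes give stable medians and
  comfortable margins for the ordinal assertions.

## Limitations

The agents emulate choice behavior only: no response times, no fatigue,
no age/sex structure (the grouping argument exists, but no demographic
model is invented), and no fitting to human data. Passing tests show that
the engine, scorer and battery behave correctly and that the part–whole
ordinal pattern emerges under heterogeneous agents; they do not show that
the agent family captures human between-subject covariance, so simulated
correlation magnitudes should not be read as normative values.
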