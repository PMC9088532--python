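# Methods

## The aggregation model

A record's classification stream is an ordered sequence of binary verdicts
(*possibly relevant* / *not relevant*) from distinct contributors.  The
collective decision rule is a run rule: the record is finalised at the first
run of `k` identical verdicts (`k = 3` by default, matching production
crowd-screening platforms).  There is no abstain state at the individual
level, and a contributor never classifies the same record twice — enforced
as a stream invariant.

What happens after a disagreement is not uniquely determined by the run rule
itself, and deployed platforms differ, so both behaviours are first-class:

- **`STREAK_CONTINUE`** (default): the record keeps circulating after a
  disagreement until some run of `k` occurs or `max_assessments` events
  (default `2k + 1`) have been consumed, after which it needs resolution.
  `2k + 1` is the smallest cap at which either verdict could still assemble
  a run after a maximally adversarial prefix.
- **`STRICT_FIRST_K`**: the first disagreement routes the record to a
  resolver immediately, so consensus requires the first `k` verdicts to
  agree.

Degenerate inputs: an empty stream (e.g. deadline expiry before any verdict)
is legal and yields *needs resolution* with zero classifications and a
warning; a stream shorter than `k` with no disagreement likewise remains
unresolved.  Mixed record ids, non-consecutive ordinals, duplicate
contributors and time-travelling timestamps are structural errors.

Under `STRICT_FIRST_K` with independent classifications the operating point
is closed-form — a relevant record reaches consensus with probability
`sens^k + (1 − sens)^k` and is collectively flagged with probability
`sens^k` — which anchors the simulator tests and makes the choice of mode
empirically checkable (see *Choice of conflict mode* below).

## Evaluation conventions

- Sensitivity, specificity and the pooled miss rate are reported to one
  decimal, crowd consensus to two, all **half-up rounded**: a ratio of
  31/32 prints as 96.9.  Banker's rounding would print 96.8, which disagrees
  with how published screening evaluations report the same ratio.
- Confusion counting requires every record to be final (crowd consensus or
  resolver verdict); unresolved records are an error naming the ids, so a
  partial evaluation cannot silently masquerade as a full one.
- Records with an `UNKNOWN` reference label are excluded from confusion
  counts but retained in consensus, which is reference-free by definition.
- Resolver verdicts count toward accuracy but never toward consensus:
  consensus measures exactly the fraction of records that did *not* need
  arbitration.
- Forward citation recovery answers a retrieval question: a missed study is
  recoverable if at least one collectively included study cites it.

## The synthetic-crowd generator

The generator emulates the statistical structure of four published
crowd-screening pilot tasks (carried in `crowdscreen.presets`): set sizes
948–5,606 records, includable-study prevalence 0.5–2%, title-only fractions
5.7–7.2%, contributor pools of 12–65, mean individual sensitivity
84.2–89.3% and specificity 82.2–90.9%, and a 48-hour deadline.

Fixed design choices, with rationale:

- **Corpus composition is exact, not Bernoulli**: relevant and title-only
  counts are fixed by half-up rounding of `n × fraction`, so a seeded corpus
  is exactly reproducible and fixture counts are deterministic.
- **Contributor accuracies** are drawn from normal distributions truncated
  to [0, 1], with the task's mean and a default spread of 0.05 absolute — a
  bell-shaped family being the least-informative realistic choice for a
  screened, trained pool.  Note a convexity effect: because `s^3` is convex,
  a spread-0.05 pool has slightly *higher* expected included-study consensus
  (~1–2 points) than a homogeneous pool at the same mean.
- **Title-only records** incur a 0.05 absolute penalty on both sensitivity
  and specificity (configurable): titles alone carry less signal, and
  observed consensus on abstract-less records runs several points lower.
- **The qualification gate** models the 16-item practice test with an 80%
  pass mark (pass at ⌈0.8·16⌉ = 13 correct).  Items are half relevant
  (rounding up), judged with the contributor's `sens`/`spec`; with equal
  accuracies this reduces exactly to a binomial tail.  Simulations of the
  published tasks leave the gate off, because published pool sizes count
  contributors who took part and had therefore already passed.
- **Activity model**: each contributor classifies at exponential
  inter-event times (Poisson process), default 60 classifications/hour —
  consistent with the published per-100-record completion times (13–74
  minutes per 100 records for pools of 12–65).  Real diurnal rhythms,
  learning, dropout and heavy-tailed individual effort are not modelled.
- **The scheduler** serves each contributor a uniformly random unfinalised
  record they have not yet classified — the simplest exchangeable policy;
  nothing in the run rule depends on assignment order.  A consequence worth
  knowing: with `STREAK_CONTINUE`, a pool smaller than `max_assessments`
  can strand records that never produce a run, since no eligible contributor
  remains; completability of every record requires a pool of at least
  `max_assessments` distinct contributors.
- **Full-history mode** (`stop_early=False`) makes every record collect the
  full `max_assessments` verdicts regardless of early runs, producing
  streams on which alternative policies can be replayed fairly.

Because contributors err **independently** in this model, simulated
collective accuracy is an upper bound on what a real crowd with correlated
errors (shared training, shared ambiguous abstracts) achieves; simulated
overall consensus likewise need not match any one platform's published
value.  Passing simulation tests therefore validates the machinery and the
independence-model predictions, not real-crowd performance.

## Choice of conflict mode for replication simulations

The published included-study consensus values for the four tasks (60%, 61%,
65%, 63%) sit almost exactly on `sens^3` for the tasks' mean individual
sensitivities (59.7%, 64.9%, 61.6%, 71.2%) — the `STRICT_FIRST_K` closed
form.  Enumerating `STREAK_CONTINUE` with the default cap of 7 instead
predicts 91–96%, far above anything observed.  Replication-style simulations
and the acceptance script therefore run the strict mode; the
`STREAK_CONTINUE` default remains for general use, where continuing past a
single disagreement is the more economical platform behaviour.

Two published inconsistencies are deliberately not reproduced: two of the
four tasks' printed specificities (73.0, 88.7) differ from the values their
own confusion counts imply (73.1, 88.4); this package always recomputes
from counts.  Similarly, printed prevalence figures differ slightly from
includes ÷ set size; the package uses the ratio.

## Replay and the effect of k

Replaying a fixed stream under different `k` compares policies on identical
data.  Nesting — every record reaching consensus at `k+1` also reaches it at
`k` — holds when both policies share an assessment cap (a run of `k+1`
within the first `m` events contains a run of `k` there).  Replay therefore
compares policies at a common cap; with each policy's own default cap
(`2k + 1`), a late run admissible under the larger cap may be invisible
under the smaller one and nesting can fail, which is a property of the caps,
not of the run rule.

## Workflow accounting

Workload is counted in assessments, not records, because dual screening
reads a record twice.  Under the speed-maximising workflow, conflicted
records are routed to the author single-assessment queue rather than
dropped: a record the crowd could not decide should never silently vanish.
The specificity-maximising workflow requires a resolver verdict for every
conflicted record and errors otherwise.  The author team itself is treated
as error-free (it *is* the reference standard), so workflow comparisons
quantify workload, not downstream accuracy.

## Problem sizes

The test suite simulates the four tasks at their full published sizes
(14,299 records total); the whole suite runs in well under a minute.
Included-study consensus has only 12–47 includable records per run, so
per-run estimates carry sampling deviations above 10 points; means are
taken over 20–120 seeds per task (more for the smaller tasks) to bring the
Monte-Carlo standard error below ~1.5 points.  Closed-form agreement checks
use 100,000 replicates per grid point; the exhaustive aggregation oracle
covers every verdict sequence up to length 8 in both modes.

## Known limitations

- Inter-contributor error correlation is unmodelled; it is the main reason
  simulated consensus need not match observed platform values.
- Contributor effort is homogeneous; published per-contributor record
  counts (ranging from 1 to >3,000) are strongly skewed.
- The two conflict modes bracket, but may not contain, a production
  platform's exact routing logic (e.g. resolver-first for some strata).
- RIS input parsing covers the tags needed for title/abstract screening
  (TI/T1, AB, ID/AN, ER); it is not a general bibliographic parser.
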