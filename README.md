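# crowdscreen

Consecutive-agreement crowd screening for evidence synthesis: aggregation,
evaluation, simulation and workload accounting for crowdsourced
title/abstract citation triage.

## The problem

Systematic and rapid reviews begin by screening thousands of search-result
records, of which typically under 2% are includable studies.  Crowdsourcing
distributes this triage across many lay contributors, each casting a binary
verdict — *possibly relevant* or *not relevant* — on the records they are
served.  The platform question is how to turn noisy individual verdicts into
reliable collective decisions, and how to quantify what the crowd buys the
review team: how many includable studies does the crowd miss (sensitivity),
how much irrelevant material does it clear away (specificity), and how often
does it decide without human arbitration (consensus)?

## The method

A record is finalised collectively when **k consecutive identical verdicts**
arrive in its stream (k = 3 in production deployments).  Records whose stream
never produces such a run go to a human *resolver*.  Two post-disagreement
behaviours are supported, because deployed platforms differ:

- `STREAK_CONTINUE` — the record keeps circulating until a run of k occurs
  or a cap of 2k+1 assessments is reached (the package default);
- `STRICT_FIRST_K` — the first disagreement routes the record to the
  resolver, so consensus requires the *first* k verdicts to agree.

Under `STRICT_FIRST_K` with independent classifications the operating point
is closed-form: a relevant record reaches consensus with probability
`sens^k + (1 − sens)^k` and is collectively flagged with probability
`sens^k`, where `sens` is individual per-classification sensitivity
(analogously with `spec` for not-relevant records).

Collective accuracy against the review team's reference standard is scored
as `sensitivity = TP/(TP+FN)`, `specificity = TN/(TN+FP)`; crowd consensus
is the fraction of records finalised without arbitration, reportable for
subgroups (includable studies; title-only records).

The simulator generates whole screening tasks — corpus with planted
prevalence and title-only fraction, a contributor pool with
truncated-normal accuracy distributions, an optional 16-item/80%
qualification gate, and an event-driven classification loop under a 48-hour
deadline — and records the full event stream so the same data can be
*replayed* under alternative policies (e.g. k = 2 vs k = 3).

## Worked example

Simulate a 1,000-record task at 1.5% prevalence with 15 contributors of
~85% individual accuracy, finalise the conflicted records with an oracle
resolver, and score against the planted labels:

```python
from crowdscreen import *
from crowdscreen.aggregation import aggregate_task
from crowdscreen.simulate import oracle_resolver_labels

cfg = TaskSimConfig(
    corpus=CorpusSpec(n_records=1000, prevalence=0.015,
                      title_only_fraction=0.07, seed=42),
    pool_size=15,
    sens_distribution=DistributionSpec(mean=0.85),
    spec_distribution=DistributionSpec(mean=0.85),
    seed=43,
)
result = simulate_task(cfg)
decisions = aggregate_task(result.stream, cfg.policy,
                           oracle_resolver_labels(result.corpus))
report = performance_report(decisions, result.corpus)
```

This prints (`completion_hours` 4.38, 3,963 classification events):

```json
{
  "counts": {"tp": 14, "tn": 980, "fp": 5, "fn": 1, "total": 1000},
  "sensitivity_pct": 93.3,
  "specificity_pct": 99.5,
  "consensus_pct": 94.3,
  "included_consensus_pct": 100.0,
  "title_only_consensus_pct": 90.0,
  "missed_record_ids": ["rec0434"]
}
```

Reading: the crowd finalised 94.3% of records without arbitration and
collectively missed one of the 15 includable studies (93.3% sensitivity);
the record it missed is named so a reviewer can inspect it.  Individual
contributors were only ~85% sensitive — requiring a run of three agreeing
verdicts is what pushes the collective rate up, since a collective miss
needs a whole run of individual errors.

The same machinery is available from a shell:

```
crowdscreen simulate --config sim.yaml --out-dir run/
crowdscreen aggregate --stream run/stream.csv --k 3 --out decisions.csv
crowdscreen evaluate  --decisions decisions.csv --records run/corpus.csv
crowdscreen replay    --stream run/stream.csv --k 2 --out decisions_k2.csv
crowdscreen workflow  --decisions decisions.csv --mode speed_max
```

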