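"""Synthetic crowd-screening tasks with the statistical structure of the four
Cochrane Rapid Review pilots.

The generator produces (a) a corpus of placeholder citation records with a
planted includable-study prevalence and a planted fraction of title-only
records; (b) a pool of contributors whose per-classification sensitivity and
specificity are drawn from truncated-normal distributions around the means
estimated from the live tasks; and (c) a full classification event stream
from an event-driven loop in which each contributor classifies unfinalised
records at a constant Poisson rate until the task completes or the deadline
passes.

Every stage is driven by explicit seeds, so a simulated task is bit-for-bit
reproducible and its recorded stream can be replayed under alternative
aggregation policies.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .aggregation import (
    AggregationPolicy,
    ClassificationEvent,
    ConflictMode,
    CrowdDecision,
    DecisionStatus,
    Verdict,
    aggregate_task,
)
from .evaluation import RecordEntry, ReferenceLabel


def _round_half_up_int(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CorpusSpec:
    """Shape of a synthetic search-result set.

    ``prevalence`` is the fraction of records that are truly includable
    studies (0.5–2% in the pilot tasks); ``title_only_fraction`` the fraction
    lacking abstracts (~6–7%).  Both counts are fixed by half-up rounding, not
    Bernoulli draws, so a spec pins its corpus composition exactly.
    """

    n_records: int
    prevalence: float
    title_only_fraction: float = 0.065
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        for name in ("prevalence", "title_only_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class DistributionSpec:
    """Descriptor for a contributor-accuracy distribution.

    ``family`` is ``"truncnorm"`` (normal truncated to [0, 1]); ``spread`` is
    the pre-truncation standard deviation, default 0.05 absolute.
    """

    mean: float
    spread: float = 0.05
    family: str = "truncnorm"

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family != "truncnorm":
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.spread == 0.0:
            return np.full(size, float(self.mean))
        a = (0.0 - self.mean) / self.spread
        b = (1.0 - self.mean) / self.spread
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.spread, size=size, random_state=rng
        )


@dataclass(frozen=True)
class ContributorProfile:
    """One crowd contributor's error model and throughput.

    ``sens``/``spec`` are per-classification probabilities of the correct
    verdict on relevant / not-relevant records with abstracts;
    ``title_only_sens``/``title_only_spec`` the same for abstract-less
    records (by default penalised, since titles alone carry less signal).
    ``rate_per_hour`` is the contributor's mean classification throughput.
    """

    contributor_id: str
    sens: float
    spec: float
    title_only_sens: float
    title_only_spec: float
    rate_per_hour: float = 60.0
    qualified: bool = True

    def __post_init__(self) -> None:
        for name in ("sens", "spec", "title_only_sens", "title_only_spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.rate_per_hour <= 0:
            raise ValueError("rate_per_hour must be positive")


@dataclass(frozen=True)
class QualificationSpec:
    """The training-module gate: a practice test of ``n_items`` records that
    must be answered with at least ``pass_fraction`` accuracy (platform
    default: 16 items, 80%)."""

    n_items: int = 16
    pass_fraction: float = 0.80

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if not 0.0 < self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction must be in (0, 1]")

    @property
    def pass_mark(self) -> int:
        return math.ceil(self.pass_fraction * self.n_items)


TITLE_ONLY_PENALTY = 0.05  # absolute accuracy penalty on abstract-less records


@dataclass(frozen=True)
class TaskSimConfig:
    """Everything needed to simulate one screening task end to end.

    ``qualification=None`` models a pre-qualified pool (contributors who
    already passed the training module, as the published pool counts do);
    supplying a :class:`QualificationSpec` gates the pool through a simulated
    practice test first.
    """

    corpus: CorpusSpec
    pool_size: int
    sens_distribution: DistributionSpec
    spec_distribution: DistributionSpec
    policy: AggregationPolicy = field(default_factory=AggregationPolicy)
    qualification: Optional[QualificationSpec] = None
    deadline_hours: float = 48.0
    rate_per_hour: float = 60.0
    title_only_penalty: float = TITLE_ONLY_PENALTY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be positive")
        if self.deadline_hours <= 0:
            raise ValueError("deadline_hours must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "TaskSimConfig":
        """Build a config from a plain dict (YAML/JSON simulation configs)."""
        data = dict(data)
        corpus = CorpusSpec(**data.pop("corpus"))
        sens = DistributionSpec(**data.pop("sens_distribution"))
        spec = DistributionSpec(**data.pop("spec_distribution"))
        policy = data.pop("policy", None)
        policy = AggregationPolicy(**policy) if policy else AggregationPolicy()
        qual = data.pop("qualification", None)
        qual = QualificationSpec(**qual) if qual else None
        return cls(
            corpus=corpus,
            sens_distribution=sens,
            spec_distribution=spec,
            policy=policy,
            qualification=qual,
            **data,
        )


def generate_corpus(spec: CorpusSpec) -> list[RecordEntry]:
    """Generate a synthetic corpus with exactly ``round(n·prevalence)``
    relevant records and ``round(n·title_only_fraction)`` title-only records,
    positions shuffled by the spec's seed.

    Titles and abstracts are placeholder text; relevance and abstract
    presence are assigned independently of each other.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_relevant = _round_half_up_int(n * spec.prevalence)
    n_title_only = _round_half_up_int(n * spec.title_only_fraction)
    if spec.prevalence > 0 and n_relevant == 0:
        warnings.warn(
            "prevalence too low for corpus size: zero relevant records generated",
            stacklevel=2,
        )
    relevant_idx = set(rng.choice(n, size=n_relevant, replace=False).tolist())
    title_only_idx = set(rng.choice(n, size=n_title_only, replace=False).tolist())
    width = len(str(n))
    records = []
    for i in range(n):
        title_only = i in title_only_idx
        records.append(
            RecordEntry(
                record_id=f"rec{i:0{width}d}",
                title=f"Synthetic citation {i}",
                abstract=None if title_only else f"Synthetic abstract for citation {i}.",
                reference_label=(
                    ReferenceLabel.RELEVANT
                    if i in relevant_idx
                    else ReferenceLabel.NOT_RELEVANT
                ),
            )
        )
    return records


def generate_pool(
    config: TaskSimConfig, rng: np.random.Generator
) -> list[ContributorProfile]:
    """Draw a contributor pool from the config's accuracy distributions."""
    sens = np.clip(config.sens_distribution.draw(rng, config.pool_size), 0.0, 1.0)
    spec = np.clip(config.spec_distribution.draw(rng, config.pool_size), 0.0, 1.0)
    pen = config.title_only_penalty
    width = len(str(config.pool_size))
    return [
        ContributorProfile(
            contributor_id=f"c{i:0{width}d}",
            sens=float(sens[i]),
            spec=float(spec[i]),
            title_only_sens=float(max(0.0, sens[i] - pen)),
            title_only_spec=float(max(0.0, spec[i] - pen)),
            rate_per_hour=config.rate_per_hour,
        )
        for i in range(config.pool_size)
    ]


def run_qualification(
    profile: ContributorProfile,
    spec: QualificationSpec,
    rng: np.random.Generator,
) -> bool:
    """Simulate the training-module practice test.

    The test presents ``ceil(n_items/2)`` relevant and the remaining
    not-relevant practice records; the contributor answers each independently
    with probability ``sens`` / ``spec`` of being correct, and passes iff the
    correct count reaches the pass mark.
    """
    n_rel = math.ceil(spec.n_items / 2)
    n_not = spec.n_items - n_rel
    correct = int(rng.binomial(n_rel, profile.sens)) + int(
        rng.binomial(n_not, profile.spec)
    )
    return correct >= spec.pass_mark


class UnqualifiedContributorError(RuntimeError):
    """Only contributors who passed the training gate may classify."""


def classify(
    profile: ContributorProfile,
    record: RecordEntry,
    rng: np.random.Generator,
) -> Verdict:
    """One Bernoulli classification of ``record`` by ``profile``.

    Relevant records yield POSSIBLY_RELEVANT with probability ``sens``
    (``title_only_sens`` for abstract-less records); not-relevant records
    yield NOT_RELEVANT with probability ``spec`` (resp. ``title_only_spec``).
    """
    if not profile.qualified:
        raise UnqualifiedContributorError(
            f"contributor {profile.contributor_id!r} has not passed qualification"
        )
    if record.reference_label is ReferenceLabel.RELEVANT:
        p_correct = profile.title_only_sens if record.title_only else profile.sens
        correct_verdict = Verdict.POSSIBLY_RELEVANT
        wrong_verdict = Verdict.NOT_RELEVANT
    else:
        p_correct = profile.title_only_spec if record.title_only else profile.spec
        correct_verdict = Verdict.NOT_RELEVANT
        wrong_verdict = Verdict.POSSIBLY_RELEVANT
    return correct_verdict if rng.random() < p_correct else wrong_verdict


@dataclass
class SimulationResult:
    """Outcome of one simulated task.

    ``completion_hours`` is the time at which the last record was finalised
    by the agreement algorithm (consensus or routed to resolution), or None
    when the task did not complete (``n_unfinalised`` records still pending
    at the deadline or after the pool was exhausted).
    """

    stream: list[ClassificationEvent]
    decisions: list[CrowdDecision]
    completion_hours: Optional[float]
    n_unfinalised: int
    corpus: list[RecordEntry]
    pool: list[ContributorProfile]

    @property
    def complete(self) -> bool:
        return self.completion_hours is not None


class _RecordState:
    """Incremental streak tracker mirroring the aggregation scan."""

    __slots__ = ("n", "streak_verdict", "streak_len", "disagreed")

    def __init__(self) -> None:
        self.n = 0
        self.streak_verdict: Optional[Verdict] = None
        self.streak_len = 0
        self.disagreed = False

    def push(self, verdict: Verdict) -> None:
        self.n += 1
        if verdict is self.streak_verdict:
            self.streak_len += 1
        else:
            if self.streak_verdict is not None:
                self.disagreed = True
            self.streak_verdict = verdict
            self.streak_len = 1

    def finalised(self, policy: AggregationPolicy) -> bool:
        if self.streak_len >= policy.k:
            return True
        if policy.conflict_mode is ConflictMode.STRICT_FIRST_K and self.disagreed:
            return True
        return self.n >= policy.max_assessments


def simulate_task(
    config: TaskSimConfig, stop_early: bool = True
) -> SimulationResult:
    """Run one screening task as an event-driven simulation.

    Each qualified contributor classifies at exponential inter-event times
    (a Poisson process at ``rate_per_hour``); at each of their events the
    scheduler serves them a uniformly random unfinalised record they have not
    yet classified.  Records are finalised per ``config.policy`` as verdicts
    arrive.  With ``stop_early=False`` every record instead collects the full
    ``policy.max_assessments`` verdicts (finalisation deferred to the end),
    producing complete histories suitable for policy replay.
    """
    rng = np.random.default_rng(config.seed)
    corpus = generate_corpus(config.corpus)
    pool = generate_pool(config, rng)
    if config.qualification is not None:
        passed = [run_qualification(p, config.qualification, rng) for p in pool]
        active = [p for p, ok in zip(pool, passed) if ok]
    else:
        active = list(pool)

    policy = config.policy
    if len(active) < policy.k:
        warnings.warn(
            f"only {len(active)} qualified contributor(s) for k={policy.k}: "
            "no record can reach consensus; task cannot complete",
            stacklevel=2,
        )

    n = len(corpus)
    pending = list(range(n))            # indices into corpus
    pos = {i: i for i in pending}       # record index -> position in pending
    states = [_RecordState() for _ in range(n)]
    events_by_record: list[list[ClassificationEvent]] = [[] for _ in range(n)]
    seen: list[set[int]] = [set() for _ in range(len(active))]

    required = (
        policy.max_assessments if not stop_early else None
    )  # stop_early=False: records leave pending only at the cap

    heap: list[tuple[float, int]] = []
    for ci, profile in enumerate(active):
        t = float(rng.exponential(1.0 / profile.rate_per_hour))
        heapq.heappush(heap, (t, ci))

    stream: list[ClassificationEvent] = []
    completion: Optional[float] = None

    def _drop_pending(ri: int) -> None:
        p = pos.pop(ri)
        last = pending.pop()
        if last != ri:
            pending[p] = last
            pos[last] = p

    while heap and pending:
        t, ci = heapq.heappop(heap)
        if t > config.deadline_hours:
            break
        profile = active[ci]
        # uniform choice among pending records this contributor has not seen;
        # rejection sampling first, exact scan as fallback
        ri = None
        if len(seen[ci]) < n:
            for _ in range(30):
                cand = pending[int(rng.integers(len(pending)))]
                if cand not in seen[ci]:
                    ri = cand
                    break
            if ri is None:
                eligible = [r for r in pending if r not in seen[ci]]
                if eligible:
                    ri = eligible[int(rng.integers(len(eligible)))]
        if ri is None:
            continue  # contributor retired: nothing left they can classify
        seen[ci].add(ri)
        record = corpus[ri]
        verdict = classify(profile, record, rng)
        state = states[ri]
        state.push(verdict)
        event = ClassificationEvent(
            record_id=record.record_id,
            contributor_id=profile.contributor_id,
            verdict=verdict,
            ordinal=state.n,
            timestamp_hours=t,
        )
        events_by_record[ri].append(event)
        stream.append(event)

        done = (
            state.n >= required
            if required is not None
            else state.finalised(policy)
        )
        if done:
            _drop_pending(ri)
            if not pending:
                completion = t
        heapq.heappush(
            heap, (t + float(rng.exponential(1.0 / profile.rate_per_hour)), ci)
        )

    decisions = aggregate_task(
        (e for events in events_by_record for e in events), policy
    )
    # records with no events at all never entered the stream; emit explicit
    # empty decisions so decisions partition the corpus
    covered = {d.record_id for d in decisions}
    for record in corpus:
        if record.record_id not in covered:
            decisions.append(
                CrowdDecision(
                    record_id=record.record_id,
                    status=DecisionStatus.NEEDS_RESOLUTION,
                    reached_by_consensus=False,
                    n_classifications=0,
                )
            )
    return SimulationResult(
        stream=stream,
        decisions=decisions,
        completion_hours=completion,
        n_unfinalised=len(pending),
        corpus=corpus,
        pool=active,
    )


class OperatingPoint(NamedTuple):
    """Strict-mode closed-form operating point of the agreement algorithm."""

    p_consensus: float
    p_collective_possibly_relevant_given_relevant: float
    p_collective_not_relevant_given_not_relevant: float


def strict_mode_operating_point(
    sens: float, spec: float, prevalence: float, k: int
) -> OperatingPoint:
    """Closed forms for STRICT_FIRST_K aggregation under independent
    classifications.

    A relevant record reaches consensus iff its first ``k`` verdicts agree:
    probability ``sens**k + (1-sens)**k`` (all correct or all wrong), and is
    collectively flagged possibly relevant with probability ``sens**k``.
    Not-relevant records are analogous with ``spec``; the marginal consensus
    probability mixes the two by prevalence.
    """
    if not 0.0 <= sens <= 1.0 or not 0.0 <= spec <= 1.0:
        raise ValueError("sens and spec must be probabilities")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    p_cons_rel = sens**k + (1.0 - sens) ** k
    p_cons_not = spec**k + (1.0 - spec) ** k
    return OperatingPoint(
        p_consensus=prevalence * p_cons_rel + (1.0 - prevalence) * p_cons_not,
        p_collective_possibly_relevant_given_relevant=sens**k,
        p_collective_not_relevant_given_not_relevant=spec**k,
    )


def estimate_contributor_accuracy(
    stream: Sequence[ClassificationEvent],
    records: Sequence[RecordEntry],
):
    """Estimate each contributor's sensitivity and specificity from a
    recorded stream against the records' planted labels.

    Returns a pandas DataFrame indexed by contributor_id with columns
    ``n_relevant``, ``sens_hat``, ``n_not_relevant``, ``spec_hat`` and
    ``n_total``; estimates are NaN where a contributor saw no records of the
    corresponding class.
    """
    import pandas as pd

    label_by_id = {r.record_id: r.reference_label for r in records}
    rows: dict[str, list[int]] = {}
    for e in stream:
        counts = rows.setdefault(e.contributor_id, [0, 0, 0, 0])  # relN, relCorrect, notN, notCorrect
        label = label_by_id[e.record_id]
        if label is ReferenceLabel.RELEVANT:
            counts[0] += 1
            counts[1] += e.verdict is Verdict.POSSIBLY_RELEVANT
        elif label is ReferenceLabel.NOT_RELEVANT:
            counts[2] += 1
            counts[3] += e.verdict is Verdict.NOT_RELEVANT
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_relevant", "_rel_ok", "n_not_relevant", "_not_ok"]
    )
    out["sens_hat"] = out["_rel_ok"] / out["n_relevant"]
    out["spec_hat"] = out["_not_ok"] / out["n_not_relevant"]
    out["n_total"] = out["n_relevant"] + out["n_not_relevant"]
    out.index.name = "contributor_id"
    return out[["n_relevant", "sens_hat", "n_not_relevant", "spec_hat", "n_total"]]


def oracle_resolver_labels(records: Sequence[RecordEntry]) -> dict[str, Verdict]:
    """Resolver labels from planted truth: the verdict an error-free resolver
    would give each record.  Used to finalise simulated tasks before
    confusion counting, isolating the crowd algorithm's contribution."""
    return {
        r.record_id: (
            Verdict.POSSIBLY_RELEVANT
            if r.reference_label is ReferenceLabel.RELEVANT
            else Verdict.NOT_RELEVANT
        )
        for r in records
    }


def review_task_config(
    task, seed: int = 0, policy: Optional[AggregationPolicy] = None, **overrides
) -> TaskSimConfig:
    """Build a simulation config emulating one of the published review tasks
    (see :mod:`crowdscreen.presets`): its set size, prevalence, title-only
    fraction, pool size and mean contributor accuracies.

    The pool is treated as pre-qualified, since the published pool sizes
    count contributors who took part (and hence had passed the training
    gate already).
    """
    cfg = TaskSimConfig(
        corpus=CorpusSpec(
            n_records=task.n_records,
            prevalence=task.prevalence,
            title_only_fraction=task.title_only_fraction,
            seed=seed,
        ),
        pool_size=task.pool_size,
        sens_distribution=DistributionSpec(mean=task.contributor_sens),
        spec_distribution=DistributionSpec(mean=task.contributor_spec),
        policy=policy or AggregationPolicy(),
        qualification=None,
        seed=seed + 1,
    )
    return replace(cfg, **overrides) if overrides else cfg
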