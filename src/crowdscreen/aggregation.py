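"""Consecutive-agreement aggregation of crowd screening classifications.

A citation record circulates among crowd contributors, each of whom casts a
binary verdict — *possibly relevant* or *not relevant* — after reading the
title and abstract.  The record is finalised collectively once ``k`` identical
verdicts arrive in a row (``k = 3`` on the Cochrane Crowd platform).  Records
whose verdict stream never produces such a run are routed to a human resolver
instead of being decided by the crowd.

Two behaviours after a disagreement are supported, because deployed platforms
differ and the distinction matters for consensus statistics:

``STREAK_CONTINUE``
    the record keeps circulating after a disagreement until a run of ``k``
    occurs or a hard cap on assessments is reached (default ``2k + 1``);

``STRICT_FIRST_K``
    the first disagreement sends the record straight to the resolver, so
    consensus requires the *first* ``k`` verdicts to agree.
"""

from __future__ import annotations

import enum
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class Verdict(str, enum.Enum):
    """A single contributor's binary screening verdict (no abstain state)."""

    POSSIBLY_RELEVANT = "possibly_relevant"
    NOT_RELEVANT = "not_relevant"


class ConflictMode(str, enum.Enum):
    """What happens to a record's stream after a disagreement."""

    STREAK_CONTINUE = "streak_continue"
    STRICT_FIRST_K = "strict_first_k"


class DecisionStatus(str, enum.Enum):
    """Collective outcome of a record's classification stream."""

    POSSIBLY_RELEVANT = "possibly_relevant"
    NOT_RELEVANT = "not_relevant"
    NEEDS_RESOLUTION = "needs_resolution"


_VERDICT_TO_STATUS = {
    Verdict.POSSIBLY_RELEVANT: DecisionStatus.POSSIBLY_RELEVANT,
    Verdict.NOT_RELEVANT: DecisionStatus.NOT_RELEVANT,
}


class MalformedStreamError(ValueError):
    """Raised when a classification stream violates its structural invariants."""


@dataclass(frozen=True)
class ClassificationEvent:
    """One contributor's verdict on one record.

    ``ordinal`` is the 1-based position of the event within the record's
    stream; ``timestamp_hours`` (optional) is hours since task start.
    """

    record_id: str
    contributor_id: str
    verdict: Verdict
    ordinal: int
    timestamp_hours: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise MalformedStreamError(
                f"ordinal must be a positive integer, got {self.ordinal!r}"
            )
        if self.timestamp_hours is not None and self.timestamp_hours < 0:
            raise MalformedStreamError("timestamp_hours must be non-negative")


@dataclass(frozen=True)
class AggregationPolicy:
    """Parameters governing collective decisions.

    Parameters
    ----------
    k
        Required streak length (platform default 3).
    conflict_mode
        Behaviour after a disagreement; see module docstring.
    max_assessments
        Cap on events consumed per record before arbitration
        (``STREAK_CONTINUE`` only ever consumes up to this many).
        Defaults to ``2k + 1``, the smallest cap at which some streak of
        length ``k`` is guaranteed to be decidable either way.
    deadline_hours
        Task deadline used by the simulator (48 h on the platform).
    """

    k: int = 3
    conflict_mode: ConflictMode = ConflictMode.STREAK_CONTINUE
    max_assessments: Optional[int] = None
    deadline_hours: float = 48.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.max_assessments is None:
            object.__setattr__(self, "max_assessments", 2 * self.k + 1)
        if self.max_assessments < self.k:
            raise ValueError(
                f"max_assessments ({self.max_assessments}) must be >= k ({self.k})"
            )
        if self.deadline_hours <= 0:
            raise ValueError("deadline_hours must be positive")
        if not isinstance(self.conflict_mode, ConflictMode):
            object.__setattr__(
                self, "conflict_mode", ConflictMode(self.conflict_mode)
            )


@dataclass
class CrowdDecision:
    """Per-record collective outcome.

    ``reached_by_consensus`` is True only when a run of ``k`` identical
    verdicts finalised the record.  ``resolver_verdict`` is set when a human
    resolver later finalised a ``NEEDS_RESOLUTION`` record.
    """

    record_id: str
    status: DecisionStatus
    reached_by_consensus: bool
    n_classifications: int
    resolver_verdict: Optional[Verdict] = None

    def __post_init__(self) -> None:
        if self.reached_by_consensus and self.status is DecisionStatus.NEEDS_RESOLUTION:
            raise ValueError("a consensus decision cannot need resolution")
        if self.resolver_verdict is not None and self.reached_by_consensus:
            raise ValueError("resolver_verdict implies the crowd did not reach consensus")

    @property
    def final_verdict(self) -> Optional[Verdict]:
        """Final screening verdict, or None while the record is unresolved."""
        if self.status is DecisionStatus.POSSIBLY_RELEVANT:
            return Verdict.POSSIBLY_RELEVANT
        if self.status is DecisionStatus.NOT_RELEVANT:
            return Verdict.NOT_RELEVANT
        return self.resolver_verdict


def _validate_stream(events: Sequence[ClassificationEvent]) -> None:
    record_ids = {e.record_id for e in events}
    if len(record_ids) > 1:
        raise MalformedStreamError(
            f"events mix record_ids: {sorted(record_ids)}"
        )
    ordinals = [e.ordinal for e in events]
    if ordinals != list(range(1, len(events) + 1)):
        raise MalformedStreamError(
            f"ordinals must be consecutive from 1, got {ordinals}"
        )
    contributors = [e.contributor_id for e in events]
    if len(set(contributors)) != len(contributors):
        raise MalformedStreamError(
            "a contributor classified the same record more than once"
        )
    stamps = [e.timestamp_hours for e in events if e.timestamp_hours is not None]
    if any(b < a for a, b in zip(stamps, stamps[1:])):
        raise MalformedStreamError("timestamps must be non-decreasing in ordinal")


def aggregate_stream(
    events: Sequence[ClassificationEvent], policy: AggregationPolicy
) -> CrowdDecision:
    """Collapse one record's ordered verdict stream into a collective decision.

    Scans verdicts in ordinal order and finalises the record at the first run
    of ``policy.k`` identical verdicts.  In ``STRICT_FIRST_K`` mode any
    disagreement before the first ``k`` agree yields ``NEEDS_RESOLUTION``
    immediately; in ``STREAK_CONTINUE`` mode scanning continues until a streak
    occurs or ``policy.max_assessments`` events are consumed.

    ``n_classifications`` of the returned decision equals the number of events
    consumed, which may be fewer than supplied when a streak or disagreement
    ends the scan early.
    """
    events = list(events)
    if not events:
        warnings.warn("empty classification stream; record needs resolution", stacklevel=2)
        return CrowdDecision(
            record_id="",
            status=DecisionStatus.NEEDS_RESOLUTION,
            reached_by_consensus=False,
            n_classifications=0,
        )
    _validate_stream(events)
    record_id = events[0].record_id
    cap = policy.max_assessments
    assert cap is not None

    streak_verdict: Optional[Verdict] = None
    streak_len = 0
    consumed = 0
    for event in events[:cap]:
        consumed += 1
        if event.verdict is streak_verdict:
            streak_len += 1
        else:
            if (
                streak_verdict is not None
                and policy.conflict_mode is ConflictMode.STRICT_FIRST_K
            ):
                return CrowdDecision(
                    record_id=record_id,
                    status=DecisionStatus.NEEDS_RESOLUTION,
                    reached_by_consensus=False,
                    n_classifications=consumed,
                )
            streak_verdict = event.verdict
            streak_len = 1
        if streak_len == policy.k:
            return CrowdDecision(
                record_id=record_id,
                status=_VERDICT_TO_STATUS[streak_verdict],
                reached_by_consensus=True,
                n_classifications=consumed,
            )
    return CrowdDecision(
        record_id=record_id,
        status=DecisionStatus.NEEDS_RESOLUTION,
        reached_by_consensus=False,
        n_classifications=consumed,
    )


def partition_stream(
    stream: Iterable[ClassificationEvent],
) -> "OrderedDict[str, list[ClassificationEvent]]":
    """Group a multi-record stream by record_id, preserving first appearance
    order between records and ordinal order within each record."""
    groups: "OrderedDict[str, list[ClassificationEvent]]" = OrderedDict()
    for event in stream:
        groups.setdefault(event.record_id, []).append(event)
    for events in groups.values():
        events.sort(key=lambda e: e.ordinal)
    return groups


def aggregate_task(
    stream: Iterable[ClassificationEvent],
    policy: AggregationPolicy,
    resolver_labels: Optional[Mapping[str, Verdict]] = None,
) -> list[CrowdDecision]:
    """Aggregate a whole task's stream: one :class:`CrowdDecision` per record.

    When ``resolver_labels`` maps a ``NEEDS_RESOLUTION`` record to a verdict,
    that record gains a ``resolver_verdict``; records absent from the map stay
    unresolved.  Resolver labels for consensus records are ignored with a
    warning, since the crowd already finalised them.
    """
    decisions: list[CrowdDecision] = []
    ignored: list[str] = []
    for record_id, events in partition_stream(stream).items():
        decision = aggregate_stream(events, policy)
        if resolver_labels and record_id in resolver_labels:
            if decision.reached_by_consensus:
                ignored.append(record_id)
            else:
                decision.resolver_verdict = Verdict(resolver_labels[record_id])
        decisions.append(decision)
    if ignored:
        warnings.warn(
            f"resolver labels for {len(ignored)} consensus record(s) ignored "
            f"(first: {ignored[0]!r})",
            stacklevel=2,
        )
    return decisions


def replay_with_policy(
    stream: Iterable[ClassificationEvent], policy: AggregationPolicy
) -> list[CrowdDecision]:
    """Re-aggregate a recorded stream under an alternative policy.

    Intended for what-if comparisons on fixed data — e.g. whether requiring
    only the first two consecutive agreements (``k = 2``) would have changed
    collective decisions.  The stream should contain full recorded histories
    (no early stopping applied), otherwise a longer-``k`` policy is starved of
    events it would have consumed.
    """
    return aggregate_task(stream, policy)
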