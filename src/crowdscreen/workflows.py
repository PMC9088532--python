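"""Routing collective crowd decisions into author-team workflows.

A review team can consume crowd output three ways, trading sensitivity
against speed against specificity:

``SENSITIVITY_MAX``
    conflicted records (no crowd consensus) go to author-team *dual*
    assessment and consensus possibly-relevant records to author single
    assessment; only consensus not-relevant records are auto-excluded.

``SPEED_MAX``
    consensus possibly-relevant and conflicted records all go to author
    single assessment; consensus not-relevant records are auto-excluded.

``SPECIFICITY_MAX``
    a crowd resolver first finalises every conflicted record; the author
    team then single-assesses only the final possibly-relevant set.

Workload is counted in *assessments* (a dual-screened record costs two),
since screening effort scales with reads, not records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

from .aggregation import CrowdDecision, DecisionStatus, Verdict


class WorkflowMode(str, enum.Enum):
    SENSITIVITY_MAX = "sensitivity_max"
    SPEED_MAX = "speed_max"
    SPECIFICITY_MAX = "specificity_max"


class MissingResolverError(ValueError):
    """SPECIFICITY_MAX needs a resolver verdict for every conflicted record."""


@dataclass(frozen=True)
class WorkloadEstimate:
    """Downstream human workload implied by a workflow choice.

    ``author_single_assessments`` and ``author_dual_assessments`` count
    assessments (dual = 2 per record); ``crowd_resolver_assessments`` counts
    conflicted records a resolver had to finalise; ``records_autoexcluded``
    counts records no human on the author team ever sees.
    """

    author_single_assessments: int
    author_dual_assessments: int
    crowd_resolver_assessments: int
    records_autoexcluded: int

    def __post_init__(self) -> None:
        if min(
            self.author_single_assessments,
            self.author_dual_assessments,
            self.crowd_resolver_assessments,
            self.records_autoexcluded,
        ) < 0:
            raise ValueError("workload counts must be non-negative")

    @property
    def total_author_assessments(self) -> int:
        return self.author_single_assessments + self.author_dual_assessments


def apply_workflow(
    decisions: Sequence[CrowdDecision],
    mode: WorkflowMode,
    resolver_labels: Optional[Mapping[str, Verdict]] = None,
) -> Tuple[list, list, WorkloadEstimate]:
    """Route decisions through one workflow.

    Returns ``(author_queue, excluded, workload)`` where ``author_queue`` is
    the list of record ids the author team must assess and ``excluded`` the
    ids never seen by the team.  Every record lands in exactly one of the
    two lists.
    """
    mode = WorkflowMode(mode)
    consensus_p = [
        d.record_id
        for d in decisions
        if d.reached_by_consensus and d.status is DecisionStatus.POSSIBLY_RELEVANT
    ]
    consensus_n = [
        d.record_id
        for d in decisions
        if d.reached_by_consensus and d.status is DecisionStatus.NOT_RELEVANT
    ]
    conflicted = [d for d in decisions if not d.reached_by_consensus]

    if mode is WorkflowMode.SENSITIVITY_MAX:
        author_queue = [d.record_id for d in conflicted] + consensus_p
        excluded = list(consensus_n)
        workload = WorkloadEstimate(
            author_single_assessments=len(consensus_p),
            author_dual_assessments=2 * len(conflicted),
            crowd_resolver_assessments=0,
            records_autoexcluded=len(excluded),
        )
    elif mode is WorkflowMode.SPEED_MAX:
        author_queue = consensus_p + [d.record_id for d in conflicted]
        excluded = list(consensus_n)
        workload = WorkloadEstimate(
            author_single_assessments=len(author_queue),
            author_dual_assessments=0,
            crowd_resolver_assessments=0,
            records_autoexcluded=len(excluded),
        )
    else:  # SPECIFICITY_MAX
        resolved_p: list[str] = []
        resolved_n: list[str] = []
        missing: list[str] = []
        for d in conflicted:
            verdict = d.resolver_verdict
            if verdict is None and resolver_labels is not None:
                verdict = resolver_labels.get(d.record_id)
            if verdict is None:
                missing.append(d.record_id)
            elif Verdict(verdict) is Verdict.POSSIBLY_RELEVANT:
                resolved_p.append(d.record_id)
            else:
                resolved_n.append(d.record_id)
        if missing:
            raise MissingResolverError(
                f"{len(missing)} conflicted record(s) lack a resolver verdict: "
                f"{missing[:10]}"
            )
        author_queue = consensus_p + resolved_p
        excluded = consensus_n + resolved_n
        workload = WorkloadEstimate(
            author_single_assessments=len(author_queue),
            author_dual_assessments=0,
            crowd_resolver_assessments=len(conflicted),
            records_autoexcluded=len(excluded),
        )
    return author_queue, excluded, workload


def workflow_screening_saving(
    decisions: Sequence[CrowdDecision],
    mode: WorkflowMode,
    resolver_labels: Optional[Mapping[str, Verdict]] = None,
) -> float:
    """Fraction of records the author team never sees under ``mode``."""
    decisions = list(decisions)
    if not decisions:
        raise ZeroDivisionError("screening saving undefined for empty decisions")
    _, excluded, _ = apply_workflow(decisions, mode, resolver_labels)
    return len(excluded) / len(decisions)
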