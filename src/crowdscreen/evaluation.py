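"""Scoring collective crowd decisions against a reference standard.

The reference standard is the review author team's final include/exclude
decision per record.  Crowd sensitivity is the proportion of truly includable
records the crowd collectively flagged *possibly relevant*; crowd specificity
the proportion of ineligible records it collectively rejected.  Crowd
consensus is reference-free: the proportion of records finalised by the
agreement algorithm without needing a resolver.

Reported percentages follow the screening literature's convention of half-up
rounding (31/32 prints as 96.9, not banker's 96.8): see :func:`round_half_up`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence, Set, Tuple

from .aggregation import CrowdDecision, DecisionStatus, Verdict


class ReferenceLabel(str, enum.Enum):
    RELEVANT = "relevant"
    NOT_RELEVANT = "not_relevant"
    UNKNOWN = "unknown"


class UnresolvedRecordsError(ValueError):
    """Confusion counting requires every record to carry a final verdict."""

    def __init__(self, record_ids: Sequence[str]):
        self.record_ids = list(record_ids)
        super().__init__(
            f"{len(self.record_ids)} record(s) lack a final verdict: "
            f"{self.record_ids[:10]}"
        )


class MissingReferenceError(KeyError):
    """A decision's record has no entry in the reference standard."""


class UndefinedMetricError(ZeroDivisionError):
    """A rate's denominator is zero (e.g. no relevant records to be sensitive to)."""


@dataclass
class RecordEntry:
    """One title/abstract citation, optionally carrying its reference label.

    ``title_only`` marks a record lacking an abstract, screened from the
    title alone; it is derived from ``abstract`` when not given and must be
    consistent with it when it is.
    """

    record_id: str
    title: str
    abstract: Optional[str] = None
    title_only: Optional[bool] = None
    reference_label: ReferenceLabel = ReferenceLabel.UNKNOWN

    def __post_init__(self) -> None:
        has_abstract = bool(self.abstract and str(self.abstract).strip())
        if self.title_only is None:
            self.title_only = not has_abstract
        elif self.title_only == has_abstract:
            raise ValueError(
                f"record {self.record_id!r}: title_only={self.title_only} "
                f"inconsistent with abstract presence"
            )
        if not isinstance(self.reference_label, ReferenceLabel):
            self.reference_label = ReferenceLabel(self.reference_label)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts of final crowd verdicts against the reference.

    tp: truly includable records the crowd flagged possibly relevant;
    fn: truly includable records the crowd rejected (missed studies);
    tn/fp analogous for ineligible records.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_relevant(self) -> int:
        return self.tp + self.fn

    @property
    def n_not_relevant(self) -> int:
        return self.tn + self.fp


@dataclass
class PerformanceReport:
    """Accuracy and consensus summary for one screening task."""

    counts: ConfusionCounts
    sensitivity_pct: float
    specificity_pct: float
    consensus_pct: float
    included_consensus_pct: Optional[float] = None
    title_only_consensus_pct: Optional[float] = None
    missed_record_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.missed_record_ids) != self.counts.fn:
            raise ValueError("missed_record_ids must have length fn")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as screening reports conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _final_verdicts(
    decisions: Sequence[CrowdDecision],
) -> dict[str, Verdict]:
    unresolved = [d.record_id for d in decisions if d.final_verdict is None]
    if unresolved:
        raise UnresolvedRecordsError(unresolved)
    return {d.record_id: d.final_verdict for d in decisions}


def confusion(
    decisions: Sequence[CrowdDecision],
    reference: Mapping[str, ReferenceLabel],
) -> ConfusionCounts:
    """Count final crowd verdicts against the reference standard.

    Every decision must be final (consensus or resolver-finalised) and every
    record must appear in ``reference``.  Records whose reference label is
    ``UNKNOWN`` are excluded from the counts — accuracy is undefined for them
    — but an entirely missing label is an error.
    """
    finals = _final_verdicts(decisions)
    tp = tn = fp = fn = 0
    for record_id, verdict in finals.items():
        if record_id not in reference:
            raise MissingReferenceError(
                f"no reference label for record {record_id!r}"
            )
        label = ReferenceLabel(reference[record_id])
        if label is ReferenceLabel.UNKNOWN:
            continue
        flagged = verdict is Verdict.POSSIBLY_RELEVANT
        if label is ReferenceLabel.RELEVANT:
            tp += flagged
            fn += not flagged
        else:
            fp += flagged
            tn += not flagged
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity_pct(counts: ConfusionCounts) -> float:
    """100·tp/(tp+fn), half-up rounded to 1 decimal."""
    if counts.n_relevant == 0:
        raise UndefinedMetricError("sensitivity undefined: no relevant records")
    return round_half_up(100.0 * counts.tp / counts.n_relevant, 1)


def specificity_pct(counts: ConfusionCounts) -> float:
    """100·tn/(tn+fp), half-up rounded to 1 decimal."""
    if counts.n_not_relevant == 0:
        raise UndefinedMetricError("specificity undefined: no non-relevant records")
    return round_half_up(100.0 * counts.tn / counts.n_not_relevant, 1)


def consensus_pct(decisions: Sequence[CrowdDecision]) -> float:
    """Percentage of records finalised without arbitration, to 2 decimals.

    Resolver-finalised records count toward accuracy but never toward
    consensus; the statistic is reference-free.
    """
    decisions = list(decisions)
    if not decisions:
        raise UndefinedMetricError("consensus undefined on an empty decision list")
    n_consensus = sum(d.reached_by_consensus for d in decisions)
    return round_half_up(100.0 * n_consensus / len(decisions), 2)


def subgroup_consensus(
    decisions: Sequence[CrowdDecision],
    records: Sequence[RecordEntry],
    predicate: Callable[[RecordEntry], bool],
) -> float:
    """Consensus restricted to records satisfying ``predicate``.

    Used for the two subgroups of interest in crowd screening: truly
    includable records (whose consensus runs lower than the task average when
    prevalence is low) and title-only records (lower still, lacking abstracts).
    """
    selected = {r.record_id for r in records if predicate(r)}
    subset = [d for d in decisions if d.record_id in selected]
    if not subset:
        raise UndefinedMetricError("subgroup predicate selected no evaluated records")
    return consensus_pct(subset)


def missed_study_report(
    decisions: Sequence[CrowdDecision],
    reference: Mapping[str, ReferenceLabel],
    records: Sequence[RecordEntry],
) -> list[RecordEntry]:
    """The false-negative records — truly includable studies the crowd
    rejected — with their titles, for human inspection."""
    finals = _final_verdicts(decisions)
    by_id = {r.record_id: r for r in records}
    missed = []
    for record_id, verdict in finals.items():
        if record_id not in reference:
            raise MissingReferenceError(
                f"no reference label for record {record_id!r}"
            )
        if (
            ReferenceLabel(reference[record_id]) is ReferenceLabel.RELEVANT
            and verdict is Verdict.NOT_RELEVANT
        ):
            missed.append(
                by_id.get(record_id, RecordEntry(record_id=record_id, title=""))
            )
    return missed


def pooled_miss_rate_pct(reports: Sequence[PerformanceReport]) -> float:
    """Pooled false-negative rate across tasks: 100·Σfn / Σ(tp+fn), 1 decimal.

    Answers "of all includable studies across the reviews, what fraction did
    the crowd reject?" — the headline safety figure of a screening crowd.
    """
    if not reports:
        raise UndefinedMetricError("no reports to pool")
    total_fn = sum(r.counts.fn for r in reports)
    total_relevant = sum(r.counts.n_relevant for r in reports)
    if total_relevant == 0:
        raise UndefinedMetricError("pooled miss rate undefined: no relevant records")
    return round_half_up(100.0 * total_fn / total_relevant, 1)


def citation_recovery(
    missed_ids: Iterable[str],
    includes_ids: Iterable[str],
    citation_edges: Iterable[Tuple[str, str]],
) -> Set[str]:
    """Forward citation tracking: which missed studies would have been
    recovered because an included study cites them?

    ``citation_edges`` are (citing_id, cited_id) pairs.  Edges touching ids
    outside the two sets are ignored with a warning.
    """
    missed = set(missed_ids)
    includes = set(includes_ids)
    known = missed | includes
    recovered: Set[str] = set()
    unknown_edges = 0
    for citing, cited in citation_edges:
        if citing not in known or cited not in known:
            unknown_edges += 1
            continue
        if citing in includes and cited in missed:
            recovered.add(cited)
    if unknown_edges:
        warnings.warn(
            f"{unknown_edges} citation edge(s) referenced unknown record ids; ignored",
            stacklevel=2,
        )
    return recovered


def performance_report(
    decisions: Sequence[CrowdDecision],
    records: Sequence[RecordEntry],
) -> PerformanceReport:
    """Build the full per-task report from decisions and labelled records.

    The reference standard is taken from each record's ``reference_label``.
    Subgroup consensus values are omitted (None) when the subgroup is empty.
    """
    reference = {r.record_id: r.reference_label for r in records}
    counts = confusion(decisions, reference)
    missed = missed_study_report(decisions, reference, records)

    def _maybe_subgroup(pred: Callable[[RecordEntry], bool]) -> Optional[float]:
        try:
            return subgroup_consensus(decisions, records, pred)
        except UndefinedMetricError:
            return None

    return PerformanceReport(
        counts=counts,
        sensitivity_pct=sensitivity_pct(counts),
        specificity_pct=specificity_pct(counts),
        consensus_pct=consensus_pct(decisions),
        included_consensus_pct=_maybe_subgroup(
            lambda r: r.reference_label is ReferenceLabel.RELEVANT
        ),
        title_only_consensus_pct=_maybe_subgroup(lambda r: bool(r.title_only)),
        missed_record_ids=[r.record_id for r in missed],
    )
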