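"""Published operating characteristics of the four Cochrane COVID-19 Rapid
Review screening tasks the simulator is calibrated against.

Each preset bundles, for one review's crowd task: the search-result set size,
the number of includable studies in the evaluation set, the contributor pool
that took part, mean individual contributor sensitivity/specificity estimated
from the task's classification data, the fraction of title-only records, and
the collective confusion counts and reported percentages the crowd achieved
under the three-consecutive-agreement algorithm within the 48-hour window.

These are inputs to replication-style simulations and fixtures, not outputs:
everything a :class:`ReviewTask` carries was observed on the live platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .aggregation import CrowdDecision, DecisionStatus, Verdict
from .evaluation import ConfusionCounts, RecordEntry, ReferenceLabel


@dataclass(frozen=True)
class ReviewTask:
    """Observed characteristics of one crowd screening task."""

    slug: str
    name: str
    n_records: int
    n_included: int          # includable studies in the evaluation set
    pool_size: int           # contributors who took part
    contributor_sens: float  # mean individual sensitivity (fraction)
    contributor_spec: float  # mean individual specificity (fraction)
    title_only_fraction: float
    counts: ConfusionCounts  # collective crowd confusion vs reference standard
    reported_sensitivity_pct: float
    reported_specificity_pct: float
    reported_consensus_pct: float
    reported_included_consensus_pct: float

    @property
    def prevalence(self) -> float:
        """Includable-study prevalence of the evaluation set."""
        return self.n_included / self.n_records


REVIEW_TASKS: tuple[ReviewTask, ...] = (
    ReviewTask(
        slug="quarantine",
        name="Quarantine measures to control COVID-19",
        n_records=5606,
        n_included=47,
        pool_size=65,
        contributor_sens=0.842,
        contributor_spec=0.822,
        title_only_fraction=0.057,
        counts=ConfusionCounts(tp=45, tn=3942, fp=1617, fn=2),
        reported_sensitivity_pct=95.7,
        reported_specificity_pct=70.9,
        reported_consensus_pct=72.02,
        reported_included_consensus_pct=60.0,
    ),
    ReviewTask(
        slug="ipc_adherence",
        name="Healthcare workers' adherence with IPC guidelines",
        n_records=3367,
        n_included=32,
        pool_size=36,
        contributor_sens=0.866,
        contributor_spec=0.841,
        title_only_fraction=0.072,
        counts=ConfusionCounts(tp=31, tn=2437, fp=897, fn=1),
        reported_sensitivity_pct=96.9,
        reported_specificity_pct=73.0,
        reported_consensus_pct=74.96,
        reported_included_consensus_pct=61.0,
    ),
    ReviewTask(
        slug="universal_screening",
        name="Universal screening for SARS-CoV-2",
        n_records=4378,
        n_included=18,
        pool_size=38,
        contributor_sens=0.851,
        contributor_spec=0.899,
        title_only_fraction=0.068,
        counts=ConfusionCounts(tp=17, tn=3075, fp=1285, fn=1),
        reported_sensitivity_pct=94.4,
        reported_specificity_pct=70.5,
        reported_consensus_pct=71.34,
        reported_included_consensus_pct=65.0,
    ),
    ReviewTask(
        slug="convalescent_plasma",
        name="Convalescent plasma for people with COVID-19",
        n_records=948,
        n_included=12,
        pool_size=12,
        contributor_sens=0.893,
        contributor_spec=0.909,
        title_only_fraction=0.066,
        counts=ConfusionCounts(tp=12, tn=827, fp=109, fn=0),
        reported_sensitivity_pct=100.0,
        reported_specificity_pct=88.7,
        reported_consensus_pct=92.19,
        reported_included_consensus_pct=63.0,
    ),
)

TASKS_BY_SLUG = {t.slug: t for t in REVIEW_TASKS}


def synthetic_outcomes(
    counts: ConfusionCounts, prefix: str = "rec"
) -> tuple[list[CrowdDecision], list[RecordEntry]]:
    """Materialise a minimal decision/record set realising given confusion
    counts, for fixtures and round-trip tests.

    All decisions are marked as consensus at ``n_classifications = 3``; the
    record ids encode their cell (``<prefix>-tp-0`` etc.) and every record is
    a synthetic placeholder citation, not real bibliographic data.
    """
    decisions: list[CrowdDecision] = []
    records: list[RecordEntry] = []
    cells = {
        "tp": (counts.tp, DecisionStatus.POSSIBLY_RELEVANT, ReferenceLabel.RELEVANT),
        "fn": (counts.fn, DecisionStatus.NOT_RELEVANT, ReferenceLabel.RELEVANT),
        "tn": (counts.tn, DecisionStatus.NOT_RELEVANT, ReferenceLabel.NOT_RELEVANT),
        "fp": (counts.fp, DecisionStatus.POSSIBLY_RELEVANT, ReferenceLabel.NOT_RELEVANT),
    }
    for cell, (n, status, label) in cells.items():
        for i in range(n):
            record_id = f"{prefix}-{cell}-{i}"
            decisions.append(
                CrowdDecision(
                    record_id=record_id,
                    status=status,
                    reached_by_consensus=True,
                    n_classifications=3,
                )
            )
            records.append(
                RecordEntry(
                    record_id=record_id,
                    title=f"Synthetic {cell.upper()} record {i}",
                    abstract="Synthetic abstract.",
                    reference_label=label,
                )
            )
    return decisions, records
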