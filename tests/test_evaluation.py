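"""Tests for accuracy and consensus scoring against a reference standard."""

import pytest

from crowdscreen.aggregation import CrowdDecision, DecisionStatus, Verdict
from crowdscreen.evaluation import (
    ConfusionCounts,
    MissingReferenceError,
    PerformanceReport,
    RecordEntry,
    ReferenceLabel,
    UndefinedMetricError,
    UnresolvedRecordsError,
    citation_recovery,
    confusion,
    consensus_pct,
    missed_study_report,
    performance_report,
    pooled_miss_rate_pct,
    round_half_up,
    sensitivity_pct,
    specificity_pct,
    subgroup_consensus,
)
from crowdscreen.presets import synthetic_outcomes

P, N = Verdict.POSSIBLY_RELEVANT, Verdict.NOT_RELEVANT
REL, NOT = ReferenceLabel.RELEVANT, ReferenceLabel.NOT_RELEVANT


def _decision(record_id, status, consensus=True, resolver=None, n=3):
    return CrowdDecision(
        record_id=record_id,
        status=status,
        reached_by_consensus=consensus,
        n_classifications=n,
        resolver_verdict=resolver,
    )


def test_confusion_basic_counts():
    decisions = [
        _decision("a", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("b", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("c", DecisionStatus.NOT_RELEVANT),
    ]
    counts = confusion(decisions, {"a": REL, "b": NOT, "c": NOT})
    assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 1, 0)
    assert counts.total == 3


def test_confusion_all_correct_has_no_errors():
    decisions = [
        _decision("a", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("b", DecisionStatus.NOT_RELEVANT),
    ]
    counts = confusion(decisions, {"a": REL, "b": NOT})
    assert counts.fp == counts.fn == 0


def test_confusion_uses_resolver_verdicts():
    decisions = [
        _decision("a", DecisionStatus.NEEDS_RESOLUTION, consensus=False, resolver=P),
    ]
    counts = confusion(decisions, {"a": REL})
    assert counts.tp == 1


def test_confusion_unresolved_records_error_names_ids():
    decisions = [_decision("bad", DecisionStatus.NEEDS_RESOLUTION, consensus=False)]
    with pytest.raises(UnresolvedRecordsError) as excinfo:
        confusion(decisions, {"bad": REL})
    assert "bad" in str(excinfo.value)


def test_confusion_missing_reference_label_errors():
    decisions = [_decision("a", DecisionStatus.POSSIBLY_RELEVANT)]
    with pytest.raises(MissingReferenceError):
        confusion(decisions, {})


def test_confusion_unknown_labels_excluded_but_consensus_keeps_them():
    decisions = [
        _decision("a", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("u", DecisionStatus.NOT_RELEVANT),
    ]
    counts = confusion(decisions, {"a": REL, "u": ReferenceLabel.UNKNOWN})
    assert counts.total == 1
    assert consensus_pct(decisions) == 100.0  # consensus is reference-free


def test_confusion_counts_conserve_at_task_scale():
    decisions, records = synthetic_outcomes(ConfusionCounts(tp=45, tn=3942, fp=1617, fn=2))
    counts = confusion(decisions, {r.record_id: r.reference_label for r in records})
    assert counts.total == 5606
    assert (counts.tp, counts.tn, counts.fp, counts.fn) == (45, 3942, 1617, 2)


@pytest.mark.parametrize(
    "tp,fn,expected",
    [(45, 2, 95.7), (31, 1, 96.9), (17, 1, 94.4), (12, 0, 100.0), (0, 5, 0.0)],
)
def test_sensitivity_formula_and_rounding(tp, fn, expected):
    assert sensitivity_pct(ConfusionCounts(tp=tp, tn=0, fp=1, fn=fn)) == expected


@pytest.mark.parametrize(
    "tn,fp,expected",
    [(3942, 1617, 70.9), (3075, 1285, 70.5), (0, 10, 0.0), (827, 109, 88.4)],
)
def test_specificity_formula_and_rounding(tn, fp, expected):
    assert specificity_pct(ConfusionCounts(tp=1, tn=tn, fp=fp, fn=0)) == expected


def test_rounding_is_half_up_not_bankers():
    # 31/32 = 96.875: banker's rounding would print 96.8
    assert round_half_up(96.875, 1) == 96.9
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(72.015, 2) == 72.02


def test_undefined_metrics_raise():
    with pytest.raises(UndefinedMetricError):
        sensitivity_pct(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))
    with pytest.raises(UndefinedMetricError):
        specificity_pct(ConfusionCounts(tp=5, tn=0, fp=0, fn=5))
    with pytest.raises(UndefinedMetricError):
        consensus_pct([])
    with pytest.raises(UndefinedMetricError):
        pooled_miss_rate_pct([])


def test_consensus_pct_values_and_order_invariance():
    decisions = [
        _decision("a", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("b", DecisionStatus.NOT_RELEVANT),
        _decision("c", DecisionStatus.NOT_RELEVANT),
        _decision("d", DecisionStatus.NEEDS_RESOLUTION, consensus=False),
    ]
    assert consensus_pct(decisions) == 75.0
    assert consensus_pct(list(reversed(decisions))) == 75.0
    assert consensus_pct(decisions[:3]) == 100.0


def test_consensus_pct_two_decimal_reporting():
    decisions = [
        _decision(f"c{i}", DecisionStatus.NOT_RELEVANT) for i in range(7202)
    ] + [
        _decision(f"r{i}", DecisionStatus.NEEDS_RESOLUTION, consensus=False)
        for i in range(2798)
    ]
    assert consensus_pct(decisions) == 72.02


def test_subgroup_consensus_identity_and_empty():
    decisions = [
        _decision("a", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("b", DecisionStatus.NEEDS_RESOLUTION, consensus=False),
    ]
    records = [
        RecordEntry("a", "t", "abs", reference_label=REL),
        RecordEntry("b", "t", "abs", reference_label=NOT),
    ]
    assert subgroup_consensus(decisions, records, lambda r: True) == consensus_pct(decisions)
    assert subgroup_consensus(decisions, records, lambda r: r.record_id == "b") == 0.0
    with pytest.raises(UndefinedMetricError):
        subgroup_consensus(decisions, records, lambda r: False)


def test_symmetry_swapping_labels_and_verdicts_swaps_metrics():
    """Relabelling relevant<->not-relevant and flipping every verdict must
    exchange tp<->tn, fp<->fn and hence sensitivity<->specificity."""
    decisions = [
        _decision("a", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("b", DecisionStatus.NOT_RELEVANT),
        _decision("c", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("d", DecisionStatus.NOT_RELEVANT),
    ]
    reference = {"a": REL, "b": REL, "c": NOT, "d": NOT}
    flip_status = {
        DecisionStatus.POSSIBLY_RELEVANT: DecisionStatus.NOT_RELEVANT,
        DecisionStatus.NOT_RELEVANT: DecisionStatus.POSSIBLY_RELEVANT,
    }
    flipped_decisions = [
        _decision(d.record_id, flip_status[d.status]) for d in decisions
    ]
    flipped_reference = {k: (NOT if v is REL else REL) for k, v in reference.items()}
    counts = confusion(decisions, reference)
    flipped = confusion(flipped_decisions, flipped_reference)
    assert (flipped.tp, flipped.tn, flipped.fp, flipped.fn) == (
        counts.tn,
        counts.tp,
        counts.fn,
        counts.fp,
    )
    assert sensitivity_pct(flipped) == specificity_pct(counts)


def test_missed_study_report_lists_false_negatives_with_titles():
    decisions = [
        _decision("hit", DecisionStatus.POSSIBLY_RELEVANT),
        _decision("miss", DecisionStatus.NOT_RELEVANT),
        _decision("ok", DecisionStatus.NOT_RELEVANT),
    ]
    reference = {"hit": REL, "miss": REL, "ok": NOT}
    records = [
        RecordEntry("hit", "Found study", "a"),
        RecordEntry("miss", "Missed study", "a"),
        RecordEntry("ok", "Irrelevant", "a"),
    ]
    missed = missed_study_report(decisions, reference, records)
    assert [r.record_id for r in missed] == ["miss"]
    assert missed[0].title == "Missed study"
    assert missed_study_report(decisions[:1], {"hit": REL}, records) == []


def test_pooled_miss_rate_across_tasks():
    reports = []
    for tp, fn in [(45, 2), (31, 1), (17, 1), (12, 0)]:
        decisions, records = synthetic_outcomes(
            ConfusionCounts(tp=tp, tn=5, fp=5, fn=fn), prefix=f"t{tp}"
        )
        reports.append(performance_report(decisions, records))
    assert pooled_miss_rate_pct(reports) == 3.7  # 4 missed of 109 includable
    single = performance_report(
        *synthetic_outcomes(ConfusionCounts(tp=9, tn=5, fp=5, fn=1))
    )
    assert pooled_miss_rate_pct([single]) == 10.0


def test_pooled_miss_rate_zero_when_nothing_missed():
    decisions, records = synthetic_outcomes(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
    assert pooled_miss_rate_pct([performance_report(decisions, records)]) == 0.0


def test_citation_recovery():
    assert citation_recovery(["m1"], ["i1"], []) == set()
    assert citation_recovery(["m1"], ["i1"], [("i1", "m1")]) == {"m1"}
    # missed records citing each other do not count; unknown ids warn
    with pytest.warns(UserWarning, match="unknown"):
        recovered = citation_recovery(
            ["m1", "m2", "m3", "m4"],
            ["i1", "i2"],
            [("i1", "m1"), ("i2", "m2"), ("m3", "m4"), ("x", "m4")],
        )
    assert recovered == {"m1", "m2"}


def test_record_entry_title_only_consistency():
    assert RecordEntry("a", "t").title_only is True
    assert RecordEntry("a", "t", abstract="text").title_only is False
    assert RecordEntry("a", "t", abstract="  ").title_only is True
    with pytest.raises(ValueError):
        RecordEntry("a", "t", abstract="text", title_only=True)


def test_performance_report_fields_are_consistent():
    decisions, records = synthetic_outcomes(ConfusionCounts(tp=3, tn=10, fp=2, fn=1))
    report = performance_report(decisions, records)
    assert report.counts.total == 16
    assert len(report.missed_record_ids) == report.counts.fn
    assert report.sensitivity_pct == 75.0
    assert report.consensus_pct == 100.0
    assert report.included_consensus_pct == 100.0
    assert report.title_only_consensus_pct is None  # no title-only records
    with pytest.raises(ValueError):
        PerformanceReport(
            counts=report.counts,
            sensitivity_pct=75.0,
            specificity_pct=80.0,
            consensus_pct=100.0,
            missed_record_ids=[],  # wrong length vs fn=1
        )
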