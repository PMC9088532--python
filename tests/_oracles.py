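"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take a different route from the production code: the
aggregation oracle tests fixed-size windows over the consumed prefix instead
of tracking a running streak.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from crowdscreen.aggregation import ClassificationEvent, Verdict

P = Verdict.POSSIBLY_RELEVANT
N = Verdict.NOT_RELEVANT


def events_from_verdicts(
    verdicts: Sequence[Verdict],
    record_id: str = "r1",
    contributor_prefix: str = "c",
    t0: float = 0.0,
) -> list[ClassificationEvent]:
    return [
        ClassificationEvent(
            record_id=record_id,
            contributor_id=f"{contributor_prefix}{i}",
            verdict=v,
            ordinal=i + 1,
            timestamp_hours=t0 + 0.1 * i,
        )
        for i, v in enumerate(verdicts)
    ]


def window_scan_decision(
    verdicts: Sequence[Verdict], k: int, strict: bool, cap: int
) -> Tuple[Optional[Verdict], bool, int]:
    """Brute-force reference: (final verdict or None, consensus?, n consumed).

    Strict mode: consensus iff the first k verdicts exist and agree; a
    disagreement is consumed and ends the scan.  Streak-continue mode: the
    earliest window of k identical verdicts within the first ``cap`` events
    wins; otherwise all available events up to the cap are consumed.
    """
    vs = list(verdicts)[:cap]
    if strict:
        # consensus at event k precedes any disagreement consumed later
        if len(vs) >= k and len(set(vs[:k])) == 1:
            return vs[0], True, k
        for i, v in enumerate(vs):
            if v != vs[0]:
                return None, False, i + 1
        return None, False, len(vs)
    for end in range(k, len(vs) + 1):
        window = vs[end - k : end]
        if len(set(window)) == 1:
            return window[0], True, end
    return None, False, len(vs)
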