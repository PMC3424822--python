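"""Per-read processing pipeline and dataset summaries.

Order of operations per read: quality segmentation -> element detection ->
terminus assembly, scoring and disambiguation -> pattern construction -> DBT
scan -> abnormality classification -> insert extraction.  Reads with a RECA
call or a chimeric DBT are filtered; a trimmable internal DBT is excised; all
other reads are trimmed via the best reasonable terminus pair, or — when only
a single confident terminus exists — from that terminus to the read's
quality/vector boundary (flag-controlled fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .abnormality import AbnormalityCall, DBTHit, classify_read, detect_dbt
from .elements import (ElementHit, QualitySegment, ReadRecord,
                       collect_element_hits)
from .patterns import (PatternString, TerminusHit, TerminusPair,
                       assemble_termini, build_pattern, disambiguate,
                       find_reasonable_pairs, score_all, select_best_pair)
from .protocol import ProtocolSpec

__all__ = [
    "RunParams",
    "ReadReport",
    "SummaryStats",
    "process_read",
    "process_dataset",
    "extract_clean_insert",
    "summarize",
]

_DNA_OK = frozenset("ACGTN")


@dataclass
class RunParams:
    """All tunable thresholds of the pipeline (defaults as documented)."""

    quality_window: int = 20
    min_q: int = 16
    poly_min_len: int = 8
    poly_max_impurity: float = 0.1
    vector_min_len: int = 20
    vector_min_identity: float = 0.94
    adapter_max_mismatch: int = 1
    max_gap: int = 2
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    min_separation: int = 200
    min_clean_len: int = 100
    dbt_max_mismatch: int = 2
    flank_window: int = 30
    min_token_len: int = 20
    single_terminus_fallback: bool = True


@dataclass
class ReadReport:
    """Everything the pipeline decided about one read."""

    read_id: str
    direction: str
    pattern: PatternString | None = None
    termini: list[TerminusHit] = field(default_factory=list)
    dbt_hits: list[DBTHit] = field(default_factory=list)
    primary: AbnormalityCall | None = None
    secondary: list[AbnormalityCall] = field(default_factory=list)
    outcome: str = "filtered"  # "clean" | "filtered"
    clean_interval: tuple[int, int] | None = None
    rejection_reason: str | None = None
    warning: str | None = None
    selected_pair: TerminusPair | None = None

    @property
    def primary_category(self) -> str:
        """The read's classification; 'expected' when nothing abnormal matched."""
        return self.primary.category if self.primary is not None else "expected"

    @property
    def pattern_rendering(self) -> str:
        return self.pattern.render() if self.pattern is not None else ""


def _shrink_past(interval: tuple[int, int],
                 obstacles: list[tuple[int, int]]) -> tuple[int, int]:
    """Move both ends of ``interval`` inward past any flanking obstacle."""
    s, e = interval
    changed = True
    while changed and s < e:
        changed = False
        for os_, oe in obstacles:
            if oe <= s or os_ >= e:
                continue
            if os_ <= s:
                s = oe
                changed = True
            elif oe >= e:
                e = os_
                changed = True
    return s, e


def extract_clean_insert(read: ReadRecord,
                         pair: TerminusPair | TerminusHit,
                         segments: list[QualitySegment],
                         vector_hits: list[ElementHit],
                         min_clean_len: int = 100,
                         exclude: list[tuple[int, int]] | None = None,
                         ) -> tuple[tuple[int, int] | None, str | None]:
    """The bona fide insert interval between the selected termini.

    Starts at the inner edge of the upstream terminus and ends at the inner
    edge of the downstream one (for a single-terminus fallback, the other
    boundary is the read end on the terminus' insert side).  Spans in
    ``exclude`` (internal DBTs) are removed keeping the larger remainder;
    both ends are then shrunk past overlapping vector hits and low-quality
    segments.  Returns ``(interval, None)`` or ``(None, reason)``.
    """
    n = len(read)
    if isinstance(pair, TerminusPair):
        s, e = pair.left.end, pair.right.start
        if e <= s:
            return None, "degenerate pair"
    else:
        if pair.family in ("5TSS", "5TNS"):
            s, e = pair.end, n
        else:
            s, e = 0, pair.start
    for xs, xe in sorted(exclude or []):
        if xe <= s or xs >= e:
            continue
        left_len = max(0, xs - s)
        right_len = max(0, e - xe)
        if left_len >= right_len:
            e = xs
        else:
            s = xe
    obstacles = [h.interval for h in vector_hits]
    obstacles += [(seg.start, seg.end) for seg in segments if seg.label == "low"]
    s, e = _shrink_past((s, e), obstacles)
    if e - s < min_clean_len:
        return None, "insert too short"
    return (s, e), None


def process_read(read: ReadRecord, protocol: ProtocolSpec,
                 params: RunParams | None = None) -> ReadReport:
    """Run the full per-read pipeline; never raises on malformed input."""
    params = params or RunParams()
    direction = read.designated_direction
    if direction == "unknown":
        direction = protocol.direction_of(read.id)
        read.designated_direction = direction
    report = ReadReport(read.id, direction)
    if not read.bases or any(c not in _DNA_OK for c in read.bases):
        report.rejection_reason = "invalid input"
        return report
    try:
        scan = collect_element_hits(
            read, protocol,
            adapter_max_mismatch=params.adapter_max_mismatch,
            poly_min_len=params.poly_min_len,
            poly_max_impurity=params.poly_max_impurity,
            vector_min_len=params.vector_min_len,
            vector_min_identity=params.vector_min_identity,
            quality_window=params.quality_window, min_q=params.min_q,
        )
    except ValueError as exc:
        report.rejection_reason = f"invalid input: {exc}"
        return report

    termini = assemble_termini(read, scan.motif_hits, protocol, params.max_gap)
    score_all(read, termini, protocol, scan.vector_hits, scan.segments,
              params.weights, params.flank_window)
    termini = disambiguate(termini)
    report.termini = termini
    pattern = build_pattern(read, termini, scan.vector_hits, scan.segments,
                            params.min_token_len)
    report.pattern = pattern
    report.dbt_hits = detect_dbt(read.bases, params.dbt_max_mismatch)
    report.primary, report.secondary = classify_read(
        pattern, direction, report.dbt_hits, scan.vector_hits, protocol
    )

    cat = report.primary.category if report.primary else ""
    if cat.startswith("RECA") or cat == "DBT-chimera":
        report.outcome = "filtered"
        report.rejection_reason = cat
        return report

    exclude = None
    eligible = termini
    if cat == "DBT-internal":
        exclude = [h.interval for h in report.dbt_hits]
        eligible = [
            t for t in termini
            if not any(t.start < e and s < t.end for s, e in exclude)
        ]

    search = find_reasonable_pairs(eligible, direction, params.min_separation)
    if search.warning:
        report.warning = search.warning
    pair = select_best_pair(search.pairs)
    chosen: TerminusPair | TerminusHit | None = pair
    if pair is None and params.single_terminus_fallback and eligible:
        chosen = max(eligible, key=lambda t: (t.confidence, -t.start))
    report.selected_pair = pair

    if chosen is None:
        if not termini:
            # nothing recognizable: keep the quality/vector-trimmed read
            interval, reason = extract_clean_insert(
                read, TerminusHit("", "5TSS", 0, 0, [], 0, 0),
                scan.segments, scan.vector_hits, params.min_clean_len
            )
            if interval is None:
                report.rejection_reason = reason
                return report
            report.outcome = "clean"
            report.clean_interval = interval
            report.warning = "untrimmed-no-termini"
            return report
        report.rejection_reason = "no usable terminus"
        return report

    interval, reason = extract_clean_insert(
        read, chosen, scan.segments, scan.vector_hits,
        params.min_clean_len, exclude
    )
    if interval is None:
        report.rejection_reason = reason
        return report
    report.outcome = "clean"
    report.clean_interval = interval
    return report


def process_dataset(reads: list[ReadRecord], protocol: ProtocolSpec,
                    params: RunParams | None = None) -> list[ReadReport]:
    params = params or RunParams()
    return [process_read(r, protocol, params) for r in reads]


# ---------------------------------------------------------------------------
# summaries


@dataclass
class SummaryStats:
    total: int
    n_with_termini: int
    n_clean: int
    n_filtered: int
    by_pattern: pd.DataFrame
    by_category: pd.DataFrame

    @property
    def pct_with_termini(self) -> float:
        return 100.0 * self.n_with_termini / self.total if self.total else 0.0


def summarize(reports: list[ReadReport]) -> SummaryStats:
    """Aggregate counts by pattern rendering and by primary category."""
    total = len(reports)
    n_term = sum(1 for r in reports if r.termini)
    n_clean = sum(1 for r in reports if r.outcome == "clean")

    def table(values: list[str]) -> pd.DataFrame:
        if not values:
            return pd.DataFrame(columns=["value", "count", "percent"])
        s = pd.Series(values).value_counts()
        return pd.DataFrame({
            "value": s.index,
            "count": s.values,
            "percent": 100.0 * s.values / total,
        })

    return SummaryStats(
        total=total,
        n_with_termini=n_term,
        n_clean=n_clean,
        n_filtered=total - n_clean,
        by_pattern=table([r.pattern_rendering for r in reports]),
        by_category=table([r.primary_category for r in reports]),
    )
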