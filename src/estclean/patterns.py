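"""Assembling element hits into cDNA termini and read pattern strings.

A terminus instance is a chain of adjacent element hits matching one
:class:`~estclean.protocol.TerminusDef` element order.  Each instance gets a
confidence score combining three sub-scores:

* **A (completeness)** — how many of the canonical terminus' elements this
  variant carries: ``100 * len(variant) / len(canonical)``;
* **B (context)** — whether the flanking sequence matches expectation
  (vector upstream of a 5'-side terminus, insert downstream, ...): 100 for the
  expected content, 50 for low-quality non-matching content, 0 for confident
  non-matching content, averaged over the two flanks;
* **C (base identity)** — percentage of terminus bases matching the expected
  element sequences.

``confidence = wA*A + wB*B + wC*C`` with weights on the simplex
(default 1/3 each).

The read's *pattern* is the ordered token string of terminus names and V/N
context tokens (optionally refined to HV/LV/HN/LN), rendered comma-separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import (ElementHit, QualitySegment, ReadRecord,
                       classify_context)
from .protocol import ProtocolSpec, SequenceElement, TerminusDef

__all__ = [
    "TerminusHit",
    "PatternString",
    "TerminusPair",
    "assemble_termini",
    "context_score",
    "score_terminus",
    "disambiguate",
    "build_pattern",
    "find_reasonable_pairs",
    "select_best_pair",
]


@dataclass
class ComponentPlacement:
    """Where one terminus element landed on the read."""

    label: str
    start: int
    end: int
    mismatches: int
    from_hit: bool  # False when filled by context-anchored literal match


@dataclass
class TerminusHit:
    """A located terminus instance with its confidence sub-scores."""

    def_name: str
    family: str
    start: int
    end: int
    components: list[ComponentPlacement]
    n_elements: float  # completeness weight of the matched definition
    mismatch_total: int
    a_score: float = 0.0
    b_score: float = 0.0
    c_score: float = 0.0
    confidence: float = 0.0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "TerminusHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TerminusPair:
    left: TerminusHit
    right: TerminusHit

    @property
    def separation(self) -> int:
        return self.right.start - self.left.end

    @property
    def cumulative_confidence(self) -> float:
        return self.left.confidence + self.right.confidence


@dataclass
class PatternString:
    """Ordered terminus/context tokens characterizing one read."""

    tokens: list[str] = field(default_factory=list)
    token_intervals: list[tuple[int, int]] = field(default_factory=list)
    refined_tokens: list[str] = field(default_factory=list)
    terminus_hits: list[TerminusHit] = field(default_factory=list)

    def render(self, refined: bool = False) -> str:
        return ",".join(self.refined_tokens if refined else self.tokens)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


# ---------------------------------------------------------------------------
# assembly

_RESCUE_BUDGET = {"enzyme_site": 1, "adapter": 1, "single_base": 0}
_SCANNABLE = {"vector_border", "poly_tail", "enzyme_site", "adapter"}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_forward(bases: str, elem: SequenceElement, pos: int,
                   hits_by_label: dict[str, list[ElementHit]],
                   max_gap: int) -> ComponentPlacement | None:
    for h in hits_by_label.get(elem.label, ()):
        if 0 <= h.start - pos <= max_gap:
            return ComponentPlacement(elem.label, h.start, h.end,
                                      h.mismatches, True)
        if h.start - pos > max_gap:
            break
    budget = _RESCUE_BUDGET.get(elem.kind)
    if budget is None:
        return None
    k = len(elem.motif)
    window = bases[pos : pos + k]
    if len(window) == k and _hamming(window, elem.motif) <= budget:
        return ComponentPlacement(elem.label, pos, pos + k,
                                  _hamming(window, elem.motif), False)
    return None


def _match_backward(bases: str, elem: SequenceElement, end_pos: int,
                    hits_by_label: dict[str, list[ElementHit]],
                    max_gap: int) -> ComponentPlacement | None:
    best = None
    for h in hits_by_label.get(elem.label, ()):
        if 0 <= end_pos - h.end <= max_gap:
            best = h  # keep the latest-ending admissible hit
        if h.start >= end_pos:
            break
    if best is not None:
        return ComponentPlacement(elem.label, best.start, best.end,
                                  best.mismatches, True)
    budget = _RESCUE_BUDGET.get(elem.kind)
    if budget is None:
        return None
    k = len(elem.motif)
    if end_pos - k < 0:
        return None
    window = bases[end_pos - k : end_pos]
    if _hamming(window, elem.motif) <= budget:
        return ComponentPlacement(elem.label, end_pos - k, end_pos,
                                  _hamming(window, elem.motif), False)
    return None


def _try_chain(bases: str, tdef: TerminusDef, anchor_idx: int,
               anchor: ElementHit, hits_by_label: dict[str, list[ElementHit]],
               max_gap: int) -> list[ComponentPlacement] | None:
    placements: list[ComponentPlacement | None] = [None] * len(tdef.elements)
    placements[anchor_idx] = ComponentPlacement(
        anchor.label, anchor.start, anchor.end, anchor.mismatches, True
    )
    pos = anchor.end
    for j in range(anchor_idx + 1, len(tdef.elements)):
        p = _match_forward(bases, tdef.elements[j], pos, hits_by_label, max_gap)
        if p is None:
            return None
        placements[j] = p
        pos = p.end
    end_pos = anchor.start
    for j in range(anchor_idx - 1, -1, -1):
        p = _match_backward(bases, tdef.elements[j], end_pos, hits_by_label,
                            max_gap)
        if p is None:
            return None
        placements[j] = p
        end_pos = p.start
    return placements  # type: ignore[return-value]


def assemble_termini(read: ReadRecord, hits: list[ElementHit],
                     protocol: ProtocolSpec,
                     max_gap: int = 2) -> list[TerminusHit]:
    """Chain adjacent element hits into every matching terminus variant.

    Every variant whose ordered element list can be anchored on at least one
    scanned hit (components at most ``max_gap`` bases apart) is produced;
    missing fixed-length motif elements may be filled by a literal match at
    the position implied by their anchored neighbours (1-mismatch budget for
    enzyme sites and adapters, exact for single bases).  Overlapping variants
    at one locus are all emitted — disambiguation happens after scoring.
    """
    hits_by_label: dict[str, list[ElementHit]] = {}
    for h in sorted(hits, key=lambda h: (h.start, h.end)):
        hits_by_label.setdefault(h.label, []).append(h)

    out: list[TerminusHit] = []
    seen: set[tuple[str, int, int]] = set()
    for tdef in protocol.termini.values():
        for i, elem in enumerate(tdef.elements):
            if elem.kind not in _SCANNABLE:
                continue
            for anchor in hits_by_label.get(elem.label, ()):
                placements = _try_chain(read.bases, tdef, i, anchor,
                                        hits_by_label, max_gap)
                if placements is None:
                    continue
                start = placements[0].start
                end = placements[-1].end
                key = (tdef.name, start, end)
                if key in seen:
                    continue
                seen.add(key)
                covered = sum(p.end - p.start for p in placements)
                gap_bases = (end - start) - covered
                mism = sum(p.mismatches for p in placements) + max(0, gap_bases)
                out.append(TerminusHit(tdef.name, tdef.family, start, end,
                                       list(placements), tdef.element_weight,
                                       mism))
    out.sort(key=lambda t: (t.start, t.end, t.def_name))
    return out


# ---------------------------------------------------------------------------
# scoring

_CTX_SCORE = {
    "vector": {"HV": 100.0, "LV": 100.0, "LN": 50.0, "HN": 0.0},
    "insert": {"HN": 100.0, "LN": 50.0, "HV": 0.0, "LV": 0.0},
}


def context_score(ctx: str | None, expected: str) -> float:
    """Per-flank context (B) sub-score.

    Where vector is expected: vector content scores 100, low-quality
    non-vector 50, high-quality non-vector 0 — and symmetrically where
    insert is expected.  A read boundary (``ctx`` None) matches expectation.
    """
    if ctx is None or expected in ("read_start", "read_end"):
        return 100.0
    return _CTX_SCORE[expected][ctx]


def score_terminus(hit: TerminusHit, tdef: TerminusDef, canonical_size: float,
                   upstream_ctx: str | None, downstream_ctx: str | None,
                   weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                   ) -> TerminusHit:
    """Fill in the A/B/C sub-scores and combined confidence of a terminus hit.

    ``upstream_ctx``/``downstream_ctx`` are HV/LV/HN/LN labels of the flanking
    windows, or None at a read boundary (treated as matching expectation).
    """
    wa, wb, wc = weights
    if min(weights) < 0 or abs(wa + wb + wc - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    hit.a_score = 100.0 * hit.n_elements / canonical_size
    hit.b_score = 0.5 * (context_score(upstream_ctx, tdef.expected_upstream)
                         + context_score(downstream_ctx, tdef.expected_downstream))
    span = len(hit)
    hit.c_score = 100.0 * max(0, span - hit.mismatch_total) / span
    hit.confidence = wa * hit.a_score + wb * hit.b_score + wc * hit.c_score
    return hit


def score_all(read: ReadRecord, termini: list[TerminusHit],
              protocol: ProtocolSpec, vector_hits: list[ElementHit],
              segments: list[QualitySegment],
              weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
              flank_window: int = 30) -> list[TerminusHit]:
    """Score every assembled terminus against its flanking contexts."""
    n = len(read)
    canon = {f: protocol.canonical(f).element_weight
             for f in {t.family for t in termini}}
    for t in termini:
        tdef = protocol.termini[t.def_name]
        up = None
        if t.start > 0:
            up = classify_context((max(0, t.start - flank_window), t.start),
                                  vector_hits, segments)
        down = None
        if t.end < n:
            down = classify_context((t.end, min(n, t.end + flank_window)),
                                    vector_hits, segments)
        score_terminus(t, tdef, canon[t.family], up, down, weights)
    return termini


def disambiguate(termini: list[TerminusHit],
                 c_tolerance: float = 5.0) -> list[TerminusHit]:
    """Resolve overlapping terminus calls: keep the most confident per locus.

    A sub-variant never outranks a same-family super-variant that spans it
    and matches its bases (C score) essentially as well — the sub-variants
    exist for loci where elements are genuinely missing, not to shadow a
    complete terminus whose flanking context happens to look unusual.  Among
    the remaining overlapping hits the highest confidence wins; ties broken
    by larger completeness (A) score, then by the earlier-starting and longer
    hit — deterministic for any input order.
    """
    survivors = [
        t for t in termini
        if not any(
            g.family == t.family and g.n_elements > t.n_elements
            and g.start <= t.start and t.end <= g.end
            and g.c_score >= t.c_score - c_tolerance
            for g in termini
        )
    ]
    ranked = sorted(
        survivors,
        key=lambda t: (-t.confidence, -t.a_score, t.start, -len(t), t.def_name),
    )
    kept: list[TerminusHit] = []
    for t in ranked:
        if any(t.overlaps(k) for k in kept):
            continue
        kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


# ---------------------------------------------------------------------------
# pattern construction


def _context_runs(cov: np.ndarray, s: int, e: int,
                  min_token_len: int) -> list[tuple[int, int, bool]]:
    """Maximal vector/non-vector runs in [s, e), small runs absorbed."""
    runs: list[list[object]] = []
    for i in range(s, e):
        v = bool(cov[i])
        if runs and runs[-1][2] == v:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, v])
    # absorb runs shorter than min_token_len into their larger neighbour
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for idx, run in enumerate(runs):
            if run[1] - run[0] >= min_token_len:
                continue
            nb = idx - 1 if idx > 0 else idx + 1
            if idx > 0 and idx + 1 < len(runs):
                left, right = runs[idx - 1], runs[idx + 1]
                nb = idx - 1 if (left[1] - left[0]) >= (right[1] - right[0]) else idx + 1
            runs[nb][0] = min(runs[nb][0], run[0])
            runs[nb][1] = max(runs[nb][1], run[1])
            del runs[idx]
            changed = True
            break
    # merge adjacent same-label runs
    merged: list[list[object]] = []
    for run in runs:
        if merged and merged[-1][2] == run[2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(int(a), int(b), bool(v)) for a, b, v in merged]


def build_pattern(read: ReadRecord, termini: list[TerminusHit],
                  vector_hits: list[ElementHit],
                  segments: list[QualitySegment],
                  min_token_len: int = 20) -> PatternString:
    """Tile the read left-to-right into terminus and V/N context tokens.

    ``termini`` must already be disambiguated (non-overlapping).  Regions
    between termini shorter than ``min_token_len`` emit no token; longer
    regions emit alternating V/N tokens for their vector/non-vector runs.
    The refined token sequence replaces V/N with HV/LV/HN/LN.
    """
    termini = sorted(termini, key=lambda t: t.start)
    for a, b in zip(termini, termini[1:]):
        if a.end > b.start:
            raise ValueError("overlapping termini passed to build_pattern")
    n = len(read)
    cov = np.zeros(n, dtype=bool)
    for h in vector_hits:
        cov[h.start : h.end] = True

    pat = PatternString(terminus_hits=list(termini))

    def emit_context(s: int, e: int) -> None:
        if e - s < min_token_len:
            return
        for a, b, is_vec in _context_runs(cov, s, e, min_token_len):
            refined = classify_context((a, b), vector_hits, segments)
            token = "V" if is_vec else "N"
            pat.tokens.append(token)
            pat.refined_tokens.append(refined[0] + token)
            pat.token_intervals.append((a, b))

    cursor = 0
    for t in termini:
        emit_context(cursor, t.start)
        pat.tokens.append(t.def_name)
        pat.refined_tokens.append(t.def_name)
        pat.token_intervals.append(t.interval)
        cursor = t.end
    emit_context(cursor, n)
    if not pat.tokens:
        # a read with nothing at all is still a single context token
        if n > 0:
            refined = classify_context((0, n), vector_hits, segments)
            token = "V" if refined.endswith("V") else "N"
            pat.tokens.append(token)
            pat.refined_tokens.append(refined[0] + token)
            pat.token_intervals.append((0, n))
    return pat


# ---------------------------------------------------------------------------
# reasonable pairs

_PAIR_FAMILIES = {"5": ("5TSS", "3TSS"), "3": ("5TNS", "3TNS")}


@dataclass
class PairSearch:
    pairs: list[TerminusPair]
    warning: str | None = None


def find_reasonable_pairs(termini: list[TerminusHit], direction: str,
                          min_separation: int = 200) -> PairSearch:
    """Direction-consistent terminus pairs delimiting a candidate insert.

    For a 5' read every ([5TSS-family], [3TSS-family]) ordered pair, for a 3'
    read every ([5TNS-family], [3TNS-family]) pair; the upstream member must
    end at least ``min_separation`` bases before the downstream member starts
    (an insert must fit between them).  Any family member is pair-eligible.
    """
    fams = _PAIR_FAMILIES.get(direction)
    if fams is None:
        return PairSearch([], warning=f"unknown read direction {direction!r}")
    lf, rf = fams
    pairs = [
        TerminusPair(l, r)
        for l in termini if l.family == lf
        for r in termini if r.family == rf
        if r.start - l.end >= min_separation
    ]
    pairs.sort(key=lambda p: (p.left.start, p.right.start))
    return PairSearch(pairs)


def select_best_pair(pairs: list[TerminusPair]) -> TerminusPair | None:
    """The pair with the highest cumulative confidence.

    Ties broken by larger separation, then by leftmost upstream terminus.
    """
    if not pairs:
        return None
    return max(
        pairs,
        key=lambda p: (p.cumulative_confidence, p.separation, -p.left.start),
    )
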