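"""Classification of abnormal cDNA terminal patterns.

Three families of wet-lab artifacts are recognized from a read's pattern:

* **RECA** (restriction enzyme cutting abnormality), types A1-F: one or both
  enzymes failed to cut, cut at the wrong site, or the excised vector stuffer
  was re-ligated with (possibly inverted) inserts.  Each type has a
  direction-specific pattern signature.
* **DBT** (double-termini adapter): palindromic adapter/enzyme concatenations
  that can fuse two independent fragments into a chimeric read.  Type 1 is
  ``CCTCGTGCC+G+AATTC+GGCACGAGG``; type 2 is ``AATTC+GGCACGAGG+CCTCGTGCC+G``.
  A DBT strictly inside a valid 5TNS...3TNS span of a 3' read is trimmable
  (``DBT-internal``); any other DBT marks the read as a chimera.
* **CASE-1..8**: the most frequent simple abnormal patterns (lone poly(A)
  fragments, single-base enzyme-site replacements, bare vector borders, a
  3'-like terminus in a designated 5' read, ...).

Precedence when several classifications apply: RECA > DBT > CASE >
direction-conflict; the first becomes the primary call, the rest secondary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .elements import ElementHit
from .patterns import PatternString
from .protocol import ProtocolSpec

__all__ = [
    "DBT_TYPE1_MOTIF",
    "DBT_TYPE2_MOTIF",
    "DBTHit",
    "AbnormalityCall",
    "detect_dbt",
    "classify_reca",
    "classify_case",
    "detect_direction_conflict",
    "resolve_dbt",
    "classify_read",
    "RECA_SIGNATURES",
    "CASE_SIGNATURES",
]

DBT_TYPE1_MOTIF = "CCTCGTGCCGAATTCGGCACGAGG"
DBT_TYPE2_MOTIF = "AATTCGGCACGAGGCCTCGTGCCG"


@dataclass(frozen=True)
class DBTHit:
    start: int
    end: int
    dbt_type: int  # 1 or 2
    repetition_index: int = 1  # ordinal within a run of consecutive DBTs
    mismatches: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AbnormalityCall:
    category: str
    signature: str
    evidence: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# DBT detection


def _motif_mismatches(arr: np.ndarray, motif: str) -> np.ndarray:
    k = len(motif)
    n = arr.size
    if n < k:
        return np.full(0, 99, dtype=np.int16)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    mm = np.zeros(n - k + 1, dtype=np.int16)
    for j in range(k):
        mm += arr[j : n - k + 1 + j] != m[j]
    return mm


def detect_dbt(bases: str, max_mismatch: int = 2,
               max_gap: int = 0) -> list[DBTHit]:
    """Non-overlapping left-to-right scan for both 24-base DBT motifs.

    At a given position the motif with fewer mismatches wins (type 1 on a
    tie).  Consecutive hits separated by at most ``max_gap`` bases form a
    repetition run and are numbered by ``repetition_index`` (1-based).
    """
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    k = len(DBT_TYPE1_MOTIF)
    mm1 = _motif_mismatches(arr, DBT_TYPE1_MOTIF)
    mm2 = _motif_mismatches(arr, DBT_TYPE2_MOTIF)
    n = mm1.size
    hits: list[DBTHit] = []
    pos = 0
    while pos < n:
        a, b = int(mm1[pos]) if pos < mm1.size else 99, int(mm2[pos]) if pos < mm2.size else 99
        if min(a, b) <= max_mismatch:
            dbt_type, mism = (1, a) if a <= b else (2, b)
            rep = 1
            if hits and pos - hits[-1].end <= max_gap:
                rep = hits[-1].repetition_index + 1
            hits.append(DBTHit(pos, pos + k, dbt_type, rep, mism))
            pos += k
        else:
            pos += 1
    return hits


# ---------------------------------------------------------------------------
# RECA signature templates (pattern rendering per designated direction)

RECA_SIGNATURES: dict[str, dict[str, str]] = {
    "RECA-A1": {"5": "N,3TNS-1,V,3TSS-2", "3": "5TNS-2,V,5TSS-1,N"},
    "RECA-A2": {"5": "5TSS,N,V,3TSS-2", "3": "5TNS-2,V,N,3TNS"},
    "RECA-A3": {"5": "5TSS,3TNS-1,V,3TSS-2", "3": "5TNS-2,V,5TSS-1,3TNS"},
    "RECA-B1": {"5": "5TSS-2,V,5TNS-1,N", "3": "N,3TSS-1,V,3TNS-2"},
    "RECA-B2": {"5": "5TSS-2,V,N,3TSS", "3": "5TNS,N,V,3TNS-2"},
    "RECA-C": {"5": "5TSS-2,V,3TSS-2", "3": "5TNS-2,V,3TNS-2"},
    "RECA-D": {"5": "N,3TNS-1,V,5TNS-1,N", "3": "N,3TSS-1,V,5TSS-1,N"},
    "RECA-E": {"5": "N,V,3TSS-2", "3": "5TNS-2,V,N"},
    "RECA-F": {"5": "V,N", "3": "N,V"},
}

#: Table of the frequent simple abnormal patterns: case id -> (direction, regex).
CASE_SIGNATURES: dict[str, tuple[str, str]] = {
    "CASE-1": ("5", r"N(?:,3TSS-3,N)+"),
    "CASE-2": ("3", r"(?:N,)?5TNS-4,N"),
    "CASE-3": ("3", r"(?:N,)?5TNS-5,N"),
    "CASE-4": ("5", r"N,3TSS-5,V"),
    "CASE-5": ("5", r"N,5TNS-1,N"),
    "CASE-6": ("3", r"5TNS-2,N"),
    "CASE-7": ("5", r"N,3TSS-5,N"),
    "CASE-8": ("5", r"N,3TSS-4,V"),
}


def _vector_near_enzyme1(vector_hits: list[ElementHit],
                         protocol: ProtocolSpec, margin: int = 300) -> bool:
    """Does any vector hit map near the enzyme-1 (EcoRI) cloning side?"""
    e1s, e1e = protocol.enzyme1_site
    lo, hi = e1s - margin, e1e
    for h in vector_hits:
        if h.vector_interval is None:
            continue
        vs, ve = h.vector_interval
        if vs < hi and lo < ve:
            return True
    return False


def classify_reca(pattern: PatternString, direction: str,
                  vector_hits: list[ElementHit] | None = None,
                  protocol: ProtocolSpec | None = None,
                  ) -> AbnormalityCall | None:
    """Match the pattern rendering against the RECA signature templates.

    The generic ``V,N`` / ``N,V`` signature of type F additionally requires
    the vector hit to map to the region flanking the enzyme-1 cloning side
    (its wrong-cut mechanism); otherwise a bare vector+insert read is not
    called.  Unmatched patterns in which a V token is directly bracketed by
    termini on both sides fall into ``RECA-other``.
    """
    if direction not in ("5", "3"):
        return None
    rendering = pattern.render()
    for category, templates in RECA_SIGNATURES.items():
        if rendering != templates.get(direction):
            continue
        if category == "RECA-F":
            if vector_hits is None or protocol is None:
                continue
            if not _vector_near_enzyme1(vector_hits, protocol):
                continue
        return AbnormalityCall(category, templates[direction],
                               [pattern.token_intervals[i]
                                for i in range(len(pattern.tokens))])
    # RECA-like leftovers: retained vector directly bracketed by termini
    terminus_tokens = {t.def_name for t in pattern.terminus_hits}
    toks = pattern.tokens
    for i, tok in enumerate(toks):
        if tok != "V" or i == 0 or i == len(toks) - 1:
            continue
        if toks[i - 1] in terminus_tokens and toks[i + 1] in terminus_tokens:
            return AbnormalityCall("RECA-other", rendering,
                                   [pattern.token_intervals[i]])
    return None


def classify_case(pattern: PatternString,
                  direction: str) -> AbnormalityCall | None:
    """Match the pattern against the frequent-abnormal-case templates."""
    if direction not in ("5", "3"):
        return None
    rendering = pattern.render()
    for case_id, (d, regex) in CASE_SIGNATURES.items():
        if d == direction and re.fullmatch(regex, rendering):
            return AbnormalityCall(case_id, rendering,
                                   list(pattern.token_intervals))
    return None


def detect_direction_conflict(pattern: PatternString,
                              direction: str) -> AbnormalityCall | None:
    """Flag a read whose only termini belong to the opposite direction.

    A designated 5' read should carry sense-strand termini (5TSS/3TSS
    families); one showing exclusively antisense-strand termini (5TNS/3TNS)
    was sequenced from the other end — and vice versa for 3' reads.
    """
    fams = {t.family for t in pattern.terminus_hits}
    if not fams:
        return None
    wrong = {"5": {"5TNS", "3TNS"}, "3": {"5TSS", "3TSS"}}.get(direction)
    if wrong is None or not fams <= wrong:
        return None
    return AbnormalityCall(
        "direction-conflict", pattern.render(),
        [t.interval for t in pattern.terminus_hits],
    )


def resolve_dbt(pattern: PatternString, dbt_hits: list[DBTHit],
                direction: str) -> AbnormalityCall:
    """Decide whether DBT hits are trimmable or mark a chimeric read.

    Trimmable (``DBT-internal``) only for a 3' read in which every DBT lies
    strictly inside a 5TNS-family ... 3TNS-family span whose termini do not
    themselves overlap a DBT — the rescue layout ``5TNS + N + DBT + 3TNS``.
    Everything else is a ``DBT-chimera``.
    """
    if not dbt_hits:
        raise ValueError("resolve_dbt requires at least one DBT hit")
    evidence = [h.interval for h in dbt_hits]
    sig = "+".join(f"DBT{h.dbt_type}" for h in dbt_hits)
    if direction == "3":
        free = [
            t for t in pattern.terminus_hits
            if not any(t.start < e and s < t.end for s, e in evidence)
        ]
        lefts = [t for t in free if t.family == "5TNS"]
        rights = [t for t in free if t.family == "3TNS"]
        lo = min(h.start for h in dbt_hits)
        hi = max(h.end for h in dbt_hits)
        if any(l.end <= lo for l in lefts) and any(hi <= r.start for r in rights):
            return AbnormalityCall("DBT-internal", sig, evidence)
    return AbnormalityCall("DBT-chimera", sig, evidence)


def classify_read(pattern: PatternString, direction: str,
                  dbt_hits: list[DBTHit],
                  vector_hits: list[ElementHit] | None = None,
                  protocol: ProtocolSpec | None = None,
                  ) -> tuple[AbnormalityCall | None, list[AbnormalityCall]]:
    """All applicable abnormality calls in precedence order.

    Returns ``(primary, secondary)``; primary is None for an expected read.
    Precedence: RECA > DBT > CASE > direction-conflict.
    """
    calls: list[AbnormalityCall] = []
    reca = classify_reca(pattern, direction, vector_hits, protocol)
    if reca is not None:
        calls.append(reca)
    if dbt_hits:
        calls.append(resolve_dbt(pattern, dbt_hits, direction))
    case = classify_case(pattern, direction)
    if case is not None:
        calls.append(case)
    conflict = detect_direction_conflict(pattern, direction)
    if conflict is not None:
        calls.append(conflict)
    if not calls:
        return None, []
    return calls[0], calls[1:]
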