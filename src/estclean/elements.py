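"""Detection of atomic terminus components in a raw Sanger read.

Four kinds of evidence are located independently and later assembled into
termini by :mod:`estclean.patterns`:

* fixed motifs (restriction enzyme sites, adapters) by windowed Hamming scan;
* poly(A)/poly(T) tails as impurity-tolerant homopolymer runs;
* vector fragments by ungapped k-mer seed-and-extend local matching against
  both strands of the plasmid sequence;
* high/low quality segmentation of the read from its phred scores.

Coordinates are 0-based half-open read intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .protocol import ProtocolSpec, reverse_complement

__all__ = [
    "ReadRecord",
    "ElementHit",
    "QualitySegment",
    "segment_quality",
    "find_motif_hits",
    "find_poly_tail",
    "find_vector_hits",
    "classify_context",
    "collect_element_hits",
    "covered_fraction",
]


@dataclass
class ReadRecord:
    """A raw EST read: id, designated direction ('5'/'3'/'unknown'), bases, quals."""

    id: str
    bases: str
    quals: np.ndarray | None = None
    designated_direction: str = "unknown"

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if self.quals is not None:
            self.quals = np.asarray(self.quals, dtype=np.int32)
            if self.quals.size != len(self.bases):
                raise ValueError(
                    f"read {self.id}: {self.quals.size} quality values for "
                    f"{len(self.bases)} bases"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ElementHit:
    """A located terminus component on the read.

    ``vector_interval`` is set only for vector hits and vector-border
    elements: the matching interval on the plasmid (always in plus-strand
    plasmid coordinates, whichever strand matched).
    """

    label: str
    start: int
    end: int
    strand_form: str = "sense"
    mismatches: int = 0
    matched_fraction: float = 1.0
    vector_interval: tuple[int, int] | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QualitySegment:
    start: int
    end: int
    label: str  # "high" | "low"


# ---------------------------------------------------------------------------
# quality segmentation


def segment_quality(read: ReadRecord, window: int = 20,
                    min_q: int = 16) -> list[QualitySegment]:
    """Partition the read into high/low quality segments.

    The read is tiled in consecutive ``window``-base blocks (the final partial
    block scored on its own mean); a block is high quality when its mean phred
    score is at least ``min_q``.  Adjacent same-label blocks are merged.  A
    read without quality values is a single all-high segment.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n == 0:
        return []
    if read.quals is None:
        return [QualitySegment(0, n, "high")]
    labels: list[str] = []
    for s in range(0, n, window):
        mean = float(read.quals[s : s + window].mean())
        labels.append("high" if mean >= min_q else "low")
    segments: list[QualitySegment] = []
    for i, lab in enumerate(labels):
        s, e = i * window, min((i + 1) * window, n)
        if segments and segments[-1].label == lab:
            segments[-1] = QualitySegment(segments[-1].start, e, lab)
        else:
            segments.append(QualitySegment(s, e, lab))
    return segments


# ---------------------------------------------------------------------------
# motif scanning


def _as_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def find_motif_hits(bases: str, motif: str, max_mismatch: int = 0,
                    label: str | None = None,
                    strand_form: str = "sense") -> list[ElementHit]:
    """All windows of ``len(motif)`` bases with <= ``max_mismatch`` mismatches.

    Equivalent to a brute-force windowed Hamming scan; hits sorted by start.
    """
    if not motif:
        raise ValueError("empty motif")
    if max_mismatch >= len(motif):
        raise ValueError("max_mismatch must be smaller than the motif length")
    k = len(motif)
    arr = _as_u8(bases)
    n = arr.size
    if n < k:
        return []
    m = _as_u8(motif)
    mm = np.zeros(n - k + 1, dtype=np.int16)
    for j in range(k):
        mm += arr[j : n - k + 1 + j] != m[j]
    lab = label if label is not None else motif
    return [
        ElementHit(lab, int(s), int(s) + k, strand_form, int(mm[s]),
                   (k - int(mm[s])) / k)
        for s in np.nonzero(mm <= max_mismatch)[0]
    ]


# ---------------------------------------------------------------------------
# poly(A)/poly(T) tails


def find_poly_tail(bases: str, base: str, min_len: int = 8,
                   max_impurity: float = 0.1) -> list[ElementHit]:
    """Maximal homopolymer runs of ``base`` with bounded interior impurity.

    A run starts and ends on ``base``; interior non-``base`` positions are
    tolerated while their fraction of the run length stays <= ``max_impurity``.
    All disjoint runs of length >= ``min_len`` are reported.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if base not in "ACGT":
        raise ValueError(f"poly tail base must be one of ACGT, got {base!r}")
    hits: list[ElementHit] = []
    n = len(bases)
    i = 0
    while i < n:
        if bases[i] != base:
            i += 1
            continue
        # longest run ending on `base` whose interior impurities stay bounded
        impurities = 0
        best_end = i + 1
        best_imp = 0
        j = i
        while j < n:
            if bases[j] == base:
                if impurities <= max_impurity * (j + 1 - i):
                    best_end = j + 1
                    best_imp = impurities
            else:
                impurities += 1
                if impurities > max_impurity * (n - i):
                    break  # can never satisfy the bound again
            j += 1
        length = best_end - i
        if length >= min_len:
            hits.append(
                ElementHit(f"poly{base}", i, best_end, "sense", best_imp,
                           (length - best_imp) / length)
            )
            i = best_end
        else:
            i += 1
    return hits


# ---------------------------------------------------------------------------
# vector fragments


@dataclass
class _Chain:
    rstart: int
    rend: int
    vstart: int  # on the indexed strand
    strand: str


@lru_cache(maxsize=8)
def _kmer_index(ref: str, k: int) -> dict[bytes, list[int]]:
    """Exact k-mer position index of a reference strand (cached per vector)."""
    ref_b = ref.encode()
    index: dict[bytes, list[int]] = {}
    for v in range(len(ref_b) - k + 1):
        index.setdefault(ref_b[v : v + k], []).append(v)
    return index


def _seed_chains(read_arr: np.ndarray, index: dict[bytes, list[int]],
                 k: int, strand: str, max_seed_gap: int = 30) -> list[_Chain]:
    """Collect k-mer seed matches and merge them along shared diagonals."""
    by_diag: dict[int, list[_Chain]] = {}
    data = read_arr.tobytes()
    for r in range(len(data) - k + 1):
        for v in index.get(data[r : r + k], ()):
            diag = v - r
            chains = by_diag.setdefault(diag, [])
            if chains and -k <= r - chains[-1].rend <= max_seed_gap:
                chains[-1].rend = max(chains[-1].rend, r + k)
            else:
                chains.append(_Chain(r, r + k, v, strand))
    return [c for chains in by_diag.values() for c in chains]


def _extend_ungapped(read_arr: np.ndarray, ref_arr: np.ndarray, chain: _Chain,
                     match: int = 1, mismatch: int = -3,
                     xdrop: int = 9) -> tuple[int, int, int]:
    """X-drop ungapped extension; returns (rstart, rend, mismatches)."""
    diag = chain.vstart - chain.rstart

    def run(direction: int, r0: int) -> int:
        best_r, best_score, score = r0, 0, 0
        r = r0
        while True:
            r += direction
            v = r + diag
            if r < 0 or r >= read_arr.size or v < 0 or v >= ref_arr.size:
                break
            score += match if read_arr[r] == ref_arr[v] else mismatch
            if score > best_score:
                best_score, best_r = score, r
            if best_score - score > xdrop:
                break
        return best_r

    left = run(-1, chain.rstart)
    right = run(+1, chain.rend - 1)
    rs, re = min(left, chain.rstart), max(right + 1, chain.rend)
    seg_r = read_arr[rs:re]
    seg_v = ref_arr[rs + diag : re + diag]
    mism = int((seg_r != seg_v).sum())
    return rs, re, mism


def find_vector_hits(bases: str, vector: str, min_len: int = 20,
                     min_identity: float = 0.94, k: int = 12) -> list[ElementHit]:
    """Ungapped local matches of the read against both strands of the vector.

    Exact ``k``-mer seeds are merged along diagonals and extended with an
    x-drop rule; hits shorter than ``min_len`` or below ``min_identity`` are
    discarded.  ``vector_interval`` of each hit is reported in plus-strand
    vector coordinates; ``strand_form`` is ``sense``/``antisense``.
    """
    if len(vector) < min_len:
        raise ValueError("vector shorter than min_len")
    read_arr = _as_u8(bases)
    if read_arr.size < k:
        return []
    hits: list[ElementHit] = []
    lv = len(vector)
    for strand, ref in (("sense", vector), ("antisense", reverse_complement(vector))):
        index = _kmer_index(ref, k)
        ref_arr = _as_u8(ref)
        seen: set[tuple[int, int]] = set()
        for chain in _seed_chains(read_arr, index, k, strand):
            rs, re, mism = _extend_ungapped(read_arr, ref_arr, chain)
            length = re - rs
            if length < min_len:
                continue
            identity = (length - mism) / length
            if identity < min_identity:
                continue
            diag = chain.vstart - chain.rstart
            ps, pe = rs + diag, re + diag  # on the indexed strand
            if strand == "sense":
                vint = (ps, pe)
            else:
                vint = (lv - pe, lv - ps)
            key = (rs, re)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                ElementHit("vector", rs, re, strand, mism, identity, vint)
            )
    hits.sort(key=lambda h: (h.start, h.end))
    # drop hits fully contained in a longer hit of the same strand
    kept: list[ElementHit] = []
    for h in hits:
        if any(
            o.start <= h.start and h.end <= o.end and len(o) > len(h)
            and o.strand_form == h.strand_form
            for o in hits
        ):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# context classification


def covered_fraction(interval: tuple[int, int],
                     pieces: list[tuple[int, int]]) -> float:
    """Fraction of ``interval`` covered by the union of ``pieces``."""
    s, e = interval
    if e <= s:
        raise ValueError("empty interval")
    merged: list[list[int]] = []
    for ps, pe in sorted(pieces):
        ps, pe = max(ps, s), min(pe, e)
        if pe <= ps:
            continue
        if merged and ps <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], pe)
        else:
            merged.append([ps, pe])
    return sum(pe - ps for ps, pe in merged) / (e - s)


def classify_context(interval: tuple[int, int], vector_hits: list[ElementHit],
                     segments: list[QualitySegment]) -> str:
    """HV/LV/HN/LN call for a read interval.

    Vector when >= 50% of the interval is covered by vector hits; high
    quality when >= 50% is covered by high-quality segments.
    """
    vec = covered_fraction(interval, [h.interval for h in vector_hits]) >= 0.5
    high = covered_fraction(
        interval, [(s.start, s.end) for s in segments if s.label == "high"]
    ) >= 0.5
    return ("H" if high else "L") + ("V" if vec else "N")


# ---------------------------------------------------------------------------
# orchestration: all atomic hits for one read


def _vf_hits_from_vector(vector_hits: list[ElementHit], protocol: ProtocolSpec,
                         min_cov: int = 20) -> list[ElementHit]:
    """Derive VF1/VF2 border element hits from raw vector alignments.

    A border element is only credited when the alignment reaches the border
    edge adjacent to its cloning site (so a vector fragment from a wrong-site
    cut does not masquerade as a clean border).
    """
    out: list[ElementHit] = []
    (vf1s, vf1e) = protocol.vf1_interval
    (vf2s, vf2e) = protocol.vf2_interval

    def map_sub(h: ElementHit, a: int, b: int) -> tuple[int, int]:
        vs, ve = h.vector_interval
        if h.strand_form == "sense":
            return h.start + (a - vs), h.start + (b - vs)
        return h.start + (ve - b), h.start + (ve - a)

    for h in vector_hits:
        if h.vector_interval is None:
            continue
        vs, ve = h.vector_interval
        # VF1: edge adjacent to enzyme-1 is its right end (vf1e)
        a, b = max(vf1s, vs), min(vf1e, ve)
        if b == vf1e and b - a >= min_cov:
            rs, re = map_sub(h, a, b)
            label = "VF1" if h.strand_form == "sense" else "VF1'"
            out.append(ElementHit(label, rs, re, h.strand_form, 0,
                                  h.matched_fraction, (a, b)))
        # VF2: edge adjacent to enzyme-2 is its left end (vf2s)
        a, b = max(vf2s, vs), min(vf2e, ve)
        if a == vf2s and b - a >= min_cov:
            rs, re = map_sub(h, a, b)
            label = "VF2" if h.strand_form == "sense" else "VF2'"
            out.append(ElementHit(label, rs, re, h.strand_form, 0,
                                  h.matched_fraction, (a, b)))
    return out


@dataclass
class ElementScan:
    """All evidence gathered from one read."""

    motif_hits: list[ElementHit] = field(default_factory=list)
    vector_hits: list[ElementHit] = field(default_factory=list)
    segments: list[QualitySegment] = field(default_factory=list)

    @property
    def all_component_hits(self) -> list[ElementHit]:
        return sorted(self.motif_hits, key=lambda h: (h.start, h.end))


def collect_element_hits(read: ReadRecord, protocol: ProtocolSpec, *,
                         adapter_max_mismatch: int = 1,
                         poly_min_len: int = 8, poly_max_impurity: float = 0.1,
                         vector_min_len: int = 20,
                         vector_min_identity: float = 0.94,
                         quality_window: int = 20, min_q: int = 16) -> ElementScan:
    """Run all element detectors for one read.

    Enzyme sites (6-mers) are matched exactly; adapters allow
    ``adapter_max_mismatch``.  VF border hits are derived from the vector
    alignments.
    """
    scan = ElementScan()
    scan.segments = segment_quality(read, quality_window, min_q)
    b = read.bases
    hits: list[ElementHit] = []
    hits += find_motif_hits(b, protocol.enzyme1_motif, 0, label="Enzyme1")
    if protocol.enzyme2_motif != protocol.enzyme1_motif:
        hits += find_motif_hits(b, protocol.enzyme2_motif, 0, label="Enzyme2")
    hits += find_motif_hits(b, protocol.adapter_sense, adapter_max_mismatch,
                            label="Adapter1")
    if protocol.adapter_antisense != protocol.adapter_sense:
        hits += find_motif_hits(b, protocol.adapter_antisense,
                                adapter_max_mismatch, label="Adapter1'",
                                strand_form="antisense")
    hits += find_poly_tail(b, "A", poly_min_len, poly_max_impurity)
    hits += find_poly_tail(b, "T", poly_min_len, poly_max_impurity)
    scan.vector_hits = find_vector_hits(
        b, protocol.vector_sequence, vector_min_len, vector_min_identity
    )
    hits += _vf_hits_from_vector(scan.vector_hits, protocol,
                                 min_cov=vector_min_len)
    scan.motif_hits = sorted(hits, key=lambda h: (h.start, h.end))
    return scan
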