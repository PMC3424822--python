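"""Cloning-protocol model for cDNA terminus pattern analysis.

A directionally cloned cDNA library leaves diagnostic sequence elements at the
two ends of every insert: the vector borders flanking the cloning sites (VF1
left of the first enzyme site, VF2 right of the second), the restriction enzyme
recognition motifs themselves, the ligated adapter, and the poly(A)/poly(T)
tail of the message.  A *terminus* is an ordered arrangement of such elements;
each of the four canonical termini (5TSS, 3TSS on the sense strand, 5TNS, 3TNS
on the antisense strand) has a family of partial sub-variants that arise when
sequencing quality, trimming or wet-lab accidents remove elements.

This module represents a protocol (:class:`ProtocolSpec`), enumerates the
terminus grammar for the default EcoRI/XhoI + 9-mer adapter protocol
(:func:`default_protocol`), and loads user protocols from YAML
(:func:`load_protocol`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ProtocolError",
    "SequenceElement",
    "TerminusDef",
    "ProtocolSpec",
    "reverse_complement",
    "default_protocol",
    "load_protocol",
    "mirror_name",
    "FAMILIES",
    "FAMILY_MIRROR",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")

#: The four canonical terminus families.
FAMILIES = ("5TSS", "3TSS", "5TNS", "3TNS")

#: Strand mirror between families: reverse-complementing a read swaps these.
FAMILY_MIRROR = {"5TSS": "3TNS", "3TNS": "5TSS", "3TSS": "5TNS", "5TNS": "3TSS"}


class ProtocolError(ValueError):
    """A protocol description failed validation."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of ``seq`` (alphabet ACGTN).

    Raises :class:`ProtocolError` naming the 1-based position of the first
    non-DNA character.
    """
    for i, ch in enumerate(seq):
        if ch not in _DNA_N:
            raise ProtocolError(
                f"non-DNA character {ch!r} at position {i + 1}"
            )
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str, allow_n: bool = False) -> str:
    alphabet = _DNA_N if allow_n else _DNA
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ProtocolError(
                f"{what}: non-DNA character {ch!r} at position {i + 1}"
            )
    if not seq:
        raise ProtocolError(f"{what}: empty sequence")
    return seq


@dataclass(frozen=True)
class SequenceElement:
    """One atomic component of a cDNA terminus.

    kind
        ``vector_border`` (a VF1/VF2 flank, matched by local alignment),
        ``enzyme_site`` / ``adapter`` (fixed motifs), ``poly_tail`` (a
        homopolymer run; ``motif`` is the single repeated base), or
        ``single_base`` (the degenerate one-base replacements seen in the
        3TSS-4 / 5TNS-4 variants).
    """

    kind: str
    motif: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in {
            "vector_border", "enzyme_site", "adapter", "poly_tail", "single_base",
        }:
            raise ProtocolError(f"unknown element kind {self.kind!r}")
        _check_dna(self.motif, f"element {self.label}")
        if self.kind in {"poly_tail", "single_base"} and len(self.motif) != 1:
            raise ProtocolError(
                f"element {self.label}: {self.kind} motif must be one base"
            )


@dataclass(frozen=True)
class TerminusDef:
    """A named terminus variant: an ordered element list within a family."""

    name: str
    family: str
    elements: tuple[SequenceElement, ...]
    expected_upstream: str = "vector"
    expected_downstream: str = "insert"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ProtocolError(f"unknown family {self.family!r}")
        if not self.elements:
            raise ProtocolError(f"terminus {self.name}: no elements")

    @property
    def element_weight(self) -> float:
        """Completeness weight: a degenerate single-base replacement counts
        half of a real element, so e.g. poly(A)+G+VF2 is less complete than
        the canonical poly(A)+enzyme site+VF2."""
        return sum(0.5 if e.kind == "single_base" else 1.0
                   for e in self.elements)


@dataclass
class ProtocolSpec:
    """A full cDNA library-construction protocol description.

    Coordinates (``vf1_interval``, ``vf2_interval``, enzyme site positions)
    are 0-based half-open on ``vector_sequence``.
    """

    vector_sequence: str
    vf1_interval: tuple[int, int]
    vf2_interval: tuple[int, int]
    enzyme1_motif: str = "GAATTC"
    enzyme2_motif: str = "CTCGAG"
    adapter_sense: str = "GGCACGAGG"
    adapter_antisense: str = "CCTCGTGCC"
    termini: dict[str, TerminusDef] = field(default_factory=dict)
    direction_rules: dict[str, str] = field(
        default_factory=lambda: {".g1": "5", ".b1": "3"}
    )

    def __post_init__(self) -> None:
        _check_dna(self.vector_sequence, "vector", allow_n=True)
        _check_dna(self.enzyme1_motif, "enzyme1")
        _check_dna(self.enzyme2_motif, "enzyme2")
        _check_dna(self.adapter_sense, "adapter_sense")
        _check_dna(self.adapter_antisense, "adapter_antisense")
        n = len(self.vector_sequence)
        for nm, (s, e) in (("vf1", self.vf1_interval), ("vf2", self.vf2_interval)):
            if not (0 <= s < e <= n):
                raise ProtocolError(f"{nm} interval [{s}, {e}) outside vector")
        if self.vf1_interval[1] > self.vf2_interval[0]:
            raise ProtocolError("vf1 interval must precede vf2 interval")
        for d in self.direction_rules.values():
            if d not in {"5", "3"}:
                raise ProtocolError(f"direction must be '5' or '3', got {d!r}")
        if not self.termini:
            self.termini = _expand_termini(self)
        names = [t.name for t in self.termini.values()]
        if len(set(names)) != len(names):
            raise ProtocolError("duplicate terminus names")

    # -- derived sequences -------------------------------------------------

    @property
    def vf1_sequence(self) -> str:
        s, e = self.vf1_interval
        return self.vector_sequence[s:e]

    @property
    def vf2_sequence(self) -> str:
        s, e = self.vf2_interval
        return self.vector_sequence[s:e]

    @property
    def enzyme1_site(self) -> tuple[int, int]:
        """Location of the enzyme-1 site adjacent to VF1's right edge."""
        p = self.vector_sequence.find(self.enzyme1_motif, self.vf1_interval[1])
        if p < 0:
            p = self.vector_sequence.find(self.enzyme1_motif)
        return (p, p + len(self.enzyme1_motif)) if p >= 0 else self.vf1_interval

    @property
    def enzyme2_site(self) -> tuple[int, int]:
        """Location of the enzyme-2 site adjacent to VF2's left edge."""
        k = len(self.enzyme2_motif)
        p = self.vector_sequence.rfind(
            self.enzyme2_motif, 0, self.vf2_interval[0]
        )
        return (p, p + k) if p >= 0 else self.vf2_interval

    def canonical(self, family: str) -> TerminusDef:
        """The maximal (canonical) terminus definition of a family."""
        defs = [t for t in self.termini.values() if t.family == family]
        if not defs:
            raise ProtocolError(f"no termini in family {family}")
        return max(defs, key=lambda t: t.element_weight)

    def direction_of(self, read_id: str) -> str:
        """Designated read direction from the naming convention: '5', '3' or 'unknown'."""
        for pat, d in self.direction_rules.items():
            if read_id.endswith(pat) or pat in read_id:
                return d
        return "unknown"


def mirror_name(name: str) -> str:
    """Strand-mirror of a terminus name (5TSS-1 <-> 3TNS-1 etc.)."""
    fam, _, suffix = name.partition("-")
    m = FAMILY_MIRROR[fam]
    return f"{m}-{suffix}" if suffix else m


# ---------------------------------------------------------------------------
# default protocol + terminus grammar


def _expand_termini(spec: ProtocolSpec) -> dict[str, TerminusDef]:
    """Terminus variant table for a two-enzyme directional protocol.

    X' denotes the reverse complement of X.  Only variants with published
    evidence are created; configs may add more.
    """
    rc = reverse_complement
    vf1 = SequenceElement("vector_border", spec.vf1_sequence, "VF1")
    vf1r = SequenceElement("vector_border", rc(spec.vf1_sequence), "VF1'")
    vf2 = SequenceElement("vector_border", spec.vf2_sequence, "VF2")
    vf2r = SequenceElement("vector_border", rc(spec.vf2_sequence), "VF2'")
    e1 = SequenceElement("enzyme_site", spec.enzyme1_motif, "Enzyme1")
    e2 = SequenceElement("enzyme_site", spec.enzyme2_motif, "Enzyme2")
    ad = SequenceElement("adapter", spec.adapter_sense, "Adapter1")
    adr = SequenceElement("adapter", spec.adapter_antisense, "Adapter1'")
    pa = SequenceElement("poly_tail", "A", "polyA")
    pt = SequenceElement("poly_tail", "T", "polyT")
    g = SequenceElement("single_base", "G", "G")
    c = SequenceElement("single_base", "C", "C")

    table: dict[str, tuple[str, tuple[SequenceElement, ...]]] = {
        # 5' end of the insert, sense strand
        "5TSS": ("5TSS", (vf1, e1, ad)),
        "5TSS-1": ("5TSS", (e1, ad)),
        "5TSS-2": ("5TSS", (vf1, e1)),
        # 3' end, sense strand
        "3TSS": ("3TSS", (pa, e2, vf2)),
        "3TSS-1": ("3TSS", (pa, e2)),
        "3TSS-2": ("3TSS", (e2, vf2)),
        "3TSS-3": ("3TSS", (pa,)),
        "3TSS-4": ("3TSS", (pa, g, vf2)),
        "3TSS-5": ("3TSS", (vf2,)),
        # 5' end of the read on the antisense strand (= mRNA 3' end)
        "5TNS": ("5TNS", (vf2r, e2, pt)),
        "5TNS-1": ("5TNS", (e2, pt)),
        "5TNS-2": ("5TNS", (vf2r, e2)),
        "5TNS-3": ("5TNS", (pt,)),
        "5TNS-4": ("5TNS", (vf2r, c, pt)),
        "5TNS-5": ("5TNS", (vf2r,)),
        # 3' end of the read on the antisense strand (= mRNA 5' end)
        "3TNS": ("3TNS", (adr, e1, vf1r)),
        "3TNS-1": ("3TNS", (adr, e1)),
        "3TNS-2": ("3TNS", (e1, vf1r)),
        "3TNS-5": ("3TNS", (vf1r,)),
    }
    out: dict[str, TerminusDef] = {}
    for name, (family, elements) in table.items():
        up = "vector" if family in ("5TSS", "5TNS") else "insert"
        down = "insert" if family in ("5TSS", "5TNS") else "vector"
        out[name] = TerminusDef(name, family, elements, up, down)
    return out


# -- synthetic fixture vector ------------------------------------------------

# Windows that must not occur in random backbone/insert sequence: anything a
# motif scan (or its 1-mismatch context rescue) could mistake for a planted
# element.  Scrubbing margins: Hamming<=1 for 6-mer enzyme sites, <=2 for the
# 9-mer adapter forms, and no A/T homopolymer run of 6+.
_SCRUB_6MERS = ("GAATTC", "CTCGAG")
_SCRUB_9MERS = ("GGCACGAGG", "CCTCGTGCC")


def _motif_mismatch_starts(arr: np.ndarray, motif: str, max_mm: int) -> np.ndarray:
    """Window starts where ``arr`` is within ``max_mm`` mismatches of ``motif``."""
    k = len(motif)
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.intp)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    mm = np.zeros(n - k + 1, dtype=np.int16)
    for j in range(k):
        mm += arr[j : n - k + 1 + j] != m[j]
    return np.nonzero(mm <= max_mm)[0]


def _offending_windows(arr: np.ndarray) -> list[tuple[int, int, str]]:
    """All windows resembling a planted element: (start, end, motif)."""
    out: list[tuple[int, int, str]] = []
    for motif in _SCRUB_6MERS:
        out.extend((int(s), int(s) + 6, motif)
                   for s in _motif_mismatch_starts(arr, motif, 1))
    for motif in _SCRUB_9MERS:
        out.extend((int(s), int(s) + 9, motif)
                   for s in _motif_mismatch_starts(arr, motif, 2))
    for run in ("AAAAAA", "TTTTTT"):
        out.extend((int(s), int(s) + 6, run)
                   for s in _motif_mismatch_starts(arr, run, 0))
    # impurity-tolerant homopolymer runs: any 10-window with >=9 identical
    # A/T can seed a detectable poly tail (and longer impure runs always
    # contain such a window)
    for run in ("A" * 10, "T" * 10):
        out.extend((int(s), int(s) + 10, run)
                   for s in _motif_mismatch_starts(arr, run, 1))
    return sorted(out)


_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def scrub_dna(seq: str, rng: np.random.Generator,
              protected: tuple[tuple[int, int], ...] = ()) -> str:
    """Mutate bases until no window mimics an enzyme/adapter/poly element.

    Positions inside ``protected`` intervals are never touched (they hold
    deliberately planted motifs; a window lying wholly inside them is left
    alone).  To move a window away from a motif, a *matching* free position
    is flipped to a base differing from both its current value and the motif
    — each mutation strictly increases that window's Hamming distance.
    Deterministic for a given ``rng`` state.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    prot = np.zeros(arr.size, dtype=bool)
    for s, e in protected:
        prot[s:e] = True

    for _ in range(60):
        touched = np.zeros(arr.size, dtype=bool)
        pending = False
        for s, e, motif in _offending_windows(arr):
            m = np.frombuffer(motif.encode(), dtype=np.uint8)
            fixable = [
                i for i in range(s, e)
                if not prot[i] and arr[i] == m[i - s]
            ]
            if not fixable:
                continue  # planted motif or junction mismatch: leave alone
            pending = True
            if touched[s:e].any():
                continue  # already perturbed this pass; recheck next pass
            i = fixable[len(fixable) // 2]
            choices = _BASES_U8[(_BASES_U8 != arr[i]) & (_BASES_U8 != m[i - s])]
            arr[i] = choices[int(rng.integers(choices.size))]
            touched[max(0, s - 1) : e + 1] = True
        if not pending:
            break
    else:  # pragma: no cover - safety valve
        raise RuntimeError("scrub_dna failed to converge")
    return arr.tobytes().decode()


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.45,
               scrub: bool = True) -> str:
    """Random insert-like DNA, optionally scrubbed of element-like windows."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    seq = rng.choice(_BASES_U8, size=n, p=[p_at, p_gc, p_gc, p_at]).tobytes().decode()
    return scrub_dna(seq, rng) if scrub else seq


_FIXTURE_SEED = 1203
_FIXTURE_LEFT = 1400      # backbone left of the enzyme-1 site
_FIXTURE_STUFFER = 200    # vector between the two sites
_FIXTURE_LEN = 3000
_VF_LEN = 50              # vector border width flanking the cloning sites


def _fixture_vector() -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Deterministic 3-kb synthetic plasmid with an EcoRI..XhoI cloning region.

    A stand-in for an unpublished real vector: random scrubbed backbone with
    GAATTC planted at 1400 and CTCGAG at 1606.  Returns (sequence, VF1, VF2).
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    left = random_dna(_FIXTURE_LEFT, rng, gc=0.5)
    stuffer = random_dna(_FIXTURE_STUFFER, rng, gc=0.5)
    right = random_dna(_FIXTURE_LEN - _FIXTURE_LEFT - _FIXTURE_STUFFER - 12,
                       rng, gc=0.5)
    seq = left + "GAATTC" + stuffer + "CTCGAG" + right
    e1s = _FIXTURE_LEFT
    e2s = _FIXTURE_LEFT + 6 + _FIXTURE_STUFFER
    protected = ((e1s, e1s + 6), (e2s, e2s + 6))
    seq = scrub_dna(seq, rng, protected)
    vf1 = (e1s - _VF_LEN, e1s)
    vf2 = (e2s + 6, e2s + 6 + _VF_LEN)
    return seq, vf1, vf2


_DEFAULT_CACHE: ProtocolSpec | None = None


def default_protocol() -> ProtocolSpec:
    """The default EcoRI/XhoI directional protocol on the synthetic fixture vector.

    Enzyme 1 = EcoRI (GAATTC), enzyme 2 = XhoI (CTCGAG), adapter
    GGCACGAGG/CCTCGTGCC, VF1/VF2 = the 50 vector bases flanking the cloning
    sites.  Read names ending ``.g1`` are designated 5', ``.b1`` 3'.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        seq, vf1, vf2 = _fixture_vector()
        _DEFAULT_CACHE = ProtocolSpec(seq, vf1, vf2)
    # return a shallow copy so callers can't corrupt the cache
    return replace(_DEFAULT_CACHE, termini=dict(_DEFAULT_CACHE.termini),
                   direction_rules=dict(_DEFAULT_CACHE.direction_rules))


# ---------------------------------------------------------------------------
# configuration loading


def load_protocol(config_text: str) -> ProtocolSpec:
    """Build a validated :class:`ProtocolSpec` from a YAML protocol config.

    Required keys: ``vector`` (inline sequence or ``{fasta: path}``), ``vf1``
    and ``vf2`` (0-based half-open ``[start, end]`` coordinate pairs).
    Optional: ``enzyme1``, ``enzyme2``, ``adapter``, ``direction_rules``.
    The terminus variant table is auto-expanded from these motifs.
    """
    try:
        cfg = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ProtocolError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ProtocolError("config must be a mapping")
    for key in ("vector", "vf1", "vf2"):
        if key not in cfg:
            raise ProtocolError(f"missing required config field {key!r}")

    vec = cfg["vector"]
    if isinstance(vec, dict):
        path = vec.get("fasta")
        if not path:
            raise ProtocolError("vector mapping must supply a 'fasta' path")
        from Bio import SeqIO

        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ProtocolError(f"no records in vector FASTA {path}")
        want = vec.get("id")
        rec = next((r for r in records if r.id == want), records[0])
        vector_seq = str(rec.seq).upper()
    else:
        vector_seq = str(vec).strip().upper()

    def interval(key: str) -> tuple[int, int]:
        v = cfg[key]
        if (not isinstance(v, (list, tuple))) or len(v) != 2:
            raise ProtocolError(f"{key} must be a [start, end] pair")
        return int(v[0]), int(v[1])

    adapter = str(cfg.get("adapter", "GGCACGAGG")).upper()
    spec = ProtocolSpec(
        vector_sequence=vector_seq,
        vf1_interval=interval("vf1"),
        vf2_interval=interval("vf2"),
        enzyme1_motif=str(cfg.get("enzyme1", "GAATTC")).upper(),
        enzyme2_motif=str(cfg.get("enzyme2", "CTCGAG")).upper(),
        adapter_sense=adapter,
        adapter_antisense=str(
            cfg.get("adapter_antisense", reverse_complement(adapter))
        ).upper(),
        direction_rules={
            str(k): str(v)
            for k, v in (cfg.get("direction_rules") or {".g1": "5", ".b1": "3"}).items()
        },
    )
    return spec
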