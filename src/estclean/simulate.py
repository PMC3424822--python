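"""Synthetic Sanger-style EST reads with exact ground truth.

Every supported construct layout concatenates real protocol segments (vector
borders, enzyme sites, adapters, poly tails, the inter-site vector stuffer)
around random insert DNA, reproducing either the expected clone structure or
one of the abnormality layouts (RECA types A1-F, DBT chimeras and the
trimmable internal-DBT rescue, the frequent simple abnormal cases).

Random inserts and spacers are scrubbed so that no window can be mistaken
for a planted element (see :func:`estclean.protocol.scrub_dna`), keeping the
ground truth unambiguous at zero error rate.  A configurable noise model adds
substitutions/indels and a phred profile; truth coordinates are remapped
through indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import ReadRecord
from .protocol import ProtocolSpec, random_dna, reverse_complement, scrub_dna

__all__ = [
    "ConstructRecipe",
    "SyntheticTruth",
    "QualityProfile",
    "LAYOUTS",
    "make_construct",
    "add_noise",
    "simulate_reads",
    "generate_dataset",
]

_POLY_LEN = 18
_STUFFER_PAD = 130  # extra vector emitted beyond VF2 for trailing-V layouts


@dataclass(frozen=True)
class ConstructRecipe:
    """One synthetic read to build: layout name, insert size, identity."""

    layout: str
    read_id: str
    insert_length: int = 400
    spacer_length: int = 9  # junction spacer for the A2/B2 incompatible ends


@dataclass
class SyntheticTruth:
    """Ground truth of a generated read."""

    read_id: str
    layout: str
    direction: str
    segments: list[tuple[str, str, int, int]]  # (kind, label, start, end)
    clean_interval: tuple[int, int] | None = None
    error_positions: list[int] = field(default_factory=list)

    @property
    def expected_category(self) -> str:
        return _EXPECTED_CATEGORY[self.layout]


# ---------------------------------------------------------------------------
# layout builders


def _segments(protocol: ProtocolSpec) -> dict[str, str]:
    """Named building blocks cut from the protocol."""
    v = protocol.vector_sequence
    e1s, e1e = protocol.enzyme1_site
    e2s, e2e = protocol.enzyme2_site
    vf1s, _ = protocol.vf1_interval
    _, vf2e = protocol.vf2_interval
    rc = reverse_complement
    pa = "A" * _POLY_LEN
    pt = "T" * _POLY_LEN
    return {
        # canonical termini
        "5TSS": v[vf1s:e1e] + protocol.adapter_sense,
        "3TSS": pa + v[e2s:vf2e],
        "5TNS": rc(v[e2s:vf2e]) + pt,
        "3TNS": protocol.adapter_antisense + rc(v[vf1s:e1e]),
        # sub-variants used by abnormal layouts
        "5TSS-1": v[e1s:e1e] + protocol.adapter_sense,
        "5TSS-2": v[vf1s:e1e],
        "3TSS-1": pa + v[e2s:e2e],
        "3TSS-2": v[e2s:vf2e],
        "3TSS-3": pa,
        "3TSS-4": pa + "G" + v[e2e:vf2e],
        "3TSS-5": v[e2e:vf2e],
        "5TNS-1": v[e2s:e2e] + pt,
        "5TNS-2": rc(v[e2s:vf2e]),
        "5TNS-4": rc(v[e2e:vf2e]) + "C" + pt,
        "5TNS-5": rc(v[e2e:vf2e]),
        "3TNS-1": protocol.adapter_antisense + v[e1s:e1e],
        "3TNS-2": v[e1s:e1e] + rc(v[vf1s:e1s]),
        # context pieces
        "stuffer": v[e1e:e2s],
        "stuffer_rc": rc(v[e1e:e2s]),
        "vector_tail": v[vf2e : vf2e + _STUFFER_PAD],
        "wrong_cut": v[e1s - 150 : e1s - 20],  # enzyme-1 flank, cut off-site
        "wrong_cut_rc": rc(v[e1s - 150 : e1s - 20]),
        "DBT1": "CCTCGTGCCGAATTCGGCACGAGG",
        "DBT2": "AATTCGGCACGAGGCCTCGTGCCG",
    }


#: layout name -> designated direction of the read
_DIRECTION = {}
#: layout name -> the primary classification the pipeline should produce
_EXPECTED_CATEGORY = {}


def _piece_plan(recipe: ConstructRecipe, seg: dict[str, str],
                rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """(kind, label, sequence) pieces for one layout, left to right.

    kind is one of terminus/vector/insert/spacer/dbt; insert and spacer
    pieces are random (scrubbed later at read level), everything else is
    planted verbatim.
    """
    L = recipe.insert_length
    S = recipe.spacer_length

    def ins(n: int, label: str = "insert") -> tuple[str, str, str]:
        return ("insert", label, random_dna(n, rng, scrub=False))

    def spacer() -> tuple[str, str, str]:
        return ("spacer", "spacer", random_dna(S, rng, scrub=False))

    def term(name: str) -> tuple[str, str, str]:
        return ("terminus", name, seg[name])

    def vec(label: str) -> tuple[str, str, str]:
        return ("vector", label, seg[label])

    def dbt(label: str) -> tuple[str, str, str]:
        return ("dbt", label, seg[label])

    half = max(120, L // 2)
    third = max(120, L // 3)
    layout = recipe.layout
    plans: dict[str, object] = {
        "expected-5": lambda: [term("5TSS"), ins(L), term("3TSS")],
        "expected-3": lambda: [term("5TNS"), ins(L), term("3TNS")],
        "RECA-A1-5": lambda: [ins(L), term("3TNS-1"), vec("stuffer"),
                              term("3TSS-2")],
        "RECA-A1-3": lambda: [term("5TNS-2"), vec("stuffer_rc"),
                              term("5TSS-1"), ins(L)],
        "RECA-A2-5": lambda: [term("5TSS"), ins(L), spacer(), vec("stuffer"),
                              term("3TSS-2")],
        "RECA-A2-3": lambda: [term("5TNS-2"), vec("stuffer_rc"), spacer(),
                              ins(L), term("3TNS")],
        "RECA-A3-5": lambda: [term("5TSS"), term("3TNS-1"), vec("stuffer"),
                              term("3TSS-2")],
        "RECA-A3-3": lambda: [term("5TNS-2"), vec("stuffer_rc"),
                              term("5TSS-1"), term("3TNS")],
        "RECA-B1-5": lambda: [term("5TSS-2"), vec("stuffer"), term("5TNS-1"),
                              ins(L)],
        "RECA-B1-3": lambda: [ins(L), term("3TSS-1"), vec("stuffer_rc"),
                              term("3TNS-2")],
        "RECA-B2-5": lambda: [term("5TSS-2"), vec("stuffer"), spacer(),
                              ins(L), term("3TSS")],
        "RECA-B2-3": lambda: [term("5TNS"), ins(L), spacer(),
                              vec("stuffer_rc"), term("3TNS-2")],
        "RECA-C-5": lambda: [term("5TSS-2"), vec("stuffer"), term("3TSS-2")],
        "RECA-C-3": lambda: [term("5TNS-2"), vec("stuffer_rc"),
                             term("3TNS-2")],
        "RECA-D-5": lambda: [ins(half), term("3TNS-1"), vec("stuffer"),
                             term("5TNS-1"), ins(half, "insert2")],
        "RECA-D-3": lambda: [ins(half), term("3TSS-1"), vec("stuffer_rc"),
                             term("5TSS-1"), ins(half, "insert2")],
        "RECA-E-5": lambda: [ins(L), vec("stuffer"), term("3TSS-2")],
        "RECA-E-3": lambda: [term("5TNS-2"), vec("stuffer_rc"), ins(L)],
        "RECA-F-5": lambda: [vec("wrong_cut"), ins(L)],
        "RECA-F-3": lambda: [ins(L), vec("wrong_cut_rc")],
        "DBT1-chimera": lambda: [ins(half), dbt("DBT1"),
                                 ins(half, "insert2")],
        "DBT2-chimera": lambda: [ins(half), dbt("DBT2"),
                                 ins(half, "insert2")],
        "DBT-internal": lambda: [term("5TNS"), ins(L), dbt("DBT1"),
                                 term("3TNS")],
        "CASE-1": lambda: [ins(third), term("3TSS-3"),
                           ins(third, "insert2"), term("3TSS-3"),
                           ins(third, "insert3")],
        "CASE-2": lambda: ([ins(half, "lead")] if rng.random() < 0.5 else [])
                          + [term("5TNS-4"), ins(L)],
        "CASE-3": lambda: ([ins(half, "lead")] if rng.random() < 0.5 else [])
                          + [term("5TNS-5"), ins(L)],
        "CASE-4": lambda: [ins(L), term("3TSS-5"), vec("vector_tail")],
        "CASE-5": lambda: [ins(half), term("5TNS-1"), ins(half, "insert2")],
        "CASE-6": lambda: [term("5TNS-2"), ins(L)],
        "CASE-7": lambda: [ins(half), term("3TSS-5"), ins(half, "insert2")],
        "CASE-8": lambda: [ins(L), term("3TSS-4"), vec("vector_tail")],
    }
    if layout not in plans:
        raise ValueError(f"unknown layout {layout!r}")
    return plans[layout]()  # type: ignore[operator]


for _name, _dir in [
    ("expected-5", "5"), ("expected-3", "3"),
    ("RECA-A1-5", "5"), ("RECA-A1-3", "3"), ("RECA-A2-5", "5"),
    ("RECA-A2-3", "3"), ("RECA-A3-5", "5"), ("RECA-A3-3", "3"),
    ("RECA-B1-5", "5"), ("RECA-B1-3", "3"), ("RECA-B2-5", "5"),
    ("RECA-B2-3", "3"), ("RECA-C-5", "5"), ("RECA-C-3", "3"),
    ("RECA-D-5", "5"), ("RECA-D-3", "3"), ("RECA-E-5", "5"),
    ("RECA-E-3", "3"), ("RECA-F-5", "5"), ("RECA-F-3", "3"),
    ("DBT1-chimera", "5"), ("DBT2-chimera", "5"), ("DBT-internal", "3"),
    ("CASE-1", "5"), ("CASE-2", "3"), ("CASE-3", "3"), ("CASE-4", "5"),
    ("CASE-5", "5"), ("CASE-6", "3"), ("CASE-7", "5"), ("CASE-8", "5"),
]:
    _DIRECTION[_name] = _dir

for _name in _DIRECTION:
    if _name.startswith("expected"):
        _EXPECTED_CATEGORY[_name] = "expected"
    elif _name.startswith("RECA"):
        _EXPECTED_CATEGORY[_name] = _name.rsplit("-", 1)[0]
    elif _name.endswith("chimera"):
        _EXPECTED_CATEGORY[_name] = "DBT-chimera"
    elif _name == "DBT-internal":
        _EXPECTED_CATEGORY[_name] = "DBT-internal"
    else:
        _EXPECTED_CATEGORY[_name] = _name

#: all supported construct layouts
LAYOUTS = tuple(_DIRECTION)

#: the 18-layout benchmark mix used for recovery experiments: both expected
#: directions, all nine RECA types (directions alternated), both chimera
#: motifs, the internal-DBT rescue, and the four most diagnostic simple cases
BENCHMARK_LAYOUTS = (
    "expected-5", "expected-3",
    "RECA-A1-5", "RECA-A2-3", "RECA-A3-5", "RECA-B1-3", "RECA-B2-5",
    "RECA-C-3", "RECA-D-5", "RECA-E-3", "RECA-F-5",
    "DBT1-chimera", "DBT2-chimera", "DBT-internal",
    "CASE-1", "CASE-2", "CASE-5", "CASE-8",
)


def _poly_junctions(bases: str, segments: list[tuple[str, str, int, int]],
                    pad: int = 3) -> list[tuple[int, int, str]]:
    """Free positions bordering a planted poly-tail that must avoid its base.

    A homopolymer run planted at a piece edge would otherwise absorb adjacent
    random bases (the run detector tolerates interior impurities), shifting
    every downstream truth coordinate.  Returns (start, end, banned_base)
    spans inside free pieces.
    """
    n = len(bases)
    spans: list[tuple[int, int, str]] = []
    for kind, _, s, e in segments:
        if kind not in ("terminus", "dbt"):
            continue
        # run of >=4 identical A/T at either edge of the planted piece
        for edge, step in ((s, 1), (e - 1, -1)):
            b = bases[edge]
            if b not in "AT":
                continue
            run = 0
            i = edge
            while s <= i < e and bases[i] == b:
                run += 1
                i += step
            if run < 4:
                continue
            if step == 1 and s - pad >= 0:  # run at left edge: pad before it
                spans.append((max(0, s - pad), s, b))
            elif step == -1 and e + pad <= n:  # run at right edge: pad after
                spans.append((e, min(n, e + pad), b))
    return spans


def _finalize_bases(raw: str, segments: list[tuple[str, str, int, int]],
                    protected: tuple[tuple[int, int], ...],
                    rng: np.random.Generator) -> str:
    """Scrub element-like windows and poly-tail junction bleed-through."""
    bases = scrub_dna(raw, rng, protected)
    for _ in range(10):
        chars = list(bases)
        changed = False
        for a, b, banned in _poly_junctions(bases, segments):
            others = [c for c in "ACGT" if c != banned]
            for i in range(a, b):
                if chars[i] == banned:
                    chars[i] = others[int(rng.integers(3))]
                    changed = True
        if not changed:
            return bases
        bases = scrub_dna("".join(chars), rng, protected)
    raise RuntimeError("could not build an unambiguous construct")  # pragma: no cover


def make_construct(recipe: ConstructRecipe, protocol: ProtocolSpec,
                   rng: np.random.Generator) -> tuple[str, SyntheticTruth]:
    """Build one error-free read and its truth map for a recipe.

    The concatenated read is scrubbed with all planted (non-random) segments
    protected, so junctions between random and planted pieces cannot form
    spurious element-like windows.
    """
    seg = _segments(protocol)
    pieces = _piece_plan(recipe, seg, rng)
    segments: list[tuple[str, str, int, int]] = []
    pos = 0
    protected: list[tuple[int, int]] = []
    parts: list[str] = []
    for kind, label, sequence in pieces:
        end = pos + len(sequence)
        segments.append((kind, label, pos, end))
        if kind not in ("insert", "spacer"):
            protected.append((pos, end))
        parts.append(sequence)
        pos = end
    bases = _finalize_bases("".join(parts), segments, tuple(protected), rng)

    clean = None
    if recipe.layout in ("expected-5", "expected-3", "DBT-internal"):
        for kind, label, s, e in segments:
            if kind == "insert":
                clean = (s, e)
                break
    truth = SyntheticTruth(recipe.read_id, recipe.layout,
                           _DIRECTION[recipe.layout], segments, clean)
    return bases, truth


# ---------------------------------------------------------------------------
# noise model


@dataclass(frozen=True)
class QualityProfile:
    """Positional phred profile: low head, high middle, decaying tail.

    Defaults collapse to a flat high-quality read (head/tail disabled), the
    regime used for the recovery experiments; Sanger-like shapes are opted
    into by setting ``head_len``/``tail_start``.
    """

    mid_q: int = 40
    head_len: int = 0
    head_q: int = 12
    tail_start: int | None = None
    tail_q: int = 8

    def quals(self, n: int) -> np.ndarray:
        q = np.full(n, self.mid_q, dtype=np.int32)
        if self.head_len > 0:
            ramp = np.linspace(self.head_q, self.mid_q,
                               min(self.head_len, n), dtype=np.int32)
            q[: ramp.size] = ramp
        if self.tail_start is not None and self.tail_start < n:
            ramp = np.linspace(self.mid_q, self.tail_q,
                               n - self.tail_start, dtype=np.int32)
            q[self.tail_start :] = ramp
        return q


def add_noise(bases: str, rng: np.random.Generator, sub_rate: float = 0.0,
              indel_rate: float = 0.0,
              profile: QualityProfile | None = None,
              ) -> tuple[str, np.ndarray, list[int], np.ndarray]:
    """Apply per-base substitutions/indels and simulate phred scores.

    Returns ``(bases, quals, error_positions, coord_map)`` where
    ``coord_map[i]`` is the output coordinate of input position ``i``
    (``coord_map[n]`` = output length), suitable for remapping truth
    intervals through indels.  Deterministic for a given ``rng``.
    """
    if not 0.0 <= sub_rate <= 0.2 or not 0.0 <= indel_rate <= 0.2:
        raise ValueError("error rates must be within [0, 0.2]")
    profile = profile or QualityProfile()
    n = len(bases)
    out: list[str] = []
    errors: list[int] = []
    coord = np.zeros(n + 1, dtype=np.int64)
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    # draw all randomness up front so rates of 0 consume no extra entropy
    do_sub = rng.random(n) < sub_rate if sub_rate > 0 else np.zeros(n, bool)
    do_indel = rng.random(n) < indel_rate if indel_rate > 0 else np.zeros(n, bool)
    for i, b in enumerate(bases):
        coord[i] = len(out)
        if do_indel[i]:
            if rng.random() < 0.5:  # deletion
                errors.append(len(out))
                continue
            out.append("ACGT"[int(rng.integers(4))])  # insertion before base
            errors.append(len(out) - 1)
        if do_sub[i]:
            out.append(others[b][int(rng.integers(3))])
            errors.append(len(out) - 1)
        else:
            out.append(b)
    coord[n] = len(out)
    new_bases = "".join(out)
    quals = profile.quals(len(new_bases))
    return new_bases, quals, errors, coord


# ---------------------------------------------------------------------------
# dataset generation


def _direction_suffix(direction: str) -> str:
    return ".g1" if direction == "5" else ".b1"


def simulate_reads(n: int, proportions: dict[str, float], seed: int,
                   insert_length_range: tuple[int, int] = (350, 450),
                   sub_rate: float = 0.0, indel_rate: float = 0.0,
                   protocol: ProtocolSpec | None = None,
                   profile: QualityProfile | None = None,
                   ) -> list[tuple[ReadRecord, SyntheticTruth]]:
    """Draw ``n`` reads according to layout proportions (largest remainder)."""
    from .protocol import default_protocol

    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("layout proportions must sum to 1")
    for layout in proportions:
        if layout not in _DIRECTION:
            raise ValueError(f"unknown layout {layout!r}")
    protocol = protocol or default_protocol()
    rng = np.random.default_rng(seed)

    # largest-remainder apportionment of n reads over the layouts
    items = sorted(proportions.items())
    raw = [(name, n * frac) for name, frac in items]
    counts = {name: int(x) for name, x in raw}
    short = n - sum(counts.values())
    for name, x in sorted(raw, key=lambda t: -(t[1] - int(t[1])))[:short]:
        counts[name] += 1

    out: list[tuple[ReadRecord, SyntheticTruth]] = []
    idx = 0
    for layout, count in counts.items():
        for _ in range(count):
            direction = _DIRECTION[layout]
            read_id = f"syn_{idx:05d}_{layout}{_direction_suffix(direction)}"
            L = int(rng.integers(insert_length_range[0],
                                 insert_length_range[1] + 1))
            spacer = int(rng.integers(3, 16))
            recipe = ConstructRecipe(layout, read_id, L, spacer)
            bases, truth = make_construct(recipe, protocol, rng)
            bases, quals, errors, coord = add_noise(
                bases, rng, sub_rate, indel_rate, profile
            )
            truth.error_positions = errors
            truth.segments = [
                (k, lab, int(coord[s]), int(coord[e]))
                for k, lab, s, e in truth.segments
            ]
            if truth.clean_interval is not None:
                s, e = truth.clean_interval
                truth.clean_interval = (int(coord[s]), int(coord[e]))
            out.append((ReadRecord(read_id, bases, quals, direction), truth))
            idx += 1
    return out


def generate_dataset(n: int, proportions: dict[str, float], seed: int,
                     out_dir: str, **kwargs) -> dict[str, str]:
    """Simulate reads and write FASTA + QUAL + a truth TSV.

    Returns the mapping of written file paths.  Columns of the truth table:
    read_id, layout, direction, expected_category, clean_start/clean_end
    (1-based inclusive, empty when the layout defines no clean insert) and
    the segment map as ``kind:label:start-end`` (1-based inclusive) joined
    by ``;``.
    """
    import os

    import pandas as pd

    pairs = simulate_reads(n, proportions, seed, **kwargs)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "reads.fasta"),
        "qual": os.path.join(out_dir, "reads.qual"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    with open(paths["fasta"], "w") as fa, open(paths["qual"], "w") as qu:
        for read, _ in pairs:
            fa.write(f">{read.id}\n{read.bases}\n")
            qu.write(f">{read.id}\n")
            qu.write(" ".join(map(str, read.quals.tolist())) + "\n")
    rows = []
    for read, truth in pairs:
        cs, ce = ("", "")
        if truth.clean_interval is not None:
            cs, ce = truth.clean_interval[0] + 1, truth.clean_interval[1]
        rows.append({
            "read_id": truth.read_id,
            "layout": truth.layout,
            "direction": truth.direction,
            "expected_category": truth.expected_category,
            "clean_start": cs,
            "clean_end": ce,
            "segments": ";".join(
                f"{k}:{lab}:{s + 1}-{e}" for k, lab, s, e in truth.segments
            ),
        })
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
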