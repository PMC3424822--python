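"""FASTA/QUAL input and TSV/FASTA report output.

All user-facing coordinates in written reports are 1-based inclusive;
in-memory intervals stay 0-based half-open.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO

from .elements import ReadRecord
from .pipeline import ReadReport, SummaryStats
from .protocol import ProtocolSpec

__all__ = [
    "read_reads",
    "write_clean_fasta",
    "report_table",
    "write_report_tsv",
    "write_summary_tsvs",
]


def read_reads(fasta_path: str, qual_path: str | None = None,
               protocol: ProtocolSpec | None = None) -> list[ReadRecord]:
    """Load a multi-FASTA (and optional paired QUAL) into read records.

    QUAL records are matched to FASTA records by id; a missing or
    length-mismatched QUAL entry raises ``ValueError``.  Designated read
    directions are derived from the protocol's naming convention when a
    protocol is given.
    """
    quals: dict[str, np.ndarray] = {}
    if qual_path is not None:
        for rec in SeqIO.parse(qual_path, "qual"):
            quals[rec.id] = np.asarray(
                rec.letter_annotations["phred_quality"], dtype=np.int32
            )
    reads: list[ReadRecord] = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        q = quals.get(rec.id)
        if qual_path is not None and q is None:
            raise ValueError(f"no QUAL record for read {rec.id}")
        read = ReadRecord(rec.id, str(rec.seq).upper(), q)
        if protocol is not None:
            read.designated_direction = protocol.direction_of(rec.id)
        reads.append(read)
    return reads


def write_clean_fasta(reports: list[ReadReport], reads: list[ReadRecord],
                      path: str) -> int:
    """Write the trimmed clean inserts; returns the number written."""
    by_id = {r.id: r for r in reads}
    n = 0
    with open(path, "w") as fh:
        for rep in reports:
            if rep.outcome != "clean" or rep.clean_interval is None:
                continue
            s, e = rep.clean_interval
            fh.write(f">{rep.read_id} /clean={s + 1}-{e}\n")
            fh.write(by_id[rep.read_id].bases[s:e] + "\n")
            n += 1
    return n


def report_table(reports: list[ReadReport]) -> pd.DataFrame:
    """One row per read: pattern, calls, outcome, 1-based clean coordinates."""
    rows = []
    for r in reports:
        cs, ce = ("", "")
        if r.clean_interval is not None:
            cs, ce = r.clean_interval[0] + 1, r.clean_interval[1]
        rows.append({
            "read_id": r.read_id,
            "direction": r.direction,
            "pattern": r.pattern_rendering,
            "pattern_refined": r.pattern.render(refined=True) if r.pattern else "",
            "primary_category": r.primary_category,
            "secondary_categories": ";".join(c.category for c in r.secondary),
            "outcome": r.outcome,
            "clean_start": cs,
            "clean_end": ce,
            "rejection_reason": r.rejection_reason or "",
            "warning": r.warning or "",
            "termini": ";".join(
                f"{t.def_name}:{t.start + 1}-{t.end}"
                f":A={t.a_score:.1f}:B={t.b_score:.1f}"
                f":C={t.c_score:.1f}:conf={t.confidence:.1f}"
                for t in r.termini
            ),
            "dbt": ";".join(
                f"type{h.dbt_type}:{h.start + 1}-{h.end}:rep{h.repetition_index}"
                for h in r.dbt_hits
            ),
        })
    return pd.DataFrame(rows)


def write_report_tsv(reports: list[ReadReport], path: str) -> None:
    report_table(reports).to_csv(path, sep="\t", index=False)


def write_summary_tsvs(stats: SummaryStats, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "patterns": os.path.join(out_dir, "summary_patterns.tsv"),
        "categories": os.path.join(out_dir, "summary_categories.tsv"),
    }
    stats.by_pattern.to_csv(paths["patterns"], sep="\t", index=False)
    stats.by_category.to_csv(paths["categories"], sep="\t", index=False)
    return paths
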