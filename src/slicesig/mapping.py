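"""Zero-mismatch, all-hit placement of reads onto reporter constructs.

Mirrors exhaustive exact short-read alignment (every occurrence reported;
with zero mismatches all hits are tied, so all are kept).  Read counts are
split across a read's mapped sites (weight = 1/n_hits) and normalized to
library size as rpm (reads per million).  Library size defaults to the
number of reads surviving preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .read_prep import RawRead
from .reporter import revcomp


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    construct_id: str
    start: int  # 0-based half-open construct coordinates
    end: int
    strand: str = "+"


@dataclass
class MappedRead:
    read_id: str
    sequence: str
    hits: list[AlignmentHit] = field(default_factory=list)
    rpm: float = 0.0  # per-hit rpm (weight x 1e6 / library size)

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits if self.hits else 0.0

    def __len__(self) -> int:
        return len(self.sequence)


def _occurrences(text: str, pattern: str) -> list[int]:
    """All (possibly overlapping) exact occurrence starts of pattern."""
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def map_exact(
    reads: Iterable[RawRead],
    constructs: dict[str, str],
    both_strands: bool = False,
) -> tuple[list[MappedRead], list[str]]:
    """Map reads by exhaustive exact substring search.

    Returns (mapped reads, ids of unmapped reads).  Default is sense-strand
    only: reporter-derived slicer fragments are sense; antisense search is
    available behind ``both_strands``.
    """
    if len(set(constructs)) != len(constructs):  # dict keys are unique; guard API misuse
        raise ValueError("duplicate construct ids")
    mapped, unmapped = [], []
    for read in reads:
        seq = read.sequence.upper()
        hits = []
        for cid, cseq in constructs.items():
            for s in _occurrences(cseq.upper(), seq):
                hits.append(AlignmentHit(read.read_id, cid, s, s + len(seq), "+"))
            if both_strands:
                for s in _occurrences(cseq.upper(), revcomp(seq)):
                    hits.append(
                        AlignmentHit(read.read_id, cid, s, s + len(seq), "-")
                    )
        if hits:
            mapped.append(MappedRead(read.read_id, seq, hits))
        else:
            unmapped.append(read.read_id)
    return mapped, unmapped


def normalize_rpm(mapped: Sequence[MappedRead], library_size: int) -> None:
    """Set per-hit rpm = (1/n_hits) x 1e6 / library_size (in place)."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    for m in mapped:
        m.rpm = m.weight * 1e6 / library_size


def filter_rpm(records: Iterable, threshold: float = 0.05) -> list:
    """Keep records with rpm >= threshold (inclusive, per the display rule)."""
    return [r for r in records if r.rpm >= threshold]


def hits_table(mapped: Sequence[MappedRead]) -> pd.DataFrame:
    rows = [
        {
            "read_id": h.read_id,
            "construct": h.construct_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "n_hits": m.n_hits,
            "weight": m.weight,
            "rpm": m.rpm,
        }
        for m in mapped
        for h in m.hits
    ]
    return pd.DataFrame(
        rows,
        columns=["read_id", "construct", "start", "end", "strand", "n_hits", "weight", "rpm"],
    )


def write_hits_tsv(mapped: Sequence[MappedRead], path: str | Path) -> None:
    hits_table(mapped).to_csv(path, sep="\t", index=False)


def write_sam(
    mapped: Sequence[MappedRead],
    constructs: dict[str, str],
    path: str | Path,
) -> None:
    """Emit hits as SAM for interoperability (NH tag = hit count;
    unmapped reads omitted; secondary hits flagged)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in constructs.items()],
    }
    tids = {cid: i for i, cid in enumerate(constructs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in mapped:
            for i, h in enumerate(m.hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = m.read_id
                seq = m.sequence if h.strand == "+" else revcomp(m.sequence)
                a.query_sequence = seq
                a.flag = (0x100 if i > 0 else 0) | (0x10 if h.strand == "-" else 0)
                a.reference_id = tids[h.construct_id]
                a.reference_start = h.start
                a.mapping_quality = 255
                a.cigartuples = [(0, len(m.sequence))]
                a.set_tag("NH", m.n_hits)
                out.write(a)
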