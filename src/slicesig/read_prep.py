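"""Small-RNA read preprocessing: 3' adapter clipping, quality trimming and
length filtering.

The trimmer implements a deterministic, documented subset of standard
small-RNA adapter clipping: a single 3' adapter, semi-global alignment
allowing substitutions and indels, an error-rate ceiling, a minimum
overlap, and BWA-style 3' quality trimming (applied before the adapter
search).  ``N`` in the read matches any adapter base.

Hit ranking among candidate adapter occurrences: fewest errors, then
longest overlap (number of adapter bases aligned), then leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimParams:
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    min_length: int = 15
    max_error_rate: float = 0.2
    min_overlap: int = 4
    quality_cutoff: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def quality_trim_index(qualities: tuple[int, ...], cutoff: int) -> int:
    """BWA-style 3' quality trim point.

    Walking from the 3' end, accumulate (cutoff - q); the trim point is
    where the running sum is maximal (and positive).  Returns the new read
    length.
    """
    if cutoff <= 0:
        return len(qualities)
    best, s, pos = 0, 0, len(qualities)
    for i in range(len(qualities) - 1, -1, -1):
        s += cutoff - qualities[i]
        if s < 0:
            break
        if s > best:
            best, pos = s, i
    return pos


def _bases_match(read_base: str, adapter_base: str) -> bool:
    return read_base == adapter_base or read_base == "N"


def find_adapter(seq: str, params: TrimParams) -> int | None:
    """Best 3' adapter occurrence; returns the read truncation index or
    None if no acceptable hit exists.

    A hit starts at read position i and aligns the adapter rightwards; the
    alignment may end by consuming the full adapter (internal hit, trailing
    read bases discarded too) or by reaching the read's 3' end (the read
    suffix matches an adapter prefix).  overlap = adapter bases consumed;
    accept iff overlap >= min_overlap and errors/overlap <= max_error_rate.
    """
    adapter = params.adapter.upper()
    n, m = len(seq), len(adapter)
    if n == 0 or m == 0:
        return None

    # Fast path 1: exact full-adapter occurrence (leftmost).  A 0-error hit
    # with maximal overlap cannot be beaten under the (errors, -overlap,
    # start) ranking.
    if "N" not in seq:
        j = seq.find(adapter)
        if j != -1 and m >= params.min_overlap:
            return j
        # Fast path 2: read suffix == adapter prefix, longest such overlap.
        max_k = min(m - 1, n)
        for k in range(max_k, params.min_overlap - 1, -1):
            if seq[n - k :] == adapter[:k]:
                return n - k

    # General case: semi-global DP with a free read prefix.  Cell (x, j)
    # holds (errors, start) for the best alignment of adapter[:j] ending at
    # read position x; lexicographic min keeps the leftmost start among
    # equal-error alignments.
    INF = m + n + 1
    prev = [(j, 0) for j in range(m + 1)]  # x = 0: leading adapter gaps
    prev[0] = (0, 0)
    rows = [prev]
    for x in range(1, n + 1):
        cur = [(0, x)] + [(INF, 0)] * m
        base = seq[x - 1]
        for j in range(1, m + 1):
            pe, ps = prev[j - 1]
            diag = (pe + (0 if _bases_match(base, adapter[j - 1]) else 1), ps)
            ue, us = prev[j]
            up = (ue + 1, us)
            le, ls = cur[j - 1]
            left = (le + 1, ls)
            cur[j] = min(diag, up, left)
        prev = cur
        rows.append(cur)

    best: tuple[int, int, int] | None = None  # (errors, -overlap, start)
    if m >= params.min_overlap:
        for x in range(1, n + 1):  # full adapter consumed, rest of read cut
            err, start = rows[x][m]
            if err / m <= params.max_error_rate:
                cand = (err, -m, start)
                if best is None or cand < best:
                    best = cand
    for j in range(params.min_overlap, m):  # adapter prefix at the read end
        err, start = rows[n][j]
        if err / j <= params.max_error_rate:
            cand = (err, -j, start)
            if best is None or cand < best:
                best = cand
    return best[2] if best is not None else None


def trim_read(read: RawRead, params: TrimParams) -> RawRead:
    """Quality-trim the 3' end, then clip the best 3' adapter hit."""
    qpos = quality_trim_index(read.qualities, params.quality_cutoff)
    seq = read.sequence[:qpos].upper()
    quals = read.qualities[:qpos]
    cut = find_adapter(seq, params)
    if cut is not None:
        seq, quals = seq[:cut], quals[:cut]
    return RawRead(read.read_id, seq, quals)


def length_filter(
    reads: Iterable[RawRead], min_length: int = 15
) -> tuple[list[RawRead], dict[str, int]]:
    """Keep reads of at least ``min_length`` nt; report kept/discarded."""
    kept, discarded = [], 0
    for r in reads:
        if len(r) >= min_length:
            kept.append(r)
        else:
            discarded += 1
    return kept, {"kept": len(kept), "discarded": discarded}


def prep_reads(
    reads: Iterable[RawRead], params: TrimParams | None = None
) -> tuple[list[RawRead], pd.DataFrame]:
    """Trim + filter a read collection; returns reads and a report table."""
    params = params or TrimParams()
    n_in = 0
    n_adapter = 0
    trimmed = []
    for r in reads:
        n_in += 1
        t = trim_read(r, params)
        if len(t) < len(r):
            n_adapter += 1
        trimmed.append(t)
    kept, counts = length_filter(trimmed, params.min_length)
    mean_len = sum(len(r) for r in kept) / len(kept) if kept else 0.0
    report = pd.DataFrame(
        [
            {
                "reads_in": n_in,
                "reads_out": counts["kept"],
                "reads_discarded_short": counts["discarded"],
                "reads_trimmed": n_adapter,
                "mean_trimmed_length": round(mean_len, 3),
            }
        ]
    )
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def prep_fastq(
    in_path: str | Path,
    out_path: str | Path,
    params: TrimParams | None = None,
    report_path: str | Path | None = None,
) -> pd.DataFrame:
    kept, report = prep_reads(read_fastq(in_path), params)
    write_fastq(kept, out_path)
    if report_path is not None:
        report.to_csv(report_path, sep="\t", index=False)
    return report
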