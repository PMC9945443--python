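"""Guide–target complementarity scanning of a piRNA pool.

Asks whether any piRNA in a pool can pair with a given target site, and
profiles where the mismatches fall.  Each pool piRNA is anchored with its
5' end at the site's anchor (guide-relative position 0) and read outward:
piRNA nt j (1-based from its 5' end) faces the target nucleotide at
guide-relative position −(j−1).  A position matches when the target base
is the Watson–Crick complement of the piRNA base; G:U wobble counts as a
mismatch by default (strict pairing), switchable.  Positions falling
outside the target site are marked ``overhang`` and excluded from the
mismatch count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .reporter import GuideSite, Reporter, complement_base, is_wobble


@dataclass(frozen=True)
class PoolEntry:
    name: str
    sequence: str
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"{self.name}: negative abundance")
        object.__setattr__(
            self, "sequence", self.sequence.upper().replace("U", "T")
        )


@dataclass(frozen=True)
class MismatchProfile:
    name: str
    states: tuple[str, ...]  # per piRNA position 1..L: match|mismatch|overhang
    abundance: float
    shift: int = 0  # anchor offset of the minimum-mismatch registration

    @property
    def n_mismatches(self) -> int:
        return sum(s == "mismatch" for s in self.states)

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, s in enumerate(self.states) if s == "mismatch")


def profile_against_site(
    pirna: str,
    site_sequence: str,
    anchor_offset: int = 0,
    allow_wobble: bool = False,
) -> tuple[str, ...]:
    """Per-position pairing states of a piRNA against a target site.

    ``site_sequence`` is the site 5'->3' on the construct; its last
    nucleotide is the anchor (position 0).  ``anchor_offset`` slides the
    piRNA 5' end by s nt (positive: downstream on the construct).
    """
    seq = pirna.upper().replace("U", "T")
    L = len(site_sequence)
    states = []
    for j, base in enumerate(seq, start=1):
        # construct index of the target nucleotide facing piRNA nt j
        idx = (L - 1) - (j - 1) + anchor_offset
        if not 0 <= idx < L:
            states.append("overhang")
            continue
        target = site_sequence[idx]
        ok = target == complement_base(base) or (
            allow_wobble and is_wobble(base, target)
        )
        states.append("match" if ok else "mismatch")
    return tuple(states)


def scan_pool(
    pool: Sequence[PoolEntry],
    site_sequence: str,
    max_mm: int = 3,
    shift: int = 0,
    allow_wobble: bool = False,
) -> list[MismatchProfile]:
    """Profile every pool piRNA against the site; keep those with at most
    ``max_mm`` mismatches, best (minimum-mismatch) registration within
    ±``shift`` nt of the anchor.  Sorted by (n_mismatches, −abundance).
    """
    if not pool:
        raise ValueError("empty piRNA pool")
    profiles = []
    for entry in pool:
        best: MismatchProfile | None = None
        for s in range(-shift, shift + 1):
            states = profile_against_site(
                entry.sequence, site_sequence, s, allow_wobble
            )
            cand = MismatchProfile(entry.name, states, entry.abundance, s)
            if best is None or cand.n_mismatches < best.n_mismatches:
                best = cand
        assert best is not None
        if best.n_mismatches <= max_mm:
            profiles.append(best)
    profiles.sort(key=lambda p: (p.n_mismatches, -p.abundance, p.name))
    return profiles


def scan_reporter_site(
    pool: Sequence[PoolEntry],
    reporter: Reporter,
    site: GuideSite | None = None,
    **kwargs,
) -> list[MismatchProfile]:
    """Scan against one of a reporter's sites (default: the first)."""
    site = site or reporter.sites[0]
    return scan_pool(pool, reporter.site_sequence(site), **kwargs)


def mismatch_heatmap_table(profiles: Sequence[MismatchProfile]) -> pd.DataFrame:
    """Long-format (piRNA, position, state, abundance) table for heatmap
    rendering, one row per piRNA nucleotide."""
    rows = [
        {
            "piRNA": p.name,
            "position": j,
            "state": state,
            "abundance": p.abundance,
            "n_mismatches": p.n_mismatches,
        }
        for p in profiles
        for j, state in enumerate(p.states, start=1)
    ]
    return pd.DataFrame(
        rows, columns=["piRNA", "position", "state", "abundance", "n_mismatches"]
    )


# ---------------------------------------------------------------------------
# Pool I/O


def read_pool_tsv(path: str | Path) -> list[PoolEntry]:
    """TSV with columns: name (optional), sequence, abundance."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sequence" not in cols:
        raise ValueError("pool TSV needs a 'sequence' column")
    entries = []
    for i, r in enumerate(df.itertuples(index=False)):
        d = r._asdict()
        name = str(d.get(cols.get("name", ""), f"piRNA{i + 1}"))
        abundance = float(d.get(cols.get("abundance", ""), 1.0))
        entries.append(PoolEntry(name, str(d[cols["sequence"]]), abundance))
    return entries


def read_pool_fasta(path: str | Path) -> list[PoolEntry]:
    """FASTA pool; abundance parsed from an ``abundance=X`` tag in the
    description when present, else 1."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        abundance = 1.0
        for tok in rec.description.split():
            if tok.startswith("abundance="):
                abundance = float(tok.split("=", 1)[1])
        entries.append(PoolEntry(rec.id, str(rec.seq), abundance))
    return entries
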