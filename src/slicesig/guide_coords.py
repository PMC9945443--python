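"""Guide-relative coordinates, end coverages and metaplots.

Guide-relative position of a construct coordinate ``c`` in a site's frame
is ``c - anchor``, where the anchor is the construct coordinate of the
target nucleotide pairing guide nt 1 (position 0).  The nucleotide pairing
guide nt k sits at ``-(k-1)``; the slicer cut lies between positions −10
and −9, so pre-piRNA 5' ends map to −9 and by-product 3' ends to −10.

A mapped hit is assigned to every site whose window its 5' end falls in
(windows of adjacent tandem sites overlap: a 45-nt inter-cleavage fragment
belongs to the frame of the site that cut its 5' end *and* appears
downstream in the previous site's frame).  Per-site coverages count the
hit fully in each window; the cross-site metaplot divides each hit's rpm
by the number of windows it entered so that total rpm is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentHit, MappedRead
from .read_prep import RawRead
from .reporter import GuideSite

#: Default site window on the 5'-end guide-relative position, for a 30-nt
#: guide and 45-nt repeat unit: upstream to the by-product region and one
#: spacer, downstream past the next cut.
DEFAULT_WINDOW = (-45, 50)

INTERSITE = "intersite"
METAPLOT = "metaplot"


@dataclass(frozen=True)
class SiteAssignment:
    """One (hit, site) pairing in the site's guide frame."""

    read_id: str
    site_id: str  # site id, or "intersite" for hits outside every window
    p5: int
    p3: int
    length: int
    rpm: float
    n_windows: int  # windows this hit fell in (1 for intersite records)
    sequence: str

    @property
    def metaplot_rpm(self) -> float:
        return self.rpm / self.n_windows


def to_guide_frame(hit: AlignmentHit, site: GuideSite) -> tuple[int, int]:
    """(p5, p3) of a hit in a site's guide frame."""
    return hit.start - site.anchor, (hit.end - 1) - site.anchor


def default_window(guide_length: int = 30, repeat_unit: int = 45) -> tuple[int, int]:
    return (-(guide_length + 15), repeat_unit + 5)


def assign_to_sites(
    mapped: Sequence[MappedRead],
    sites: Sequence[GuideSite],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[SiteAssignment]:
    """Assign every hit of every mapped read to site windows by its 5' end.

    Hits outside every window are kept in the "intersite" bucket so that
    rpm is conserved, never dropped silently.
    """
    lo, hi = window
    out: list[SiteAssignment] = []
    for m in mapped:
        for h in m.hits:
            frames = []
            for site in sites:
                p5, p3 = to_guide_frame(h, site)
                if lo <= p5 <= hi:
                    frames.append((site.site_id, p5, p3))
            n = len(frames)
            if n == 0:
                out.append(
                    SiteAssignment(
                        m.read_id, INTERSITE, h.start, h.end - 1, len(m),
                        m.rpm, 1, m.sequence,
                    )
                )
            else:
                for sid, p5, p3 in frames:
                    out.append(
                        SiteAssignment(m.read_id, sid, p5, p3, len(m), m.rpm, n, m.sequence)
                    )
    return out


def end_coverage(
    assignments: Iterable[SiteAssignment], which: str = "5p"
) -> pd.DataFrame:
    """Per-position summed rpm of read ends, per site and as a metaplot.

    Returns a tidy frame (site_id, position, rpm); the ``metaplot`` rows
    sum window-weighted rpm over all sites.
    """
    if which not in ("5p", "3p"):
        raise ValueError("which must be '5p' or '3p'")
    per_site: dict[tuple[str, int], float] = {}
    meta: dict[int, float] = {}
    for a in assignments:
        if a.site_id == INTERSITE:
            continue
        pos = a.p5 if which == "5p" else a.p3
        key = (a.site_id, pos)
        per_site[key] = per_site.get(key, 0.0) + a.rpm
        meta[pos] = meta.get(pos, 0.0) + a.metaplot_rpm
    rows = [
        {"site_id": sid, "position": pos, "rpm": rpm}
        for (sid, pos), rpm in sorted(per_site.items())
    ]
    rows += [
        {"site_id": METAPLOT, "position": pos, "rpm": rpm}
        for pos, rpm in sorted(meta.items())
    ]
    return pd.DataFrame(rows, columns=["site_id", "position", "rpm"])


def metaplot_series(coverage: pd.DataFrame) -> pd.Series:
    meta = coverage[coverage.site_id == METAPLOT]
    return pd.Series(meta.rpm.values, index=meta.position.values, dtype=float)


def modal_position(coverage: pd.DataFrame) -> int:
    """Position of maximal metaplot rpm (smallest position wins ties)."""
    s = metaplot_series(coverage)
    if s.empty or not (s > 0).any():
        raise ValueError("all-zero coverage")
    return int(s.index[np.argmax(s.values)])


def body_coverage(assignments: Iterable[SiteAssignment]) -> pd.DataFrame:
    """Per-position summed rpm over full read extents (every position a
    read covers, not just its ends), per site and as a metaplot."""
    per_site: dict[tuple[str, int], float] = {}
    meta: dict[int, float] = {}
    for a in assignments:
        if a.site_id == INTERSITE:
            continue
        for pos in range(a.p5, a.p3 + 1):
            key = (a.site_id, pos)
            per_site[key] = per_site.get(key, 0.0) + a.rpm
            meta[pos] = meta.get(pos, 0.0) + a.metaplot_rpm
    rows = [
        {"site_id": sid, "position": pos, "rpm": rpm}
        for (sid, pos), rpm in sorted(per_site.items())
    ]
    rows += [
        {"site_id": METAPLOT, "position": pos, "rpm": rpm}
        for pos, rpm in sorted(meta.items())
    ]
    return pd.DataFrame(rows, columns=["site_id", "position", "rpm"])


def length_profile(
    reads: Iterable[RawRead | MappedRead],
    min_len: int = 15,
    max_len: int = 50,
    library_size: int | None = None,
) -> pd.DataFrame:
    """Read-length histogram over ``min_len..max_len`` nt (counts and rpm)."""
    counts = np.zeros(max_len - min_len + 1, dtype=int)
    n = 0
    for r in reads:
        n += 1
        L = len(r)
        if min_len <= L <= max_len:
            counts[L - min_len] += 1
    denom = library_size if library_size else n
    rpm = counts * 1e6 / denom if denom else counts.astype(float)
    return pd.DataFrame(
        {"length": np.arange(min_len, max_len + 1), "count": counts, "rpm": rpm}
    )


def modal_length(profile: pd.DataFrame) -> int:
    if profile["count"].sum() == 0:
        raise ValueError("empty length profile")
    return int(profile.loc[profile["count"].idxmax(), "length"])


def length_by_start(
    assignments: Iterable[SiteAssignment],
) -> pd.DataFrame:
    """(5'-end position, read length) -> summed window-weighted rpm.

    Marginalizing over lengths recovers the 5'-end metaplot coverage.
    """
    cells: dict[tuple[int, int], float] = {}
    for a in assignments:
        if a.site_id == INTERSITE:
            continue
        key = (a.p5, a.length)
        cells[key] = cells.get(key, 0.0) + a.metaplot_rpm
    rows = [
        {"position": p, "length": L, "rpm": rpm}
        for (p, L), rpm in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["position", "length", "rpm"])
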