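"""Slicer-product classification and the core biological inferences.

Classifies site-assigned reads into the diagnostic fragment categories of
a PIWI slicing event:

* ``pre_piRNA``   — 5' end at the slicer cut (guide-relative −9): the
  downstream cleavage fragment, the would-be secondary piRNA precursor.
* ``by_product``  — 3' end at the cut (−10): the upstream fragment whose
  5' end is trimmed back to the PIWI footprint (17/19 nt here).
* ``mature_like`` — piRNA-sized (26–30 nt) reads with neither slicer end.
* ``phased_candidate`` — reads downstream of a cut whose 5' end abuts
  another read's 3' end head-to-tail, as Zucchini/MitoPLD phasing would
  produce.
* ``unclassified`` — everything else.

Category predicates are evaluated in a fixed priority order (pre_piRNA >
by_product > mature_like > phased_candidate): slicer-end evidence is the
primary signal, so a 17-nt read with 5' end at −26 (hence 3' end at −10)
is a by-product even though other predicates might fire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .guide_coords import INTERSITE, SiteAssignment, metaplot_series
from .reporter import BY_PRODUCT_P3, PRE_PIRNA_P5

CATEGORIES = ("pre_piRNA", "by_product", "mature_like", "phased_candidate", "unclassified")
MATURE_RANGE = (26, 30)


@dataclass(frozen=True)
class FragmentCall:
    read_id: str
    site_id: str
    category: str
    p5: int
    p3: int
    rpm: float
    metaplot_rpm: float
    first_nt: str
    length: int
    sequence: str


def phased_chain_positions(
    assignments: Sequence[SiteAssignment],
    repeat_unit: int = 45,
    window: int = 50,
) -> set[tuple[str, int]]:
    """Per-site 5'-end positions that continue a head-to-tail chain
    anchored at the slicer cut.

    A phased trail starts with a piRNA whose 5' end is the cut (−9); each
    follow-up starts one past the previous piece's 3' end.  Every link in
    the chain must itself be piRNA-sized (26–30 nt) — phasing produces
    mature piRNA pieces, and without the size requirement chance
    adjacency of background reads seeds spurious chains.  Positions that
    coincide with the slicer cut of the next tandem site are excluded —
    adjacency there is produced by slicing at the next site, not by
    phasing — as is everything beyond ``window`` nt of the cut.
    """
    slicer_positions = {PRE_PIRNA_P5, PRE_PIRNA_P5 + repeat_unit}
    lo, hi = PRE_PIRNA_P5 + 1, PRE_PIRNA_P5 + window
    by_site_p5: dict[str, dict[int, list[int]]] = {}
    for a in assignments:
        if a.site_id == INTERSITE:
            continue
        if not MATURE_RANGE[0] <= a.length <= MATURE_RANGE[1]:
            continue
        by_site_p5.setdefault(a.site_id, {}).setdefault(a.p5, []).append(a.p3)
    chain: set[tuple[str, int]] = set()
    for sid, p5_map in by_site_p5.items():
        frontier = set(p5_map.get(PRE_PIRNA_P5, ()))
        seen_p3: set[int] = set()
        while frontier:
            p3 = frontier.pop()
            if p3 in seen_p3:
                continue
            seen_p3.add(p3)
            nxt = p3 + 1
            if nxt in slicer_positions or not lo <= nxt <= hi:
                continue
            if nxt in p5_map:
                chain.add((sid, nxt))
                frontier.update(p5_map[nxt])
    return chain


def classify_fragments(
    assignments: Sequence[SiteAssignment], tol: int = 0
) -> list[FragmentCall]:
    """Assign one category per (read, site) pairing.

    ``tol`` widens the slicer-end windows (±tol nt) for noisy data; the
    default 0 reflects the nucleotide-exact ends slicer products carry.
    """
    site_assignments = [a for a in assignments if a.site_id != INTERSITE]
    chain = phased_chain_positions(site_assignments)
    calls = []
    for a in site_assignments:
        if abs(a.p5 - PRE_PIRNA_P5) <= tol:
            cat = "pre_piRNA"
        elif abs(a.p3 - BY_PRODUCT_P3) <= tol:
            cat = "by_product"
        elif MATURE_RANGE[0] <= a.length <= MATURE_RANGE[1]:
            cat = "mature_like"
        elif (a.site_id, a.p5) in chain:
            # head-to-tail: 5' end continues a chain anchored at the cut
            cat = "phased_candidate"
        else:
            cat = "unclassified"
        calls.append(
            FragmentCall(
                read_id=a.read_id,
                site_id=a.site_id,
                category=cat,
                p5=a.p5,
                p3=a.p3,
                rpm=a.rpm,
                metaplot_rpm=a.metaplot_rpm,
                first_nt=a.sequence[0] if a.sequence else "",
                length=a.length,
                sequence=a.sequence,
            )
        )
    return calls


def infer_cleavage_site(coverage: pd.DataFrame, guide_length: int = 30) -> int:
    """Guide nucleotide index after which cleavage occurred.

    A cut after guide nt k leaves downstream 5' ends at the target
    nucleotide pairing nt k, i.e. at guide-relative position −(k−1), so
    k = 1 − p* where p* is the modal 5'-end metaplot position.  The search
    is restricted to the paired window [−(L_g−1), 0]: only those positions
    correspond to a guide index.  Ties resolve to the smaller k with a
    warning.
    """
    s = metaplot_series(coverage)
    s = s[(s.index >= -(guide_length - 1)) & (s.index <= 0)]
    if s.empty or not (s > 0).any():
        raise ValueError("all-zero 5'-end coverage within the paired window")
    peak = s.max()
    modal = [int(p) for p, v in s.items() if v == peak]
    ks = sorted(1 - p for p in modal)
    if len(ks) > 1:
        warnings.warn(
            f"tied modal 5'-end positions {sorted(modal)}; "
            f"returning smallest guide index {ks[0]}"
        )
    return ks[0]


@dataclass(frozen=True)
class PhasingReport:
    verdict: str  # "phasing detected" | "phasing absent" | "insufficient data"
    head_to_tail_fraction: float
    mature_size_fraction: float
    distance_distribution: dict[int, float]  # next 5' end - cut 5' end, rpm
    threshold: float


def detect_phasing(
    calls: Sequence[FragmentCall],
    window: int = 50,
    threshold: float = 0.05,
    repeat_unit: int = 45,
) -> PhasingReport:
    """Test whether slicer cuts initiated phased piRNA production.

    Two signals are measured downstream of each site's cut (guide-relative
    window (−9, −9 + window]):

    * head-to-tail fraction: rpm of reads whose 5' end continues a
      head-to-tail chain anchored at the cut (see
      :func:`phased_chain_positions`; 5' ends coinciding with the next
      tandem site's slicer cut are excluded, as adjacency there is made
      by slicing, not phasing), over total downstream rpm;
    * mature-size fraction: among reads starting at the cut (p5 = −9),
      the rpm fraction of piRNA-sized (26–30 nt) reads — a phased trail
      converts the 45-nt pre-piRNA into piRNA-sized pieces.

    Verdict is "phasing absent" when both fractions fall below
    ``threshold``, "phasing detected" when either reaches it.
    """
    site_calls = [c for c in calls if c.site_id != INTERSITE]
    cuts_present = any(c.category in ("pre_piRNA", "by_product") for c in site_calls)
    if not site_calls or not cuts_present:
        return PhasingReport("insufficient data", 0.0, 0.0, {}, threshold)

    chain = phased_chain_positions(site_calls, repeat_unit=repeat_unit, window=window)

    downstream = [
        c for c in site_calls if PRE_PIRNA_P5 < c.p5 <= PRE_PIRNA_P5 + window
    ]
    total = sum(c.metaplot_rpm for c in downstream)
    h2t = 0.0
    dist: dict[int, float] = {}
    for c in downstream:
        d = c.p5 - PRE_PIRNA_P5
        dist[d] = dist.get(d, 0.0) + c.metaplot_rpm
        if (c.site_id, c.p5) in chain and MATURE_RANGE[0] <= c.length <= MATURE_RANGE[1]:
            h2t += c.metaplot_rpm
    h2t_frac = h2t / total if total > 0 else 0.0

    at_cut = [c for c in site_calls if c.p5 == PRE_PIRNA_P5]
    at_cut_total = sum(c.metaplot_rpm for c in at_cut)
    mature = sum(
        c.metaplot_rpm for c in at_cut if MATURE_RANGE[0] <= c.length <= MATURE_RANGE[1]
    )
    if at_cut_total == 0 and total == 0:
        return PhasingReport("insufficient data", 0.0, 0.0, {}, threshold)
    mature_frac = mature / at_cut_total if at_cut_total > 0 else 0.0

    verdict = (
        "phasing absent"
        if h2t_frac < threshold and mature_frac < threshold
        else "phasing detected"
    )
    return PhasingReport(verdict, h2t_frac, mature_frac, dist, threshold)


def first_nt_composition(calls: Iterable[FragmentCall]) -> pd.DataFrame:
    """rpm-weighted 5'-base frequencies per category (U reported as T)."""
    acc: dict[tuple[str, str], float] = {}
    totals: dict[str, float] = {}
    for c in calls:
        base = c.first_nt.upper().replace("U", "T")
        if base not in "ACGT":
            continue
        acc[(c.category, base)] = acc.get((c.category, base), 0.0) + c.metaplot_rpm
        totals[c.category] = totals.get(c.category, 0.0) + c.metaplot_rpm
    rows = []
    for cat in CATEGORIES:
        if cat not in totals:
            continue
        for base in "ACGT":
            rows.append(
                {
                    "category": cat,
                    "base": base,
                    "frequency": acc.get((cat, base), 0.0) / totals[cat],
                }
            )
    return pd.DataFrame(rows, columns=["category", "base", "frequency"])


def calls_table(calls: Sequence[FragmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "site_id": c.site_id,
                "category": c.category,
                "p5": c.p5,
                "p3": c.p3,
                "length": c.length,
                "first_nt": c.first_nt,
                "rpm": c.rpm,
                "sequence": c.sequence,
            }
            for c in calls
        ],
        columns=[
            "read_id", "site_id", "category", "p5", "p3",
            "length", "first_nt", "rpm", "sequence",
        ],
    )


def signature_summary(calls: Sequence[FragmentCall]) -> pd.DataFrame:
    """Per-site rpm by category, modal pre-piRNA length and by-product
    length spectrum."""
    df = calls_table(calls)
    if df.empty:
        return pd.DataFrame(
            columns=["site_id", "category", "rpm", "modal_length", "lengths"]
        )
    rows = []
    for (sid, cat), grp in df.groupby(["site_id", "category"]):
        by_len = grp.groupby("length")["rpm"].sum()
        rows.append(
            {
                "site_id": sid,
                "category": cat,
                "rpm": grp["rpm"].sum(),
                "modal_length": int(by_len.idxmax()),
                "lengths": ",".join(str(x) for x in sorted(by_len.index)),
            }
        )
    return pd.DataFrame(rows)


def site_read_listing(
    calls: Sequence[FragmentCall], rpm_min: float = 0.05
) -> pd.DataFrame:
    """Per-site unique-read listing (sequence, ends, summed rpm), filtered
    at the display threshold (>= rpm_min)."""
    df = calls_table(calls)
    if df.empty:
        return pd.DataFrame(columns=["site_id", "sequence", "p5", "p3", "category", "rpm"])
    agg = (
        df.groupby(["site_id", "sequence", "p5", "p3", "category"], as_index=False)["rpm"]
        .sum()
    )
    agg = agg[agg.rpm >= rpm_min].sort_values(
        ["site_id", "rpm"], ascending=[True, False]
    )
    return agg.reset_index(drop=True)[["site_id", "sequence", "p5", "p3", "category", "rpm"]]
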