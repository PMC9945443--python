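"""Reporter constructs carrying tandem piRNA target sites.

A reporter is a DNA construct with one or more binding sites for a guide
piRNA embedded in a 3'-UTR-like context.  Each site is the reverse
complement of the guide (a "perfect" site) or carries non-complementary
bases opposite guide nucleotides 10 and 11 (a "bulge" site, which places
the mismatches exactly at the slicer cleavage site).  Sites are separated
by fixed spacers, so consecutive slicer cuts are one repeat unit apart.

Coordinate conventions
----------------------
Construct coordinates are 0-based half-open.  Guide-relative positions
follow the small-RNA field's convention: position 0 is the target
nucleotide pairing the guide's 5'-most nucleotide (nt 1), and the target
nucleotide pairing guide nt k sits at -(k-1).  Because the guide anneals
antisense to the target, guide-relative positions increase 5'->3' along
the construct and a site of guide length L spans positions -(L-1)..0.
Slicer cleavage occurs between the nucleotides pairing guide nt 10 and
nt 11, i.e. between guide-relative positions -10 and -9; the downstream
(pre-piRNA) fragment starts at -9 and the upstream (by-product) fragment
ends at -10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

#: Guide nucleotide indices flanking the slicer cut (cleavage after nt 10).
CLEAVAGE_GUIDE_NT = 10
#: Guide-relative position of a pre-piRNA 5' end (pairs guide nt 10).
PRE_PIRNA_P5 = -(CLEAVAGE_GUIDE_NT - 1)
#: Guide-relative position of a by-product 3' end (pairs guide nt 11).
BY_PRODUCT_P3 = -CLEAVAGE_GUIDE_NT

# Default synthetic guide: 30 nt, 5' U (as DNA: T) reflecting the piRNA 1U
# bias, nt 10 = C and nt 11 = A so that perfect-site pre-piRNAs start with G
# and default bulge-site pre-piRNAs start with C.
DEFAULT_GUIDE_SEQ = "TGAGGATTCCAGTTCGAGTCATCGGTACGA"
# Fixed spacer (15 nt) giving a 45-nt repeat unit with a 30-nt site.
DEFAULT_SPACER = "ACTGCTAGTCAGGAT"
# Fixed UTR-like flanks.
DEFAULT_FLANK5 = "GCTTAGCATCGAATCCTGAGGTTACCAGTTGACGAATGCTTCCAGAGTTA"
DEFAULT_FLANK3 = (
    "CTTGAACGTTAGCCATGGATAGCCTTGAGTACCGATTAGGCATCGTTAGCAATGGCTTAC"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(COMPLEMENT)


def is_wobble(guide_base: str, target_base: str) -> bool:
    """G:U wobble between a guide base and the target base it faces."""
    g = guide_base.upper().replace("U", "T")
    t = target_base.upper().replace("U", "T")
    return (g, t) in {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class GuideRNA:
    """A guide piRNA, 5'->3'.  Guide nucleotides are indexed 1-based."""

    name: str = "piR-synthetic"
    sequence: str = DEFAULT_GUIDE_SEQ

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if len(seq) < 16:
            raise ValueError(f"guide too short ({len(seq)} nt; need >= 16)")
        if set(seq) - set("ACGT"):
            raise ValueError(f"guide alphabet outside ACGT/U: {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def nt(self, k: int) -> str:
        """Guide nucleotide at 1-based index ``k``."""
        if not 1 <= k <= len(self):
            raise IndexError(f"guide index {k} outside 1..{len(self)}")
        return self.sequence[k - 1]


@dataclass(frozen=True)
class SiteSpec:
    """Perfect or bulge target-site design.

    ``mismatch_bases`` maps a guide index to the target base substituted at
    the position pairing that guide nucleotide; the substituted base must
    not be Watson-Crick complementary to the guide nucleotide.
    """

    kind: str = "perfect"
    mismatch_bases: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "bulge"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "perfect" and self.mismatch_bases:
            raise ValueError("perfect site cannot carry mismatches")

    @property
    def mismatch_positions(self) -> frozenset[int]:
        return frozenset(self.mismatch_bases)

    @classmethod
    def perfect(cls) -> "SiteSpec":
        return cls(kind="perfect")

    @classmethod
    def bulge(cls, guide: GuideRNA) -> "SiteSpec":
        """Default bulge: non-complementary, non-wobble transversions at
        guide positions 10 and 11."""
        subs: dict[int, str] = {}
        for k in (10, 11):
            comp = complement_base(guide.nt(k))
            for cand in "CATG":
                if cand == comp or is_wobble(guide.nt(k), cand):
                    continue
                # prefer the transversion partner of the complementary base
                purines = set("AG")
                if (cand in purines) != (comp in purines):
                    subs[k] = cand
                    break
            else:  # pragma: no cover - always finds a transversion
                raise RuntimeError("no valid substitution")
        return cls(kind="bulge", mismatch_bases=subs)

    def validate_against(self, guide: GuideRNA) -> None:
        if self.kind == "bulge" and self.mismatch_positions != {10, 11}:
            raise ValueError(
                f"bulge site must mismatch guide nt 10 and 11, got "
                f"{sorted(self.mismatch_positions)}"
            )
        for k, base in self.mismatch_bases.items():
            if base.upper() == complement_base(guide.nt(k)):
                raise ValueError(
                    f"substitution {base} at guide nt {k} is the complementary "
                    "base and would not be a mismatch"
                )


@dataclass(frozen=True)
class ReporterLayout:
    """Geometry of the tandem-site insert."""

    n_sites: int = 10
    spacer: str = DEFAULT_SPACER
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site")

    def repeat_unit(self, site_length: int) -> int:
        return site_length + len(self.spacer)


@dataclass(frozen=True)
class GuideSite:
    """One target site on the construct.

    ``anchor`` is the construct coordinate of the target nucleotide pairing
    guide nt 1 (= ``end - 1``).  Guide-relative position of construct
    coordinate c is ``c - anchor``; guide nt k pairs coordinate
    ``anchor - (k - 1)``.
    """

    site_id: str
    start: int
    end: int
    kind: str

    @property
    def anchor(self) -> int:
        return self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_guide_position(self, coord: int) -> int:
        return coord - self.anchor

    def to_construct_coord(self, position: int) -> int:
        return position + self.anchor

    @property
    def cleavage_coordinate(self) -> int:
        """Construct coordinate of the pre-piRNA 5' end (slicer cut is
        immediately 5' of this nucleotide)."""
        return self.to_construct_coord(PRE_PIRNA_P5)


@dataclass(frozen=True)
class Reporter:
    """A construct sequence with its ordered target sites."""

    construct_id: str
    sequence: str
    sites: tuple[GuideSite, ...]
    guide: GuideRNA

    def __len__(self) -> int:
        return len(self.sequence)

    def site_sequence(self, site: GuideSite) -> str:
        return self.sequence[site.start : site.end]

    def sites_table(self) -> pd.DataFrame:
        """Site annotation (0-based half-open construct coordinates)."""
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "start": s.start,
                    "end": s.end,
                    "kind": s.kind,
                    "cleavage_coordinate": s.cleavage_coordinate,
                }
                for s in self.sites
            ]
        )


def build_site_sequence(guide: GuideRNA, spec: SiteSpec) -> str:
    """Target-site sequence, 5'->3' on the construct.

    The site is the reverse complement of the guide; for a bulge site the
    target base pairing guide nt k (at site offset L-k from the site start)
    is replaced by the configured non-complementary base.
    """
    spec.validate_against(guide)
    site = list(revcomp(guide.sequence))
    L = len(guide)
    for k, base in spec.mismatch_bases.items():
        site[L - k] = base.upper()
    return "".join(site)


def build_reporter(
    guide: GuideRNA,
    spec: SiteSpec,
    layout: ReporterLayout,
    construct_id: str | None = None,
) -> Reporter:
    """Assemble flank5 + n x (site + spacer) + flank3 and record site frames."""
    site_seq = build_site_sequence(guide, spec)
    parts = [layout.flank5]
    sites = []
    pos = len(layout.flank5)
    for i in range(layout.n_sites):
        sites.append(
            GuideSite(
                site_id=f"site{i + 1}",
                start=pos,
                end=pos + len(site_seq),
                kind=spec.kind,
            )
        )
        parts.append(site_seq)
        pos += len(site_seq)
        if i < layout.n_sites - 1:
            parts.append(layout.spacer)
            pos += len(layout.spacer)
    parts.append(layout.flank3)
    if construct_id is None:
        construct_id = f"{layout.n_sites}x{'Perf' if spec.kind == 'perfect' else 'Bulge'}"
    return Reporter(
        construct_id=construct_id,
        sequence="".join(parts),
        sites=tuple(sites),
        guide=guide,
    )


# ---------------------------------------------------------------------------
# I/O


def write_reporter_fasta(reporter: Reporter, path: str | Path) -> None:
    rec = SeqRecord(Seq(reporter.sequence), id=reporter.construct_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_sites_tsv(reporter: Reporter, path: str | Path) -> None:
    reporter.sites_table().to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[GuideSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        GuideSite(
            site_id=str(r.site_id), start=int(r.start), end=int(r.end), kind=str(r.kind)
        )
        for r in df.itertuples()
    ]


def load_reporter(
    fasta: str | Path, sites_tsv: str | Path, guide: GuideRNA
) -> Reporter:
    rec = next(SeqIO.parse(str(fasta), "fasta"))
    return Reporter(
        construct_id=rec.id,
        sequence=str(rec.seq).upper(),
        sites=tuple(read_sites_tsv(sites_tsv)),
        guide=guide,
    )
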