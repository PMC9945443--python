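"""Simulation of PIWI-immunoprecipitation small-RNA libraries.

The simulator emits the read classes a PIWI-IP library of a sliced
tandem-site reporter contains:

``mature``
    piRNA-sized reads (length mode ~26 nt for MILI-like or ~30 nt for
    MIWI-like libraries) drawn from a synthetic piRNA pool with a 1U bias;
    the guide itself is one pool species.  These reads represent the bulk
    of the library and generally do not map to the reporter.
``pre``
    pre-piRNA fragments: the downstream slicer-cleavage fragment, running
    from one site's cut (5' end at the target nucleotide pairing guide
    nt 10) to one nucleotide before the next site's cut.  For the last
    (or only) site the 3' extent is a configurable downstream length.
``byproduct``
    the upstream cleavage fragment, 3' end at the cut (pairing guide
    nt 11) and 5' end 17 or 19 nt upstream, reflecting the footprint of
    the bound PIWI protein.
``phased``
    head-to-tail chains of piRNA-sized fragments downstream of a cut, the
    signature of Zucchini/MitoPLD-driven phased biogenesis.  Off by
    default: the observation the pipeline is built to detect is that this
    class is *absent* from the real libraries.
``background``
    reads from random construct positions.

All randomness flows through a single seeded generator; a fixed seed
yields byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .reporter import BY_PRODUCT_P3, GuideRNA, Reporter

CLASSES = ("mature", "pre", "byproduct", "phased", "background")


@dataclass(frozen=True)
class SimRead:
    """A simulated read with its ground-truth label."""

    read_id: str
    sequence: str
    label: str  # one of CLASSES
    source_site: str | None = None


@dataclass(frozen=True)
class SimConfig:
    n_reads: int = 10_000
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "mature": 0.80,
            "pre": 0.08,
            "byproduct": 0.05,
            "phased": 0.0,
            "background": 0.07,
        }
    )
    #: Modal mature-piRNA length: 26 (MILI-like) or 30 (MIWI-like).
    mature_mode: int = 26
    #: Discretized symmetric spread (s.d. in nt) of the mature length peak.
    mature_spread: float = 1.5
    #: 5'-end offset distribution of by-product fragments (guide-relative).
    byproduct_offsets: dict[int, float] = field(
        default_factory=lambda: {-26: 0.5, -28: 0.5}
    )
    #: Fraction of sites that are sliced (fragments only arise from these).
    slicing_fraction: float = 1.0
    #: 3' extent (nt) of the pre-piRNA from the last site's cut.
    last_site_extent: int = 45
    #: Lengths of phased follow-up pieces (sampled uniformly).
    phased_lengths: tuple[int, ...] = (26, 27, 28, 29, 30)
    n_pool_species: int = 200
    pool_species_length: int = 45
    u1_fraction: float = 0.9
    background_length_range: tuple[int, int] = (15, 35)
    seed: int = 0
    #: 3' sequencing adapter appended to every read (None: no adapter).
    adapter: str | None = None
    quality_char: str = "I"

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if abs(sum(self.byproduct_offsets.values()) - 1.0) > 1e-9:
            raise ValueError("byproduct offset probabilities must sum to 1")

    def only(self, cls: str, **kwargs) -> "SimConfig":
        """Copy of this config emitting a single read class."""
        props = {c: (1.0 if c == cls else 0.0) for c in CLASSES}
        return replace(self, proportions=props, **kwargs)


def class_counts(cfg: SimConfig) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n_reads to classes."""
    exact = {c: cfg.n_reads * cfg.proportions.get(c, 0.0) for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = cfg.n_reads - sum(counts.values())
    by_rem = sorted(CLASSES, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def pre_pirna_interval(
    reporter: Reporter, site_index: int, last_site_extent: int
) -> tuple[int, int]:
    """Construct interval [start, end) of the pre-piRNA from site ``i``'s cut.

    Runs to one nucleotide before the next site's cut; the last site's
    fragment extends ``last_site_extent`` nt downstream instead.
    """
    sites = reporter.sites
    start = sites[site_index].cleavage_coordinate
    if site_index + 1 < len(sites):
        end = sites[site_index + 1].cleavage_coordinate
    else:
        end = start + last_site_extent
    if end > len(reporter) or start < 0:
        raise ValueError(
            f"site {sites[site_index].site_id} too close to the construct end "
            "to draw a pre-piRNA fragment"
        )
    return start, end


def byproduct_interval(
    reporter: Reporter, site_index: int, p5_offset: int
) -> tuple[int, int]:
    """Construct interval of a by-product: 3' end at the nucleotide pairing
    guide nt 11, 5' end at guide-relative ``p5_offset`` (−26 or −28)."""
    site = reporter.sites[site_index]
    end = site.to_construct_coord(BY_PRODUCT_P3) + 1
    start = site.to_construct_coord(p5_offset)
    if start < 0:
        raise ValueError(f"{site.site_id}: by-product would run off the 5' end")
    return start, end


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _make_pool(cfg: SimConfig, guide: GuideRNA, rng: np.random.Generator) -> list[str]:
    pool = []
    for _ in range(cfg.n_pool_species):
        seq = _random_seq(rng, cfg.pool_species_length)
        if rng.random() < cfg.u1_fraction:
            seq = "T" + seq[1:]
        pool.append(seq)
    if pool:
        # the targeting guide is itself an abundant library species
        pool[0] = guide.sequence + _random_seq(
            rng, max(0, cfg.pool_species_length - len(guide))
        )
    return pool


def _sliced_sites(cfg: SimConfig, reporter: Reporter, rng: np.random.Generator) -> list[int]:
    n = len(reporter.sites)
    k = max(1, int(round(cfg.slicing_fraction * n)))
    return sorted(rng.choice(n, size=min(k, n), replace=False).tolist())


def simulate_reads(reporter: Reporter, guide: GuideRNA, cfg: SimConfig) -> list[SimRead]:
    """Simulate labelled reads (adapter not yet appended)."""
    if not reporter.sites:
        raise ValueError("reporter has no sites")
    rng = np.random.default_rng(cfg.seed)
    counts = class_counts(cfg)
    pool = _make_pool(cfg, guide, rng)
    sliced = _sliced_sites(cfg, reporter, rng)
    reads: list[SimRead] = []
    serial = 0

    def emit(seq: str, label: str, site: str | None = None) -> None:
        nonlocal serial
        serial += 1
        reads.append(SimRead(f"sim{serial:07d}_{label}", seq, label, site))

    for _ in range(counts["mature"]):
        species = pool[rng.integers(0, len(pool))]
        length = int(np.clip(round(rng.normal(cfg.mature_mode, cfg.mature_spread)),
                             16, len(species)))
        emit(species[:length], "mature")

    for _ in range(counts["pre"]):
        i = sliced[rng.integers(0, len(sliced))]
        s, e = pre_pirna_interval(reporter, i, cfg.last_site_extent)
        emit(reporter.sequence[s:e], "pre", reporter.sites[i].site_id)

    offsets = sorted(cfg.byproduct_offsets)
    probs = np.array([cfg.byproduct_offsets[o] for o in offsets])
    for _ in range(counts["byproduct"]):
        i = sliced[rng.integers(0, len(sliced))]
        off = offsets[rng.choice(len(offsets), p=probs)]
        s, e = byproduct_interval(reporter, i, off)
        emit(reporter.sequence[s:e], "byproduct", reporter.sites[i].site_id)

    n_phased = counts["phased"]
    while n_phased > 0:
        i = sliced[rng.integers(0, len(sliced))]
        site = reporter.sites[i]
        pos = site.cleavage_coordinate
        # head-to-tail chain of piRNA-sized pieces starting at the cut
        for _ in range(3):
            if n_phased == 0:
                break
            length = int(cfg.phased_lengths[rng.integers(0, len(cfg.phased_lengths))])
            if pos + length > len(reporter):
                break
            emit(reporter.sequence[pos : pos + length], "phased", site.site_id)
            n_phased -= 1
            pos += length

    lo, hi = cfg.background_length_range
    for _ in range(counts["background"]):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(1, len(reporter) - length)))
        emit(reporter.sequence[start : start + length], "background")

    return reads


def reads_to_fastq(reads: list[SimRead], cfg: SimConfig) -> str:
    """Render reads as 4-line FASTQ (Phred+33), appending the 3' adapter."""
    adapter = cfg.adapter or ""
    out = []
    for r in reads:
        seq = r.sequence + adapter
        out.append(f"@{r.read_id}\n{seq}\n+\n{cfg.quality_char * len(seq)}\n")
    return "".join(out)


def simulate_library(
    reporter: Reporter,
    guide: GuideRNA,
    cfg: SimConfig,
    fastq_path: str | Path | None = None,
) -> list[SimRead]:
    """Simulate a library; optionally write FASTQ.  Deterministic under seed."""
    reads = simulate_reads(reporter, guide, cfg)
    if fastq_path is not None:
        Path(fastq_path).write_text(reads_to_fastq(reads, cfg))
    return reads
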