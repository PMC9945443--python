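"""End-to-end pipeline: simulate -> prep -> map -> coverage -> signatures -> scan.

The run configuration is a validated, YAML-round-trippable model; unknown
keys are rejected.  Every stage writes its outputs to the run directory so
any stage can be re-run from the intermediate files via the CLI, and the
run finishes with a machine-readable JSON summary.  The same configuration
and seed yield byte-identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import complementarity as cmp_mod
from . import guide_coords, mapping, read_prep, signatures, simulate
from .reporter import (
    GuideRNA,
    Reporter,
    ReporterLayout,
    SiteSpec,
    build_reporter,
    write_reporter_fasta,
    write_sites_tsv,
)

log = logging.getLogger("slicesig")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Block):
    simulate: bool = True
    prep: bool = True
    map: bool = True
    coverage: bool = True
    signatures: bool = True
    scan: bool = True


class GuideConfig(_Block):
    name: str = "piR-synthetic"
    sequence: str | None = None  # None: package default guide

    def build(self) -> GuideRNA:
        if self.sequence is None:
            return GuideRNA(name=self.name)
        return GuideRNA(name=self.name, sequence=self.sequence)


class ReporterConfig(_Block):
    kind: str = "perfect"  # perfect | bulge
    n_sites: int = 10
    spacer: str | None = None
    flank5: str | None = None
    flank3: str | None = None

    def build(self, guide: GuideRNA) -> Reporter:
        spec = (
            SiteSpec.perfect() if self.kind == "perfect" else SiteSpec.bulge(guide)
        )
        kwargs = {}
        for f in ("spacer", "flank5", "flank3"):
            v = getattr(self, f)
            if v is not None:
                kwargs[f] = v
        layout = ReporterLayout(n_sites=self.n_sites, **kwargs)
        return build_reporter(guide, spec, layout)


class SimulateConfig(_Block):
    n_reads: int = 10_000
    proportions: dict[str, float] = Field(
        default_factory=lambda: {
            "mature": 0.80, "pre": 0.08, "byproduct": 0.05,
            "phased": 0.0, "background": 0.07,
        }
    )
    mature_mode: int = 26
    mature_spread: float = 1.5
    byproduct_offsets: dict[int, float] = Field(
        default_factory=lambda: {-26: 0.5, -28: 0.5}
    )
    slicing_fraction: float = 1.0
    last_site_extent: int = 45
    adapter: str | None = "AGATCGGAAGAGCACACGTCT"

    def build(self, seed: int) -> simulate.SimConfig:
        return simulate.SimConfig(
            n_reads=self.n_reads,
            proportions=dict(self.proportions),
            mature_mode=self.mature_mode,
            mature_spread=self.mature_spread,
            byproduct_offsets={int(k): v for k, v in self.byproduct_offsets.items()},
            slicing_fraction=self.slicing_fraction,
            last_site_extent=self.last_site_extent,
            adapter=self.adapter,
            seed=seed,
        )


class PrepConfig(_Block):
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    min_length: int = 15
    max_error_rate: float = 0.2
    min_overlap: int = 4
    quality_cutoff: int = 10

    def build(self) -> read_prep.TrimParams:
        return read_prep.TrimParams(
            adapter=self.adapter,
            min_length=self.min_length,
            max_error_rate=self.max_error_rate,
            min_overlap=self.min_overlap,
            quality_cutoff=self.quality_cutoff,
        )


class MapConfig(_Block):
    both_strands: bool = False


class CoverageConfig(_Block):
    window_lo: int = -45
    window_hi: int = 50


class SignaturesConfig(_Block):
    tol: int = 0
    phasing_window: int = 50
    phasing_threshold: float = 0.05
    rpm_min: float = 0.05


class ScanConfig(_Block):
    pool_path: str | None = None  # TSV/FASTA; None: synthetic pool
    n_pool: int = 1000
    pool_length: int = 30
    max_mm: int = 3
    shift: int = 0
    allow_wobble: bool = False


class RunConfig(_Block):
    seed: int = 0
    stages: StageToggles = Field(default_factory=StageToggles)
    guide: GuideConfig = Field(default_factory=GuideConfig)
    reporter: ReporterConfig = Field(default_factory=ReporterConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    prep: PrepConfig = Field(default_factory=PrepConfig)
    map: MapConfig = Field(default_factory=MapConfig)
    coverage: CoverageConfig = Field(default_factory=CoverageConfig)
    signatures: SignaturesConfig = Field(default_factory=SignaturesConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def synthetic_pool(
    guide: GuideRNA, n: int, length: int, seed: int
) -> list[cmp_mod.PoolEntry]:
    """The guide plus n−1 random piRNA species with a 1U bias and
    abundances spanning a realistic dynamic range."""
    rng = np.random.default_rng(seed)
    entries = [cmp_mod.PoolEntry(guide.name, guide.sequence, 100.0)]
    bases = np.array(list("ACGT"))
    for i in range(n - 1):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if rng.random() < 0.9:
            seq = "T" + seq[1:]
        abundance = float(np.round(rng.lognormal(0.0, 1.5), 4))
        entries.append(cmp_mod.PoolEntry(f"pool{i + 1:04d}", seq, abundance))
    return entries


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order; write outputs and a JSON
    summary; return the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages_run": []}
    guide = config.guide.build()
    reporter = config.reporter.build(guide)
    stages = config.stages

    def _stage(name):
        log.info("[%s] running", name)
        report["stages_run"].append(name)

    raw_fastq = out / "reads.raw.fastq"
    trimmed_fastq = out / "reads.trimmed.fastq"

    if stages.simulate:
        _stage("simulate")
        cfg = config.simulate.build(config.seed)
        reads = simulate.simulate_library(reporter, guide, cfg, raw_fastq)
        write_reporter_fasta(reporter, out / "construct.fa")
        write_sites_tsv(reporter, out / "sites.tsv")
        report["simulate"] = {
            "construct_id": reporter.construct_id,
            "construct_length": len(reporter),
            "n_sites": len(reporter.sites),
            "n_reads": len(reads),
        }

    prepped: list[read_prep.RawRead] = []
    if stages.prep:
        _stage("prep")
        if not raw_fastq.exists():
            raise FileNotFoundError(f"prep stage needs {raw_fastq}")
        prep_report = read_prep.prep_fastq(
            raw_fastq, trimmed_fastq, config.prep.build(), out / "prep_report.tsv"
        )
        prepped = list(read_prep.read_fastq(trimmed_fastq))
        report["prep"] = {
            k: (float(v) if k == "mean_trimmed_length" else int(v))
            for k, v in prep_report.iloc[0].items()
        }

    mapped: list[mapping.MappedRead] = []
    if stages.map:
        _stage("map")
        if not prepped:
            if not trimmed_fastq.exists():
                raise FileNotFoundError(f"map stage needs {trimmed_fastq}")
            prepped = list(read_prep.read_fastq(trimmed_fastq))
        constructs = {reporter.construct_id: reporter.sequence}
        mapped, unmapped = mapping.map_exact(
            prepped, constructs, config.map.both_strands
        )
        mapping.normalize_rpm(mapped, library_size=len(prepped))
        mapping.write_hits_tsv(mapped, out / "hits.tsv")
        report["map"] = {
            "library_size": len(prepped),
            "mapped_reads": len(mapped),
            "unmapped_reads": len(unmapped),
        }

    assignments: list[guide_coords.SiteAssignment] = []
    if stages.coverage:
        _stage("coverage")
        window = (config.coverage.window_lo, config.coverage.window_hi)
        assignments = guide_coords.assign_to_sites(mapped, reporter.sites, window)
        cov5 = guide_coords.end_coverage(assignments, "5p")
        cov3 = guide_coords.end_coverage(assignments, "3p")
        cov5.to_csv(out / "coverage_5p.tsv", sep="\t", index=False)
        cov3.to_csv(out / "coverage_3p.tsv", sep="\t", index=False)
        guide_coords.body_coverage(assignments).to_csv(
            out / "coverage_body.tsv", sep="\t", index=False
        )
        profile = guide_coords.length_profile(prepped)
        profile.to_csv(out / "length_profile.tsv", sep="\t", index=False)
        lbs = guide_coords.length_by_start(assignments)
        lbs.to_csv(out / "length_by_start.tsv", sep="\t", index=False)
        cov_report: dict = {"n_assignments": len(assignments)}
        try:
            cov_report["modal_5p_position"] = guide_coords.modal_position(cov5)
        except ValueError:
            cov_report["modal_5p_position"] = None
        try:
            cov_report["modal_length"] = guide_coords.modal_length(profile)
        except ValueError:
            cov_report["modal_length"] = None
        report["coverage"] = cov_report
        report["_cov5"] = cov5  # internal hand-off, dropped before writing

    if stages.signatures:
        _stage("signatures")
        if not assignments:
            window = (config.coverage.window_lo, config.coverage.window_hi)
            assignments = guide_coords.assign_to_sites(mapped, reporter.sites, window)
        calls = signatures.classify_fragments(assignments, tol=config.signatures.tol)
        signatures.calls_table(calls).to_csv(
            out / "fragment_calls.tsv", sep="\t", index=False
        )
        signatures.signature_summary(calls).to_csv(
            out / "signature_summary.tsv", sep="\t", index=False
        )
        signatures.first_nt_composition(calls).to_csv(
            out / "first_nt.tsv", sep="\t", index=False
        )
        signatures.site_read_listing(calls, config.signatures.rpm_min).to_csv(
            out / "site_reads.tsv", sep="\t", index=False
        )
        cat_rpm = {c: 0.0 for c in signatures.CATEGORIES}
        for c in calls:
            cat_rpm[c.category] += c.metaplot_rpm
        sig_report: dict = {"category_rpm": {k: round(v, 4) for k, v in cat_rpm.items()}}
        cov5 = report.pop("_cov5", None)
        if cov5 is None:
            cov5 = guide_coords.end_coverage(assignments, "5p")
        try:
            sig_report["inferred_cleavage_after_nt"] = signatures.infer_cleavage_site(
                cov5, guide_length=len(guide)
            )
        except ValueError:
            sig_report["inferred_cleavage_after_nt"] = None
        phasing = signatures.detect_phasing(
            calls,
            window=config.signatures.phasing_window,
            threshold=config.signatures.phasing_threshold,
        )
        sig_report["phasing"] = {
            "verdict": phasing.verdict,
            "head_to_tail_fraction": round(phasing.head_to_tail_fraction, 6),
            "mature_size_fraction": round(phasing.mature_size_fraction, 6),
        }
        pre_calls = [c for c in calls if c.category == "pre_piRNA"]
        if pre_calls:
            lengths: dict[int, float] = {}
            for c in pre_calls:
                lengths[c.length] = lengths.get(c.length, 0.0) + c.metaplot_rpm
            sig_report["modal_pre_piRNA_length"] = max(lengths, key=lengths.get)
            first: dict[str, float] = {}
            for c in pre_calls:
                first[c.first_nt] = first.get(c.first_nt, 0.0) + c.metaplot_rpm
            sig_report["pre_piRNA_first_nt"] = max(first, key=first.get)
        report["signatures"] = sig_report
    report.pop("_cov5", None)

    if stages.scan:
        _stage("scan")
        if config.scan.pool_path:
            p = Path(config.scan.pool_path)
            pool = (
                cmp_mod.read_pool_fasta(p)
                if p.suffix in (".fa", ".fasta")
                else cmp_mod.read_pool_tsv(p)
            )
        else:
            pool = synthetic_pool(
                guide, config.scan.n_pool, config.scan.pool_length, config.seed
            )
        profiles = cmp_mod.scan_reporter_site(
            pool,
            reporter,
            max_mm=config.scan.max_mm,
            shift=config.scan.shift,
            allow_wobble=config.scan.allow_wobble,
        )
        cmp_mod.mismatch_heatmap_table(profiles).to_csv(
            out / "scan.tsv", sep="\t", index=False
        )
        report["scan"] = {
            "pool_size": len(pool),
            "profiles_reported": len(profiles),
            "perfect_complements": sum(p.n_mismatches == 0 for p in profiles),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def demo_config(name: str) -> RunConfig:
    """Shipped demo configurations: 'perfect-10x' and 'bulge-10x'."""
    path = Path(__file__).parent / "configs" / f"{name.replace('-', '_')}.yaml"
    if not path.exists():
        raise ValueError(f"unknown demo config {name!r}")
    return RunConfig.from_yaml(path)


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity < 0 else (
        logging.INFO if verbosity == 0 else logging.DEBUG
    )
    logging.basicConfig(
        stream=sys.stderr, level=level, format="%(name)s %(levelname)s: %(message)s"
    )
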