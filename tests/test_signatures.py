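"""Fragment classification, cleavage-site inference, phasing, 5'-nt bias."""

import pytest

from conftest import as_raw_reads
from slicesig.guide_coords import SiteAssignment, assign_to_sites, end_coverage
from slicesig.mapping import map_exact, normalize_rpm
from slicesig.signatures import (
    classify_fragments,
    detect_phasing,
    first_nt_composition,
    infer_cleavage_site,
    signature_summary,
    site_read_listing,
)
from slicesig.simulate import SimConfig, simulate_reads


def _assignments(reporter, guide, cfg, window=(-45, 50)):
    sim = simulate_reads(reporter, guide, cfg)
    raw = as_raw_reads(sim)
    mapped, _ = map_exact(raw, {reporter.construct_id: reporter.sequence})
    normalize_rpm(mapped, library_size=len(raw))
    return sim, assign_to_sites(mapped, reporter.sites, window)


def _a(read_id, site, p5, p3, rpm=1.0, seq=None):
    length = p3 - p5 + 1
    return SiteAssignment(read_id, site, p5, p3, length, rpm, 1, seq or "G" * length)


def test_classification_examples():
    calls = classify_fragments(
        [
            _a("pre", "site1", -9, 35),           # 45 nt from the cut
            _a("bp", "site1", -26, -10),          # 17 nt ending at the cut
            _a("mat", "site1", 0, 27),            # 28 nt, no slicer end
            _a("odd", "site1", 5, 25),            # 21 nt, nothing diagnostic
        ]
    )
    by_id = {c.read_id: c.category for c in calls}
    assert by_id == {
        "pre": "pre_piRNA",
        "bp": "by_product",
        "mat": "mature_like",
        "odd": "unclassified",
    }
    bp = next(c for c in calls if c.read_id == "bp")
    assert bp.length == 17


def test_classification_is_a_partition_and_conserves_rpm(perfect10, guide):
    cfg = SimConfig(n_reads=800, seed=41)
    _, assignments = _assignments(perfect10, guide, cfg)
    calls = classify_fragments(assignments)
    site_assignments = [a for a in assignments if a.site_id != "intersite"]
    assert len(calls) == len(site_assignments)
    assert sum(c.rpm for c in calls) == pytest.approx(
        sum(a.rpm for a in site_assignments)
    )


def test_labeled_slicer_products_recovered_exactly(perfect10, guide):
    """At tol=0 every simulated pre-piRNA and by-product read is classified
    into its ground-truth category at its source site."""
    cfg = SimConfig(
        n_reads=600,
        seed=43,
        proportions={
            "mature": 0.0, "pre": 0.6, "byproduct": 0.4,
            "phased": 0.0, "background": 0.0,
        },
    )
    sim, assignments = _assignments(perfect10, guide, cfg)
    truth = {r.read_id: (r.label, r.source_site) for r in sim}
    calls = classify_fragments(assignments, tol=0)
    expected = {"pre": "pre_piRNA", "byproduct": "by_product"}
    # every call whose frame shows the diagnostic end is labelled correctly
    for c in calls:
        label, _ = truth[c.read_id]
        if c.p5 == -9:
            assert c.category == "pre_piRNA" and label == "pre"
        elif c.p3 == -10:
            assert c.category == "by_product" and label == "byproduct"
    # and every simulated read is recovered at its source site
    called = {(c.read_id, c.site_id, c.category) for c in calls}
    for r in sim:
        assert (r.read_id, r.source_site, expected[r.label]) in called


def test_infer_cleavage_site_perfect_and_bulge(perfect10, bulge10, guide):
    for rep in (perfect10, bulge10):
        cfg = SimConfig(n_reads=500, seed=47)
        _, assignments = _assignments(rep, guide, cfg)
        cov = end_coverage(assignments, "5p")
        assert infer_cleavage_site(cov) == 10


def test_infer_cleavage_site_definitional_cases():
    cov = end_coverage([_a("r", "site1", -9, 35)], "5p")
    assert infer_cleavage_site(cov) == 10
    cov0 = end_coverage([_a("r", "site1", 0, 27)], "5p")
    assert infer_cleavage_site(cov0) == 1
    with pytest.raises(ValueError):
        infer_cleavage_site(end_coverage([], "5p"))


def test_infer_cleavage_site_invariant_to_rpm_scaling():
    base = [_a("r1", "site1", -9, 35, rpm=1.0), _a("r2", "site1", -5, 30, rpm=0.5)]
    scaled = [_a(a.read_id, a.site_id, a.p5, a.p3, rpm=a.rpm * 1e4) for a in base]
    assert infer_cleavage_site(end_coverage(base, "5p")) == infer_cleavage_site(
        end_coverage(scaled, "5p")
    )


def test_phasing_absent_for_pre_only_library(perfect10, guide, pre_only_cfg):
    _, assignments = _assignments(perfect10, guide, pre_only_cfg)
    report = detect_phasing(classify_fragments(assignments))
    assert report.verdict == "phasing absent"
    assert report.head_to_tail_fraction == 0.0
    assert report.mature_size_fraction == 0.0


def test_phasing_detected_when_planted(perfect10, guide):
    cfg = SimConfig(
        n_reads=800,
        seed=53,
        proportions={
            "mature": 0.3, "pre": 0.1, "byproduct": 0.1,
            "phased": 0.4, "background": 0.1,
        },
    )
    _, assignments = _assignments(perfect10, guide, cfg)
    report = detect_phasing(classify_fragments(assignments))
    assert report.verdict == "phasing detected"
    assert report.mature_size_fraction > 0.05
    # the planted head-to-tail trail is visible in the distance spectrum
    assert report.head_to_tail_fraction > 0.05


def test_phasing_insufficient_data_without_cuts():
    report = detect_phasing(classify_fragments([_a("m", "site1", 0, 27)]))
    assert report.verdict == "insufficient data"
    assert detect_phasing([]).verdict == "insufficient data"


def test_first_nt_composition_perfect_G_bulge_C(perfect10, bulge10, guide):
    cfg = SimConfig(n_reads=400, seed=59)
    for rep, base in ((perfect10, "G"), (bulge10, "C")):
        _, assignments = _assignments(rep, guide, cfg)
        comp = first_nt_composition(classify_fragments(assignments))
        pre = comp[(comp.category == "pre_piRNA")].set_index("base")["frequency"]
        assert pre[base] == pytest.approx(1.0)


def test_first_nt_u1_bias_recovered(perfect10, guide):
    # mature pool planted with 90% U1: recover the simulator parameter from
    # the trimmed reads themselves (mature reads rarely map to the reporter)
    cfg = SimConfig(n_reads=5000, seed=61, u1_fraction=0.9).only("mature")
    reads = simulate_reads(perfect10, guide, cfg)
    u1 = sum(r.sequence.startswith("T") for r in reads) / len(reads)
    assert u1 == pytest.approx(0.9, abs=0.05)


def test_summary_and_listing_tables(perfect10, guide):
    cfg = SimConfig(n_reads=600, seed=67)
    _, assignments = _assignments(perfect10, guide, cfg)
    calls = classify_fragments(assignments)
    summary = signature_summary(calls)
    assert {"pre_piRNA", "by_product"} <= set(summary.category)
    pre = summary[summary.category == "pre_piRNA"]
    assert (pre.modal_length == 45).all()
    listing = site_read_listing(calls, rpm_min=0.05)
    assert (listing.rpm >= 0.05).all()
    assert not listing.empty
    # category rpm sums match the calls
    assert summary.rpm.sum() == pytest.approx(sum(c.rpm for c in calls))
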