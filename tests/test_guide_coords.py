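"""Guide-frame transforms, end coverages, metaplots, length profiles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import as_raw_reads
from slicesig.guide_coords import (
    INTERSITE,
    METAPLOT,
    SiteAssignment,
    assign_to_sites,
    body_coverage,
    end_coverage,
    length_by_start,
    length_profile,
    metaplot_series,
    modal_length,
    modal_position,
    to_guide_frame,
)
from slicesig.mapping import AlignmentHit, MappedRead, map_exact, normalize_rpm
from slicesig.reporter import GuideSite
from slicesig.simulate import SimConfig, simulate_reads


def _mapped_library(reporter, guide, cfg):
    raw = as_raw_reads(simulate_reads(reporter, guide, cfg))
    mapped, _ = map_exact(raw, {reporter.construct_id: reporter.sequence})
    normalize_rpm(mapped, library_size=len(raw))
    return mapped


def test_guide_frame_positions(perfect10):
    site = perfect10.sites[0]
    # hit starting at the nucleotide pairing guide nt 10 -> p5 = -9
    h = AlignmentHit("r", "c", site.cleavage_coordinate, site.cleavage_coordinate + 45)
    p5, p3 = to_guide_frame(h, site)
    assert p5 == -9 and p3 == 35
    # hit starting at the anchor -> p5 = 0
    h0 = AlignmentHit("r", "c", site.anchor, site.anchor + 20)
    assert to_guide_frame(h0, site)[0] == 0
    # 17-nt hit with p3 = -10 has p5 = -26 (independent interval arithmetic)
    h17 = AlignmentHit("r", "c", site.anchor - 26, site.anchor - 26 + 17)
    p5, p3 = to_guide_frame(h17, site)
    assert (p5, p3) == (-26, -10)
    assert p5 == p3 - 17 + 1


@given(
    anchor=st.integers(50, 500),
    p=st.integers(-60, 60),
)
@settings(max_examples=50, deadline=None)
def test_frame_round_trip_identity(anchor, p):
    site = GuideSite("s", anchor - 29, anchor + 1, "perfect")
    assert site.to_guide_position(site.to_construct_coord(p)) == p


def test_single_read_end_coverage():
    a = SiteAssignment("r", "site1", -9, 35, 45, 1.0, 1, "G" * 45)
    cov = end_coverage([a], "5p")
    meta = metaplot_series(cov)
    assert meta.to_dict() == {-9: 1.0}
    assert modal_position(cov) == -9


def test_metaplot_sums_over_sites():
    reads = [
        SiteAssignment("r1", "site1", -9, 35, 45, 2.0, 1, "G" * 45),
        SiteAssignment("r2", "site2", -9, 35, 45, 3.0, 1, "G" * 45),
    ]
    cov = end_coverage(reads, "5p")
    assert metaplot_series(cov)[-9] == pytest.approx(5.0)
    per_site = cov[cov.site_id != METAPLOT]
    assert per_site.rpm.sum() == pytest.approx(5.0)


def test_metaplot_equals_per_site_sums_on_simulated_library(perfect10, guide):
    cfg = SimConfig(n_reads=600, seed=23)
    mapped = _mapped_library(perfect10, guide, cfg)
    assignments = assign_to_sites(mapped, perfect10.sites)
    cov = end_coverage(assignments, "5p")
    # brute-force recomputation: per-position window-weighted sums
    expected: dict[int, float] = {}
    for a in assignments:
        if a.site_id == INTERSITE:
            continue
        expected[a.p5] = expected.get(a.p5, 0.0) + a.rpm / a.n_windows
    meta = metaplot_series(cov)
    assert set(meta.index) == set(expected)
    for p, v in expected.items():
        assert meta[p] == pytest.approx(v)


def test_rpm_conserved_across_site_and_intersite_buckets(perfect10, guide):
    cfg = SimConfig(n_reads=500, seed=29)
    mapped = _mapped_library(perfect10, guide, cfg)
    assignments = assign_to_sites(mapped, perfect10.sites)
    total_assigned = sum(a.metaplot_rpm for a in assignments)
    total_mapped = sum(m.rpm * m.n_hits for m in mapped)
    assert total_assigned == pytest.approx(total_mapped)


def test_length_profile_modes(perfect10, guide):
    mili = SimConfig(n_reads=4000, seed=31, mature_mode=26).only("mature")
    reads = as_raw_reads(simulate_reads(perfect10, guide, mili))
    assert modal_length(length_profile(reads)) == 26
    miwi = SimConfig(n_reads=4000, seed=31, mature_mode=30).only("mature")
    reads = as_raw_reads(simulate_reads(perfect10, guide, miwi))
    assert modal_length(length_profile(reads)) == 30
    # single 45-nt read -> mode 45
    single = as_raw_reads(simulate_reads(perfect10, guide,
                                         SimConfig(n_reads=1, seed=1).only("pre")))
    assert modal_length(length_profile(single)) == 45


def test_length_by_start_marginal_matches_end_coverage(perfect10, guide):
    cfg = SimConfig(n_reads=600, seed=37)
    mapped = _mapped_library(perfect10, guide, cfg)
    assignments = assign_to_sites(mapped, perfect10.sites)
    mat = length_by_start(assignments)
    meta = metaplot_series(end_coverage(assignments, "5p"))
    marg = mat.groupby("position")["rpm"].sum()
    assert set(marg.index) == set(meta.index)
    for p in marg.index:
        assert marg[p] == pytest.approx(meta[p])
    # single pre-piRNA read occupies exactly one cell
    one = [SiteAssignment("r", "site1", -9, 35, 45, 1.0, 1, "G" * 45)]
    m1 = length_by_start(one)
    assert len(m1) == 1 and tuple(m1.iloc[0][["position", "length"]]) == (-9, 45)
    assert length_by_start([]).empty


def test_body_coverage_integral_equals_rpm_times_length(perfect10, guide):
    cfg = SimConfig(n_reads=300, seed=39)
    mapped = _mapped_library(perfect10, guide, cfg)
    assignments = assign_to_sites(mapped, perfect10.sites)
    body = body_coverage(assignments)
    meta_total = body[body.site_id == METAPLOT].rpm.sum()
    expected = sum(
        a.metaplot_rpm * a.length for a in assignments if a.site_id != INTERSITE
    )
    assert meta_total == pytest.approx(expected)


def test_hits_outside_windows_go_to_intersite_bucket(perfect10):
    far = MappedRead("r", "A" * 20, [AlignmentHit("r", perfect10.construct_id, 0, 20)], 1.0)
    assignments = assign_to_sites([far], perfect10.sites)
    assert [a.site_id for a in assignments] == [INTERSITE]


def test_modal_position_rejects_empty():
    with pytest.raises(ValueError):
        modal_position(end_coverage([], "5p"))
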