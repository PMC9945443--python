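import pytest

from slicesig import (
    GuideRNA,
    ReporterLayout,
    SimConfig,
    SiteSpec,
    build_reporter,
)
from slicesig.read_prep import RawRead


@pytest.fixture(scope="session")
def guide():
    return GuideRNA()


@pytest.fixture(scope="session")
def perfect10(guide):
    return build_reporter(guide, SiteSpec.perfect(), ReporterLayout(n_sites=10))


@pytest.fixture(scope="session")
def bulge10(guide):
    return build_reporter(guide, SiteSpec.bulge(guide), ReporterLayout(n_sites=10))


def as_raw_reads(sim_reads, quality=40):
    """SimRead -> RawRead with constant qualities (no adapter appended)."""
    return [
        RawRead(r.read_id, r.sequence, tuple([quality] * len(r.sequence)))
        for r in sim_reads
    ]


@pytest.fixture()
def pre_only_cfg():
    return SimConfig(n_reads=500, seed=11).only("pre")
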