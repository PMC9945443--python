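"""Adapter/quality trimming and length filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicesig.read_prep import (
    RawRead,
    TrimParams,
    find_adapter,
    length_filter,
    prep_reads,
    quality_trim_index,
    read_fastq,
    trim_read,
    write_fastq,
)

ADAPTER = "AGATCGGAAGAGCACACGTCT"
PARAMS = TrimParams()


def _read(seq, q=40):
    return RawRead("r", seq, tuple([q] * len(seq)))


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            match = ca == cb or ca == "N"
            cur.append(min(prev[j - 1] + (0 if match else 1), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def brute_force_best_hit(seq: str, params: TrimParams):
    """Oracle: enumerate every (start, end-mode) adapter occurrence and
    rank by (errors, -overlap, start)."""
    adapter = params.adapter
    n, m = len(seq), len(adapter)
    cands = []
    for i in range(n):
        # internal: full adapter against every read substring starting at i
        best_full = min(
            (_levenshtein(seq[i:x], adapter) for x in range(i + 1, n + 1)),
            default=None,
        )
        if best_full is not None and m >= params.min_overlap:
            if best_full / m <= params.max_error_rate:
                cands.append((best_full, -m, i))
        # suffix: adapter prefix against the full read suffix
        for j in range(params.min_overlap, m):
            err = _levenshtein(seq[i:], adapter[:j])
            if err / j <= params.max_error_rate:
                cands.append((err, -j, i))
    return min(cands)[2] if cands else None


def test_exact_adapter_trimmed():
    insert = "TGGATCCTGAACGTTAGCCATGGATA"  # 26 nt
    t = trim_read(_read(insert + ADAPTER), PARAMS)
    assert t.sequence == insert and len(t) == 26


def test_no_adapter_read_unchanged():
    seq = "TTTTTTTTTTTTTTTTTTTTTTTTTT"
    assert trim_read(_read(seq), PARAMS).sequence == seq


def test_one_substitution_in_21nt_overlap_trimmed():
    insert = "CTTGAACGTTAGCCATGGATAGCCTTGAGT"  # 30 nt
    mutated = ADAPTER[:10] + "T" + ADAPTER[11:]
    assert mutated != ADAPTER and _levenshtein(mutated, ADAPTER) == 1
    read = _read(insert + mutated)
    assert find_adapter(read.sequence, PARAMS) == brute_force_best_hit(
        read.sequence, PARAMS
    ) == 30
    assert trim_read(read, PARAMS).sequence == insert


def test_partial_adapter_at_read_end():
    insert = "CTTGAACGTTAGCCATGGATAGCCTT"
    t = trim_read(_read(insert + ADAPTER[:7]), PARAMS)
    assert t.sequence == insert


def test_n_in_read_matches_any_adapter_base():
    insert = "CTTGAACGTTAGCCATGGATAGCCTT"
    seq = insert + ADAPTER[:5] + "N" + ADAPTER[6:]
    assert find_adapter(seq, PARAMS) == len(insert)


@given(
    insert=st.text(alphabet="ACGT", min_size=15, max_size=40),
    adapter_len=st.integers(min_value=0, max_value=21),
)
@settings(max_examples=60, deadline=None)
def test_agreement_with_brute_force_oracle(insert, adapter_len):
    seq = insert + ADAPTER[:adapter_len]
    assert find_adapter(seq, PARAMS) == brute_force_best_hit(seq, PARAMS)
    once = trim_read(_read(seq), PARAMS)
    assert len(once) <= len(seq)
    assert len(trim_read(once, PARAMS)) <= len(once)


@given(
    insert=st.text(alphabet="CT", min_size=15, max_size=40),
    adapter_len=st.integers(min_value=0, max_value=21),
)
@settings(max_examples=40, deadline=None)
def test_trim_idempotent_when_insert_cannot_mimic_adapter(insert, adapter_len):
    # Error-tolerant trimming is only idempotent when the remaining insert
    # cannot itself pass for an adapter prefix; a C/T-only insert cannot
    # (every adapter prefix >= 4 nt carries too many A/G bases).
    seq = insert + ADAPTER[:adapter_len]
    once = trim_read(_read(seq), PARAMS)
    assert trim_read(once, PARAMS).sequence == once.sequence


def test_quality_trim_bwa_rule():
    # trailing low-quality run trimmed at the running-sum maximum
    quals = tuple([35] * 20 + [2] * 5)
    assert quality_trim_index(quals, 10) == 20
    assert quality_trim_index(tuple([35] * 25), 10) == 25
    assert quality_trim_index(quals, 0) == 25


def test_length_filter_inclusive_boundary():
    reads = [_read("A" * n) for n in (14, 15, 16)]
    kept, counts = length_filter(reads, 15)
    assert sorted(len(r) for r in kept) == [15, 16]
    assert counts == {"kept": 2, "discarded": 1}
    kept, counts = length_filter([], 15)
    assert kept == [] and counts == {"kept": 0, "discarded": 0}


def test_prep_reads_report_counts(perfect10, guide):
    from slicesig.simulate import SimConfig, simulate_reads

    cfg = SimConfig(n_reads=300, seed=2, adapter=ADAPTER)
    sim = simulate_reads(perfect10, guide, cfg)
    raw = [
        RawRead(r.read_id, r.sequence + ADAPTER, tuple([40] * (len(r.sequence) + 21)))
        for r in sim
    ]
    kept, report = prep_reads(raw)
    # oracle: recount planted insert lengths independently
    expected_kept = sum(len(r.sequence) >= 15 for r in sim)
    assert report.loc[0, "reads_out"] == expected_kept == len(kept)
    trimmed = {r.read_id: r.sequence for r in kept}
    assert all(trimmed[r.read_id] == r.sequence for r in sim if len(r.sequence) >= 15)


def test_fastq_roundtrip(tmp_path):
    reads = [RawRead(f"r{i}", "ACGTACGTACGTACGT", tuple([30 + i] * 16)) for i in range(3)]
    path = tmp_path / "x.fastq"
    write_fastq(reads, path)
    back = list(read_fastq(path))
    assert back == reads


def test_trim_params_validation():
    with pytest.raises(ValueError):
        TrimParams(max_error_rate=0.7)
    with pytest.raises(ValueError):
        TrimParams(min_overlap=0)
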