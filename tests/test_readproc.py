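"""Read processing: trimming, demultiplexing, and the Hamming aligner
against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnapipe import (
    Read,
    align_hamming,
    align_reads,
    demultiplex,
    filter_min_length,
    revcomp,
    trim_adapter,
)

ADAPTER = "AGATCGGAAGAGCACACGTCT"


# ---------------------------------------------------------------- trimming
def brute_force_trim(seq, adapter, min_overlap=3):
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx]
    best = 0
    for ov in range(min_overlap, min(len(seq), len(adapter) - 1) + 1):
        if seq.endswith(adapter[:ov]):
            best = max(best, ov)
    return seq[: len(seq) - best] if best else seq


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGTACGT" + ADAPTER[:12], "ACGTACGT"),
        ("ACGTTTTTCCA", "ACGTTTTTCCA"),           # no adapter overlap
        ("CCCCGGGG" + ADAPTER[:3], "CCCCGGGG"),    # 3-nt suffix overlap
        ("AA" + ADAPTER + "TTTT", "AA"),           # internal full adapter
    ],
)
def test_trim_adapter_examples(seq, expected):
    assert trim_adapter(seq, ADAPTER) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=60),
       st.integers(min_value=0, max_value=21))
def test_trim_adapter_matches_brute_force(insert, n_adapter):
    seq = insert + ADAPTER[:n_adapter]
    assert trim_adapter(seq, ADAPTER) == brute_force_trim(seq, ADAPTER)


def test_filter_min_length_threshold():
    reads = [Read(f"r{i}", "A" * n) for i, n in enumerate((14, 15, 16))]
    kept = filter_min_length(reads, 15)
    assert [len(r.sequence) for r in kept] == [15, 16]
    assert filter_min_length([], 15) == []


# ------------------------------------------------------------ demultiplex
BARCODES = {"libA": "ATCACG", "libB": "CGATGT"}


def test_demultiplex_assigns_by_barcode():
    reads = [
        Read("a", "ACGTACGTACGTACGTACGTACGT" + BARCODES["libA"] + ADAPTER[:10]),
        Read("b", "TGCATGCATGCATGCATGCATGCA" + BARCODES["libB"] + ADAPTER[:10]),
        Read("c", "GGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGG"),
    ]
    bins = demultiplex(reads, BARCODES, ADAPTER)
    assert [r.read_id for r in bins["libA"]] == ["a"]
    assert [r.read_id for r in bins["libB"]] == ["b"]
    assert [r.read_id for r in bins["undetermined"]] == ["c"]


def test_demultiplex_conserves_read_count(rng):
    reads = []
    for i in range(1000):
        tag = ("libA", "libB", None)[i % 3]
        insert = "".join(rng.choice(list("ACGT"), size=20))
        if tag:
            seq = insert + BARCODES[tag] + ADAPTER
        else:
            seq = insert + "TTTTTT" + "CATCATCATCATCATCATCAT"
        reads.append(Read(f"r{i}", seq[:51]))
    bins = demultiplex(reads, BARCODES, ADAPTER)
    assert sum(len(v) for v in bins.values()) == 1000
    assert len(bins["libA"]) >= 300 and len(bins["libB"]) >= 300


def test_demultiplex_rejects_barcode_collision():
    with pytest.raises(ValueError, match="collision|unique"):
        demultiplex([], {"a": "ACGTAC", "b": "ACGTAC"}, ADAPTER)


# ----------------------------------------------------------------- aligner
def brute_force_align(read_seq, reference, max_mm=0, forbidden=frozenset()):
    """Independent double-loop scan over all offsets and both strands."""
    L = len(read_seq)
    candidates = []
    for strand in "+-":
        query = read_seq if strand == "+" else revcomp(read_seq)
        for start in range(len(reference) - L + 1):
            mmpos = []
            for j in range(L):
                ref_base = reference[start + j]
                q_base = query[j]
                read_pos = j + 1 if strand == "+" else L - j
                if q_base != ref_base or q_base == "N":
                    mmpos.append(read_pos)
            if len(mmpos) <= max_mm and not (set(mmpos) & forbidden):
                candidates.append(
                    (len(mmpos), start, 0 if strand == "+" else 1, strand,
                     tuple(sorted(mmpos)))
                )
    if not candidates:
        return None
    n_mm, start, _, strand, mmpos = min(candidates, key=lambda c: c[:3])
    return (strand, start, start + L, mmpos)


def test_align_exact_example():
    hit = align_hamming("CCCCGGGG", "AAAACCCCGGGGTTTT", max_mm=0)
    assert (hit.strand, hit.start, hit.end) == ("+", 4, 12)
    assert hit.mismatch_positions == ()


def test_align_with_mismatch_example():
    hit = align_hamming("CCCTGGGG", "AAAACCCCGGGGTTTT", max_mm=3)
    assert hit.start == 4 and hit.mismatch_positions == (4,)


def test_forbidden_positions_block_seed_mismatches():
    ref = "AAAACCCCGGGGTTTT"
    # single mismatch at read position 5 (inside the 2-10 guide seed)
    hit = align_hamming("CCCCAGGG", ref, max_mm=3,
                        forbidden_positions=frozenset(range(2, 11)))
    assert hit is None


def test_minus_strand_five_prime_convention():
    ref = "AAAACCCAGGGGTTTT"
    hit = align_hamming(revcomp("CCCAGGGG"), ref, max_mm=0)
    assert hit.strand == "-" and (hit.start, hit.end) == (4, 12)


def test_n_counts_as_mismatch():
    assert align_hamming("CCNCGGGG", "AAAACCCCGGGGTTTT", max_mm=0) is None
    hit = align_hamming("CCNCGGGG", "AAAACCCCGGGGTTTT", max_mm=1)
    assert hit.mismatch_positions == (3,)


@settings(max_examples=400, deadline=None, derandomize=True)
@given(st.data())
def test_align_hamming_equals_brute_force(data):
    rng_seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    ref = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 80)))
    L = int(rng.integers(5, 15))
    if rng.random() < 0.5:  # planted read (possibly mutated)
        start = int(rng.integers(0, len(ref) - L + 1))
        read = list(ref[start : start + L])
        for _ in range(rng.integers(0, 3)):
            read[rng.integers(0, L)] = rng.choice(list("ACGT"))
        read = "".join(read)
        if rng.random() < 0.5:
            read = revcomp(read)
    else:
        read = "".join(rng.choice(list("ACGT"), size=L))
    max_mm = int(rng.integers(0, 4))
    forbidden = frozenset(
        int(p) for p in rng.choice(range(1, L + 1),
                                   size=rng.integers(0, 4), replace=False)
    ) if rng.random() < 0.4 else frozenset()
    expected = brute_force_align(read, ref, max_mm, forbidden)
    hit = align_hamming(read, ref, max_mm=max_mm, forbidden_positions=forbidden)
    if expected is None:
        assert hit is None
    else:
        assert (hit.strand, hit.start, hit.end, hit.mismatch_positions) == expected


def test_exact_mode_equals_substring_search(rng):
    # max_mm=0 must agree with naive substring search on both strands
    for _ in range(200):
        ref = "".join(rng.choice(list("ACGT"), size=60))
        start = int(rng.integers(0, 50))
        read = ref[start : start + 10]
        if rng.random() < 0.5:
            read = revcomp(read)
        hit = align_hamming(read, ref, max_mm=0)
        assert hit is not None and hit.n_mismatch == 0
        query = read if hit.strand == "+" else revcomp(read)
        assert ref.find(query) == hit.start


def test_align_reads_splits_aligned_and_unaligned():
    refs = {"t1": "ACGTACGTACGTACGTACGT"}
    reads = [Read("hit", "ACGTACGTAC"), Read("miss", "TTTTTTTTTT")]
    aligned, unaligned = align_reads(reads, refs, max_mm=0)
    assert [a.read_id for a in aligned] == ["hit"]
    assert [u.read_id for u in unaligned] == ["miss"]


def test_pipeline_recovers_truth_coordinates(reporter, params, simulation):
    """trim -> filter -> exact align recovers >=99% of reporter-derived
    fragments at their true coordinates on error-free reads."""
    from pirnapipe import simulate_library

    fragments, _ = simulation
    records = simulate_library(fragments, params, "control")
    tail = params.barcode_map["control"] + params.adapter_seq
    by_id = {f"control.{f.read_id}": f for f in fragments}
    n_reporter = n_recovered = 0
    for read_id, seq, _ in records:
        frag = by_id[read_id]
        if frag.true_class == "mirna":
            continue
        n_reporter += 1
        trimmed = trim_adapter(seq, tail)
        if len(trimmed) < 15:
            continue
        hit = align_hamming(trimmed, reporter.sequence, max_mm=0)
        if hit and hit.strand == "+" and hit.start == frag.start:
            # 51-mers are sequencing-truncated, so only the start must agree
            if hit.end == frag.end or frag.end - frag.start > params.max_read_length:
                n_recovered += 1
    assert n_reporter > 5000
    assert n_recovered / n_reporter >= 0.99
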