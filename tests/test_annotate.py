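"""Preprocessing and two-phase annotation, checked against brute force.

The brute-force aligner below re-derives every result by exhaustive
enumeration of (read, reference, offset) placements and shares no code
with the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirage import (
    DEFAULT_ADAPTER,
    InputError,
    MatureReference,
    PreprocessParams,
    Read,
    align_phase1,
    align_phase2,
    annotate,
    filter_length,
    filter_n,
    preprocess,
    trim_adapter,
)
from mirage.simulate import SimulationConfig, simulate_smallrna_reads


def _read(seq: str, read_id: str = "r") -> Read:
    return Read(read_id, seq, "I" * len(seq))


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------

def _mm(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_annotate(reads, ref: MatureReference, max_mm: int = 2):
    """Exhaustive re-derivation of the two-phase assignment of every read."""
    ref_list = list(ref.items())
    results = {}
    for read in reads:
        candidates = []  # (mm, offset, ref_idx, phase)
        for phase in (1, 2):
            for ref_idx, (mid, mature) in enumerate(ref_list):
                if phase == 1 and len(read.seq) <= len(mature):
                    for off in range(len(mature) - len(read.seq) + 1):
                        m = _mm(read.seq, mature[off : off + len(read.seq)])
                        if m <= max_mm:
                            candidates.append((m, off, ref_idx, 1, mid))
                if phase == 2 and len(mature) < len(read.seq):
                    for off in range(len(read.seq) - len(mature) + 1):
                        m = _mm(mature, read.seq[off : off + len(mature)])
                        if m <= max_mm:
                            candidates.append((m, off, ref_idx, 2, mid))
        phase1 = [c for c in candidates if c[3] == 1]
        pool = phase1 if phase1 else candidates
        if pool:
            m, off, _, phase, mid = min(pool)
            results[read.id] = (mid, phase, m, off)
        else:
            results[read.id] = None
    return results


def _random_instance(rng):
    n_ref = rng.integers(1, 11)
    ref = MatureReference(
        [
            (f"mir{j}", "".join(rng.choice(list("ACGT"), size=rng.integers(18, 26))))
            for j in range(n_ref)
        ]
    )
    ref_seqs = list(ref.entries.values())
    reads = []
    for i in range(rng.integers(1, 101)):
        if rng.random() < 0.7:  # reference-derived read with mutations
            base = ref_seqs[rng.integers(len(ref_seqs))]
            length = int(rng.integers(15, 41))
            if length <= len(base):
                start = rng.integers(0, len(base) - length + 1)
                seq = list(base[start : start + length])
            else:
                seq = list(base) + list(rng.choice(list("ACGT"), size=length - len(base)))
            for _ in range(rng.integers(0, 4)):
                pos = rng.integers(len(seq))
                seq[pos] = "ACGT"[rng.integers(4)]
            seq = "".join(seq)
        else:  # random read
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(15, 41)))
        reads.append(_read(seq, f"r{i}"))
    return reads, ref


def _as_tuples(assignments):
    return {a.read_id: (a.mirna_id, a.phase, a.mismatches, a.offset) for a in assignments}


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def test_filter_n_removes_exactly_reads_with_n():
    reads = [_read("ACGT", "a"), _read("ACNT", "b"), _read("NNNN", "c")]
    assert [r.id for r in filter_n(reads)] == ["a"]
    assert filter_n([]) == []
    clean = [_read("ACGT", "a"), _read("TTTT", "b")]
    assert filter_n(clean) == clean  # identity when no N present


@pytest.mark.parametrize(
    "insert,overlap_len,n_subs,expect_trim",
    [
        ("TAGCACCATCTGAAATCGGTTA", 33, 0, True),   # full adapter
        ("TAGCACCATCTGAAATCGGTTA", 12, 1, True),   # budget min(2, 12//8) = 1
        ("TAGCACCATCTGAAATCGGTTA", 16, 2, True),   # budget min(2, 16//8) = 2
        ("TAGCACCATCTGAAATCGGTTA", 12, 2, False),  # over the prorated budget
    ],
)
def test_trim_adapter_overlap_budget(insert, overlap_len, n_subs, expect_trim):
    """Adapter prefixes at the 3' end are removed within the prorated
    mismatch budget min(2, L // 8); over-budget overlaps are left alone."""
    params = PreprocessParams()
    adapter_part = list(DEFAULT_ADAPTER[:overlap_len])
    # substitute the first n_subs adapter bases (transversion keeps them wrong)
    for i in range(n_subs):
        adapter_part[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[adapter_part[i]]
    read = _read(insert + "".join(adapter_part))
    out = trim_adapter(read, params)
    if expect_trim:
        assert out.seq == insert
        assert out.qual == "I" * len(insert)
    else:
        assert out.seq == read.seq


def test_trim_adapter_no_match_unchanged():
    read = _read("TAGCACCATCTGAAATCGGTTA")  # no adapter-like suffix
    assert trim_adapter(read, PreprocessParams()) is read


def test_trim_adapter_matches_bruteforce_overlap_scan():
    """Against an independent longest-suffix/prefix scan on random reads."""
    rng = np.random.default_rng(7)
    params = PreprocessParams()

    def oracle(seq):
        while True:
            for L in range(min(len(seq), len(DEFAULT_ADAPTER)), 5, -1):
                if _mm(seq[-L:], DEFAULT_ADAPTER[:L]) <= min(2, L // 8):
                    seq = seq[:-L]
                    break
            else:
                return seq

    for _ in range(200):
        insert = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 30)))
        keep = rng.integers(0, 34)
        adapter = list(DEFAULT_ADAPTER[:keep])
        for _s in range(rng.integers(0, 3)):
            if adapter:
                pos = rng.integers(len(adapter))
                adapter[pos] = "ACGT"[rng.integers(4)]
        seq = insert + "".join(adapter)
        assert trim_adapter(_read(seq), params).seq == oracle(seq)


@given(st.text(alphabet="ACGT", min_size=0, max_size=60))
@settings(max_examples=150, derandomize=True)
def test_trim_adapter_idempotent_and_never_grows(seq):
    params = PreprocessParams()
    once = trim_adapter(_read(seq), params)
    twice = trim_adapter(once, params)
    assert twice.seq == once.seq
    assert len(once.seq) <= len(seq)
    assert len(once.qual) == len(once.seq)


def test_filter_length_bounds():
    params = PreprocessParams()
    reads = [_read("A" * n, f"len{n}") for n in (17, 18, 33, 34)]
    assert [r.id for r in filter_length(reads, params)] == ["len18", "len33"]
    same = [_read("A" * 22, f"r{i}") for i in range(3)]
    assert filter_length(same, params) == same
    assert filter_length([], params) == []


def test_preprocess_counts_are_conserved():
    reads = [
        _read("ACGTN" + "A" * 20, "has_n"),
        _read("A" * 5, "too_short"),
        _read("TAGCACCATCTGAAATCGGTTA" + DEFAULT_ADAPTER, "good"),
    ]
    clean, stats = preprocess(reads)
    assert [r.id for r in clean] == ["good"]
    assert clean[0].seq == "TAGCACCATCTGAAATCGGTTA"
    assert stats == {
        "input_reads": 3, "removed_n": 1, "removed_length": 1, "output_reads": 1,
    }


# --------------------------------------------------------------------------
# alignment phases
# --------------------------------------------------------------------------

def test_phase1_exact_read_is_assigned_at_offset_zero(small_reference):
    a = align_phase1(_read("TAGCACCATCTGAAATCGGTTA"), small_reference)
    assert (a.mirna_id, a.phase, a.mismatches, a.offset) == ("miR-29a", 1, 0, 0)


def test_phase1_two_mismatch_prefix_read(small_reference):
    # miR-29a[0:20] with substitutions at positions 5 and 10
    seq = list("TAGCACCATCTGAAATCGGTTA"[:20])
    seq[5], seq[10] = "G", "A"
    a = align_phase1(_read("".join(seq)), small_reference)
    assert (a.mirna_id, a.mismatches, a.offset) == ("miR-29a", 2, 0)


def test_phase1_three_mismatches_rejected(small_reference):
    seq = list("TAGCACCATCTGAAATCGGTTA")
    seq[2], seq[7], seq[12] = "T", "C", "C"
    # confirm via enumeration that the best placement has >= 3 mismatches
    oracle = brute_force_annotate([_read("".join(seq))], small_reference, max_mm=2)
    assert oracle["r"] is None
    assert align_phase1(_read("".join(seq)), small_reference) is None


def test_phase2_mature_inside_longer_read(small_reference):
    read = _read("GG" + "TAGCACCATCTGAAATCGGTTA" + "AC")
    a = align_phase2(read, small_reference)
    assert (a.mirna_id, a.phase, a.mismatches, a.offset) == ("miR-29a", 2, 0, 2)


def test_phase2_read_shorter_than_every_mature(small_reference):
    assert align_phase2(_read("ACGTACGTACGT"), small_reference) is None


def test_phase2_with_two_substitutions(small_reference):
    core = list("TAGCACCATCTGAAATCGGTTA")
    core[3], core[9] = "T", "G"
    read = _read("CGAT" + "".join(core) + "ACGT")
    a = align_phase2(read, small_reference)
    assert (a.mirna_id, a.mismatches, a.offset) == ("miR-29a", 2, 4)


def test_aligner_rejects_n_bases(small_reference):
    with pytest.raises(InputError):
        align_phase1(_read("TAGCACCATCTGAAATCGGTNA"), small_reference)


# --------------------------------------------------------------------------
# two-phase annotation
# --------------------------------------------------------------------------

def test_annotate_single_exact_read(small_reference):
    assigns, table = annotate([_read("TGAGGTAGTAGGTTGTATAGTT")], small_reference)
    assert len(assigns) == 1 and assigns[0].mirna_id == "let-7a"
    assert table.counts["let-7a"] == 1 and table.unassigned == 0


def test_annotate_empty_reference_errors():
    with pytest.raises(InputError):
        annotate([_read("ACGT" * 6)], MatureReference([]))


def test_annotate_random_33mers_all_unassigned(small_reference):
    rng = np.random.default_rng(11)
    reads = [
        _read("".join(rng.choice(list("ACGT"), size=33)), f"r{i}") for i in range(30)
    ]
    oracle = brute_force_annotate(reads, small_reference)
    expected_unassigned = sum(1 for v in oracle.values() if v is None)
    _, table = annotate(reads, small_reference)
    assert table.unassigned == expected_unassigned == 30


def test_annotate_recovers_generator_ground_truth(small_reference):
    cfg = SimulationConfig(read_count=300, error_rate=0.0, n_rate=0.0, rng_seed=5)
    reads, truth = simulate_smallrna_reads(small_reference, cfg)
    clean, _ = preprocess(reads)
    assigns, table = annotate(clean, small_reference)
    assert table.unassigned == 0
    for a in assigns:
        assert truth.read_sources[a.read_id] == a.mirna_id
    expected = {}
    for mid in truth.read_sources.values():
        expected[mid] = expected.get(mid, 0) + 1
    assert {m: c for m, c in table.counts.items() if c} == expected


def test_isomir_extension_forces_phase_two(small_reference):
    cfg = SimulationConfig(
        read_count=20, error_rate=0.0, n_rate=0.0,
        isomir_len_shift={4: 1.0}, rng_seed=2,
    )
    reads, _ = simulate_smallrna_reads(small_reference, cfg)
    clean, _ = preprocess(reads)
    assert all(len(r.seq) >= 24 for r in clean)  # shortest mature (20) + 4
    assigns, table = annotate(clean, small_reference)
    assert table.unassigned == 0
    assert all(a.phase == 2 for a in assigns)


def test_annotate_equals_bruteforce_on_random_instances(small_reference):
    rng = np.random.default_rng(100)
    for _ in range(20):
        reads, ref = _random_instance(rng)
        assigns, table = annotate(reads, ref)
        got = _as_tuples(assigns)
        oracle = brute_force_annotate(reads, ref)
        for read in reads:
            assert got.get(read.id) == oracle[read.id]
        assert table.total == len(reads)


def test_conservation_and_uniqueness(small_reference):
    rng = np.random.default_rng(42)
    reads, ref = _random_instance(rng)
    assigns, table = annotate(reads, ref)
    assert sum(table.counts.values()) + table.unassigned == len(reads)
    assert len({a.read_id for a in assigns}) == len(assigns)


def test_raising_max_mm_never_loses_assignments(small_reference):
    rng = np.random.default_rng(13)
    reads, ref = _random_instance(rng)
    previous = -1
    for max_mm in (0, 1, 2, 3):
        assigns, _ = annotate(reads, ref, max_mm=max_mm)
        assert len(assigns) >= previous
        previous = len(assigns)
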