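"""Tandem array detection and motif canonicalization."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from repeataudit import tandem_scan as ts

from conftest import mutate, random_seq


def brute_canonical(motif: str) -> str:
    """Independent oracle: minimum over explicit rotation lists, with
    Biopython supplying the reverse complement."""
    rc = str(Seq(motif).reverse_complement())
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


@pytest.mark.parametrize("motif,expected", [
    ("GAG", "AGG"),
    ("A", "A"),
    ("TTTAGGG", brute_canonical("TTTAGGG")),  # == AAACCCT
    ("AAG", "AAG"),
    ("AGAGGG", "AGAGGG"),
])
def test_canonical_motif_examples(motif, expected):
    assert ts.canonical_motif(motif) == expected
    # idempotence
    assert ts.canonical_motif(expected) == expected


def test_canonical_motif_rejects_bad_input():
    with pytest.raises(ValueError):
        ts.canonical_motif("")
    with pytest.raises(ValueError):
        ts.canonical_motif("ACGU")


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=50),
       st.integers(min_value=0, max_value=49))
def test_canonical_invariance_property(motif, shift):
    """Rotations and the reverse complement share one canonical form."""
    shift = shift % len(motif)
    rotated = motif[shift:] + motif[:shift]
    rc = str(Seq(motif).reverse_complement())
    c = ts.canonical_motif(motif)
    assert c == ts.canonical_motif(rotated) == ts.canonical_motif(rc)
    assert c == brute_canonical(motif)


def test_exact_telomere_array():
    arrays = ts.find_arrays("TTTAGGG" * 100, min_array_len=500,
                            max_motif_len=50)
    assert len(arrays) == 1
    a = arrays[0]
    assert (a.start, a.end) == (0, 700)
    assert a.motif == "AAACCCT"
    assert a.copy_count == pytest.approx(100.0)
    assert a.purity == 1.0


def test_array_with_substitutions_recovers_interval():
    rng = np.random.default_rng(17)
    bg = random_seq(rng, 3000)
    planted = mutate("TTTAGGG" * 100, 0.05, rng)
    seq = bg[:1500] + planted + bg[1500:]
    arrays = ts.find_arrays(seq, min_array_len=500, max_motif_len=50)
    assert len(arrays) == 1
    a = arrays[0]
    assert abs(a.start - 1500) <= 7 and abs(a.end - 2200) <= 7
    assert a.purity >= 0.9
    assert a.motif == "AAACCCT"


def _consensus_purity_oracle(seq: str, period: int, window: int) -> float:
    """Best consensus-match purity of any window at the given period."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = 0.0
    for start in range(0, arr.size - window + 1, 25):
        w = arr[start:start + window]
        cols = np.arange(window) % period
        purity_num = 0
        for c in range(period):
            vals, counts = np.unique(w[cols == c], return_counts=True)
            purity_num += counts.max()
        best = max(best, purity_num / window)
    return best


def test_random_sequence_yields_no_arrays():
    rng = np.random.default_rng(23)
    seq = random_seq(rng, 10_000)
    arrays = ts.find_arrays(seq, min_array_len=500, max_motif_len=50,
                            min_purity=0.8)
    small = [a for a in arrays if len(a.motif) <= 6 and a.length >= 500]
    assert small == []
    # oracle: no 500 bp window reaches 0.8 purity at any period <= 6
    for p in range(1, 7):
        assert _consensus_purity_oracle(seq, p, 500) < 0.8


def test_primitive_motif_preferred_over_multiple():
    arrays = ts.find_arrays("AGAGGG" * 200, min_array_len=500,
                            max_motif_len=50)
    assert len(arrays) == 1
    assert arrays[0].motif == "AGAGGG"  # not a 12/18-mer multiple


def test_arrays_split_at_n_runs():
    half = "TTTAGGG" * 100
    seq = half + "N" * 50 + half
    arrays = ts.find_arrays(seq, min_array_len=500, max_motif_len=50)
    assert len(arrays) == 2
    assert all(a.purity == 1.0 for a in arrays)


def test_output_intervals_disjoint_long_motif():
    rng = np.random.default_rng(5)
    unit = random_seq(rng, 327)
    seq = random_seq(rng, 1500) + unit * 20 + random_seq(rng, 1500)
    arrays = ts.find_arrays(seq, min_array_len=1000, max_motif_len=2000)
    assert len(arrays) == 1
    a = arrays[0]
    assert a.length == pytest.approx(20 * 327, abs=10)
    assert len(a.motif) == 327
    ordered = sorted(arrays, key=lambda x: x.start)
    for x, y in zip(ordered, ordered[1:]):
        assert x.end <= y.start


def test_scan_reads_threshold_and_empty():
    reads = [(f"r{i}", "TTTAGGG" * 100) for i in range(5)]
    arrays, summary = ts.scan_reads(reads, min_array_len=500,
                                    thresholds=(1000,), max_motif_len=25)
    assert summary["reads_exceeding"][1000] == 0  # 700 bp < 1 kb
    assert len(arrays) == 5
    arrays, summary = ts.scan_reads([], max_motif_len=25)
    assert len(arrays) == 0
    assert summary["reads_exceeding"] == {1000: 0, 10000: 0}


def test_scan_reads_telomere_counts_match_provenance_oracle():
    """The number of reads with a >= 1 kb telomeric array equals the
    number of reads overlapping a planted telomere by >= 1 kb."""
    from repeataudit import synthetic_data as sd
    spec = sd.GenomeSpec(chrom_length=400_000, telomere_len=5_000,
                         subtel_blocks=(), centromere=None, seed=19)
    genome, truth = sd.simulate_genome(spec)
    reads = sd.simulate_reads(
        genome, sd.ReadProfile(target_depth=10,
                               length_law=("uniform", 3_000, 5_000)),
        seed=20)
    arrays, summary = ts.scan_reads(reads.reads, min_array_len=1000,
                                    thresholds=(1000,), max_motif_len=25)
    tel = truth.features.query("feature_class=='telomere'")
    p = reads.provenance
    ov = np.zeros(len(p))
    for _, t in tel.iterrows():
        ov += np.maximum(0, np.minimum(p.end, t.end)
                         - np.maximum(p.start, t.start))
    expected = int((ov >= 1000).sum())
    tel_reads = set(
        arrays.query("motif=='AAACCCT' and length >= 1000").sequence_id)
    assert len(tel_reads) == expected
    assert summary["reads_exceeding"][1000] >= len(tel_reads)


def test_scan_reads_skips_unreadable_records():
    reads = [("ok", "TTTAGGG" * 200), ("bad",), 12345]
    arrays, summary = ts.scan_reads(reads, min_array_len=500,
                                    max_motif_len=25)
    assert summary["skipped"] == 2
    assert set(arrays.sequence_id) == {"ok"}
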