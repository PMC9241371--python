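"""Anchor placement, window aggregation, feature-distance classification."""

import numpy as np
import pytest

from repeataudit import _seq, read_place as rp


@pytest.fixture(scope="module")
def placed(small_genome_mod):
    genome = small_genome_mod[1]
    index = rp.AnchorIndex(genome.assembly, 51)
    return genome, index


@pytest.fixture(scope="module")
def small_genome_mod():
    from repeataudit import synthetic_data as sd
    spec = sd.GenomeSpec(
        chrom_length=1_000_000, telomere_len=5_000,
        subtel_blocks=(("hvt01", 20_000),),
        centromere=sd.CentromereSpec(total_len=60_000, n_retro_insertions=4),
        seed=41)
    return (spec, *sd.simulate_genome(spec))


def test_verbatim_read_recovers_source_position(placed):
    genome, index = placed
    arr = genome.chromosomes["chr1"][200_000:215_000]
    p = rp.place_reads([("r", arr)], genome.assembly, index=index)[0]
    assert p.confidence == "unique"
    assert p.chrom == "chr1"
    assert abs(p.position - 200_000) <= 500


def test_satellite_only_read_unplaced(placed):
    genome, index = placed
    p = rp.place_reads([("sat", "AGAGGG" * 2000)], genome.assembly,
                       index=index)[0]
    assert p.confidence == "unplaced"


def test_half_satellite_read_placed_by_flank(placed):
    genome, index = placed
    flank = genome.chromosomes["chr1"][300_000:309_000]
    read = np.concatenate(
        [_seq.to_u8("AGAGGG" * 1500), flank])
    p = rp.place_reads([("half", read)], genome.assembly, index=index)[0]
    assert p.confidence == "unique"
    assert abs(p.position - (300_000 - 9_000)) <= 1_000


def test_reverse_complement_read_placed(placed):
    genome, index = placed
    arr = _seq.revcomp_arr(genome.chromosomes["chr1"][400_000:412_000])
    p = rp.place_reads([("rc", arr)], genome.assembly, index=index)[0]
    assert p.confidence == "unique"
    assert abs(p.position - 400_000) <= 500


def test_placement_of_error_free_unique_reads_is_complete(placed):
    genome, index = placed
    rng = np.random.default_rng(10)
    reads, wants = [], []
    for i in range(30):
        s = int(rng.integers(150_000, 900_000 - 15_000))
        reads.append((f"u{i}", genome.chromosomes["chr1"][s:s + 15_000]))
        wants.append(s)
    pls = rp.place_reads(reads, genome.assembly, index=index)
    assert all(p.confidence == "unique" for p in pls)
    assert all(abs(p.position - w) <= 500 for p, w in zip(pls, wants))


def test_anchor_k_validation():
    with pytest.raises(ValueError):
        rp.AnchorIndex({"c": "ACGT" * 100}, k=21)
    with pytest.raises(ValueError):
        rp.AnchorIndex({"c": "ACGT"}, k=51)  # assembly shorter than k


def test_window_counts_sum_and_edges():
    pls = [rp.Placement(f"r{i}", "c", 1_000 + i, "unique")
           for i in range(10)]
    pls.append(rp.Placement("amb", "unplaced", -1, "ambiguous"))
    df = rp.window_counts(pls, 5_000, {"c": 20_000})
    assert df["count"].sum() == 10
    assert df.iloc[0]["count"] == 10
    # window = chromosome length: one window holding everything
    df1 = rp.window_counts(pls, 20_000, {"c": 20_000})
    assert len(df1) == 1 and df1.iloc[0]["count"] == 10
    df0 = rp.window_counts([], 5_000, {"c": 20_000})
    assert df0["count"].sum() == 0


def test_feature_distance_boundary_convention():
    feats = rp.FeatureSet({"c": [(1_000, 2_000)]})
    mk = lambda pos: rp.Placement("r", "c", pos, "unique")
    r = 100
    out = rp.classify_by_feature_distance([mk(2_000 + r)], feats, radius=r)
    assert out["near"] == 1.0  # distance exactly == radius counts near
    out = rp.classify_by_feature_distance([mk(2_000 + r + 1)], feats,
                                          radius=r)
    assert out["far"] == 1.0
    out = rp.classify_by_feature_distance([mk(1_000)], feats, radius=r)
    assert out["near"] == 1.0  # on the boundary: distance 0


def test_satellite_reads_cluster_at_centromere(placed):
    """Reads carrying the centromeric satellite either place near the
    centromere (via unique flanks) or stay unplaced; almost none place
    far away."""
    genome, index = placed
    arr = genome.chromosomes["chr1"]
    reads = []
    rng = np.random.default_rng(12)
    # centromere occupies the middle ~60 kb of the 1 Mb chromosome
    cen = (470_000, 530_000)
    for i in range(40):
        s = int(rng.integers(cen[0] - 12_000, cen[1] - 3_000))
        reads.append((f"s{i}", arr[s:s + 15_000]))
    pls = rp.place_reads(reads, genome.assembly, index=index)
    feats = rp.FeatureSet({"chr1": [cen]})
    out = rp.classify_by_feature_distance(pls, feats, radius=100_000)
    assert out["near"] + out["unplaced"] >= 0.95
    assert out["far"] <= 0.05


def test_feature_distance_fractions_sum_to_one():
    feats = rp.FeatureSet({"c": [(500, 600)]})
    pls = [rp.Placement("a", "c", 550, "unique"),
           rp.Placement("b", "c", 5_000, "unique"),
           rp.Placement("u", "unplaced", -1, "unplaced"),
           rp.Placement("m", "unplaced", -1, "ambiguous")]
    out = rp.classify_by_feature_distance(pls, feats, radius=100)
    assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)
    assert out["unplaced"] == 0.5
    out = rp.classify_by_feature_distance([], feats, radius=100)
    assert all(np.isnan(v) for v in out.values())
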