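"""Generator ground truth, determinism, and sampling calibration."""

import numpy as np
import pytest

from repeataudit import _seq, synthetic_data as sd


def test_telomere_features_by_construction():
    spec = sd.GenomeSpec(chrom_length=500_000, telomere_len=10_000,
                         subtel_blocks=(), centromere=None, seed=1)
    genome, truth = sd.simulate_genome(spec)
    tel = truth.features.query("feature_class=='telomere'")
    assert len(tel) == 2
    assert set(tel.end - tel.start) == {10_000}
    # planted verbatim: forward array at the left terminus
    left = genome.chromosomes["chr1"][:7].tobytes().decode()
    assert left == "TTTAGGG"


def test_rdna_locus_interval_length():
    spec = sd.GenomeSpec(chrom_length=1_000_000, telomere_len=0,
                         subtel_blocks=(), centromere=None,
                         rdna_loci=(sd.RdnaLocus("rdna_5h", 50, 0, 200_000),),
                         seed=2)
    _, truth = sd.simulate_genome(spec)
    row = truth.features.query("feature_class=='rdna_rdna_5h'").iloc[0]
    assert row.end - row.start == 50 * 8_900
    assert row.copies == 50


def test_determinism_byte_identical(tmp_path):
    spec = sd.GenomeSpec(chrom_length=400_000, seed=9,
                         centromere=sd.CentromereSpec(total_len=50_000,
                                                      n_retro_insertions=3),
                         telomere_len=2_000, subtel_blocks=(("hvt01", 5_000),))
    g1, t1 = sd.simulate_genome(spec)
    g2, t2 = sd.simulate_genome(spec)
    f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
    g1.to_fasta(f1), g2.to_fasta(f2)
    assert f1.read_bytes() == f2.read_bytes()
    assert t1.features.equals(t2.features)
    r1 = sd.simulate_reads(g1, sd.ReadProfile(target_depth=2), seed=5)
    r2 = sd.simulate_reads(g2, sd.ReadProfile(target_depth=2), seed=5)
    q1, q2 = tmp_path / "a.fq", tmp_path / "b.fq"
    r1.to_fastq(q1), r2.to_fastq(q2)
    assert q1.read_bytes() == q2.read_bytes()


def test_conservation_of_planted_motif_bases():
    """Re-scanning the emitted genome over truth intervals finds every
    planted motif tiling verbatim (base-level conservation)."""
    spec = sd.GenomeSpec(chrom_length=1_000_000, telomere_len=4_000,
                         subtel_blocks=(("pas1", 10_000),),
                         microsat_arrays=(("AAC", 3_000, "interstitial"),),
                         centromere=None, seed=3)
    genome, truth = sd.simulate_genome(spec)
    chrom = genome.chromosomes["chr1"]
    checked = 0
    for _, row in truth.features.iterrows():
        if row.feature_class in ("gap", "telomere"):
            continue  # right telomere is planted reverse-complemented
        seg = chrom[row.start:row.end].tobytes().decode()
        tiled = row.motif * (len(seg) // len(row.motif) + 1)
        assert seg == tiled[:len(seg)]
        checked += 1
    assert checked >= 3


def test_depth_calibration_and_total_bases():
    spec = sd.GenomeSpec(chrom_length=1_000_000, telomere_len=0,
                         subtel_blocks=(), centromere=None, seed=4)
    genome, _ = sd.simulate_genome(spec)
    reads = sd.simulate_reads(genome, sd.ReadProfile(target_depth=30), seed=6)
    assert 28.5e6 <= reads.total_bases <= 31.5e6
    realized = reads.total_bases / genome.total_length
    assert abs(realized - 30) / 30 < 0.05


def test_cp_fraction_matches_request():
    spec = sd.GenomeSpec(chrom_length=500_000, telomere_len=0,
                         subtel_blocks=(), centromere=None, seed=4)
    genome, _ = sd.simulate_genome(spec)
    reads = sd.simulate_reads(
        genome, sd.ReadProfile(target_depth=10, cp_fraction=0.093), seed=8)
    cp_ids = set(reads.provenance.query("is_cp").read_id)
    cp_bases = sum(len(s) for rid, s in reads.reads if rid in cp_ids)
    assert cp_bases / reads.total_bases == pytest.approx(0.093, abs=0.01)


def test_ga_dropout_noop_at_factor_one():
    spec = sd.GenomeSpec(chrom_length=300_000, telomere_len=0,
                         subtel_blocks=(), centromere=None, seed=4)
    genome, _ = sd.simulate_genome(spec)
    reads = sd.simulate_reads(
        genome, sd.ReadProfile(target_depth=50, ga_dropout_factor=1.0),
        seed=9)
    cov = np.zeros(300_001)
    nuc = reads.provenance.query("~is_cp")
    np.add.at(cov, nuc.start.to_numpy(), 1)
    np.add.at(cov, nuc.end.to_numpy(), -1)
    cov = np.cumsum(cov[:-1])
    w = cov[:300_000].reshape(300, 1000).mean(axis=1)
    interior = w[20:-20]  # read-length edge ramps excluded
    assert abs(interior.mean() - 50) / 50 < 0.1


def test_empty_genome_rejected():
    g = sd.Genome({}, {}, np.empty(0, dtype=np.uint8))
    with pytest.raises(ValueError):
        sd.simulate_reads(g, sd.ReadProfile(), seed=0)


def test_profile_validation():
    with pytest.raises(ValueError):
        sd.ReadProfile(target_depth=0)
    with pytest.raises(ValueError):
        sd.ReadProfile(substitution_rate=1.5)
    with pytest.raises(ValueError):
        sd.ReadProfile(ga_dropout_factor=0.0)


def test_packing_error_names_chromosome():
    with pytest.raises(sd.PackingError, match="chr1"):
        sd.simulate_genome(sd.GenomeSpec(chrom_length=300_000, seed=1))


def test_optical_molecule_examples():
    # 20 tandem copies of an 8.9 kb unit, one label site each
    unit = np.frombuffer(sd.MONOMERS["rdna_5h"].encode(), dtype=np.uint8)
    spec = sd.GenomeSpec(chrom_length=500_000, telomere_len=0,
                         subtel_blocks=(), centromere=None, seed=5)
    genome, _ = sd.simulate_genome(spec)
    arr = genome.chromosomes["chr1"]
    arr[100_000:100_000 + 20 * unit.size] = np.tile(unit, 20)
    mols, prov = sd.simulate_optical_molecules(
        genome, stretch=1.048, min_len=150_000, seed=6, coverage=30,
        mol_len_law=("constant", 400_000), jitter_sd=0.0)
    expected = unit.size * 1.048  # 8900 x 1.048 = 9327.2
    spacings = np.concatenate([np.diff(m.labels) for m in mols])
    in_array = spacings[np.abs(spacings - expected) < 100]
    assert in_array.size > 0
    assert np.allclose(in_array, expected, atol=1)
    assert all(m.length >= 150_000 for m in mols)
    # stretch 1, no jitter: coordinates equal motif positions exactly
    mols1, prov1 = sd.simulate_optical_molecules(
        genome, stretch=1.0, min_len=150_000, seed=6, coverage=5,
        mol_len_law=("constant", 400_000), jitter_sd=0.0)
    m = mols1[0]
    src = prov1.set_index("molecule_id").loc[m.molecule_id]
    seg = genome.chromosomes[src.chrom][src.start:src.end]
    expect = sd._find_motif(seg, _seq.to_u8(sd.LABEL_MOTIF))
    assert np.array_equal(m.labels.astype(int), expect)


def test_hic_matrix_construction():
    m = sd.simulate_hic_matrix(60, 20, noise=0.0, seed=0)
    assert np.array_equal(m, m.T)
    assert (m >= 0).all()
    # rabl_weight 0: contacts depend on |i-j| only (no anti-diagonal ridge)
    m0 = sd.simulate_hic_matrix(60, 20, rabl_weight=0.0, noise=0.0, seed=0)
    for d in (3, 11, 25):
        band = np.diagonal(m0, offset=d)
        assert np.allclose(band, band[0])
    # ridge intersects the main diagonal at the centromere bin
    m1 = sd.simulate_hic_matrix(60, 20, rabl_weight=1.0, noise=0.0, seed=0)
    gain = m1 - m0
    assert gain[20, 20] == pytest.approx(gain.max(), rel=1e-9)
    with pytest.raises(ValueError):
        sd.simulate_hic_matrix(10, 10, seed=0)


def test_chip_null_and_extreme_factor(small_genome):
    spec, genome, truth = small_genome
    chip, inp = sd.simulate_chip(genome, truth, {}, depth=1.0, seed=3)
    pc = chip.provenance.true_class.value_counts(normalize=True)
    pi = inp.provenance.true_class.value_counts(normalize=True)
    for cls in pc.index:
        assert pc[cls] == pytest.approx(pi.get(cls, 0.0), abs=0.01)
    chip2, inp2 = sd.simulate_chip(
        genome, truth, {"centromere_satellite": 0.01}, depth=1.0, seed=4)
    c2 = (chip2.provenance.true_class == "centromere_satellite").sum()
    i2 = (inp2.provenance.true_class == "centromere_satellite").sum()
    assert c2 <= 0.02 * i2 + 2  # ~1% of input-proportional expectation


def test_chip_unknown_class_rejected(small_genome):
    spec, genome, truth = small_genome
    with pytest.raises(KeyError):
        sd.simulate_chip(genome, truth, {"no_such_class": 2.0}, depth=0.5,
                         seed=0)
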