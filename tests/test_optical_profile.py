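"""Label-run detection, stretch correction, histograms, locus sizing."""

import numpy as np
import pytest

from repeataudit import optical_profile as op


def mol(intervals, mid="m"):
    labels = np.concatenate([[0.0], np.cumsum(intervals)])
    return op.OpticalMolecule(mid, labels[-1] + 1000, labels)


def oracle_runs(intervals, min_units, tol):
    """Independent enumeration: every interval segment, validity by direct
    median recomputation, maximality by definition."""
    iv = np.asarray(intervals, dtype=float)
    n = iv.size

    def valid(i, j):
        if i < 0 or j > n or j - i < 1:
            return False
        seg = iv[i:j]
        med = np.median(seg)
        return (seg.max() < (1 + tol) * med) and (seg.min() > (1 - tol) * med)

    segs = [(i, j) for i in range(n) for j in range(i + min_units, n + 1)
            if valid(i, j) and not valid(i - 1, j) and not valid(i, j + 1)]
    return [(i, j) for i, j in segs
            if not any((a <= i and j <= b) and (a, b) != (i, j)
                       for a, b in segs)]


def test_uniform_run_detected():
    runs = op.detect_runs(mol([9000.0] * 10))
    assert len(runs) == 1
    r = runs[0]
    assert (r.n_units, r.raw_unit_size) == (10, 9000.0)


def test_outlier_interval_splits_run():
    intervals = [9000.0] * 4 + [11000.0] + [9000.0] * 5
    runs = op.detect_runs(mol(intervals), min_units=6)
    # neither fragment reaches 6 units except the 5-long tail -> at most
    # one run survives, and none spans the outlier
    assert all(not (r.first_label <= 4 < r.last_label) or r.n_units < 6
               for r in runs)
    got = [(r.first_label, r.last_label) for r in runs]
    assert got == oracle_runs(intervals, 6, 0.1)


@pytest.mark.parametrize("pair,expect_run", [
    ((9000.0, 9800.0), True),   # 4.3% from the 9400 median: run survives
    ((9000.0, 11000.0), False),  # exactly 10% from the 10000 median: breaks
])
def test_alternating_intervals_tolerance_boundary(pair, expect_run):
    intervals = list(pair) * 5
    runs = op.detect_runs(mol(intervals), min_units=6, tolerance=0.1)
    assert bool(runs) == expect_run


def test_few_labels_yield_nothing():
    assert op.detect_runs(op.OpticalMolecule("m", 1e5, np.array([5.0]))) == []
    assert op.detect_runs(op.OpticalMolecule("m", 1e5, np.array([]))) == []


def test_runs_agree_with_oracle_on_random_molecules():
    rng = np.random.default_rng(77)
    for _ in range(300):
        n = rng.integers(6, 28)
        # mixture of regular and irregular spacings
        base = rng.uniform(2000, 12000)
        iv = np.where(rng.random(n) < 0.6,
                      base * (1 + rng.normal(0, 0.03, n)),
                      rng.uniform(500, 20000, n))
        runs = op.detect_runs(mol(iv), min_units=6, tolerance=0.1)
        got = sorted((r.first_label, r.last_label) for r in runs)
        assert got == sorted(oracle_runs(iv, 6, 0.1))


def test_stretch_correction():
    assert op.correct_stretch(9450) == pytest.approx(8996.4)
    assert op.correct_stretch(9450, 1.0) == 9450
    assert 1.048 * 0.952 == pytest.approx(1.0, abs=0.003)
    with pytest.raises(ValueError):
        op.correct_stretch(0)


def test_unit_histogram_weights():
    runs = op.correct_runs([op.LabelRun("m", 0, 10, 10, 8900.0)], 1.0)
    h = op.unit_histogram(runs, 100)
    assert h.sum() == 10
    assert h.idxmax() == 8900.0
    assert op.unit_histogram([], 100).empty
    bimodal = op.correct_runs(
        [op.LabelRun("a", 0, 10, 10, 8900.0),
         op.LabelRun("b", 0, 10, 10, 9800.0)], 1.0)
    h2 = op.unit_histogram(bimodal, 100)
    assert h2[8900.0] == h2[9800.0] == 10


def test_size_locus_arithmetic():
    units, size = op.size_locus(565_420, 232, total_bases=5.042e9)
    assert units == pytest.approx(2437.2, rel=1e-3)
    assert size == pytest.approx(21.73e6, rel=1e-3)
    units, size = op.size_locus(192_345, 232, total_bases=1.886e9)
    assert size == pytest.approx(8.129e6, rel=1e-3)
    assert op.size_locus(0, 100, unit_size=9000) == (0, 0)
    with pytest.raises(ValueError):
        op.size_locus(10, 0)


def test_molecule_tsv_roundtrip(tmp_path):
    mols = [op.OpticalMolecule("a", 2e5, np.array([10.0, 9010.0])),
            op.OpticalMolecule("b", 3e5, np.array([]))]
    p = tmp_path / "mols.tsv"
    op.molecules_to_tsv(mols, p)
    back = op.molecules_from_tsv(p)
    assert [m.molecule_id for m in back] == ["a", "b"]
    assert np.allclose(back[0].labels, mols[0].labels, atol=0.1)
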