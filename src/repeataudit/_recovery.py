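"""End-to-end synthetic recovery pipelines.

Shared by the test suite and the acceptance script: each function builds a
synthetic dataset with known ground truth, runs the corresponding analysis
modules, and returns planted vs. estimated quantities.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from . import (abundance, centromere_signals, gap_audit, monomer_align,
               optical_profile, synthetic_data, tandem_scan)

TEL_MOTIF = tandem_scan.canonical_motif("TTTAGGG")  # AAACCCT
SAT_MOTIF = tandem_scan.canonical_motif("AGAGGG")


def _per_read_values(read_ids, mapping) -> np.ndarray:
    return np.array([mapping.get(r, 0.0) for r in read_ids], dtype=float)


def repeat_recovery(seed: int, substitution_rate: float = 0.0,
                    depth: float = 30.0, n_boot: int = 200) -> Dict:
    """Plant telomeres (10 kb/terminus), subtelomeric blocks (200 kb) and a
    satellite+retroelement centromere (500 kb) in a 5 Mb genome, sequence
    at the requested depth, and recover per-class non-redundant sizes.

    Returns per-class dicts {planted, estimated, bootstrap_se}.
    """
    spec = synthetic_data.GenomeSpec(seed=seed)
    genome, truth = synthetic_data.simulate_genome(spec)
    planted = truth.class_bases()
    reads = synthetic_data.simulate_reads(
        genome, synthetic_data.ReadProfile(
            target_depth=depth, substitution_rate=substitution_rate),
        seed=seed + 1)
    realized = reads.total_bases / genome.total_length
    read_ids = [rid for rid, _ in reads.reads]

    arrays, _ = tandem_scan.scan_reads(reads.reads, min_array_len=1000,
                                       max_motif_len=25)
    per_read_by_motif = {}
    if len(arrays):
        g = arrays.groupby(["motif", "sequence_id"])["length"].sum()
        for motif in (TEL_MOTIF, SAT_MOTIF):
            per_read_by_motif[motif] = (g[motif].to_dict()
                                        if motif in g.index.levels[0] else {})
    min_ident = 0.9 if substitution_rate == 0 else 0.85
    hv = monomer_align.align_monomer(
        synthetic_data.MONOMERS["hvt01"], reads.reads,
        monomer_align.FilterPolicy(110, min_ident), "hvt01")
    cer = monomer_align.align_monomer(
        synthetic_data.MONOMERS["cereba"], reads.reads,
        monomer_align.FilterPolicy(800, min_ident), "cereba")
    hv_per_read = monomer_align.cumulative_by_sequence(hv)
    cer_per_read = monomer_align.cumulative_by_sequence(cer)

    tel = _per_read_values(read_ids, per_read_by_motif.get(TEL_MOTIF, {}))
    sat = _per_read_values(read_ids, per_read_by_motif.get(SAT_MOTIF, {}))
    hvv = _per_read_values(read_ids, hv_per_read)
    cen = sat + _per_read_values(read_ids, cer_per_read)

    out = {"realized_depth": realized}
    for name, values, truth_bp in [
            ("telomere", tel, planted["telomere"]),
            ("hvt01", hvv, planted["hvt01"]),
            ("centromere", cen,
             planted["centromere_satellite"] + planted["cereba"])]:
        est = abundance.nonredundant_size(values.sum(), realized).\
            nonredundant_total
        se = abundance.bootstrap_se(values, realized, n_boot=n_boot,
                                    seed=seed + 2)
        out[name] = {"planted": float(truth_bp), "estimated": float(est),
                     "bootstrap_se": float(se)}
    return out


def optical_recovery(seed: int, n_units: int = 300,
                     coverage: float = 200.0) -> Dict:
    """Simulate stretched, labelled molecules over an rDNA array and size
    the locus back from label-spacing runs."""
    unit_len = len(synthetic_data.MONOMERS["rdna_5h"])
    spec = synthetic_data.GenomeSpec(
        chrom_length=4_000_000, telomere_len=0, subtel_blocks=(),
        centromere=None,
        rdna_loci=(synthetic_data.RdnaLocus("rdna_5h", n_units, 0,
                                            600_000),),
        seed=seed)
    genome, truth = synthetic_data.simulate_genome(spec)
    row = truth.features.query("feature_class=='rdna_rdna_5h'").iloc[0]
    mols, prov = synthetic_data.simulate_optical_molecules(
        genome, stretch=1.048, min_len=150_000, seed=seed + 1,
        coverage=coverage)
    runs = optical_profile.profile_molecules(
        mols, min_units=6, tolerance=0.1, coefficient=0.952,
        min_len=150_000)
    totals = optical_profile.class_totals(runs)
    ov = np.maximum(0, np.minimum(prov.end, row.end)
                    - np.maximum(prov.start, row.start))
    locus_cov = float(ov.sum() / (row.end - row.start))
    units_est, locus_bp = optical_profile.size_locus(
        float(totals.total_units[0]), locus_cov,
        total_bases=float(totals.total_bases[0]))
    return {"units_true": n_units, "units_est": units_est,
            "locus_bp_true": float(row.end - row.start),
            "locus_bp_est": locus_bp, "locus_coverage": locus_cov,
            "n_runs": len(runs)}


def centromere_call_accuracy(seed: int, n_matrices: int = 20,
                             n_bins: int = 200, rabl_weight: float = 0.5,
                             noise: float = 0.1) -> Dict:
    """Hi-C directionality calls over simulated Rabl matrices."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_matrices):
        c = int(rng.integers(30, n_bins - 30))
        m = synthetic_data.simulate_hic_matrix(
            n_bins, c, rabl_weight=rabl_weight, noise=noise,
            seed=seed + 100 + i)
        track = centromere_signals.directionality_index(m, window_bins=20)
        b, _ = centromere_signals.call_centromere(track)
        hits += abs(b - c) <= 1
    return {"n_matrices": n_matrices, "within_one_bin": hits}


def chip_recovery(seed: int, factor: float = 11.0,
                  n_read_pairs: int = 50_000) -> Dict:
    """Recover a per-class ChIP/input enrichment factor.

    The enriched class occupies ~0.4% of the genome (as a narrow
    centromeric satellite does); the expected measured ratio is
    factor / (1 + (factor-1) * f) for class fraction f.
    """
    G = 2_000_000
    read_len = 120
    spec = synthetic_data.GenomeSpec(
        chrom_length=G, telomere_len=0, subtel_blocks=(),
        centromere=synthetic_data.CentromereSpec(total_len=8_000,
                                                 n_retro_insertions=0),
        seed=seed)
    genome, truth = synthetic_data.simulate_genome(spec)
    depth = n_read_pairs * read_len / G
    refs = {"centromere_satellite": "AGAGGG" * 20}
    policy = monomer_align.FilterPolicy(100, 0.9)

    def run(factors):
        chip, inp = synthetic_data.simulate_chip(genome, truth, factors,
                                                 depth=depth, seed=seed + 1)
        tab = centromere_signals.class_enrichment(chip.reads, inp.reads,
                                                  refs, policy)
        return float(tab.set_index("repeat_class")
                     .ratio["centromere_satellite"])

    return {"ratio": run({"centromere_satellite": factor}),
            "null_ratio": run({}),
            "class_fraction": 8_000 / G}


def gap_recovery(seed: int) -> Dict:
    """Plant a gap plan and audit it back."""
    plan = (synthetic_data.GapPlan("pericentric", 5_000, 600, "AAG"),
            synthetic_data.GapPlan("pericentric", 3_000, 1_200, "ACT"),
            synthetic_data.GapPlan("distal", 2_000, 800, "AAC"),
            synthetic_data.GapPlan("interstitial", 1_000, 0))
    spec = synthetic_data.GenomeSpec(chrom_length=3_000_000, gap_plan=plan,
                                     seed=seed)
    genome, truth = synthetic_data.simulate_genome(spec)
    planned = sorted(map(tuple, truth.features.query(
        "feature_class=='gap'")[["chrom", "start", "end"]].to_numpy()))
    found = sorted(gap_audit.find_gaps(genome.assembly))
    records = gap_audit.audit_gaps(genome.assembly)
    by_interval = {(r.chromosome, r.start, r.end):
                   (r.classification, r.dominant_motif) for r in records}
    want = {}
    gaps = truth.features.query("feature_class=='gap'")
    flanks = truth.features[
        truth.features.feature_class.str.startswith("gap_flank")]
    for _, g in gaps.iterrows():
        motif = None
        for _, f in flanks.iterrows():
            if f.end == g.start and f.end - f.start >= 500:
                motif = tandem_scan.canonical_motif(f.motif)
        want[(g.chrom, int(g.start), int(g.end))] = (
            ("repeat_adjacent", motif) if motif else ("other", None))
    return {"planned": planned, "found": found,
            "classes_match": by_interval == want,
            "n_gaps": len(found)}
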