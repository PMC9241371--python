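"""Genome size estimation from read depth and k-mer spectra.

Two assembly-free estimators: (i) total sequenced bases divided by the
median alignment depth, with an optional chloroplast-contamination
correction that subtracts the bases of reads mostly alignable to the cp
genome; (ii) a simplified k-mer-spectrum estimator that divides the total
k-mer mass above the error valley by the homozygous-peak depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _seq


@dataclass(frozen=True)
class DepthSummary:
    """Window-depth summary: mean/median depth, and the mode of the
    0.1-fold-binned per-window depth distribution."""

    total_bases: int
    mean_depth: float
    median_depth: float
    mode_depth: float


def depth_summary(window_depths: np.ndarray, total_bases: int
                  ) -> DepthSummary:
    """Summarize per-window (1 kb) depth values."""
    d = np.asarray(window_depths, dtype=float)
    if d.size == 0:
        raise ValueError("no windows")
    binned = np.round(d * 10) / 10
    vals, counts = np.unique(binned, return_counts=True)
    return DepthSummary(int(total_bases), float(d.mean()),
                        float(np.median(d)), float(vals[counts.argmax()]))


def window_depths_from_intervals(intervals_by_chrom: Dict[str, list],
                                 chrom_lengths: Dict[str, int],
                                 window: int = 1_000) -> np.ndarray:
    """Per-window mean depth from read alignment intervals."""
    out = []
    for chrom, L in chrom_lengths.items():
        cov = np.zeros(L + 1, dtype=np.int64)
        for s, e in intervals_by_chrom.get(chrom, []):
            cov[max(0, s)] += 1
            cov[min(L, e)] -= 1
        cov = np.cumsum(cov[:-1])
        n_win = int(np.ceil(L / window))
        pad = n_win * window - L
        w = np.concatenate([cov, np.zeros(pad)]).reshape(n_win, window)
        means = w.sum(axis=1) / np.minimum(
            window, L - np.arange(n_win) * window)
        out.append(means)
    return np.concatenate(out)


def gse_from_depth(total_bases: float, median_depth: float) -> float:
    """Genome size = sequenced base pairs / median depth."""
    if median_depth <= 0:
        raise ValueError("median depth must be > 0")
    return total_bases / median_depth


# ---------------------------------------------------------------------------
# chloroplast correction

def cp_correction(reads: Iterable[Tuple[str, object]], cp_reference,
                  length_fraction: float = 0.9
                  ) -> Tuple[List[str], int, int]:
    """Flag chloroplast reads and correct the sequenced-base total.

    A read is flagged when the merged coverage of its cp-matching 15-mer
    seeds spans >= ``length_fraction`` of the read. Returns
    (flagged_read_ids, corrected_total_bases, total_bases).
    """
    cp = _seq.to_u8(cp_reference)
    if cp.size == 0:
        raise ValueError("cp reference is empty")
    k = 15
    cpc = np.concatenate([cp, _seq.revcomp_arr(cp)])
    codes, valid = _seq.kmer_codes(_seq.base_codes(cpc), k)
    # exclude k-mers spanning the fwd/rev junction
    valid[cp.size - k + 1:cp.size] = False
    table = np.unique(codes[valid])
    flagged, total, flagged_bases = [], 0, 0
    for rid, seq in reads:
        arr = _seq.to_u8(seq)
        total += arr.size
        if arr.size < k:
            continue
        rc, rv = _seq.kmer_codes(_seq.base_codes(arr), k)
        pos = np.flatnonzero(rv)
        if pos.size == 0:
            continue
        j = np.searchsorted(table, rc[pos])
        j = np.minimum(j, table.size - 1)
        hit = pos[table[j] == rc[pos]]
        if hit.size == 0:
            continue
        cov = sum(e - s for s, e in _seq.merge_intervals(
            [(int(p), int(p) + k) for p in hit]))
        if cov / arr.size >= length_fraction:
            flagged.append(rid)
            flagged_bases += arr.size
    return flagged, total - flagged_bases, total


# ---------------------------------------------------------------------------
# k-mer spectrum

def kmer_spectrum(reads: Iterable[Tuple[str, object]], k: int = 21
                  ) -> Dict[int, int]:
    """Multiplicity histogram of distinct canonical k-mers over a read set.

    K-mers are strand-canonicalized (min of code and reverse-complement
    code), as is standard for k-mer counters, so reads from either strand
    increment the same species.
    """
    if k % 2 == 0 or not 15 <= k <= 31:
        raise ValueError("k must be odd and in [15, 31] for spectra")
    chunks = []
    for _, seq in reads:
        arr = _seq.to_u8(seq)
        codes, valid = _seq.kmer_codes(_seq.base_codes(arr), k)
        chunks.append(_seq.canonical_kmer_codes(codes[valid], k))
    if not chunks:
        return {}
    allk = np.concatenate(chunks)
    _, counts = np.unique(allk, return_counts=True)
    mult, n = np.unique(counts, return_counts=True)
    return {int(m): int(c) for m, c in zip(mult, n)}


def gse_from_kmers(reads: Iterable[Tuple[str, object]], k: int = 21,
                   spectrum: Optional[Dict[int, int]] = None
                   ) -> Tuple[float, Dict[str, float]]:
    """Simplified k-mer-spectrum genome size estimate.

    The error cutoff is the first local minimum of the (smoothed) spectrum;
    the homozygous peak is the smoothed mode above it. Because a finite
    read sample makes the raw histogram lumpy, the peak depth is refined to
    the count-weighted mean multiplicity over the window
    [max(cutoff, mode/2), 1.5 x mode] rather than the raw mode. GSE =
    (sum of multiplicity x count at multiplicities >= cutoff) / peak
    depth. Raises ValueError("spectrum uninformative") when no peak rises
    above the error valley (high-error read sets).
    """
    if spectrum is None:
        spectrum = kmer_spectrum(reads, k)
    if not spectrum:
        raise ValueError("spectrum uninformative")
    maxm = max(spectrum)
    h = np.zeros(maxm + 2)
    for m, c in spectrum.items():
        h[m] = c
    # moving-average smoothing for valley/mode detection only
    w = 5
    kern = np.ones(w) / w
    hs = np.convolve(h, kern, mode="same")
    valley = None
    for m in range(1, maxm):
        if hs[m] < hs[m + 1]:
            valley = m
            break
    if valley is None:
        # monotone spectrum: no error component to cut away
        cutoff = 1
        peak_mode = int(np.argmax(hs[1:maxm + 1]) + 1)
    else:
        cutoff = valley
        rest = hs[valley + 1:maxm + 1]
        if rest.size == 0 or rest.max() <= 0:
            raise ValueError("spectrum uninformative")
        peak_mode = valley + 1 + int(np.argmax(rest))
        if hs[peak_mode] <= hs[valley]:
            raise ValueError("spectrum uninformative")
    lo = max(cutoff, int(peak_mode * 0.5))
    hi = min(maxm, int(np.ceil(peak_mode * 1.5)))
    ms = np.arange(lo, hi + 1)
    wts = h[lo:hi + 1]
    peak_depth = float((ms * wts).sum() / wts.sum()) if wts.sum() else \
        float(peak_mode)
    mass = sum(m * c for m, c in spectrum.items() if m >= cutoff)
    gse = mass / peak_depth
    return gse, {"cutoff": float(cutoff), "peak_mode": float(peak_mode),
                 "peak_depth": peak_depth, "kmer_mass": float(mass)}


def spectrum_to_tsv(spectrum: Dict[int, int], path) -> None:
    pd.DataFrame(sorted(spectrum.items()),
                 columns=["multiplicity", "count"]).to_csv(
        path, sep="\t", index=False)
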