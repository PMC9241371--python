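"""Anchor-based placement of repeat-bearing reads on an assembly.

A read is placed by assembly-unique k-mers (default k=51, identified via a
64-bit rolling hash): if at least three unique anchors agree on one offset
(within +/-500 bp) on one strand the read is "unique"; conflicting anchor
clusters make it "ambiguous"; otherwise it is "unplaced". The
unique/ambiguous/unplaced trichotomy stands in for mapping-quality cuts of
a full aligner. Placements can be aggregated in genomic windows and
classified by distance to annotated features (e.g. centromere gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _seq

ANCHOR_AGREE_BP = 500
MIN_ANCHORS = 3


@dataclass(frozen=True)
class Placement:
    read_id: str
    chrom: str  # chromosome name or "unplaced"
    position: int  # leftmost placed bp (-1 when not placed)
    confidence: str  # unique | ambiguous | unplaced


@dataclass
class FeatureSet:
    """Named intervals per chromosome (0-based, half-open)."""

    intervals: Dict[str, List[Tuple[int, int]]]


class AnchorIndex:
    """Assembly-unique k-mer index (hash -> single location)."""

    def __init__(self, assembly: Dict[str, object], k: int = 51):
        if k < 31:
            raise ValueError("anchor k must be >= 31")
        self.k = k
        hashes, chrom_ids, positions = [], [], []
        self.chrom_names = []
        any_long_enough = False
        for ci, (name, seq) in enumerate(assembly.items()):
            arr = _seq.to_u8(seq)
            self.chrom_names.append(name)
            if arr.size < k:
                continue
            any_long_enough = True
            h, valid = _seq.kmer_hashes(_seq.base_codes(arr), k)
            idx = np.flatnonzero(valid)
            hashes.append(h[idx])
            chrom_ids.append(np.full(idx.size, ci, dtype=np.int32))
            positions.append(idx.astype(np.int64))
        if not any_long_enough:
            raise ValueError("assembly shorter than anchor k")
        h = np.concatenate(hashes)
        c = np.concatenate(chrom_ids)
        p = np.concatenate(positions)
        order = np.argsort(h, kind="stable")
        h, c, p = h[order], c[order], p[order]
        uniq_first = np.concatenate(([True], h[1:] != h[:-1]))
        grp = np.cumsum(uniq_first) - 1
        counts = np.bincount(grp)
        singletons = counts[grp] == 1
        self.hashes = h[singletons]
        self.chroms = c[singletons]
        self.positions = p[singletons]

    def lookup(self, read_arr: np.ndarray):
        """(chrom_id, assembly_pos, read_pos) for every unique-anchor hit."""
        h, valid = _seq.kmer_hashes(_seq.base_codes(read_arr), self.k)
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            return (np.empty(0, np.int32), np.empty(0, np.int64),
                    np.empty(0, np.int64))
        hh = h[idx]
        j = np.searchsorted(self.hashes, hh)
        j = np.minimum(j, self.hashes.size - 1)
        hit = self.hashes[j] == hh
        return self.chroms[j[hit]], self.positions[j[hit]], idx[hit]


def _cluster_offsets(chroms, offsets) -> List[Tuple[int, int, int]]:
    """Greedy offset clustering per chromosome: (chrom, offset, n)."""
    out = []
    for c in np.unique(chroms):
        off = np.sort(offsets[chroms == c])
        start = 0
        for i in range(1, off.size + 1):
            if i == off.size or off[i] - off[i - 1] > ANCHOR_AGREE_BP:
                seg = off[start:i]
                out.append((int(c), int(np.median(seg)), seg.size))
                start = i
    return out


def place_reads(reads: Iterable[Tuple[str, object]],
                assembly: Dict[str, object], k: int = 51,
                index: Optional[AnchorIndex] = None) -> List[Placement]:
    """Place reads on the assembly by unique k-mer anchors (both strands)."""
    if index is None:
        index = AnchorIndex(assembly, k)
    placements = []
    for rid, seq in reads:
        arr = _seq.to_u8(seq)
        clusters = []
        for orient_arr in (arr, _seq.revcomp_arr(arr)):
            c, p, r = index.lookup(orient_arr)
            if c.size:
                clusters.extend(_cluster_offsets(c, p - r))
        big = [cl for cl in clusters if cl[2] >= MIN_ANCHORS]
        n_anchors = sum(cl[2] for cl in clusters)
        if len(big) == 1:
            ci, off, _ = big[0]
            placements.append(Placement(rid, index.chrom_names[ci],
                                        max(0, off), "unique"))
        elif len(big) > 1 or n_anchors >= MIN_ANCHORS:
            placements.append(Placement(rid, "unplaced", -1, "ambiguous"))
        else:
            placements.append(Placement(rid, "unplaced", -1, "unplaced"))
    return placements


def window_counts(placements: Sequence[Placement], window: int,
                  chrom_lengths: Dict[str, int]) -> pd.DataFrame:
    """Counts of uniquely placed reads per genomic window.

    The counts sum to the number of unique placements.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    rows = []
    by_chrom: Dict[str, list] = {c: [] for c in chrom_lengths}
    for p in placements:
        if p.confidence == "unique" and p.chrom in by_chrom:
            by_chrom[p.chrom].append(min(p.position,
                                         chrom_lengths[p.chrom] - 1))
    for chrom, L in chrom_lengths.items():
        n_win = max(1, int(np.ceil(L / window)))
        counts = np.bincount(np.array(by_chrom[chrom], dtype=int) // window,
                             minlength=n_win) if by_chrom[chrom] else \
            np.zeros(n_win, dtype=int)
        for w in range(n_win):
            rows.append((chrom, w * window, min((w + 1) * window, L),
                         int(counts[w])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def classify_by_feature_distance(placements: Sequence[Placement],
                                 features: FeatureSet,
                                 radius: int) -> Dict[str, float]:
    """Fractions of reads near/far from features, or unplaced.

    Distance is from the placement position to the nearest feature interval
    edge (0 inside an interval); ties at exactly ``radius`` count as near.
    Ambiguous placements count with the unplaced fraction. The three
    fractions sum to 1 over the classified reads; NaN fractions when there
    are no placements.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    counts = {"near": 0, "far": 0, "unplaced": 0}
    for p in placements:
        if p.confidence != "unique":
            counts["unplaced"] += 1
            continue
        dmin = np.inf
        for s, e in features.intervals.get(p.chrom, []):
            d = max(0, s - p.position, p.position - e)
            dmin = min(dmin, d)
        counts["near" if dmin <= radius else "far"] += 1
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: v / total for k, v in counts.items()}


def placements_to_bed(placements: Sequence[Placement], path,
                      read_lengths: Optional[Dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        for p in placements:
            if p.confidence != "unique":
                continue
            ln = read_lengths.get(p.read_id, 1) if read_lengths else 1
            fh.write(f"{p.chrom}\t{p.position}\t{p.position + ln}\t"
                     f"{p.read_id}\t{p.confidence}\n")
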