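"""Centromere localization from Hi-C directionality and ChIP enrichment.

The directionality index (DI) records, per matrix bin, the imbalance
between upstream and downstream contact sums over a flanking window; in a
Rabl-configured genome its sign flips sharply at the centromere, where the
Hi-C anti-diagonal crosses the main diagonal. ChIP/input enrichment per
repeat class is computed from normalized read counts after assigning each
read to the class of its best qualifying monomer alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import monomer_align, read_place


@dataclass(frozen=True)
class DirectionalityTrack:
    bin_size: int
    window_bins: int
    di: np.ndarray


def directionality_index(matrix: np.ndarray, window_bins: int = 20,
                         bin_size: int = 1_000_000) -> DirectionalityTrack:
    """Signed up/downstream contact imbalance per bin.

    For bin b with A = contacts to [b-w, b), B = contacts to (b, b+w],
    E = (A+B)/2: DI(b) = sign(B-A) * ((A-E)^2 + (B-E)^2) / E, and 0 when
    E = 0 or A = B. Edge bins use symmetrically truncated windows
    (w_eff = min(w, b, n-1-b)) so a uniform matrix yields DI = 0
    everywhere.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = m.shape[0]
    di = np.zeros(n)
    for b in range(n):
        w = min(window_bins, b, n - 1 - b)
        if w == 0:
            continue
        a = m[b, b - w:b].sum()
        bsum = m[b, b + 1:b + w + 1].sum()
        e = (a + bsum) / 2.0
        if e == 0 or a == bsum:
            continue
        di[b] = np.sign(bsum - a) * ((a - e) ** 2 + (bsum - e) ** 2) / e
    return DirectionalityTrack(bin_size, window_bins, di)


def call_centromere(track: DirectionalityTrack) -> Tuple[int, float]:
    """Centromere bin from the largest sign-changing DI jump.

    Among transitions b -> b+1 where DI changes sign, picks the one with
    the largest |DI(b+1) - DI(b)| (ties to the lowest coordinate) and
    returns (bin, jump magnitude); the bin is the transition endpoint whose
    DI is closer to zero (the crossing bin). Raises when DI never changes
    sign — callers should treat a small jump magnitude as an unreliable
    call.
    """
    di = track.di
    if di.size == 0:
        raise ValueError("empty track")
    prod = di[:-1] * di[1:]
    cand = np.flatnonzero(prod < 0)
    if cand.size == 0:
        raise ValueError("no discontinuity")
    jumps = np.abs(di[cand + 1] - di[cand])
    best = cand[int(np.argmax(jumps))]
    b = best if abs(di[best]) <= abs(di[best + 1]) else best + 1
    return int(b), float(jumps.max())


# ---------------------------------------------------------------------------
# ChIP enrichment

def assign_read_class(reads: Iterable[Tuple[str, object]],
                      repeat_references: Dict[str, str],
                      policy: monomer_align.FilterPolicy) -> Dict[str, str]:
    """Best qualifying repeat class per read ("background" if none).

    Reads are matched against every reference; the class of the hit with
    the most aligned columns (then highest identity) wins.
    """
    best: Dict[str, Tuple[float, float, str]] = {}
    reads = list(reads)
    for cls, mono in repeat_references.items():
        hits = monomer_align.align_monomer(mono, reads, policy,
                                           monomer_id=cls)
        for h in hits:
            key = (h.length, h.identity, cls)
            if h.sequence_id not in best or key > best[h.sequence_id]:
                best[h.sequence_id] = key
    return {rid: (best[rid][2] if rid in best else "background")
            for rid, _ in reads}


def class_enrichment(chip_reads: Iterable[Tuple[str, object]],
                     input_reads: Iterable[Tuple[str, object]],
                     repeat_references: Dict[str, str],
                     policy: monomer_align.FilterPolicy) -> pd.DataFrame:
    """ChIP/input enrichment ratio of normalized read counts per class.

    ratio = (chip_count/chip_total) / (input_count/input_total); NaN when a
    class has no input reads, 0 when it has no ChIP reads.
    """
    chip_reads, input_reads = list(chip_reads), list(input_reads)
    if not chip_reads or not input_reads:
        raise ValueError("both read sets must be non-empty")
    chip_cls = assign_read_class(chip_reads, repeat_references, policy)
    inp_cls = assign_read_class(input_reads, repeat_references, policy)
    classes = sorted(set(repeat_references) | {"background"})
    chip_tot, inp_tot = len(chip_reads), len(input_reads)
    if inp_tot == 0:
        raise ValueError("zero input total")
    rows = []
    for cls in classes:
        cc = sum(1 for v in chip_cls.values() if v == cls)
        ic = sum(1 for v in inp_cls.values() if v == cls)
        if ic == 0:
            ratio = float("nan")
        else:
            ratio = (cc / chip_tot) / (ic / inp_tot)
        rows.append((cls, cc, ic, ratio))
    return pd.DataFrame(rows, columns=["repeat_class", "chip_count",
                                       "input_count", "ratio"])


def window_coverage(chip_placements: Sequence[read_place.Placement],
                    input_placements: Sequence[read_place.Placement],
                    chrom_lengths: Dict[str, int],
                    window: int = 1_000,
                    read_lengths: Optional[Dict[str, int]] = None
                    ) -> pd.DataFrame:
    """Windowed counts of uniquely placed, deduplicated ChIP/input reads.

    Duplicates are collapsed on identical (chromosome, position, length).
    """
    def dedup(placements):
        seen = set()
        out = []
        for p in placements:
            if p.confidence != "unique":
                continue
            ln = read_lengths.get(p.read_id, 0) if read_lengths else 0
            key = (p.chrom, p.position, ln)
            if key in seen:
                continue
            seen.add(key)
            out.append(p)
        return out

    chip = read_place.window_counts(dedup(chip_placements), window,
                                    chrom_lengths)
    inp = read_place.window_counts(dedup(input_placements), window,
                                   chrom_lengths)
    chip = chip.rename(columns={"count": "chip_count"})
    chip["input_count"] = inp["count"]
    return chip
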