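"""Tandem repeat array detection on reads and contigs.

Detects maximal tandem arrays with motifs up to 2 kb, reports them with
canonical motifs (lexicographically minimal over all rotations of the motif
and of its reverse complement), fractional copy numbers (interval length /
motif length) and purity (fraction of bases matching the ideal array built
from the consensus motif).

The detector seeds candidate periods by direct lag self-comparison for small
periods and by exact 21-mer recurrence for larger ones, then extends while
windowed purity stays above the configured minimum. It is deliberately
simpler than full alignment-based repeat finders: on clean arrays it recovers
planted intervals exactly, which is the contract the rest of the package
relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _seq

logger = logging.getLogger(__name__)

#: Periods up to this bound are sought by direct lag comparison.
SMALL_PERIOD_MAX = 60
#: Runs of at least this many Ns split a sequence before scanning.
N_SPLIT_RUN = 10


@dataclass(frozen=True)
class RepeatArray:
    """A detected tandem array on one sequence (0-based, half-open)."""

    sequence_id: str
    start: int
    end: int
    motif: str
    copy_count: float
    purity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat motif.

    The lexicographically minimal sequence among all cyclic rotations of the
    motif and of its reverse complement; e.g. GAG, CTC, CCT, TCC and GGA all
    canonicalize to AGG. Idempotent.
    """
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    if set(motif) - set("ACGTN"):
        raise ValueError(f"motif contains non-ACGTN characters: {motif!r}")
    best = None
    for s in (motif, _seq.revcomp(motif)):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i:i + len(s)]
            if best is None or rot < best:
                best = rot
    return best


# ---------------------------------------------------------------------------
# detection internals

def _consensus(seg: np.ndarray, a: int, b: int, period: int,
               phase: int) -> np.ndarray:
    """Majority-vote consensus motif of seg[a:b] at the given period.

    ``phase`` anchors column 0; column of position i is (i - phase) % period.
    """
    idx = np.arange(a, b)
    cols = (idx - phase) % period
    codes = _seq.base_codes(seg[a:b])
    counts = np.zeros((period, 4), dtype=np.int64)
    ok = codes < 4
    np.add.at(counts, (cols[ok], codes[ok].astype(np.int64)), 1)
    cons_codes = counts.argmax(axis=1)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[cons_codes]


def _refine(seg: np.ndarray, a0: int, b0: int, period: int,
            min_purity: float) -> Tuple[int, int, float, np.ndarray] | None:
    """Polish a candidate [a0, b0) with known period into exact bounds.

    Builds the consensus from the candidate core, extends both ends while the
    match score (match - min_purity) stays profitable, then trims mismatching
    boundary bases. Returns (start, end, purity, consensus) or None.
    """
    L = seg.size
    margin = max(2 * period, 128)
    lo = max(0, a0 - margin)
    hi = min(L, b0 + margin)
    cons = _consensus(seg, a0, min(b0, L), period, a0)
    idx = np.arange(lo, hi)
    match = (seg[lo:hi] == cons[(idx - a0) % period])

    score = match.astype(np.float64) - min_purity
    # extend left from a0
    left = score[:a0 - lo][::-1]
    csum = np.cumsum(left)
    ext_l = int(np.argmax(csum)) + 1 if left.size and csum.max() > 0 else 0
    right = score[b0 - lo:]
    csum = np.cumsum(right)
    ext_r = int(np.argmax(csum)) + 1 if right.size and csum.max() > 0 else 0
    s, e = a0 - ext_l, b0 + ext_r
    # snap boundaries to a short run of exact matches so that arrays do not
    # bleed into flanking sequence whose first base happens to continue the
    # pattern
    w = max(1, min(6, period, (e - s) // 2))
    cm = np.concatenate(([0], np.cumsum(match, dtype=np.int64)))
    run_ok = (cm[w:] - cm[:-w]) == w  # run_ok[i]: match[i:i+w] all True
    i0, i1 = s - lo, e - lo  # candidate bounds, relative
    starts = np.flatnonzero(run_ok[i0:max(i0, i1 - w + 1)])
    if starts.size == 0:
        return None
    s = lo + i0 + int(starts[0])
    e = lo + i0 + int(starts[-1]) + w
    if e - s < 2 * period:
        return None
    purity = float(np.mean(match[s - lo:e - lo]))
    if purity < min_purity:
        return None
    # rotate consensus so it reads from the array start
    rot = (s - a0) % period
    return s, e, purity, np.concatenate([cons[rot:], cons[:rot]])


def _candidate_regions(m: np.ndarray, thr: float, w: int,
                       min_len: int) -> np.ndarray:
    """Intervals where the moving average of match array m exceeds thr.

    Regions separated by short sub-threshold dips (local error clusters in
    an otherwise continuous array) are bridged before length filtering.
    """
    if m.size < w:
        return np.empty((0, 2), dtype=np.int64)
    c = np.concatenate(([0], np.cumsum(m, dtype=np.int64)))
    avg = (c[w:] - c[:-w]) / w
    regions = _seq.runs_true(avg >= thr)
    if regions.size == 0:
        return regions
    bridge = max(48, 3 * w)
    merged = [list(regions[0])]
    for a, b in regions[1:]:
        if a - merged[-1][1] <= bridge:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    regions = np.array(merged, dtype=np.int64)
    return regions[(regions[:, 1] + w - regions[:, 0]) >= min_len * 0.5]


def _small_period_candidates(seg: np.ndarray, is_n: np.ndarray, pmax: int,
                             min_array_len: int, min_purity: float) -> list:
    out = []
    thr = max(2.0 * min_purity - 1.0, 0.55)
    for p in range(1, pmax + 1):
        if seg.size < max(2 * p, min_array_len):
            break
        m = (seg[p:] == seg[:-p]) & ~is_n[p:] & ~is_n[:-p]
        w = min(max(16, 2 * p), m.size)
        for a, b in _candidate_regions(m, thr, w, min_array_len):
            ref = _refine(seg, int(a), int(min(b + w + p, seg.size)), p,
                          min_purity)
            if ref is not None:
                out.append((*ref[:3], p, ref[3]))
    return out


def _long_period_candidates(seg: np.ndarray, max_motif_len: int,
                            min_array_len: int, min_purity: float) -> list:
    k = 21
    if seg.size < 2 * SMALL_PERIOD_MAX:
        return []
    codes = _seq.base_codes(seg)
    km, valid = _seq.kmer_codes(codes, k)
    pos = np.flatnonzero(valid)
    if pos.size < 2:
        return []
    order = np.argsort(km[pos], kind="stable")
    cs = km[pos][order]
    ps = pos[order]
    same = cs[1:] == cs[:-1]
    d = ps[1:] - ps[:-1]
    sel = same & (d > SMALL_PERIOD_MAX) & (d <= max_motif_len)
    if not np.any(sel):
        return []
    periods = d[sel]
    votes = ps[:-1][sel]
    out = []
    uniq, counts = np.unique(periods, return_counts=True)
    for p, c in zip(uniq, counts):
        if c < 3:
            continue
        v = np.sort(votes[periods == p])
        # cluster votes separated by more than one unit
        breaks = np.flatnonzero(np.diff(v) > p + k)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [v.size]))
        for s_i, e_i in zip(starts, ends):
            a = int(v[s_i])
            b = int(min(v[e_i - 1] + p + k, seg.size))
            if b - a < max(2 * p, min_array_len) * 0.8:
                continue
            ref = _refine(seg, a, b, int(p), min_purity)
            if ref is not None:
                out.append((*ref[:3], int(p), ref[3]))
    return out


def _overlaps(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _resolve_overlaps(cands: list) -> list:
    """Non-overlapping selection; prefer the smallest period whose purity is
    within 0.02 of the local maximum (primitive motif over its multiples)."""
    chosen = []
    cands = list(cands)
    while cands:
        seed = max(cands, key=lambda c: c[2] - c[1])
        cluster = [c for c in cands if _overlaps((c[0], c[1]), (seed[0], seed[1]))]
        maxpur = max(c[2] for c in cluster)
        best = min((c for c in cluster if c[2] >= maxpur - 0.02),
                   key=lambda c: (c[3], -(c[1] - c[0]), c[0]))
        chosen.append(best)
        cands = [c for c in cands if not _overlaps((c[0], c[1]),
                                                   (best[0], best[1]))]
    return sorted(chosen, key=lambda c: c[0])


def find_arrays(sequence, min_array_len: int = 1000,
                max_motif_len: int = 2000, min_purity: float = 0.8,
                sequence_id: str = "seq") -> List[RepeatArray]:
    """Detect maximal tandem repeat arrays in one sequence.

    Parameters
    ----------
    sequence : str, bytes or uint8 array
    min_array_len : minimum reported array length in bp
    max_motif_len : largest period considered (capped at 2000)
    min_purity : minimum fraction of bases matching the ideal array

    Returns non-overlapping :class:`RepeatArray` records sorted by start.
    Arrays are split at runs of >= 10 Ns; N never matches.
    """
    if max_motif_len > 2000:
        raise ValueError("max_motif_len must be <= 2000")
    arr = _seq.to_u8(sequence)
    out: List[RepeatArray] = []
    # split at long N runs
    is_n_full = _seq.base_codes(arr) >= 4
    nruns = [(a, b) for a, b in _seq.runs_true(is_n_full) if b - a >= N_SPLIT_RUN]
    bounds = [0] + [x for ab in nruns for x in ab] + [arr.size]
    for off, stop in zip(bounds[::2], bounds[1::2]):
        seg = arr[off:stop]
        if seg.size < min_array_len or seg.size < 2:
            continue
        is_n = is_n_full[off:stop]
        cands = _small_period_candidates(
            seg, is_n, min(SMALL_PERIOD_MAX, max_motif_len),
            min_array_len, min_purity)
        if max_motif_len > SMALL_PERIOD_MAX:
            cands += _long_period_candidates(seg, max_motif_len,
                                             min_array_len, min_purity)
        cands = [c for c in cands if c[1] - c[0] >= min_array_len]
        for s, e, pur, p, cons in _resolve_overlaps(cands):
            out.append(RepeatArray(
                sequence_id=sequence_id, start=off + s, end=off + e,
                motif=canonical_motif(_seq.to_str(cons)),
                copy_count=(e - s) / p, purity=pur))
    return out


def scan_reads(reads: Iterable[Tuple[str, object]],
               min_array_len: int = 1000,
               thresholds: Sequence[int] = (1000, 10000),
               max_motif_len: int = 50,
               min_purity: float = 0.8):
    """Scan a read set for tandem arrays and summarize.

    Parameters
    ----------
    reads : iterable of (read_id, sequence)
    thresholds : array-length cutoffs for the reads-exceeding counts

    Returns
    -------
    (arrays, summary) : (pandas.DataFrame, dict)
        ``arrays`` has one row per detected array (sequence_id, start, end,
        motif, copy_count, purity). ``summary`` holds per-read maximal array
        length, cumulative array length per canonical motif, counts of reads
        exceeding each threshold, and the number of skipped records.
    """
    rows = []
    per_read_max = {}
    skipped = 0
    for rec in reads:
        try:
            read_id, seq = rec
            arrays = find_arrays(seq, min_array_len=min_array_len,
                                 max_motif_len=max_motif_len,
                                 min_purity=min_purity, sequence_id=read_id)
        except Exception as exc:  # unreadable record: skip, keep going
            logger.warning("skipping unreadable record: %s", exc)
            skipped += 1
            continue
        per_read_max[read_id] = max((a.length for a in arrays), default=0)
        for a in arrays:
            rows.append((a.sequence_id, a.start, a.end, a.motif,
                         a.copy_count, a.purity))
    arrays_df = pd.DataFrame(
        rows, columns=["sequence_id", "start", "end", "motif",
                       "copy_count", "purity"])
    if len(arrays_df):
        arrays_df["length"] = arrays_df.end - arrays_df.start
        cum_by_motif = arrays_df.groupby("motif")["length"].sum().to_dict()
    else:
        arrays_df["length"] = pd.Series(dtype=int)
        cum_by_motif = {}
    summary = {
        "per_read_max": per_read_max,
        "cumulative_by_motif": cum_by_motif,
        "reads_exceeding": {
            int(t): int(sum(v >= t for v in per_read_max.values()))
            for t in thresholds},
        "skipped": skipped,
    }
    if skipped:
        logger.warning("scan_reads skipped %d unreadable records", skipped)
    return arrays_df, summary


def arrays_to_tsv(arrays: Iterable[RepeatArray], path) -> None:
    pd.DataFrame(
        [(a.sequence_id, a.start, a.end, a.motif, a.copy_count, a.purity)
         for a in arrays],
        columns=["sequence_id", "start", "end", "motif", "copy_count",
                 "purity"],
    ).to_csv(path, sep="\t", index=False)
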