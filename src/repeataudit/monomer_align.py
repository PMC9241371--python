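"""Quantification of known repeat monomers on reads and assemblies.

Monomers (subtelomeric satellites, retrotransposon domains, rDNA units, 5S)
are located by exact 11-mer seeding on both strands followed by edit-distance
verification with edlib. Hits are filtered by an explicit per-monomer policy
(minimum alignment length and identity), merged for cumulative-length
accounting, and counted separately for copy-number summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from . import _seq

logger = logging.getLogger(__name__)

SEED_K = 11


@dataclass(frozen=True)
class FilterPolicy:
    """Alignment acceptance policy: minimum length (bp) and identity."""

    min_alignment_len: int
    min_identity: float = 0.0

    def __post_init__(self):
        if self.min_alignment_len < 1:
            raise ValueError("min_alignment_len must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


@dataclass(frozen=True)
class MonomerHit:
    """One local alignment of a monomer to a sequence (0-based, half-open)."""

    monomer_id: str
    sequence_id: str
    start: int
    end: int
    identity: float
    strand: str  # "+" or "-"

    @property
    def length(self) -> int:
        return self.end - self.start


class _SeedIndex:
    """Sorted seed k-mer table of one monomer strand."""

    def __init__(self, monomer_arr: np.ndarray, max_offsets_per_seed: int = 8):
        codes, valid = _seq.kmer_codes(_seq.base_codes(monomer_arr), SEED_K)
        pos = np.flatnonzero(valid)
        order = np.argsort(codes[pos], kind="stable")
        c = codes[pos][order]
        p = pos[order]
        # cap offsets per seed (periodic monomers repeat their k-mers);
        # kept offsets are spread evenly so the seed extent still spans the
        # whole monomer
        keep = np.ones(c.size, dtype=bool)
        if c.size:
            newgrp = np.concatenate(([True], c[1:] != c[:-1]))
            starts = np.flatnonzero(newgrp)
            sizes = np.diff(np.concatenate((starts, [c.size])))
            for st, g in zip(starts, sizes):
                if g > max_offsets_per_seed:
                    sel = np.round(np.linspace(0, g - 1,
                                               max_offsets_per_seed)
                                   ).astype(int)
                    mask = np.zeros(g, dtype=bool)
                    mask[sel] = True
                    keep[st:st + g] = mask
        self.codes = c[keep]
        self.offsets = p[keep]

    def diagonals(self, read_codes: np.ndarray, read_valid: np.ndarray):
        """Per-diagonal seed clusters for one read.

        Returns (diagonal, support, qmin, qmax) arrays, where qmin/qmax is
        the monomer-offset extent of the seeds supporting each diagonal.
        """
        empty = np.empty(0, dtype=np.int64)
        rpos = np.flatnonzero(read_valid)
        if rpos.size == 0 or self.codes.size == 0:
            return empty, empty, empty, empty
        rc = read_codes[rpos]
        lo = np.searchsorted(self.codes, rc, side="left")
        hi = np.searchsorted(self.codes, rc, side="right")
        n = hi - lo
        hitmask = n > 0
        if not np.any(hitmask):
            return empty, empty, empty, empty
        rsel = rpos[hitmask]
        lo, n = lo[hitmask], n[hitmask]
        # expand (read_pos, monomer_offset) pairs
        total = int(n.sum())
        idx = np.repeat(lo, n) + (np.arange(total)
                                  - np.repeat(np.cumsum(n) - n, n))
        q = self.offsets[idx].astype(np.int64)
        r = np.repeat(rsel, n).astype(np.int64)
        d = r - q
        order = np.argsort(d, kind="stable")
        d, q = d[order], q[order]
        newgrp = np.concatenate(([True], d[1:] != d[:-1]))
        gid = np.cumsum(newgrp) - 1
        ngrp = gid[-1] + 1
        support = np.bincount(gid, minlength=ngrp)
        qmin = np.full(ngrp, np.iinfo(np.int64).max, dtype=np.int64)
        qmax = np.full(ngrp, -1, dtype=np.int64)
        np.minimum.at(qmin, gid, q)
        np.maximum.at(qmax, gid, q)
        return d[newgrp], support, qmin, qmax


#: Extension beyond the seed-supported monomer extent when verifying (bp).
_EXT_MARGIN = 30


_CIGAR_RE = None


def _local_trim(cigar: str):
    """Best-scoring local sub-alignment of an edlib path.

    Scores +1 per match column and -2 per mismatch/gap column (BLAST-like)
    and keeps the maximal-scoring contiguous block, so forced terminal
    mismatch or gap runs from glocal verification are trimmed away.

    Returns (t_offset, t_used, columns, matches) of the kept block, where
    t_offset/t_used are in target (read) coordinates relative to the
    alignment start.
    """
    global _CIGAR_RE
    if _CIGAR_RE is None:
        import re
        _CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
    runs = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    scores = [(n if op == "=" else -2 * n) for n, op in runs]
    # Kadane over whole runs (optimal blocks start/end on match runs)
    best = (0, 0, 0)  # score, start_run, end_run (half-open)
    cur, cur_start = 0, 0
    for i, sc in enumerate(scores):
        if cur <= 0:
            cur, cur_start = 0, i
        cur += sc
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
    _, r0, r1 = best
    t_off = sum(n for n, op in runs[:r0] if op in "=XDM")
    t_used = cols = matches = 0
    for n, op in runs[r0:r1]:
        cols += n
        if op in "=XDM":
            t_used += n
        if op == "=":
            matches += n
    return t_off, t_used, cols, matches


def _identity_hit(read_arr, mono_arr, d, policy, qmin, qmax):
    """Verify one candidate diagonal; return (start, end, identity,
    alignment columns) or None.

    The query is the monomer clipped to the seed-supported extent plus a
    margin; the resulting alignment is end-trimmed to its best local block.
    Identity counts gap columns as non-matches.
    """
    rl, ml = read_arr.size, mono_arr.size
    q_s = max(0, int(qmin) - _EXT_MARGIN)
    q_e = min(ml, int(qmax) + SEED_K + _EXT_MARGIN)
    # clip to the part of the monomer that projects onto the read
    q_s = max(q_s, -d)
    q_e = min(q_e, rl - d)
    if q_e - q_s < min(policy.min_alignment_len, ml, rl):
        return None
    query = mono_arr[q_s:q_e].tobytes()
    ov_s, ov_e = d + q_s, d + q_e
    # window generous enough to absorb length differences between monomer
    # variants (indel-divergent copies)
    slack = max(72, (q_e - q_s) // 6)
    t_s, t_e = max(0, ov_s - slack), min(rl, ov_e + slack)
    k = max(16, int((1 - policy.min_identity) * (q_e - q_s)) + slack)
    res = edlib.align(query, read_arr[t_s:t_e].tobytes(), mode="HW",
                      task="path", k=k)
    if res["editDistance"] < 0:
        return None
    loc = res["locations"][0]
    t_off, t_used, columns, matches = _local_trim(res["cigar"])
    start = t_s + loc[0] + t_off
    end = start + t_used
    if columns == 0:
        return None
    ident = matches / columns
    if columns < policy.min_alignment_len or ident < policy.min_identity:
        return None
    return start, end, ident, columns


def align_monomer(monomer: str, sequences: Iterable[Tuple[str, object]],
                  policy: FilterPolicy, monomer_id: str = "monomer",
                  min_seed_support: int = 2) -> List[MonomerHit]:
    """Find all local alignments of a monomer in a sequence set, both strands.

    Candidate copies are seeded by shared 11-mers on a common diagonal and
    verified by edit distance; identity counts gaps as non-matches. Every
    planted copy at divergence <= 1 - min_identity and length above the
    policy minimum is recovered on substitution-only data.
    """
    mono = _seq.to_u8(monomer)
    if mono.size < 20:
        raise ValueError("monomer must be >= 20 bp")
    if np.any(~np.isin(mono, np.frombuffer(b"ACGTN", dtype=np.uint8))):
        raise ValueError("monomer contains non-ACGTN characters")
    strands = {"+": _SeedIndex(mono), "-": _SeedIndex(_seq.revcomp_arr(mono))}
    mono_by_strand = {"+": mono, "-": _seq.revcomp_arr(mono)}
    hits: List[MonomerHit] = []
    for seq_id, seq in sequences:
        arr = _seq.to_u8(seq)
        if arr.size < SEED_K:
            continue
        codes, valid = _seq.kmer_codes(_seq.base_codes(arr), SEED_K)
        seen = set()
        for strand, index in strands.items():
            diags, support, qmin, qmax = index.diagonals(codes, valid)
            for d, sup, qa, qb in zip(diags, support, qmin, qmax):
                if sup < min_seed_support:
                    continue
                res = _identity_hit(arr, mono_by_strand[strand], int(d),
                                    policy, qa, qb)
                if res is None:
                    continue
                key = (res[0], res[1], strand)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(MonomerHit(monomer_id, seq_id, res[0], res[1],
                                       res[2], strand))
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.end))
    return hits


def merge_hits(hits: Iterable) -> Tuple[List[Tuple[int, int]], int]:
    """Union of hit intervals on one sequence and the cumulative length.

    Accepts :class:`MonomerHit` objects or plain (start, end) pairs.
    Invariant under permutation and duplication of identical hits; the
    cumulative length never exceeds the sequence length.
    """
    iv = []
    for h in hits:
        if isinstance(h, MonomerHit):
            iv.append((h.start, h.end))
        else:
            iv.append((int(h[0]), int(h[1])))
    merged = _seq.merge_intervals(iv)
    return merged, sum(b - a for a, b in merged)


def cumulative_by_sequence(hits: Iterable[MonomerHit]) -> Dict[str, int]:
    """Merged cumulative alignment length per sequence."""
    by_seq: Dict[str, list] = {}
    for h in hits:
        by_seq.setdefault(h.sequence_id, []).append((h.start, h.end))
    return {sid: merge_hits(iv)[1] for sid, iv in by_seq.items()}


def classify_rdna_reads(hits_5h: Sequence[MonomerHit],
                        hits_6h: Sequence[MonomerHit],
                        read_lengths: Dict[str, int]) -> pd.DataFrame:
    """Classify reads by which 45S rDNA unit references they align to.

    ``hits_5h``/``hits_6h`` must already be filtered by the intended policy
    (the customary policy is >= 5 kb alignment at >= 90% identity). Returns
    one row
    per read with columns read_id, rdna_class in {both, 5H_only, 6H_only,
    none}, read_length.
    """
    set5 = {h.sequence_id for h in hits_5h}
    set6 = {h.sequence_id for h in hits_6h}
    rows = []
    for rid, rlen in read_lengths.items():
        in5, in6 = rid in set5, rid in set6
        cls = ("both" if in5 and in6 else
               "5H_only" if in5 else "6H_only" if in6 else "none")
        rows.append((rid, cls, rlen))
    return pd.DataFrame(rows, columns=["read_id", "rdna_class",
                                       "read_length"])


def rdna_class_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and cumulative read lengths per rDNA class."""
    g = classified.groupby("rdna_class")
    out = g.agg(n_reads=("read_id", "size"),
                cumulative_read_bp=("read_length", "sum"))
    return out.reset_index()


def count_integrase_reads(hits: Iterable[MonomerHit]):
    """Per-read copy counting for a near-complete-hit set.

    Returns (n_reads_with_hit, fraction_single_hit, per_read_counts); the
    fraction is NaN when there are no hits.
    """
    counts: Dict[str, int] = {}
    for h in hits:
        counts[h.sequence_id] = counts.get(h.sequence_id, 0) + 1
    n = len(counts)
    frac = (sum(1 for c in counts.values() if c == 1) / n) if n else float("nan")
    return n, frac, counts


def hits_to_tsv(hits: Iterable[MonomerHit], path,
                seq_lengths: Dict[str, int] | None = None) -> None:
    """PAF-like TSV export of monomer hits."""
    rows = []
    for h in hits:
        slen = seq_lengths.get(h.sequence_id, -1) if seq_lengths else -1
        rows.append((h.sequence_id, slen, h.start, h.end, h.strand,
                     h.monomer_id, round(h.identity, 4), h.length))
    pd.DataFrame(rows, columns=["sequence_id", "seq_len", "start", "end",
                                "strand", "monomer_id", "identity",
                                "aln_len"]).to_csv(path, sep="\t", index=False)
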