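"""Low-level sequence utilities shared across modules.

Sequences are handled internally as ``numpy.uint8`` arrays of ASCII codes
(upper-case). Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

import numpy as np

COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in [(ord("A"), ord("T")), (ord("C"), ord("G")),
               (ord("a"), ord("t")), (ord("c"), ord("g"))]:
    COMPLEMENT[_a], COMPLEMENT[_b] = _b, _a

# ACGT -> 0..3, everything else (incl. N) -> 4
CODES = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    CODES[ord(_c)] = _i
    CODES[ord(_c.lower())] = _i

_UPPER = np.arange(256, dtype=np.uint8)
for _c in range(ord("a"), ord("z") + 1):
    _UPPER[_c] = _c - 32


def to_u8(seq) -> np.ndarray:
    """Coerce a str/bytes/array sequence to an upper-case uint8 ASCII array."""
    if isinstance(seq, np.ndarray):
        arr = seq.astype(np.uint8, copy=False)
    elif isinstance(seq, (bytes, bytearray, memoryview)):
        arr = np.frombuffer(bytes(seq), dtype=np.uint8)
    else:
        arr = np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)
    return _UPPER[arr]


def to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return COMPLEMENT[arr][::-1]


def revcomp(seq: str) -> str:
    return to_str(revcomp_arr(to_u8(seq)))


def base_codes(arr: np.ndarray) -> np.ndarray:
    """Map ASCII array to 2-bit base codes; non-ACGT becomes 4."""
    return CODES[arr]


def kmer_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """2-bit-packed k-mer integer codes for every position (k <= 31).

    Returns (codes64, valid) where valid[i] is False if the window
    contains a non-ACGT base.
    """
    if k > 31:
        raise ValueError("kmer_codes supports k <= 31; use kmer_hashes")
    n = codes.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    out = np.zeros(n, dtype=np.uint64)
    bad = codes >= 4
    for j in range(k):
        out <<= np.uint64(2)
        out |= (codes[j:j + n] & np.uint8(3)).astype(np.uint64)
    # window validity: no bad base in [i, i+k)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return out, valid


def revcomp_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit-packed k-mer codes (vectorized)."""
    x = (~codes).astype(np.uint64)
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    x = ((x & m2) << np.uint64(2)) | ((x >> np.uint64(2)) & m2)
    x = ((x & m4) << np.uint64(4)) | ((x >> np.uint64(4)) & m4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-canonical k-mer codes: min(code, revcomp code)."""
    return np.minimum(codes, revcomp_kmer_codes(codes, k))


_HASH_BASE = np.uint64(1099511628211)


def kmer_hashes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """64-bit polynomial rolling hashes of all k-mers (any k).

    Wrap-around arithmetic in uint64; collisions are astronomically rare at
    the genome sizes handled here.
    """
    n = codes.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    out = np.zeros(n, dtype=np.uint64)
    bad = codes >= 4
    with np.errstate(over="ignore"):
        for j in range(k):
            out *= _HASH_BASE
            out += (codes[j:j + n] + np.uint8(1)).astype(np.uint64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return out, valid


def runs_true(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True as an (n, 2) array of half-open intervals."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return np.stack([starts, ends], axis=1)


def merge_intervals(iv: Iterable[Tuple[int, int]]) -> list:
    """Union of half-open intervals, sorted and disjoint."""
    iv = sorted((int(a), int(b)) for a, b in iv if b > a)
    out = []
    for a, b in iv:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def read_fasta(path) -> Iterator[Tuple[str, str]]:
    from Bio import SeqIO
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_fastx(path) -> Iterator[Tuple[str, str]]:
    from Bio import SeqIO
    p = str(path)
    fmt = "fastq" if p.endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(p, fmt):
        yield rec.id, str(rec.seq).upper()


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
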