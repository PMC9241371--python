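"""Assembly gap detection and repeat-flank classification.

Locates N-gaps in pseudomolecules, scans the 1 kb flanks of each gap for
tandem repeat arrays, classifies gaps as repeat-adjacent when a flank
carries an array of at least 500 bp, and summarizes gap classes by dominant
flank motif and feature proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import _seq, tandem_scan


@dataclass
class GapRecord:
    chromosome: str
    start: int
    end: int
    left_arrays: List[tandem_scan.RepeatArray] = field(default_factory=list)
    right_arrays: List[tandem_scan.RepeatArray] = field(default_factory=list)
    classification: str = "other"  # repeat_adjacent | other
    dominant_motif: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def find_gaps(assembly: Dict[str, object] | Iterable[Tuple[str, object]],
              min_n_run: int = 10) -> List[Tuple[str, int, int]]:
    """Maximal runs of >= min_n_run consecutive Ns per chromosome."""
    items = assembly.items() if isinstance(assembly, dict) else assembly
    gaps = []
    for chrom, seq in items:
        arr = _seq.to_u8(seq)
        is_n = arr == ord("N")
        for s, e in _seq.runs_true(is_n):
            if e - s >= min_n_run:
                gaps.append((chrom, int(s), int(e)))
    return gaps


def classify_gap(gap: Tuple[str, int, int], chrom_seq, flank: int = 1_000,
                 min_array: int = 500, max_motif_len: int = 2_000,
                 min_purity: float = 0.8) -> GapRecord:
    """Classify one gap by the tandem arrays in its flanking windows.

    Flanks are clipped at chromosome ends; arrays are measured only within
    the flank window. A gap is repeat_adjacent when either flank carries an
    array >= ``min_array`` bp; the dominant motif is the canonical motif of
    the longest qualifying array (left/right symmetric).
    """
    chrom, s, e = gap
    arr = _seq.to_u8(chrom_seq)
    left = arr[max(0, s - flank):s]
    right = arr[e:e + flank]
    kwargs = dict(min_array_len=min_array, max_motif_len=max_motif_len,
                  min_purity=min_purity)
    la = tandem_scan.find_arrays(left, sequence_id=f"{chrom}:left", **kwargs)
    ra = tandem_scan.find_arrays(right, sequence_id=f"{chrom}:right",
                                 **kwargs)
    rec = GapRecord(chrom, s, e, la, ra)
    qualifying = [a for a in la + ra if a.length >= min_array]
    if qualifying:
        rec.classification = "repeat_adjacent"
        rec.dominant_motif = max(qualifying, key=lambda a: a.length).motif
    return rec


def audit_gaps(assembly: Dict[str, object], min_n_run: int = 10,
               flank: int = 1_000, min_array: int = 500,
               max_motif_len: int = 2_000) -> List[GapRecord]:
    """find_gaps + classify_gap over a whole assembly."""
    if isinstance(assembly, dict):
        seqs = assembly
    else:
        seqs = dict(assembly)
    records = []
    for gap in find_gaps(seqs, min_n_run=min_n_run):
        records.append(classify_gap(gap, seqs[gap[0]], flank=flank,
                                    min_array=min_array,
                                    max_motif_len=max_motif_len))
    return records


def gap_report(records: Sequence[GapRecord],
               features: Optional[Dict[str, Dict[str, list]]] = None,
               radius: int = 1_000_000) -> pd.DataFrame:
    """Summary counts per dominant-motif class and feature-proximity
    stratum.

    ``features`` maps a feature name to per-chromosome interval lists; a
    gap's stratum is the first feature whose intervals lie within
    ``radius`` of it ("none" otherwise). Per-class counts sum to the number
    of records.
    """
    rows = []
    for rec in records:
        motif = rec.dominant_motif if rec.classification == \
            "repeat_adjacent" else "other"
        stratum = "none"
        if features:
            for name, per_chrom in features.items():
                for fs, fe in per_chrom.get(rec.chromosome, []):
                    if fs - radius <= rec.end and rec.start <= fe + radius:
                        stratum = name
                        break
                if stratum != "none":
                    break
        rows.append((motif, rec.classification, stratum))
    df = pd.DataFrame(rows, columns=["dominant_motif", "classification",
                                     "stratum"])
    if df.empty:
        return pd.DataFrame(columns=["dominant_motif", "classification",
                                     "stratum", "n_gaps"])
    return (df.groupby(["dominant_motif", "classification", "stratum"])
            .size().reset_index(name="n_gaps"))


def gaps_to_bed(records: Sequence[GapRecord], path) -> None:
    """BED export: name = classification, score = longest flank array bp."""
    with open(path, "w") as fh:
        for r in records:
            longest = max((a.length for a in r.left_arrays + r.right_arrays),
                          default=0)
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t"
                     f"{r.classification}\t{longest}\n")
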