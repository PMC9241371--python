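"""Label-spacing profiling of optical-map molecules.

Detects runs of regularly spaced labels on single molecules (tandem rDNA
arrays produce one label per unit), corrects the map stretch, histograms
unit sizes weighted by unit counts, classifies size categories, and sizes
loci from molecule coverage.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Stretch-correction coefficient removing the map's relative expansion.
DEFAULT_STRETCH_COEF = 0.952
#: Molecule length cutoff applied before run detection (bp).
DEFAULT_MIN_MOLECULE_LEN = 150_000


@dataclass
class OpticalMolecule:
    """A single labelled molecule: ordered label coordinates in bp."""

    molecule_id: str
    length: float
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)


@dataclass(frozen=True)
class LabelRun:
    """A maximal run of near-equal label intervals on one molecule."""

    molecule_id: str
    first_label: int  # index of the first label in the run
    last_label: int  # index of the last label (inclusive)
    n_units: int  # number of intervals in the run
    raw_unit_size: float  # median interval, uncorrected bp
    corrected_unit_size: Optional[float] = None


@dataclass(frozen=True)
class SizeClass:
    label: str
    low: float
    high: float  # half-open [low, high)

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("size class needs low < high")

    def contains(self, size: float) -> bool:
        return self.low <= size < self.high


#: 45S rDNA label-spacing category (corrected bp).
RDNA_45S_CLASS = SizeClass("45S", 8_400, 10_100)


def _segment_valid(sorted_vals: Sequence[float], tolerance: float) -> bool:
    # strict inequality: an interval exactly at the tolerance bound breaks
    # the run
    n = len(sorted_vals)
    med = (sorted_vals[n // 2] if n % 2
           else 0.5 * (sorted_vals[n // 2 - 1] + sorted_vals[n // 2]))
    return (sorted_vals[-1] < (1 + tolerance) * med
            and sorted_vals[0] > (1 - tolerance) * med)


def detect_runs(molecule: OpticalMolecule, min_units: int = 6,
                tolerance: float = 0.1) -> List[LabelRun]:
    """Maximal runs of consecutive intervals within ``tolerance`` (relative)
    of the run's median interval.

    A run of intervals [i, j) is valid when every interval lies within
    tolerance x median of the median; reported runs cannot be extended by
    one adjacent interval, hold >= min_units intervals, and are not
    contained in another reported run. Molecules with < 2 labels yield an
    empty list.
    """
    labels = np.sort(molecule.labels)
    iv = np.diff(labels)
    n = iv.size
    if n < min_units:
        return []
    ratio_cap = (1 + tolerance) / (1 - tolerance)
    # validity[i] = set of j (exclusive) with segment [i, j) valid
    valid_end: List[List[bool]] = []
    for i in range(n):
        flags = []
        vals: List[float] = []
        lo = hi = None
        for j in range(i, n):
            x = iv[j]
            insort(vals, x)
            lo = vals[0]
            hi = vals[-1]
            if lo <= 0 or hi / lo >= ratio_cap:
                # min/max only worsen: no longer segment from i is valid
                flags.extend([False] * (n - j))
                break
            flags.append(_segment_valid(vals, tolerance))
        valid_end.append(flags)

    def is_valid(i, j):  # segment [i, j) of intervals
        if j - i < 1 or j > n:
            return False
        k = j - 1 - i
        return k < len(valid_end[i]) and valid_end[i][k]

    runs = []
    for i in range(n):
        for k, ok in enumerate(valid_end[i]):
            j = i + k + 1
            if not ok or j - i < min_units:
                continue
            if is_valid(i - 1, j) or is_valid(i, j + 1):
                continue  # extendable
            runs.append((i, j))
    # drop runs contained in another reported run
    keep = [r for r in runs
            if not any(o != r and o[0] <= r[0] and o[1] >= r[1]
                       for o in runs)]
    out = []
    for i, j in sorted(keep):
        seg = iv[i:j]
        out.append(LabelRun(molecule.molecule_id, first_label=i,
                            last_label=j, n_units=j - i,
                            raw_unit_size=float(np.median(seg))))
    return out


def correct_stretch(raw_size: float,
                    coefficient: float = DEFAULT_STRETCH_COEF) -> float:
    """Remove the optical map's length expansion (raw x coefficient)."""
    if raw_size <= 0:
        raise ValueError("raw_size must be > 0")
    return raw_size * coefficient


def correct_runs(runs: Iterable[LabelRun],
                 coefficient: float = DEFAULT_STRETCH_COEF) -> List[LabelRun]:
    return [replace(r, corrected_unit_size=correct_stretch(r.raw_unit_size,
                                                           coefficient))
            for r in runs]


def profile_molecules(molecules: Iterable[OpticalMolecule],
                      min_units: int = 6, tolerance: float = 0.1,
                      coefficient: float = DEFAULT_STRETCH_COEF,
                      min_len: float = DEFAULT_MIN_MOLECULE_LEN
                      ) -> List[LabelRun]:
    """Size-filter molecules, detect runs and apply stretch correction."""
    runs: List[LabelRun] = []
    for mol in molecules:
        if mol.length < min_len:
            continue
        runs.extend(detect_runs(mol, min_units=min_units,
                                tolerance=tolerance))
    return correct_runs(runs, coefficient)


def unit_histogram(runs: Sequence[LabelRun], bin_width: float
                   ) -> pd.Series:
    """Histogram of corrected unit sizes weighted by each run's n_units.

    Returns a Series indexed by bin left edge; the total weight equals the
    summed unit count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sizes = np.array([r.corrected_unit_size if r.corrected_unit_size
                      is not None else r.raw_unit_size for r in runs])
    weights = np.array([r.n_units for r in runs], dtype=float)
    if sizes.size == 0:
        return pd.Series(dtype=float)
    lo = np.floor(sizes.min() / bin_width) * bin_width
    hi = np.floor(sizes.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(sizes, bins=edges, weights=weights)
    return pd.Series(counts, index=edges[:-1])


def class_totals(runs: Sequence[LabelRun],
                 classes: Sequence[SizeClass] = (RDNA_45S_CLASS,)
                 ) -> pd.DataFrame:
    """Total spanned-unit counts and base totals per size class.

    A run of n intervals touches n+1 labels, i.e. it spans about n+1
    labelled units of the underlying array (half a unit beyond each
    terminal label); counting only the n intervals would understate
    coverage-normalized locus sizes by one unit per molecule. Base totals
    accumulate spanned units x corrected unit size.
    """
    rows = []
    for cl in classes:
        tot_units = 0
        tot_bases = 0.0
        for r in runs:
            size = (r.corrected_unit_size if r.corrected_unit_size
                    is not None else r.raw_unit_size)
            if cl.contains(size):
                tot_units += r.n_units + 1
                tot_bases += (r.n_units + 1) * size
        rows.append((cl.label, tot_units, tot_bases))
    return pd.DataFrame(rows, columns=["size_class", "total_units",
                                       "total_bases"])


def size_locus(total_units: float, coverage_fold: float,
               unit_size: Optional[float] = None,
               total_bases: Optional[float] = None
               ) -> Tuple[float, float]:
    """Coverage-normalized locus size from class totals.

    Returns (units_per_locus, locus_size_bp) = (total units / coverage,
    class base total / coverage). The base total is taken from
    ``total_bases`` when given, otherwise total_units x unit_size.
    """
    if coverage_fold <= 0:
        raise ValueError("coverage_fold must be > 0")
    if total_bases is None:
        total_bases = total_units * (unit_size or 0.0)
    return total_units / coverage_fold, total_bases / coverage_fold


def molecules_to_tsv(molecules: Iterable[OpticalMolecule], path) -> None:
    """Simplified BNX-like TSV: molecule_id, length_bp, label positions."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tlength_bp\tlabels\n")
        for m in molecules:
            lab = ",".join(f"{x:.1f}" for x in m.labels)
            fh.write(f"{m.molecule_id}\t{m.length:.1f}\t{lab}\n")


def molecules_from_tsv(path) -> List[OpticalMolecule]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            mid, length, labs = line.rstrip("\n").split("\t")
            labels = (np.array([float(x) for x in labs.split(",")])
                      if labs else np.empty(0))
            out.append(OpticalMolecule(mid, float(length), labels))
    return out
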