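"""Coverage-normalized repeat abundance and extrapolation arithmetic.

Cumulative repeat observations in reads are converted to non-redundant
genome-wide totals by dividing by the assumed sequencing depth, then to
per-arm or per-chromosome averages. Also provides read-count-based copy
numbers, fraction-of-genome conversions, component-fraction extrapolation,
and a bootstrap standard error over per-read observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class AbundanceEstimate:
    repeat_class: str
    cumulative_observed: float  # bp observed across reads
    assumed_depth: float  # fold coverage
    nonredundant_total: float  # bp, cumulative / depth
    per_unit: float  # bp per arm or chromosome
    unit_count: int  # 14 arms or 7 chromosomes


def nonredundant_size(cumulative_bp: float, depth: float, n_units: int = 1,
                      repeat_class: str = "") -> AbundanceEstimate:
    """Genome-wide non-redundant repeat size and per-unit average.

    nonredundant_total = cumulative_bp / depth; per_unit divides by the
    number of arms or chromosomes. Rounding happens only at report time.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    total = cumulative_bp / depth
    return AbundanceEstimate(repeat_class, float(cumulative_bp),
                             float(depth), total, total / n_units, n_units)


def copy_number(n_single_hit_reads: float, depth: float,
                n_chromosomes: int = 7) -> float:
    """Monomer copies per chromosome from read counts at a given depth."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    return n_single_hit_reads / depth / n_chromosomes


def extrapolate_from_fraction(component_total_bp: float,
                              component_fraction: float) -> float:
    """Total size implied by a component and its assumed fraction."""
    if not 0 < component_fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return component_total_bp / component_fraction


def fraction_of_genome(percent: float, genome_size: float) -> float:
    """Convert a genome percentage into base pairs."""
    if percent < 0:
        raise ValueError("percent must be >= 0")
    return percent / 100.0 * genome_size


def bootstrap_se(per_read_bp: Sequence[float], depth: float,
                 n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap SE of the non-redundant total over per-read observations."""
    x = np.asarray(per_read_bp, dtype=float)
    if x.size == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    totals = x[idx].sum(axis=1) / depth
    return float(totals.std(ddof=1))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to significant figures for report rendering."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)
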