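import numpy as np
import pytest

from repeataudit import synthetic_data as sd


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate(seq: str, rate: float, rng) -> str:
    """Apply i.i.d. substitutions (always to a different base)."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = int(round(arr.size * rate))
    if n:
        pos = rng.choice(arr.size, n, replace=False)
        codes = np.searchsorted(lut, arr[pos])
        arr[pos] = lut[(codes + rng.integers(1, 4, n)) % 4]
    return arr.tobytes().decode()


@pytest.fixture(scope="session")
def small_genome():
    """1 Mb genome with a compact repeat landscape, reused across tests."""
    spec = sd.GenomeSpec(
        chrom_length=1_000_000, telomere_len=5_000,
        subtel_blocks=(("hvt01", 20_000),),
        centromere=sd.CentromereSpec(total_len=60_000, n_retro_insertions=4),
        microsat_arrays=(("AAG", 8_000, "pericentric"),),
        gap_plan=(sd.GapPlan("pericentric", 2_000, 800, "AAG"),),
        seed=41)
    genome, truth = sd.simulate_genome(spec)
    return spec, genome, truth
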