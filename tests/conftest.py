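import numpy as np
import pytest

from ctcfloops.intervals import ChromSizes, GenomicInterval, Peak, PeakSet
from ctcfloops.synthetic import FactorSpec, SimConfig, simulate_all


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 10_000_000, "chr2": 10_000_000})


@pytest.fixture(scope="session")
def planted_sim():
    """One medium simulation with planted co-binding, boosts and conditions,
    shared by the statistics tests."""
    cfg = SimConfig(
        seed=11,
        factor_specs=[
            FactorSpec("PROM", 0.3, 200),
            FactorSpec("NEUT", 0.3, 200),
            FactorSpec("BGONLY", 0.0, 500),
        ],
        promoting_factors=["PROM"],
        loop_boost=2.0,
    )
    return cfg, simulate_all(cfg)


def random_intervals(rng, n, chrom_len=100_000, chroms=("chrA", "chrB"), max_len=400):
    """n random half-open intervals for oracle-equivalence tests."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, chrom_len)))
    return out


def random_peaks(rng, n, chrom_len=100_000, chroms=("chrA", "chrB"), width=200):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - width))
        out.append(
            Peak(
                GenomicInterval(chrom, start, start + width),
                int(rng.integers(0, width)),
                float(rng.lognormal(2, 1)),
                f"p{i}",
            )
        )
    return out
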