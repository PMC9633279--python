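import numpy as np
import pandas as pd
import pytest

from sweepkit import GenotypeMatrix, VariantRecord
from sweepkit.io_formats import MISSING


def make_gm(
    rng: np.random.Generator,
    n_samples: int = 20,
    n_variants: int = 10,
    missing_rate: float = 0.1,
    chrom: str = "chr1",
    max_pos: int = 100_000,
    two_pops: bool = True,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> GenotypeMatrix:
    """Random small genotype matrix with metadata, for unit/property tests."""
    pos = np.sort(rng.choice(max_pos, size=n_variants, replace=False) + 1)
    p = rng.uniform(*maf_range, size=n_variants)
    dosage = rng.binomial(2, p, size=(n_samples, n_variants)).astype(np.int16)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    variants = [
        VariantRecord(chrom=chrom, pos=int(q), ref="A", alt=("C",), id=f"v{k}")
        for k, q in enumerate(pos)
    ]
    samples = [f"s{k:03d}" for k in range(n_samples)]
    if two_pops:
        half = n_samples // 2
        pops = ["popA"] * half + ["popB"] * (n_samples - half)
    else:
        pops = ["popA"] * n_samples
    meta = pd.DataFrame({"population": pops}, index=pd.Index(samples, name="sample"))
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage, sample_meta=meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231109)


@pytest.fixture
def gm_factory():
    return make_gm
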