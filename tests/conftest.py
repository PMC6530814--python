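import numpy as np
import pytest

from regscore.io import EnergyMatrix, GeneModel, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_peaks(rng, n, chrom="chr1", span=100_000, with_signal=True):
    peaks = []
    seen = set()
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 800))
        if (start, start + length) in seen:
            continue
        seen.add((start, start + length))
        peaks.append(
            Peak(
                chrom,
                start,
                start + length,
                score=float(rng.uniform(0, 100)),
                signal=float(rng.uniform(0, 10)) if with_signal else 0.0,
            )
        )
    return peaks


def random_genes(rng, n, chrom="chr1", span=100_000):
    return [
        GeneModel(
            gene_id=f"g{i}",
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            tss=int(rng.integers(1, span)),
        )
        for i in range(n)
    ]


def random_energy_matrix(rng, name="tf", max_width=12, lo=0.0, hi=3.0):
    width = int(rng.integers(4, max_width + 1))
    energies = rng.uniform(lo, hi, size=(width, 4))
    return EnergyMatrix(tf_name=name, energies=energies)
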