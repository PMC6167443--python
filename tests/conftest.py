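import numpy as np
import pytest

from lncsig import simulate
from lncsig.models import GeneModel, GenomeAnnotation, Peak


@pytest.fixture
def small_config():
    return simulate.SimConfig(n_coding=50, n_lnc=200, n_up=20, n_down=10, seed=7)


@pytest.fixture
def small_dataset(small_config):
    ann, truth = simulate.simulate_annotation(small_config)
    peaks = simulate.simulate_peaks(ann, truth, small_config)
    cm = simulate.simulate_counts(ann, truth, small_config)
    return ann, truth, peaks, cm


@pytest.fixture
def toy_annotation():
    genes = [
        GeneModel(id="pc1", chrom="chr1", strand="+", start=100, end=500,
                  biotype="coding", exons=((100, 200), (400, 500))),
        GeneModel(id="pc2", chrom="chr1", strand="-", start=1000, end=1400,
                  biotype="coding", exons=((1000, 1400),)),
    ]
    return GenomeAnnotation(genes=genes, chrom_lengths={"chr1": 5000})


def random_annotation(rng: np.random.Generator, n_coding=4, n_lnc=6,
                      chrom_len=20_000) -> GenomeAnnotation:
    """Random but valid annotation for round-trip / oracle tests."""
    genes = []
    for i in range(n_coding + n_lnc):
        start = int(rng.integers(0, max(1, chrom_len - 3000)))
        end = start + int(rng.integers(200, min(2500, chrom_len - start)))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "coding" if i < n_coding else "lncRNA"
        n_ex = int(rng.integers(1, 4))
        bounds = sorted(rng.choice(np.arange(start, end + 1), size=2 * n_ex, replace=False))
        exons = tuple(
            (int(bounds[2 * k]), int(bounds[2 * k + 1]))
            for k in range(n_ex)
            if bounds[2 * k] < bounds[2 * k + 1]
        )
        genes.append(GeneModel(
            id=f"g{i}", chrom=f"chr{int(rng.integers(1, 3))}", strand=strand,
            start=start, end=end, biotype=biotype, exons=exons,
        ))
    lengths = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_lengths=lengths)


def random_peaks(rng: np.random.Generator, n=20, chrom_len=20_000) -> list[Peak]:
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 500))
        peaks.append(Peak(
            chrom=f"chr{int(rng.integers(1, 3))}", start=start,
            end=start + int(rng.integers(1, 400)),
            score=float(rng.random()) if rng.random() < 0.5 else None,
        ))
    return peaks
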