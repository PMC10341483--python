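import numpy as np
import pandas as pd
import pytest

from regucircuit.annotation import GeneRecord, GenomeAnnotation
from regucircuit.diffcount import CountMatrix


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Four genes on two chromosomes, both strands, one overlapping pair."""
    return GenomeAnnotation(
        [
            GeneRecord("geneA", "chr1", 10_000, 15_000, "+"),
            GeneRecord("geneB", "chr1", 14_000, 20_000, "-"),
            GeneRecord("geneC", "chr1", 40_000, 46_000, "+"),
            GeneRecord("geneD", "chr2", 5_000, 9_000, "-"),
        ]
    )


def nb_count_matrix(
    rng,
    n_features=200,
    mean=100.0,
    dispersion=0.1,
    n_per_group=3,
    lfc_index=None,
    lfc=2.0,
    times=None,
):
    """Gamma-Poisson count matrix helper shared by the diffcount tests."""
    if times is None:
        cols = [f"control_r{i}" for i in range(n_per_group)] + [
            f"mutant_r{i}" for i in range(n_per_group)
        ]
        cond = ["control"] * n_per_group + ["mutant"] * n_per_group
        time = None
    else:
        cols, cond, time = [], [], []
        for t in times:
            for c in ("control", "mutant"):
                for i in range(n_per_group):
                    cols.append(f"{c}_{t}_r{i}")
                    cond.append(c)
                    time.append(t)
    mu = np.full((n_features, len(cols)), mean)
    if lfc_index is not None:
        is_mut = np.array([c == "mutant" for c in cond])
        mu[np.ix_(lfc_index, is_mut)] *= 2.0**lfc
    if dispersion < 1e-7:
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(1.0 / dispersion, dispersion * mu))
    counts = pd.DataFrame(y, index=[f"f{i:04d}" for i in range(n_features)], columns=cols)
    return CountMatrix(
        counts,
        pd.Series(cond, index=cols),
        pd.Series(time, index=cols) if time is not None else None,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    from regucircuit.annotation import Interval

    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, start + length))
    return out
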