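import numpy as np
import pandas as pd
import pytest

from bsahopper import simdata


@pytest.fixture
def tiny_config():
    """A small, fast BIL simulation: one chromosome, one planted QTL."""
    return simdata.SimConfig(
        n_chromosomes=1,
        chrom_length_bp=5_000_000,
        marker_spacing_bp=100_000,
        qtls=(simdata.Qtl(0, 2_000_000, 10.0),),
        n_lines=40,
        seed=7,
    )


@pytest.fixture
def tiny_truth(tiny_config):
    return simdata.simulate_bil_population(tiny_config)


def make_truth(genotypes, config=None, baseline=34.0):
    """Hand-built SimTruth around an explicit 0/1/2 genotype matrix."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_lines, n_markers = genotypes.shape
    config = config or simdata.SimConfig(
        n_chromosomes=1,
        chrom_length_bp=(n_markers + 1) * 1000,
        marker_spacing_bp=1000,
        qtls=(),
        n_lines=n_lines,
        seed=0,
    )
    line_ids = tuple(f"BIL{i + 1:03d}" for i in range(n_lines))
    pos = np.arange(1000, 1000 * (n_markers + 1), 1000, dtype=np.int64)[:n_markers]
    auc = pd.DataFrame(
        {pop: np.full(n_lines, baseline) for pop in config.populations},
        index=list(line_ids),
    )
    return simdata.SimTruth(
        config=config,
        line_ids=line_ids,
        marker_chrom=np.zeros(n_markers, dtype=int),
        marker_pos=pos,
        genotypes=genotypes,
        qtl_dosage=np.zeros((n_lines, 0), dtype=np.int8),
        auc_genetic=auc,
    )
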