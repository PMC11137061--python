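from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from evoreseq.containers import GenotypeMatrix


def make_genotype_matrix(
    gt,
    depth=None,
    ref_reads=None,
    alt_reads=None,
    *,
    chrom=None,
    pos=None,
    is_indel=None,
    mutagenized=None,
    covered_bases=20e6,
):
    """Assemble a GenotypeMatrix from plain arrays with sensible defaults."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    if depth is None:
        depth = np.full(gt.shape, 20, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    if alt_reads is None:
        alt_reads = np.where(gt == 1, depth // 2, np.where(gt == 2, depth, 0))
    if ref_reads is None:
        ref_reads = depth - np.asarray(alt_reads)
    sites = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["2L"] * n_sites,
            "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 10_000,
            "ref": "A",
            "alt": "T",
            "is_indel": is_indel if is_indel is not None else False,
        }
    )
    individuals = pd.DataFrame(
        {
            "name": [f"ind{i}" for i in range(n_ind)],
            "mutagenized": mutagenized if mutagenized is not None else True,
            "covered_bases": covered_bases,
        }
    )
    return GenotypeMatrix(
        sites=sites,
        individuals=individuals,
        gt=gt,
        depth=depth,
        ref_reads=np.asarray(ref_reads, dtype=np.int64),
        alt_reads=np.asarray(alt_reads, dtype=np.int64),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
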