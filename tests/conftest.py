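import numpy as np
import pandas as pd
import pytest

from introscan import diffexpr as de


def make_matrix(counts: np.ndarray, groups: list, gene_ids=None) -> de.CountMatrix:
    """Wrap a raw array into a CountMatrix with one sample per group label."""
    counts = np.asarray(counts)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(counts.shape[0])]
    reps: dict = {}
    sample_ids, rep_idx = [], []
    for g in groups:
        reps[g] = reps.get(g, 0) + 1
        sample_ids.append(f"{g}_r{reps[g]}")
        rep_idx.append(reps[g])
    samples = pd.DataFrame(
        {"group": groups, "replicate": rep_idx},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index
    )
    return de.CountMatrix(frame, samples)


def unit_factors(matrix: de.CountMatrix, lib_size=None) -> de.NormFactors:
    """NormFactors with TMM factor 1 (and optionally forced library sizes)."""
    if lib_size is None:
        lib = matrix.lib_sizes.astype(float)
    else:
        lib = pd.Series(float(lib_size), index=matrix.counts.columns)
    return de.NormFactors(lib_size=lib, factor=pd.Series(1.0, index=matrix.counts.columns))


@pytest.fixture
def nb_null_matrix():
    """2 groups x 6 replicates, 400 NB genes, no true effects (disp 0.2)."""
    rng = np.random.default_rng(42)
    base = rng.lognormal(5.0, 1.0, 400)
    mu = np.tile(base[:, None], (1, 12))
    y = rng.poisson(rng.gamma(1.0 / 0.2, 0.2 * mu))
    return make_matrix(y, ["A"] * 6 + ["B"] * 6)
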