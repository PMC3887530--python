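import numpy as np
import pandas as pd
import pytest

from antagde.core import ExpressionMatrix
from antagde.simulate import SimConfig, simulate_experiment, simulate_peaks


def make_matrix(values, genotypes, chroms=None, gene_ids=None):
    """Small ExpressionMatrix builder for hand-constructed tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    counts = {}
    sample_ids, rows = [], []
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
        sid = f"{g}_r{counts[g]}"
        sample_ids.append(sid)
        rows.append({"sample": sid, "genotype": g, "replicate": counts[g]})
    chroms = chroms or ["I"] * n_genes
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        pd.DataFrame(rows).set_index("sample"),
        pd.DataFrame({"chrom": chroms}, index=pd.Index(gene_ids, name="gene")),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated experiment at the documented study conditions."""
    cfg = SimConfig(seed=20260927)
    matrix, annotation, calls, truth = simulate_experiment(cfg)
    return cfg, matrix, annotation, calls, truth


@pytest.fixture(scope="session")
def default_peaks(default_sim):
    cfg, _, annotation, _, truth = default_sim
    return simulate_peaks(truth, annotation, cfg)
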