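import numpy as np
import pandas as pd
import pytest

from riisdeg import CountMatrix, simulate_dataset


def build_count_matrix(gene_counts: dict, library_sizes: dict | None = None,
                       groups: dict | None = None, lengths: dict | None = None,
                       heat_shock: dict | None = None) -> CountMatrix:
    """Construct a CountMatrix with exact library sizes via a filler gene.

    gene_counts: {gene_id: {sample_id: count}}.  If ``library_sizes`` is given,
    a `_filler` gene absorbs the remainder so each column total is exact.
    """
    counts = pd.DataFrame(gene_counts).T.fillna(0).astype(np.int64)
    if library_sizes is not None:
        filler = {s: int(library_sizes[s]) - int(counts[s].sum())
                  for s in counts.columns}
        if any(v < 0 for v in filler.values()):
            raise ValueError("library size smaller than gene counts")
        counts.loc["_filler"] = pd.Series(filler)
    groups = groups or {}
    heat_shock = heat_shock or {}
    meta = pd.DataFrame(
        {
            "group": [groups.get(s, "G") for s in counts.columns],
            "replicate": list(range(1, len(counts.columns) + 1)),
            "heat_shock": [heat_shock.get(s, 0) for s in counts.columns],
            "rnai_target": ["" for _ in counts.columns],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    lens = pd.Series({g: (lengths or {}).get(g, 1000) for g in counts.index},
                     name="length_bp")
    return CountMatrix(counts=counts, lengths=lens, sample_meta=meta)


@pytest.fixture(scope="session")
def default_sim():
    """The default 16,000-gene daf16-dominant simulation, fixed seed."""
    return simulate_dataset(n_genes=16000, seed=1)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_dataset(n_genes=2000, seed=3)
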