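import numpy as np
import pandas as pd
import pytest

from chemoshift.io import ExpressionMatrix, SampleDesign


def make_design(reps_per_cell: int = 2) -> SampleDesign:
    """Balanced 2x2 design: control/drug x NT/CSC, reference levels first."""
    rows, ids = [], []
    for t in ("control", "drug"):
        for p in ("NT", "CSC"):
            for r in range(1, reps_per_cell + 1):
                ids.append(f"{t}_{p}_r{r}")
                rows.append((t, p, r))
    table = pd.DataFrame(rows, columns=["treatment", "phenotype", "replicate"],
                         index=pd.Index(ids, name="sample"))
    return SampleDesign(table, treatment_levels=("control", "drug"),
                        phenotype_levels=("NT", "CSC"))


def matrix_from_cell_means(cell_means: dict, design: SampleDesign,
                           genes=("g1",), noise=None, rng=None) -> ExpressionMatrix:
    """Build a matrix whose samples take exact per-cell values (plus noise).

    ``cell_means`` maps (treatment, phenotype) -> value (scalar or per-gene
    sequence).
    """
    n_genes = len(genes)
    values = np.zeros((n_genes, len(design.sample_ids)))
    for j, sample in enumerate(design.sample_ids):
        row = design.table.loc[sample]
        v = cell_means[(row["treatment"], row["phenotype"])]
        values[:, j] = np.broadcast_to(np.asarray(v, dtype=float), (n_genes,))
    if noise is not None:
        values = values + noise
    elif rng is not None:
        values = values + rng.normal(0, 0.1, values.shape)
    return ExpressionMatrix(pd.DataFrame(values, index=list(genes),
                                         columns=design.sample_ids))


@pytest.fixture
def design2():
    return make_design(reps_per_cell=2)


@pytest.fixture
def small_experiment():
    """A small planted-effect experiment shared across integration tests."""
    from chemoshift.simulate import SimulationConfig, simulate_experiment

    config = SimulationConfig(n_genes=1500, n_tfs=10, targets_per_tf=80,
                              dampening=0.8, seed=11)
    return simulate_experiment(config)
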