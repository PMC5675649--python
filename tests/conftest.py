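import numpy as np
import pandas as pd
import pytest

import tepsel
from tepsel.mrmr import RankedFeatureList


@pytest.fixture(scope="session")
def small_cohort():
    """One strong-signal synthetic cohort shared by read-only tests."""
    config = tepsel.SyntheticConfig(
        n_genes=300, n_informative=20, effect_size=2.0, seed=7
    )
    matrix, labels, truth = tepsel.generate_expression(config)
    return config, matrix, labels, truth


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    _, matrix, labels, truth = small_cohort
    processed = tepsel.preprocess(matrix)
    return processed, labels, truth


def random_discrete_dataset(rng, n_features=None, n_samples=30):
    """Random discrete matrix + labels for oracle-equivalence checks."""
    if n_features is None:
        n_features = rng.integers(3, 21)
    states = rng.integers(0, 3, size=(n_features, n_samples))
    genes = [f"F{i}" for i in range(n_features)]
    samples = [f"S{i}" for i in range(n_samples)]
    d = tepsel.DiscreteMatrix(pd.DataFrame(states, index=genes, columns=samples))
    n_classes = int(rng.integers(2, 5))
    labels = pd.Series(rng.integers(0, n_classes, n_samples).astype(str), index=samples)
    return d, labels


def brute_force_mrmr(d, labels):
    """Naive mRMR reference: recompute D and R from scratch each iteration.

    O(N^2 * iterations) pairwise plug-in MI calls; independent of the
    incremental bookkeeping in the implementation under test.
    """
    genes = list(d.gene_ids)
    y = labels.loc[d.sample_ids].to_numpy()
    states = {g: d.states.loc[g].to_numpy() for g in genes}
    relevance = {g: tepsel.mutual_information(states[g], y) for g in genes}
    selected, scores = [], []
    remaining = list(genes)
    while remaining:
        best_gene, best_score = None, -np.inf
        for g in remaining:  # input order => first max wins ties
            if selected:
                red = sum(
                    tepsel.mutual_information(states[g], states[s]) for s in selected
                ) / len(selected)
            else:
                red = 0.0
            score = relevance[g] - red
            if score > best_score:
                best_gene, best_score = g, score
        selected.append(best_gene)
        scores.append(best_score)
        remaining.remove(best_gene)
    return RankedFeatureList(
        pd.DataFrame({"feature": selected, "score": scores}), "mrmr"
    )
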