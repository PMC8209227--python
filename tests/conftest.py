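import numpy as np
import pytest

import ddrain


@pytest.fixture(scope="session")
def clean_well():
    """A simulated artifact-free sample well (true VAF 30%, n=6000)."""
    cfg = ddrain.config_for_vaf(30.0, lambda_wt=0.5, n_droplets=6000, seed=101)
    well, labels = ddrain.simulate_well(cfg, well_id="A01", sample_id="S1")
    return well, labels, cfg


@pytest.fixture(scope="session")
def training_set():
    """Ground-truth-labeled training droplets pooled from one clean well."""
    cfg = ddrain.config_for_vaf(50.0, lambda_wt=0.5, n_droplets=4000, seed=777)
    well, labels = ddrain.simulate_well(cfg)
    keep = np.random.default_rng(0).choice(well.n_droplets, 2000, replace=False)
    return ddrain.TrainingSet(
        amplitudes=well.amplitudes[keep],
        labels=labels[keep],
        source_wells=("T01",),
        source_samples=("TS1",),
    )


@pytest.fixture(scope="session")
def ntc_well():
    return ddrain.simulate_ntc(
        ddrain.SimulationConfig(lambda_wt=0.0, lambda_mut=0.0, n_droplets=3000, seed=55),
        well_id="H12",
    )


def brute_force_knn(query, train_amps, train_codes, k):
    """Exhaustive k-NN with the package's tie rule, written independently.

    For each query droplet: sort all training droplets by Euclidean
    distance (stable), take the first k, count votes per class, and
    among the top-voted classes return the one whose member appears
    first in the neighbor list.
    """
    out = np.empty(len(query), dtype=np.int64)
    for i, q in enumerate(query):
        d = np.sqrt(((train_amps - q) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        nb = train_codes[order]
        votes = {}
        for c in nb:
            votes[c] = votes.get(c, 0) + 1
        top = max(votes.values())
        tied = {c for c, v in votes.items() if v == top}
        for c in nb:
            if c in tied:
                out[i] = c
                break
    return out
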