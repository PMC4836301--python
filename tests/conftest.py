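import numpy as np
import pytest

import cgiset as cg
from cgiset.containers import Pathway, PathwayCollection, ProbeAnnotation
from cgiset.topology import assemble_features


@pytest.fixture(scope="session")
def small_study():
    """A small b1 study with one positive and one negative pathway."""
    return cg.simulate_study(
        cg.ModelSpec(form="b1"), K=2, genes_per_pathway=6, overlap_fraction=0.2,
        probes_per_gene_range=(1, 3), n_pairs=12, seed=11,
        gamma=[0.2, -0.2], background_genes=3,
    )


@pytest.fixture(scope="session")
def conjugate_toy():
    """Fixed-variance single-pathway toy where gamma's posterior is closed form."""
    m, n = 10, 5
    genes = tuple(f"G{i}" for i in range(m))
    annotation = ProbeAnnotation(
        tuple(f"p{i}" for i in range(m)), genes, np.ones(m, dtype=bool)
    )
    pathways = PathwayCollection((Pathway("P1", "toy", genes),))
    features = assemble_features(annotation, pathways)
    rng = np.random.default_rng(7)
    params = {"b": 0.02, "tau2": 0.01, "sigma2": 0.04, "gamma_true": 0.25,
              "gamma_var": 1.0}
    beta_true = rng.normal(params["b"], np.sqrt(params["tau2"]), m)
    theta_vals = beta_true + params["gamma_true"] + rng.normal(
        0.0, np.sqrt(params["sigma2"]), (n, m)
    )
    theta = cg.PairedDifferenceMatrix(
        tuple(f"pair{i}" for i in range(n)), annotation.probe_ids,
        np.clip(theta_vals, -1, 1),
    )
    return {
        "theta": theta, "features": features, "annotation": annotation,
        "beta_true": beta_true, **params,
        "fixed": {"b_Y": params["b"], "b_N": params["b"],
                  "tau2_Y": params["tau2"], "tau2_N": params["tau2"],
                  "sigma2_eps": params["sigma2"]},
    }


def batch_mcse(draws, n_batches=100):
    """Batch-means Monte-Carlo standard error of the mean of a chain."""
    draws = np.asarray(draws, dtype=float).ravel()
    usable = (draws.size // n_batches) * n_batches
    batches = draws[:usable].reshape(n_batches, -1).mean(axis=1)
    return batches.std(ddof=1) / np.sqrt(n_batches)
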