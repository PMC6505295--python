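import numpy as np
import pytest

from scnpf import (
    ExpressionMatrix,
    SimulationConfig,
    affinity_kernel,
    cluster_similarity,
    external_metrics,
    scnpf_fusion,
    scnpf_propagation,
    simulate_expression,
    simulate_network,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr(rng):
    values = rng.poisson(3.0, size=(50, 20)).astype(float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(50)],
        [f"c{i}" for i in range(20)],
    )


def run_pipeline(seed, r=0.5, dropout=0.7, return_views=False):
    """Simulate the default fixture and run propagate -> fuse -> spectral."""
    cfg = SimulationConfig(seed=seed, dropout_rate_target=dropout)
    expr, labels, modules = simulate_expression(cfg)
    net = simulate_network(modules, seed=seed, gene_ids=expr.gene_ids)
    from scnpf import PropagationConfig

    pcfg = PropagationConfig(r=r)
    ctx = scnpf_propagation(expr, mode="context", cfg=pcfg)
    pri = scnpf_propagation(expr, mode="priori", net=net, cfg=pcfg)
    fused = scnpf_fusion([ctx, pri])
    ari_fused = external_metrics(
        cluster_similarity(fused, cfg.n_clusters, "spectral", seed=1000).labels, labels
    )["ari"]
    out = {
        "expr": expr,
        "labels": labels,
        "ctx": ctx,
        "pri": pri,
        "fused": fused,
        "ari_fused": ari_fused,
    }
    if return_views:
        raw_sim = affinity_kernel(expr)
        out["ari_raw"] = external_metrics(
            cluster_similarity(raw_sim, cfg.n_clusters, "spectral", seed=1000).labels,
            labels,
        )["ari"]
    return out


@pytest.fixture(scope="session")
def default_pipeline_runs():
    """Ten seeded runs of the full pipeline on the default fixture."""
    return [run_pipeline(seed, return_views=True) for seed in range(10)]
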