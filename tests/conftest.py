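import numpy as np
import pytest

from vlincworks.simulate import SimulationConfig, simulate_world


@pytest.fixture(scope="session")
def world():
    """The default-size simulated world shared across the suite."""
    return simulate_world(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def big_expression():
    """Latent expression at the compendium's full sample count (no tags)."""
    from vlincworks.simulate import generate_annotation, generate_expression

    cfg = SimulationConfig(
        seed=11,
        n_samples={"normal": 399, "cancer": 332, "stem": 92, "immortalized": 10},
    )
    bundle, truth = generate_annotation(cfg)
    latent, samples = generate_expression(cfg, bundle, truth)
    return cfg, bundle, truth, latent, samples


@pytest.fixture(scope="session")
def metric_world():
    """A wide world (500 vlincs, 833 samples, latent expression wrapped as
    an expression matrix) for class-metric effect recovery, where medians
    over the LTR/nonLTR categories are stable."""
    import pandas as pd

    from vlincworks.annotate import annotate_vlincs
    from vlincworks.quantify import ExpressionMatrix
    from vlincworks.simulate import generate_annotation, generate_expression

    cfg = SimulationConfig(
        seed=13,
        chrom_length=200_000_000,
        n_vlincs=2000,
        n_genes=150,
        n_samples={"normal": 399, "cancer": 332, "stem": 92, "immortalized": 10},
    )
    bundle, truth = generate_annotation(cfg)
    latent, samples = generate_expression(cfg, bundle, truth)
    kinds = pd.Series(
        ["vlinc" if f.startswith("vlinc") else "gene" for f in latent.matrix.index],
        index=latent.matrix.index,
    )
    lengths = pd.Series(1_000, index=latent.matrix.index)
    expr = ExpressionMatrix(latent.matrix, kinds, lengths)
    anns = annotate_vlincs(bundle)
    return cfg, bundle, truth, latent, samples, anns, expr


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
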