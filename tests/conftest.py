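import numpy as np
import pandas as pd
import pytest

from irlncpair import CohortConfig, PipelineConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def reference_cohort():
    """One reference synthetic cohort (seed 7) shared across tests."""
    cfg = CohortConfig(seed=7)
    expr, truth, clinical = generate_cohort(cfg)
    return cfg, expr, truth, clinical


@pytest.fixture(scope="session")
def reference_run(reference_cohort):
    cfg, expr, truth, clinical = reference_cohort
    lnc = [g for g in expr.values.index if g.startswith("LNC")]
    result = run_pipeline(
        expr,
        clinical,
        lnc,
        truth.immune_gene_ids,
        config=PipelineConfig(seed=cfg.seed),
    )
    return cfg, expr, truth, clinical, result


@pytest.fixture()
def toy_survival():
    """Twenty samples, one binary covariate, moderate effect, no ties."""
    rng = np.random.default_rng(42)
    n = 20
    x = np.repeat([0, 1], n // 2)
    h = 0.01 * np.exp(0.8 * x)
    t = rng.exponential(1.0 / h)
    c = rng.exponential(250.0, n)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "x": x.astype(float),
        }
    )
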