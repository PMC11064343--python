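import pytest
from hypothesis import HealthCheck, settings

from kgablate import KnowledgeGraph, SyntheticConfig, Triple, generate_kg
from kgablate.pipeline import run_grid

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def triangle_kg():
    """Three triples over three entities: degrees all 2."""
    return KnowledgeGraph(
        [Triple("a", "r1", "b"), Triple("b", "r2", "c"), Triple("a", "r1", "c")]
    )


@pytest.fixture
def star_kg():
    """Hub with three leaves: the canonical hubby toy graph."""
    return KnowledgeGraph([Triple("h", "r", f"l{i}") for i in range(3)])


@pytest.fixture(scope="session")
def planted_kg():
    """Default synthetic KG with noise-free planted compositional semantics."""
    kg, meta = generate_kg(SyntheticConfig(seed=11))
    return kg, meta


@pytest.fixture(scope="session")
def headline_grid():
    """Desk-scale perturbation grid on the default synthetic family.

    TransE at 50 epochs over 8 seeds: the full semantic contrast
    (control / corrupt / flatten across d) under high-degree downsampling
    (alpha = 2), plus the uniform (alpha = 0) and low-degree (alpha = -2)
    downsampling controls.  Shared by the trend and stability checks since
    it is by far the most expensive computation in the suite.
    """
    base = {
        "dataset_label": "synthetic-default",
        "task": "drug-disease",
        "models": ["TransE"],
        "seeds": list(range(8)),
        "epochs": 50,
    }
    main = run_grid({
        **base,
        "alphas": [2.0],
        "ds": [1.0, 0.5, 0.25],
        "modes": ["control", "corrupt", "flatten"],
    })
    controls = run_grid({
        **base,
        "alphas": [0.0, -2.0],
        "ds": [1.0, 0.25],
        "modes": ["control", "corrupt"],
    })
    import pandas as pd

    return pd.concat([main, controls], ignore_index=True)


@pytest.fixture(scope="session")
def small_planted_kg():
    """Reduced synthetic KG for fast training-behavior checks."""
    cfg = SyntheticConfig(
        n_drugs=40, n_genes=40, n_diseases=40, n_binds=160, n_associates=160,
        n_treats=120, n_background_triples=160, seed=7,
    )
    kg, meta = generate_kg(cfg)
    return kg, meta
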