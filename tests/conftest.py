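import numpy as np
import pandas as pd
import pytest

from gbmkit import simulate as sim
from gbmkit.expression import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "A": [2.0, 4.0, 6.0],
            "B": [4.0, 8.0, 12.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data, scale="log2")


@pytest.fixture
def duplicate_annotation() -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["A", "B"],
                "condition": ["wt", "wt"],
                "replicate_group": ["r1", "r2"],
            }
        ),
        reference="wt",
    )


@pytest.fixture
def centroids() -> pd.DataFrame:
    return sim.gen_centroids(n_genes=20, seed=42)


@pytest.fixture
def planted_profile(centroids) -> tuple[pd.Series, str]:
    """Profile = one centroid plus small noise; returns (profile, subtype)."""
    rng = np.random.default_rng(7)
    label = "Proneural"
    values = centroids[label].to_numpy() + rng.normal(0, 0.1, len(centroids))
    return pd.Series(values, index=centroids.index), label


@pytest.fixture
def flat_track() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    n = 300
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 50_000,
            "lrr": rng.normal(0, 0.1, n),
            "baf": 0.5,
            "gc_fraction": rng.uniform(0.35, 0.65, n),
            "is_allelic": True,
        }
    )
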