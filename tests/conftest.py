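import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from pdxsig.io import ExpressionMatrix, FeatureAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, biotypes=None, prefix="G", sample_prefix="S"):
    """Small annotated expression matrix from a 2-d array."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    biotypes = biotypes or ["coding"] * p
    feats = [
        FeatureAnnotation(
            feature_id=f"{prefix}{i + 1}",
            biotype=biotypes[i],
            chrom="chr1",
            start=1000 * (i + 1),
            end=1000 * (i + 1) + 500,
            strand="+" if i % 2 == 0 else "-",
        )
        for i in range(p)
    ]
    samples = [f"{sample_prefix}{j + 1}" for j in range(n)]
    return ExpressionMatrix(feats, samples, values)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(8, 1, size=(6, 5)))
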