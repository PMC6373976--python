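import pytest

from tsscall import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """The reference synthetic study: 200 genes, 2 reps x 3 genotypes."""
    return simulate(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def called_bundle(default_bundle):
    """Reference bundle with clusters called, annotated and classified."""
    from tsscall import annotate_clusters, build_feature_set, call_tss, classify_clusters

    clusters = call_tss(default_bundle.libraries)
    features = build_feature_set(default_bundle.genes)
    annotate_clusters(clusters, features)
    classify_clusters(clusters)
    return default_bundle, clusters, features
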