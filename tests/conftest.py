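import numpy as np
import pytest

from repeatratio import CountTable, parse_feature_id


@pytest.fixture
def tiny_table() -> CountTable:
    """3 features (2 genes, 1 repeat) x 2 samples."""
    features = [
        parse_feature_id("ENSG00000136997"),
        parse_feature_id("ENSG00000141510"),
        parse_feature_id("ALR/Alpha:centr:Satellite"),
    ]
    counts = np.array([[100, 200], [50, 80], [5, 0]], dtype=np.int64)
    return CountTable(features=features, samples=["P1", "P2"], counts=counts)


def make_table(counts: np.ndarray, n_repeats: int = 1) -> CountTable:
    """Count table with the last ``n_repeats`` rows tagged as repeats."""
    counts = np.asarray(counts, dtype=np.int64)
    n_feat, n_samp = counts.shape
    features = []
    for i in range(n_feat - n_repeats):
        features.append(parse_feature_id(f"GENE{i:05d}"))
    for i in range(n_repeats):
        features.append(parse_feature_id(f"REP{i:04d}:Alu:SINE"))
    return CountTable(
        features=features,
        samples=[f"s{j}" for j in range(n_samp)],
        counts=counts,
    )
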