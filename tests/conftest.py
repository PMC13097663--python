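import numpy as np
import pytest

from morphodiverge.landmark_io import (
    LandmarkConfiguration,
    LandmarkDataset,
    PairingMap,
    SpecimenMetadata,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_config(specimen_id, coords, labels=None, mask=None):
    coords = np.asarray(coords, dtype=float)
    if labels is None:
        labels = [f"LM{i + 1}" for i in range(coords.shape[0])]
    return LandmarkConfiguration(specimen_id, coords, labels, missing_mask=mask)


def toy_symmetric_dataset(n=4, noise=0.0, seed=0):
    """Small 3D dataset with 3 bilateral pairs + 2 midline landmarks."""
    rng = np.random.default_rng(seed)
    labels = ["L1", "R1", "L2", "R2", "L3", "R3", "M1", "M2"]
    pairing = PairingMap([("L1", "R1"), ("L2", "R2"), ("L3", "R3")], ["M1", "M2"])
    right = np.array([[0.6, 0.1, 0.2], [0.5, -0.4, 0.1], [0.3, 0.3, -0.5]])
    template = []
    for r in right:
        l = r.copy()
        l[0] = -l[0]
        template += [l, r]
    template += [[0.0, 0.8, 0.0], [0.0, -0.2, 0.6]]
    template = np.asarray(template)
    template -= template.mean(axis=0)
    template /= np.linalg.norm(template)
    configs, meta = [], {}
    for i in range(n):
        x = template + noise * rng.standard_normal(template.shape)
        configs.append(make_config(f"s{i}", x, list(labels)))
        meta[f"s{i}"] = SpecimenMetadata(f"s{i}", species="sp", sex="M" if i % 2 else "F")
    return LandmarkDataset(configs, pairing, meta), template
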