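import numpy as np
import pytest

import ewsdda.simulate as sim
from ewsdda import OmicsDataset, PlantedSignal, generate_staged

EQUAL_STAGED_SIZES = {c: 30 for c in sim.STAGED_CLASS_ORDER}


def motif_signal(persistent: bool = False, signal_class: str = "I",
                 effect_size: float = 4.0, n_features: int = 6) -> PlantedSignal:
    """Hub-first motif: hub f001 with 5 partners (the clean recovery layout)."""
    feats = sim._feature_names(n_features)
    return PlantedSignal(feats[0], feats[1:6], signal_class, effect_size, persistent=persistent)


@pytest.fixture
def small_dataset() -> OmicsDataset:
    """3 features x 4 samples, two classes of 2."""
    return OmicsDataset(
        feature_ids=["fA", "fB", "fC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array([[2.0, 4.0, 1.0, 3.0], [1.0, 2.0, 2.0, 6.0], [5.0, 5.0, 4.0, 2.0]]),
        class_of={"s1": "N", "s2": "N", "s3": "I", "s4": "I"},
        class_order=["N", "I"],
    )


@pytest.fixture
def staged_null() -> OmicsDataset:
    return generate_staged(n_features=8, class_sizes=EQUAL_STAGED_SIZES, signals=[], seed=7)


def random_dataset(rng: np.random.Generator, m: int, class_sizes: list[int]) -> OmicsDataset:
    """Unstructured positive dataset with z classes for oracle checks."""
    labels = []
    for k, nk in enumerate(class_sizes):
        labels += [f"c{k}"] * nk
    n = len(labels)
    vals = np.exp(rng.normal(1.0, 1.0, size=(m, n)))
    sample_ids = [f"s{i}" for i in range(n)]
    return OmicsDataset(
        feature_ids=[f"f{i}" for i in range(m)],
        sample_ids=sample_ids,
        values=vals,
        class_of=dict(zip(sample_ids, labels)),
        class_order=[f"c{k}" for k in range(len(class_sizes))],
    )
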