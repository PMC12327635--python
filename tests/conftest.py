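import numpy as np
import pytest

from mangroveseg import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """Deterministic 128x128 six-class scene shared across read-only tests."""
    return generate_scene(SceneSpec(height=128, width=128, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def soft_probability_map(classes: np.ndarray, num_classes: int = 6,
                         confidence: float = 0.7) -> np.ndarray:
    """Probability stack putting `confidence` on the given class map and the
    remainder spread uniformly over the other classes."""
    rest = (1.0 - confidence) / (num_classes - 1)
    out = np.full(classes.shape + (num_classes,), rest, dtype=np.float32)
    np.put_along_axis(out, classes[..., None].astype(np.int64), confidence, axis=-1)
    return out


def random_probs(rng: np.random.Generator, shape: tuple, num_classes: int) -> np.ndarray:
    z = rng.normal(size=shape + (num_classes,))
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)
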