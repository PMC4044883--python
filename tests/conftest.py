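import numpy as np
import pytest

from hairpinldr.ldr import ClassGaussian


def rand_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    B = rng.standard_normal((n, n))
    return scale * (B @ B.T / n) + 0.5 * np.eye(n)


def random_gaussian_pair(
    rng: np.random.Generator,
    n: int,
    homoscedastic: bool = False,
    mean_scale: float = 1.0,
    cov_scale2: float = 1.0,
) -> tuple[ClassGaussian, ClassGaussian]:
    p1 = float(rng.uniform(0.2, 0.8))
    S1 = rand_spd(rng, n)
    S2 = S1.copy() if homoscedastic else rand_spd(rng, n, cov_scale2)
    return (
        ClassGaussian(rng.standard_normal(n) * mean_scale, S1, p1),
        ClassGaussian(rng.standard_normal(n) * mean_scale, S2, 1.0 - p1),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
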