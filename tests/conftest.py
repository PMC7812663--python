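import numpy as np
import pytest

from grmforge import (
    GenotypeFrequencies,
    GenotypeMatrix,
    compute_frequencies,
    simulate_genotypes,
)


def freqs(p_AA: float, p_Aa: float, p_aa: float, n_obs: int = 1000) -> GenotypeFrequencies:
    """Single-marker frequency object from exact proportions."""
    return GenotypeFrequencies.from_proportions([p_AA], [p_Aa], [p_aa], n_obs=n_obs)


def panel_from_counts(n_AA: int, n_Aa: int, n_aa: int) -> GenotypeMatrix:
    """One-marker panel with the given genotype counts."""
    codes = np.array([[2]] * n_AA + [[1]] * n_Aa + [[0]] * n_aa, dtype=np.int16)
    ids = [f"i{k}" for k in range(len(codes))]
    return GenotypeMatrix(ids, ["m1"], codes)


def random_simplex(rng: np.random.Generator, size: int) -> np.ndarray:
    """Strictly interior genotype-frequency triples (all classes present)."""
    x = rng.dirichlet([1.0, 1.0, 1.0], size=size)
    return 0.97 * x + 0.01  # keep away from the simplex boundary


@pytest.fixture(scope="session")
def f1_panel() -> GenotypeMatrix:
    """Complete crossbred-style panel with heterozygote excess."""
    return simulate_genotypes(
        n=120,
        m=250,
        mode="f1_cross",
        freq_law=("uniform", 0.1, 0.5),
        freq_law2=("uniform", 0.5, 0.9),
        seed=11,
    )


@pytest.fixture(scope="session")
def f1_frequencies(f1_panel):
    return compute_frequencies(f1_panel)
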