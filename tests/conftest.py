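import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from drqdiv import SurveyRecord, TraitTable


@pytest.fixture
def small_traits() -> TraitTable:
    """Three species, two scaled quantitative traits, one nominal trait."""
    df = pd.DataFrame(
        {
            "body_size": [0.0, 0.5, 1.0],
            "host_specificity": [0.2, 0.7, 1.0],
            "microhabitat": ["body", "nest", "body"],
        },
        index=pd.Index(["a", "b", "c"], name="species"),
    )
    return TraitTable(df, ("body_size", "host_specificity"), ("microhabitat",))


def random_trait_table(rng: np.random.Generator, n_species: int,
                       n_quant: int = 3, n_nominal: int = 2,
                       missingness: float = 0.15) -> TraitTable:
    """Random mixed-trait table with missing cells, quantitative in [0, 1]."""
    species = [f"s{i}" for i in range(n_species)]
    data = {f"q{j}": rng.random(n_species) for j in range(n_quant)}
    df = pd.DataFrame(data, index=pd.Index(species, name="species"))
    for j in range(n_nominal):
        df[f"n{j}"] = rng.choice(list("xyz"), size=n_species)
    mask = rng.random(df.shape) < missingness
    for i in range(n_species):  # never strip a species of all its traits
        if mask[i].all():
            mask[i, 0] = False
    df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return TraitTable(df, tuple(f"q{j}" for j in range(n_quant)),
                      tuple(f"n{j}" for j in range(n_nominal)))


def random_distance_matrix(rng: np.random.Generator, n: int,
                           unit: bool = True) -> DistanceMatrix:
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    if unit and d.max() > 0:
        d = d / d.max()
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(np.ones(n))


@pytest.fixture
def toy_records() -> list[SurveyRecord]:
    return [
        SurveyRecord("h1", "u1", 10, {"f1": 3, "f2": 1}, period="1999"),
        SurveyRecord("h1", "u1", 5, {"f1": 4, "f3": 2}, period="2000"),
        SurveyRecord("h1", "u2", 20, {"f1": 30, "f2": 10}),
        SurveyRecord("h2", "u1", 9, {"f2": 5}),
    ]
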