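"""The additive decomposition of functional diversity structure.

For an assemblage with relative abundances p and pairwise functional
dissimilarities d ∈ [0, 1]:

* Gini–Simpson diversity   S = 1 − Σ p_i²
* Rao quadratic diversity  Q = Σ_i Σ_j p_i p_j d(i, j)
* Functional redundancy    R = S − Q
* Simpson dominance        D = 1 − S

so that D + R + Q = 1: the triplet (D, R, Q) is a point on the 2-simplex
and is the unit of analysis throughout the package. S is the probability
that two individuals drawn at random (with replacement) are different
species; Q is their expected functional dissimilarity; R is the part of
species diversity not expressed as functional difference — large when
co-occurring species share traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "DRQComposition",
    "gini_simpson",
    "rao_quadratic",
    "drq_compose",
    "drq_contrasts",
    "compose_table",
]

SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class DRQComposition:
    """Dominance / redundancy / Rao diversity triplet of one assemblage."""

    D: float
    R: float
    Q: float
    n_species: int

    def __post_init__(self) -> None:
        if abs(self.D + self.R + self.Q - 1.0) > 1e-12:
            raise ValueError("D + R + Q must equal 1")
        if min(self.D, self.R, self.Q) < -1e-12:
            raise ValueError("components must be non-negative")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")

    @property
    def S(self) -> float:
        """Gini–Simpson diversity, R + Q."""
        return self.R + self.Q

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.D, self.R, self.Q)


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("relative abundances must be a non-empty 1-D vector")
    if np.any(p < -SIMPLEX_TOL):
        raise ValueError("relative abundances must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"relative abundances sum to {total}, not 1")
    return np.clip(p, 0.0, None) / total


def gini_simpson(p) -> float:
    """S = 1 − Σ p_i²: probability two random individuals differ in species."""
    p = _check_simplex(np.asarray(p, dtype=float))
    return float(1.0 - p @ p)


def rao_quadratic(p: pd.Series, dm: DistanceMatrix) -> float:
    """Q = Σ_i Σ_j p_i p_j d(i, j), the full double sum (d(i, i) = 0).

    ``p`` is a Series of relative abundances indexed by species label; the
    labels must all be present in ``dm``.
    """
    p = pd.Series(p, dtype=float)
    missing = [sp for sp in p.index if sp not in dm.ids]
    if missing:
        raise KeyError(f"species absent from the dissimilarity matrix: {missing}")
    w = _check_simplex(p.to_numpy())
    sub = dm.filter(list(p.index)).data
    return float(w @ sub @ w)


def drq_compose(p: pd.Series, dm: DistanceMatrix) -> DRQComposition:
    """Decompose one assemblage into its (D, R, Q) composition."""
    p = pd.Series(p, dtype=float)
    s = gini_simpson(p.to_numpy())
    q = rao_quadratic(p, dm)
    r = s - q
    if r < -1e-9:
        raise ValueError(
            f"negative redundancy R = {r}: dissimilarities exceed 1; "
            "apply rescale_to_unit to the distance matrix first"
        )
    if r < 0.0:  # rounding only; preserve the additive identity exactly
        r, q = 0.0, s
    return DRQComposition(D=1.0 - s, R=r, Q=q, n_species=int(p.size))


def drq_contrasts(c: DRQComposition) -> tuple[float, float, float]:
    """Edge contrasts of the ternary diagram.

    Returns (R + Q, D + R, D + Q): Simpson diversity, functional
    homogeneity and functional uniqueness. Each equals one minus the
    opposing component.
    """
    return (c.R + c.Q, c.D + c.R, c.D + c.Q)


def compose_table(assemblages, dm: DistanceMatrix) -> pd.DataFrame:
    """DRQ compositions for every assemblage in an :class:`AssemblageTable`.

    Returns a DataFrame indexed by (host_species, unit) with columns
    ``n_species, D, R, Q, S, simpson_diversity, functional_homogeneity,
    functional_uniqueness``.
    """
    rows = []
    for key in assemblages.keys:
        comp = drq_compose(assemblages.profile(key), dm)
        div, hom, uniq = drq_contrasts(comp)
        rows.append(
            {
                "n_species": comp.n_species,
                "D": comp.D,
                "R": comp.R,
                "Q": comp.Q,
                "S": comp.S,
                "simpson_diversity": div,
                "functional_homogeneity": hom,
                "functional_uniqueness": uniq,
            }
        )
    index = pd.MultiIndex.from_tuples(assemblages.keys, names=["host_species", "unit"])
    return pd.DataFrame(rows, index=index)
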