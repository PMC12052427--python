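"""Mixed-trait tables and functional dissimilarity matrices.

Functional distances between parasite species are built in four steps:

1. min–max scale each quantitative trait over the species pool,
2. Gower dissimilarity over the mixed (quantitative + nominal) traits,
   with pairwise deletion of missing values,
3. Lingoes correction, making the matrix Euclidean-embeddable,
4. rescale so the largest off-diagonal dissimilarity is 1.

The final rescale guarantees every dissimilarity lies in [0, 1], which is
what keeps Rao's quadratic diversity Q bounded by the Gini–Simpson
diversity S and hence the redundancy R = S − Q non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import eigh
from skbio import DistanceMatrix

__all__ = [
    "TraitTable",
    "scale_quantitative_traits",
    "gower_dissimilarity",
    "lingoes_correction",
    "rescale_to_unit",
    "read_distance_csv",
    "write_distance_csv",
]

QUANT_PREFIX = "q:"
NOMINAL_PREFIX = "n:"


@dataclass(frozen=True)
class TraitTable:
    """Species × trait table holding quantitative and nominal traits.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by species label. Quantitative columns are floats (NaN for
        missing); nominal columns are strings (NaN/None for missing).
    quantitative, nominal : tuple of str
        Column names of each kind. Every column of ``data`` must appear in
        exactly one of the two.
    """

    data: pd.DataFrame
    quantitative: tuple[str, ...] = field(default=())
    nominal: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species labels: {dup}")
        declared = set(self.quantitative) | set(self.nominal)
        undeclared = [c for c in self.data.columns if c not in declared]
        if undeclared:
            raise ValueError(f"traits of unknown kind: {undeclared}")
        if set(self.quantitative) & set(self.nominal):
            raise ValueError("a trait cannot be both quantitative and nominal")
        if len(self.data) and self.data.isna().all(axis=1).any():
            bad = self.data.index[self.data.isna().all(axis=1)].tolist()
            raise ValueError(f"species with no observed trait: {bad}")
        # normalize nominal cells: trimmed strings, comparisons are case-sensitive
        for col in self.nominal:
            vals = self.data[col]
            object.__setattr__(
                self,
                "data",
                self.data.assign(
                    **{col: vals.where(vals.isna(), vals.astype("string").str.strip())}
                ),
            )

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_species(self) -> int:
        return len(self.data)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_csv(cls, path: str | Path, kinds: Mapping[str, str] | str | Path | None = None) -> "TraitTable":
        """Read a trait CSV (first column ``species``).

        Trait kinds come either from a ``q:``/``n:`` column-name prefix or
        from ``kinds`` — a mapping (or YAML file) of trait name to
        ``"quantitative"`` / ``"nominal"``. Empty cells are missing.
        """
        df = pd.read_csv(path, dtype=str).set_index("species")
        if isinstance(kinds, (str, Path)):
            with open(kinds) as fh:
                kinds = yaml.safe_load(fh)
        quant, nominal, rename = [], [], {}
        for col in df.columns:
            if col.startswith(QUANT_PREFIX):
                rename[col] = col[len(QUANT_PREFIX):]
                quant.append(rename[col])
            elif col.startswith(NOMINAL_PREFIX):
                rename[col] = col[len(NOMINAL_PREFIX):]
                nominal.append(rename[col])
            elif kinds and col in kinds:
                kind = str(kinds[col]).lower()
                if kind.startswith("q"):
                    quant.append(col)
                elif kind.startswith("n"):
                    nominal.append(col)
                else:
                    raise ValueError(f"unknown trait kind {kinds[col]!r} for {col!r}")
            else:
                raise ValueError(
                    f"cannot determine kind of trait {col!r}: use a 'q:'/'n:' "
                    "header prefix or pass a kinds mapping"
                )
        df = df.rename(columns=rename)
        for col in quant:
            df[col] = pd.to_numeric(df[col])
        return cls(df, tuple(quant), tuple(nominal))

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = [
            (QUANT_PREFIX if c in self.quantitative else NOMINAL_PREFIX) + c
            for c in out.columns
        ]
        out.index.name = "species"
        out.to_csv(path)


# ---------------------------------------------------------------- operations

def scale_quantitative_traits(table: TraitTable) -> TraitTable:
    """Min–max scale each quantitative trait to [0, 1] over the species pool.

    A constant trait maps to 0 for all species (it then contributes nothing
    to any Gower distance). A trait with all values missing is an error.
    """
    if table.n_species == 0:
        raise ValueError("empty trait table")
    if not table.quantitative:
        raise ValueError("no quantitative traits to scale")
    data = table.data.copy()
    for col in table.quantitative:
        x = data[col].astype(float)
        if x.isna().all():
            raise ValueError(f"quantitative trait {col!r} has all values missing")
        lo, hi = x.min(), x.max()
        data[col] = (x - lo) / (hi - lo) if hi > lo else x * 0.0
    return TraitTable(data, table.quantitative, table.nominal)


def gower_dissimilarity(table: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity between species from mixed traits.

    d(i, j) is the mean, over traits observed in *both* species, of the
    per-trait contribution: |x_i − x_j| for quantitative traits (which must
    already be scaled to [0, 1]), and a 0/1 mismatch indicator for nominal
    traits. Traits are equally weighted; a pair sharing no observed trait
    is an error.
    """
    if table.n_species < 2:
        raise ValueError("need at least two species for a distance matrix")
    s = table.n_species
    total = np.zeros((s, s))
    count = np.zeros((s, s))
    for col in table.quantitative:
        x = table.data[col].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        finite = x[obs]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError(
                f"quantitative trait {col!r} is not scaled to [0, 1]; "
                "run scale_quantitative_traits first"
            )
        both = np.outer(obs, obs)
        xi = np.where(obs, x, 0.0)
        total += np.where(both, np.abs(xi[:, None] - xi[None, :]), 0.0)
        count += both
    for col in table.nominal:
        codes, _ = pd.factorize(table.data[col], use_na_sentinel=True)
        obs = codes >= 0
        both = np.outer(obs, obs)
        total += np.where(both, (codes[:, None] != codes[None, :]).astype(float), 0.0)
        count += both
    off = ~np.eye(s, dtype=bool)
    if np.any(count[off] == 0):
        i, j = np.argwhere((count == 0) & off)[0]
        ids = table.species_ids
        raise ValueError(
            f"species pair ({ids[i]!r}, {ids[j]!r}) shares no observed trait"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    d = 0.5 * (d + d.T)  # symmetric up to rounding already; enforce exactly
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=table.species_ids)


def _centered_gram(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ (d * d) @ j


def lingoes_correction(
    dm: DistanceMatrix, tol: float = 1e-10
) -> tuple[DistanceMatrix, float]:
    """Make a dissimilarity matrix Euclidean-embeddable (Lingoes 1971).

    Computes the doubly centred Gram matrix of −½ d²; if its smallest
    eigenvalue λ_min ≥ −tol the matrix is already Euclidean and is returned
    unchanged with constant ``c = 0``. Otherwise ``c = −λ_min`` and every
    off-diagonal dissimilarity becomes sqrt(d² + 2c), which is monotone in
    d and renders the centred Gram matrix positive semi-definite.
    """
    d = np.asarray(dm.data, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative dissimilarities")
    if d.shape[0] < 2:
        return dm, 0.0
    lam_min = eigh(_centered_gram(d), eigvals_only=True, subset_by_index=[0, 0])[0]
    if lam_min >= -tol:
        return dm, 0.0
    c = float(-lam_min)
    d2 = np.sqrt(d * d + 2.0 * c)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(d2, ids=dm.ids), c


def rescale_to_unit(dm: DistanceMatrix) -> DistanceMatrix:
    """Divide all dissimilarities by the maximum off-diagonal value.

    Idempotent; an all-zero matrix is returned unchanged. Needed because
    the Lingoes correction can push Gower distances above 1, while the
    D/R/Q decomposition assumes dissimilarities in [0, 1].
    """
    d = np.asarray(dm.data, dtype=float)
    mx = d.max()
    if mx == 0 or mx == 1.0:
        return dm
    return DistanceMatrix(d / mx, ids=dm.ids)


# -------------------------------------------------------------- distance I/O

def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "species"
    df.to_csv(path)


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))
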