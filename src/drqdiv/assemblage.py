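"""Survey records, abundance normalisation and sample-selection filters.

An *assemblage* is the set of parasite species collected from one host
species in one sampling unit (a region at the continental scale, a
habitat-homogeneous subsite at the regional scale), after pooling counts
across sampling periods. Abundance of a parasite species in an assemblage
is the mean number of individuals per examined host — infested and
uninfested hosts alike — and relative abundances are those means
normalised to sum to one.

Three selection rules mirror standard practice for aggregated parasite
counts: assemblages from fewer than 10 examined hosts are unreliable and
dropped; within-host comparisons need a host present in at least two
factor levels with at least three samples overall; between-host
comparisons need a factor level where at least two host species each have
at least three samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SurveyRecord",
    "AssemblageTable",
    "GroupingDesign",
    "pool_counts",
    "mean_abundance",
    "relative_abundance",
    "filter_min_hosts",
    "select_within_host_design",
    "select_between_host_design",
    "read_survey_csv",
    "write_survey_csv",
]

FACTORS = ("ecological", "geographic", "host")


@dataclass(frozen=True)
class SurveyRecord:
    """Parasite counts from one host species in one unit (and period)."""

    host_species: str
    unit: str
    n_examined: int
    counts: Mapping[str, int]
    period: str | None = None

    def __post_init__(self) -> None:
        if self.n_examined < 0:
            raise ValueError("n_examined must be non-negative")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("parasite counts must be non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.host_species, self.unit)


@dataclass(frozen=True)
class GroupingDesign:
    """Maps each (host species, unit) assemblage to its factor levels."""

    table: pd.DataFrame  # columns: host_species, unit, ecological, geographic

    def __post_init__(self) -> None:
        required = {"host_species", "unit", "ecological", "geographic"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"grouping table missing columns: {sorted(missing)}")
        keys = self.table[["host_species", "unit"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (host_species, unit) keys in grouping table")
        object.__setattr__(
            self,
            "_lookup",
            {
                (row.host_species, row.unit): (str(row.ecological), str(row.geographic))
                for row in self.table.itertuples()
            },
        )

    def level(self, key: tuple[str, str], factor: str) -> str:
        if factor == "host":
            return key[0]
        self._check_factor(factor)
        try:
            eco, geo = self._lookup[key]
        except KeyError:
            raise KeyError(f"assemblage {key} not in grouping design") from None
        return eco if factor == "ecological" else geo

    def levels(self, keys: Sequence[tuple[str, str]], factor: str) -> list[str]:
        return [self.level(k, factor) for k in keys]

    @staticmethod
    def _check_factor(factor: str) -> None:
        if factor not in FACTORS:
            raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupingDesign":
        df = pd.read_csv(path, dtype=str).rename(
            columns={"ecological_group": "ecological", "geographic_group": "geographic"}
        )
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"ecological": "ecological_group", "geographic": "geographic_group"}
        )
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class AssemblageTable:
    """Per-assemblage mean and relative parasite abundances.

    ``rel_abundance`` and ``mean_abund`` are wide DataFrames indexed by
    (host_species, unit) with one column per parasite species; zeros mark
    absence. ``meta`` carries ``n_examined`` and ``n_species`` per row.
    Assemblages where no parasite was recorded are excluded at
    construction (they carry no information for the decomposition).
    """

    mean_abund: pd.DataFrame
    rel_abundance: pd.DataFrame
    meta: pd.DataFrame
    n_dropped_empty: int = 0

    @property
    def keys(self) -> list[tuple[str, str]]:
        return list(self.rel_abundance.index)

    def profile(self, key: tuple[str, str]) -> pd.Series:
        """Relative abundances of the species present in one assemblage."""
        row = self.rel_abundance.loc[key]
        return row[row > 0]

    @classmethod
    def from_records(cls, records: Iterable[SurveyRecord]) -> "AssemblageTable":
        records = list(records)
        keys, rows, meta_rows, dropped = [], [], [], 0
        for rec in records:
            if rec.n_examined == 0:
                raise ValueError(f"record {rec.key} has zero hosts examined")
            ma = mean_abundance(rec)
            if sum(ma.values()) == 0:
                dropped += 1
                continue
            keys.append(rec.key)
            rows.append(ma)
            meta_rows.append(
                {"n_examined": rec.n_examined, "n_species": sum(v > 0 for v in ma.values())}
            )
        index = pd.MultiIndex.from_tuples(keys, names=["host_species", "unit"])
        mean_df = pd.DataFrame(rows, index=index).fillna(0.0).sort_index(axis=1)
        rel_df = mean_df.div(mean_df.sum(axis=1), axis=0)
        meta = pd.DataFrame(meta_rows, index=index)
        return cls(mean_df, rel_df, meta, dropped)


# ---------------------------------------------------------------- operations

def pool_counts(records: Iterable[SurveyRecord]) -> list[SurveyRecord]:
    """Pool counts and examined hosts across sampling periods.

    Returns one record per (host_species, unit), with n_examined summed and
    counts summed species-wise (species absent in a period count as zero).
    Output order follows first appearance of each key.
    """
    pooled: dict[tuple[str, str], dict] = {}
    for rec in records:
        slot = pooled.setdefault(rec.key, {"n": 0, "counts": {}})
        slot["n"] += rec.n_examined
        for sp, c in rec.counts.items():
            slot["counts"][sp] = slot["counts"].get(sp, 0) + c
    return [
        SurveyRecord(host, unit, slot["n"], slot["counts"])
        for (host, unit), slot in pooled.items()
    ]


def mean_abundance(record: SurveyRecord) -> dict[str, float]:
    """Mean parasites per examined host (infested and uninfested alike)."""
    if record.n_examined < 1:
        raise ValueError(f"record {record.key}: no hosts examined")
    return {sp: c / record.n_examined for sp, c in record.counts.items()}


def relative_abundance(mean_abundances: Mapping[str, float]) -> dict[str, float]:
    """Normalise per-species abundances to a unit-sum simplex vector."""
    total = float(sum(mean_abundances.values()))
    if total <= 0:
        raise ValueError("empty assemblage: all abundances are zero")
    return {sp: v / total for sp, v in mean_abundances.items()}


def filter_min_hosts(
    records: Iterable[SurveyRecord], min_examined: int = 10
) -> list[SurveyRecord]:
    """Keep records from at least ``min_examined`` examined host individuals."""
    return [r for r in records if r.n_examined >= min_examined]


@dataclass(frozen=True)
class SelectionReport:
    """Eligible strata plus an exclusion table with reasons."""

    selected: dict[str, list[tuple[str, str]]]
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["stratum", "reason"])
    )


def select_within_host_design(
    keys: Sequence[tuple[str, str]],
    design: GroupingDesign,
    factor: str,
    min_levels: int = 2,
    min_samples: int = 3,
) -> SelectionReport:
    """Hosts eligible for within-host tests across levels of ``factor``.

    A host species qualifies when its assemblages occur in at least
    ``min_levels`` levels of the factor and number at least ``min_samples``
    in total.
    """
    GroupingDesign._check_factor(factor)
    by_host: dict[str, list[tuple[str, str]]] = {}
    for key in keys:
        by_host.setdefault(key[0], []).append(key)
    selected, excl = {}, []
    for host, hkeys in sorted(by_host.items()):
        levels = set(design.levels(hkeys, factor))
        if len(hkeys) < min_samples:
            excl.append({"stratum": host, "reason": f"only {len(hkeys)} samples (< {min_samples})"})
        elif len(levels) < min_levels:
            excl.append({"stratum": host, "reason": f"only {len(levels)} {factor} level(s) (< {min_levels})"})
        else:
            selected[host] = hkeys
    return SelectionReport(selected, pd.DataFrame(excl, columns=["stratum", "reason"]))


def select_between_host_design(
    keys: Sequence[tuple[str, str]],
    design: GroupingDesign,
    factor: str,
    min_hosts: int = 2,
    min_samples: int = 3,
) -> SelectionReport:
    """Factor levels eligible for between-host tests.

    Within each level of ``factor``, host species with at least
    ``min_samples`` assemblages are retained; the level qualifies when at
    least ``min_hosts`` such host species remain.
    """
    GroupingDesign._check_factor(factor)
    by_level: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for key in keys:
        lev = design.level(key, factor)
        by_level.setdefault(lev, {}).setdefault(key[0], []).append(key)
    selected, excl = {}, []
    for lev, hosts in sorted(by_level.items()):
        good = {h: ks for h, ks in hosts.items() if len(ks) >= min_samples}
        if len(good) < min_hosts:
            excl.append(
                {
                    "stratum": lev,
                    "reason": (
                        f"only {len(good)} host species with >= {min_samples} "
                        f"samples (< {min_hosts})"
                    ),
                }
            )
        else:
            selected[lev] = [k for h in sorted(good) for k in good[h]]
    return SelectionReport(selected, pd.DataFrame(excl, columns=["stratum", "reason"]))


# ------------------------------------------------------------------- I/O

def read_survey_csv(path: str | Path) -> list[SurveyRecord]:
    """Read a long-format survey CSV.

    Columns: ``host_species, unit, period, n_examined, parasite_species,
    count``. Rows sharing (host_species, unit, period) form one record and
    must agree on n_examined.
    """
    df = pd.read_csv(path, dtype={"host_species": str, "unit": str, "period": str})
    records = []
    for (host, unit, period), grp in df.groupby(
        ["host_species", "unit", "period"], dropna=False, sort=False
    ):
        n_ex = grp["n_examined"].unique()
        if len(n_ex) != 1:
            raise ValueError(
                f"inconsistent n_examined for ({host}, {unit}, {period})"
            )
        counts = dict(zip(grp["parasite_species"], grp["count"].astype(int)))
        records.append(
            SurveyRecord(
                host, unit, int(n_ex[0]), counts,
                None if pd.isna(period) else str(period),
            )
        )
    return records


def write_survey_csv(records: Iterable[SurveyRecord], path: str | Path) -> None:
    rows = [
        {
            "host_species": r.host_species,
            "unit": r.unit,
            "period": r.period if r.period is not None else "",
            "n_examined": r.n_examined,
            "parasite_species": sp,
            "count": c,
        }
        for r in records
        for sp, c in sorted(r.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
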