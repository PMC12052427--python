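"""Model/results interface tying the whole analysis together.

:class:`FunctionalDiversityModel` holds the raw inputs (survey records,
trait table, grouping design) and the selection thresholds; ``fit()``
runs the full procedure — pool counts, apply the minimum-hosts filter,
build relative abundances, build the functional distance matrix
(scale → Gower → Lingoes → unit rescale), decompose every assemblage
into (D, R, Q), and run the permutational tests for the requested
comparisons — returning a :class:`FunctionalDiversityResults` with the
compositions, test tables, exclusion log and plotting helpers.

Two comparison families exist for a chosen factor (``ecological`` or
``geographic``):

* ``within_host`` — for each eligible host species, do its assemblages
  differ between factor levels?
* ``between_host`` — within each eligible factor level, do assemblages
  differ between host species?

Each omnibus PERMANOVA is followed by univariate permutation ANOVAs on
the single components D, R and Q; these are computed for every test and
flagged with the omnibus outcome, so the conventional reading (consult
them only where the omnibus is significant) is a filter on the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import assemblage as asm
from .assemblage import AssemblageTable, GroupingDesign, SurveyRecord
from .drq import compose_table
from .permutation import bray_curtis_matrix, permanova_test, univariate_perm_anova
from .ternary import render_ternary, ternary_table
from .traits import (
    TraitTable,
    gower_dissimilarity,
    lingoes_correction,
    rescale_to_unit,
    scale_quantitative_traits,
)

__all__ = ["FunctionalDiversityModel", "FunctionalDiversityResults"]

COMPARISONS = ("within_host", "between_host")

OMNIBUS_COLS = [
    "comparison", "factor", "stratum", "n_assemblages", "n_groups",
    "statistic", "p_value", "n_perm", "seed", "significant",
]
UNIVARIATE_COLS = [
    "comparison", "factor", "stratum", "component", "statistic", "p_value",
    "n_perm", "seed", "omnibus_significant",
]
EXCLUSION_COLS = ["stage", "comparison", "stratum", "reason"]


class FunctionalDiversityModel:
    """Functional diversity structure of parasite assemblages.

    Parameters
    ----------
    records : iterable of SurveyRecord
        Raw (possibly per-period) survey counts.
    traits : TraitTable
        Mixed-trait table for the parasite species pool.
    design : GroupingDesign
        Factor levels for every (host species, unit) assemblage.
    min_hosts_examined, min_levels, min_samples : int
        Selection thresholds (defaults 10, 2, 3).
    distance_tol : float
        Eigenvalue tolerance of the Euclidean-embeddability check.
    """

    def __init__(
        self,
        records: Iterable[SurveyRecord],
        traits: TraitTable,
        design: GroupingDesign,
        min_hosts_examined: int = 10,
        min_levels: int = 2,
        min_samples: int = 3,
        distance_tol: float = 1e-10,
    ) -> None:
        self.records = list(records)
        self.traits = traits
        self.design = design
        self.min_hosts_examined = min_hosts_examined
        self.min_levels = min_levels
        self.min_samples = min_samples
        self.distance_tol = distance_tol
        self._distance: DistanceMatrix | None = None
        self._lingoes_c: float | None = None
        self._assemblages: AssemblageTable | None = None

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_csv(
        cls,
        survey: str | Path,
        traits: str | Path,
        grouping: str | Path,
        trait_kinds=None,
        **kwargs,
    ) -> "FunctionalDiversityModel":
        return cls(
            asm.read_survey_csv(survey),
            TraitTable.from_csv(traits, kinds=trait_kinds),
            GroupingDesign.from_csv(grouping),
            **kwargs,
        )

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "FunctionalDiversityModel":
        """Build from a :class:`drqdiv.simulate.SyntheticDataset` bundle."""
        return cls(dataset.records, dataset.traits, dataset.design, **kwargs)

    # ------------------------------------------------------------ components
    @property
    def distance(self) -> DistanceMatrix:
        """Functional distances: scale → Gower → Lingoes → unit rescale."""
        if self._distance is None:
            scaled = scale_quantitative_traits(self.traits)
            dm = gower_dissimilarity(scaled)
            dm, c = lingoes_correction(dm, tol=self.distance_tol)
            self._distance = rescale_to_unit(dm)
            self._lingoes_c = c
        return self._distance

    @property
    def lingoes_constant(self) -> float:
        self.distance
        return self._lingoes_c

    @property
    def assemblages(self) -> AssemblageTable:
        """Pooled, filtered assemblages with relative abundances."""
        if self._assemblages is None:
            pooled = asm.pool_counts(self.records)
            kept = asm.filter_min_hosts(pooled, self.min_hosts_examined)
            self._assemblages = AssemblageTable.from_records(kept)
            self._n_dropped_hosts = len(pooled) - len(kept)
        return self._assemblages

    # ------------------------------------------------------------ fitting
    def fit(
        self,
        factor: str = "ecological",
        comparisons: Sequence[str] = COMPARISONS,
        n_perm: int = 10_000,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> "FunctionalDiversityResults":
        """Run the decomposition and the permutational tests.

        ``seed`` drives every permutation stream (one child seed per
        test, drawn in a deterministic order); ``alpha`` only flags
        significance in the output tables.
        """
        bad = [c for c in comparisons if c not in COMPARISONS]
        if bad:
            raise ValueError(f"unknown comparisons {bad}; expected {COMPARISONS}")
        table = self.assemblages
        comps = compose_table(table, self.distance)
        master = np.random.default_rng(seed)
        omnibus_rows, uni_rows, excl_rows = [], [], []
        if self._n_dropped_hosts:
            excl_rows.append(
                {
                    "stage": "min_hosts", "comparison": "", "stratum": "",
                    "reason": (
                        f"{self._n_dropped_hosts} assemblage(s) with fewer than "
                        f"{self.min_hosts_examined} hosts examined"
                    ),
                }
            )
        if table.n_dropped_empty:
            excl_rows.append(
                {
                    "stage": "empty", "comparison": "", "stratum": "",
                    "reason": f"{table.n_dropped_empty} assemblage(s) with no parasites recorded",
                }
            )

        strata: list[tuple[str, str, list, list]] = []
        if "within_host" in comparisons:
            report = asm.select_within_host_design(
                table.keys, self.design, factor, self.min_levels, self.min_samples
            )
            for _, row in report.exclusions.iterrows():
                excl_rows.append(
                    {"stage": "selection", "comparison": "within_host",
                     "stratum": row["stratum"], "reason": row["reason"]}
                )
            for host, keys in report.selected.items():
                labels = self.design.levels(keys, factor)
                strata.append(("within_host", host, keys, labels))
        if "between_host" in comparisons:
            report = asm.select_between_host_design(
                table.keys, self.design, factor, min_hosts=2, min_samples=self.min_samples
            )
            for _, row in report.exclusions.iterrows():
                excl_rows.append(
                    {"stage": "selection", "comparison": "between_host",
                     "stratum": row["stratum"], "reason": row["reason"]}
                )
            for level, keys in report.selected.items():
                labels = [k[0] for k in keys]
                strata.append(("between_host", level, keys, labels))

        for comparison, stratum, keys, labels in strata:
            sub = comps.loc[keys]
            test_seed = int(master.integers(2**31))
            try:
                dm = bray_curtis_matrix(sub)
                res = permanova_test(dm, labels, n_perm=n_perm, seed=test_seed)
            except ValueError as err:
                excl_rows.append(
                    {"stage": "test", "comparison": comparison,
                     "stratum": stratum, "reason": f"omnibus test degenerate: {err}"}
                )
                continue
            significant = res.p_value < alpha
            omnibus_rows.append(
                {
                    "comparison": comparison, "factor": factor, "stratum": stratum,
                    "n_assemblages": len(keys), "n_groups": len(res.group_sizes),
                    "statistic": res.statistic, "p_value": res.p_value,
                    "n_perm": res.n_perm, "seed": test_seed, "significant": significant,
                }
            )
            for component in ("D", "R", "Q"):
                uni_seed = int(master.integers(2**31))
                try:
                    ures = univariate_perm_anova(
                        sub[component].to_numpy(), labels, n_perm=n_perm, seed=uni_seed
                    )
                except ValueError as err:
                    excl_rows.append(
                        {"stage": "test", "comparison": comparison, "stratum": stratum,
                         "reason": f"univariate {component} test degenerate: {err}"}
                    )
                    continue
                uni_rows.append(
                    {
                        "comparison": comparison, "factor": factor, "stratum": stratum,
                        "component": component, "statistic": ures.statistic,
                        "p_value": ures.p_value, "n_perm": ures.n_perm,
                        "seed": uni_seed, "omnibus_significant": significant,
                    }
                )

        return FunctionalDiversityResults(
            model=self,
            factor=factor,
            compositions=comps,
            omnibus_tests=pd.DataFrame(omnibus_rows, columns=OMNIBUS_COLS),
            univariate_tests=pd.DataFrame(uni_rows, columns=UNIVARIATE_COLS),
            exclusions=pd.DataFrame(excl_rows, columns=EXCLUSION_COLS),
            n_perm=n_perm,
            seed=seed,
            alpha=alpha,
        )


@dataclass
class FunctionalDiversityResults:
    """Fitted decomposition plus permutational test tables."""

    model: FunctionalDiversityModel
    factor: str
    compositions: pd.DataFrame
    omnibus_tests: pd.DataFrame
    univariate_tests: pd.DataFrame
    exclusions: pd.DataFrame
    n_perm: int
    seed: int | None
    alpha: float = 0.05

    @property
    def n_tests(self) -> int:
        return len(self.omnibus_tests)

    @property
    def n_significant(self) -> int:
        return int(self.omnibus_tests["significant"].sum())

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        lines = [
            "Functional diversity structure (D/R/Q decomposition)",
            "=" * 64,
            f"Assemblages analysed:     {len(self.compositions)}",
            f"Parasite species pool:    {len(self.model.distance.ids)}",
            f"Lingoes constant:         {self.model.lingoes_constant:.6g}",
            f"Partitioning factor:      {self.factor}",
            f"Permutations per test:    {self.n_perm} (seed={self.seed})",
            f"Omnibus tests run:        {self.n_tests}"
            f" ({self.n_significant} significant at alpha={self.alpha})",
            "",
            "Mean composition:  D={:.3f}  R={:.3f}  Q={:.3f}".format(
                *self.compositions[["D", "R", "Q"]].mean()
            ),
        ]
        if self.n_tests:
            lines += [
                "",
                "Omnibus PERMANOVA (Bray-Curtis on DRQ compositions)",
                "-" * 64,
                self.omnibus_tests.drop(columns=["factor", "seed"]).to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                ),
            ]
        if len(self.exclusions):
            lines += ["", f"Exclusions: {len(self.exclusions)} (see .exclusions)"]
        return "\n".join(lines)

    def ternary_coordinates(self, group_by: str = "host_species") -> pd.DataFrame:
        return ternary_table(self.compositions, group_by=group_by)

    def plot_ternary(
        self, path: str | Path, group_by: str = "host_species",
        stratum: str | None = None, comparison: str = "within_host",
        title: str | None = None,
    ) -> Path:
        """Render a DRQ ternary diagram (optionally for one tested stratum).

        For a ``within_host`` stratum the points are that host's
        assemblages grouped by factor level; for ``between_host`` the
        points are the level's assemblages grouped by host species.
        """
        comps = self.compositions
        if stratum is not None:
            if comparison == "within_host":
                comps = comps[comps.index.get_level_values("host_species") == stratum]
                levels = self.model.design.levels(list(comps.index), self.factor)
                pts = ternary_table(comps)
                pts["group"] = levels
            else:
                levels = self.model.design.levels(list(comps.index), self.factor)
                comps = comps[[lv == stratum for lv in levels]]
                pts = ternary_table(comps, group_by="host_species")
            if title is None:
                title = f"{comparison}: {stratum}"
        else:
            if group_by == self.factor:
                pts = ternary_table(comps)
                pts["group"] = self.model.design.levels(list(comps.index), self.factor)
            else:
                pts = ternary_table(comps, group_by=group_by)
        return render_ternary(pts, path, title=title)

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compositions": outdir / "drq_compositions.csv",
            "omnibus": outdir / "omnibus_tests.csv",
            "univariate": outdir / "univariate_tests.csv",
            "exclusions": outdir / "exclusions.csv",
        }
        self.compositions.reset_index().to_csv(paths["compositions"], index=False)
        self.omnibus_tests.to_csv(paths["omnibus"], index=False)
        self.univariate_tests.to_csv(paths["univariate"], index=False)
        self.exclusions.to_csv(paths["exclusions"], index=False)
        return paths
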