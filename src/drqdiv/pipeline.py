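"""File-level orchestration: read inputs, fit, write results and figures.

Thin wrappers over :class:`~drqdiv.model.FunctionalDiversityModel` that
read the three input CSVs, run one comparison family, and write results
tables, a ternary figure per tested stratum, and a plain-text log
recording seeds and every exclusion. Used by the command-line interface;
library users normally call the model directly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .model import FunctionalDiversityModel, FunctionalDiversityResults

__all__ = ["AnalysisConfig", "run_within_host", "run_between_host", "run_all"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Paths, thresholds and randomisation settings for one analysis run."""

    survey: str
    traits: str
    grouping: str
    outdir: str
    seed: int
    factor: str = "ecological"
    scale: str = "continental"
    n_perm: int = 10_000
    min_hosts_examined: int = 10
    min_levels: int = 2
    min_samples: int = 3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.factor not in ("ecological", "geographic"):
            raise ValueError(f"invalid factor {self.factor!r}")
        if min(self.min_hosts_examined, self.min_levels, self.min_samples) < 1:
            raise ValueError("thresholds must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        return cls(**raw)


def _model(cfg: AnalysisConfig) -> FunctionalDiversityModel:
    return FunctionalDiversityModel.from_csv(
        cfg.survey, cfg.traits, cfg.grouping,
        min_hosts_examined=cfg.min_hosts_examined,
        min_levels=cfg.min_levels,
        min_samples=cfg.min_samples,
    )


def _write_outputs(
    results: FunctionalDiversityResults, cfg: AnalysisConfig, comparison: str
) -> FunctionalDiversityResults:
    outdir = Path(cfg.outdir) / comparison.replace("_", "-")
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_csv(outdir)
    for stratum in results.omnibus_tests["stratum"]:
        safe = str(stratum).replace("/", "_").replace(" ", "_")
        results.plot_ternary(
            outdir / f"ternary_{safe}.svg",
            stratum=stratum, comparison=comparison,
        )
    log = [
        f"scale: {cfg.scale}",
        f"comparison: {comparison}",
        f"factor: {cfg.factor}",
        f"n_perm: {cfg.n_perm}",
        f"seed: {cfg.seed}",
        f"thresholds: min_hosts_examined={cfg.min_hosts_examined} "
        f"min_levels={cfg.min_levels} min_samples={cfg.min_samples}",
        f"tests run: {results.n_tests}",
        f"significant (alpha={cfg.alpha}): {results.n_significant}",
        "",
        "exclusions:",
    ]
    if len(results.exclusions):
        log += [
            f"  [{row.stage}] {row.comparison} {row.stratum}: {row.reason}"
            for row in results.exclusions.itertuples()
        ]
    else:
        log.append("  none")
    if results.n_tests == 0:
        log.append("no eligible strata: empty result set")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return results


def run_within_host(cfg: AnalysisConfig) -> FunctionalDiversityResults:
    """Within each eligible host species, test across factor levels."""
    results = _model(cfg).fit(
        factor=cfg.factor, comparisons=("within_host",),
        n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha,
    )
    return _write_outputs(results, cfg, "within_host")


def run_between_host(cfg: AnalysisConfig) -> FunctionalDiversityResults:
    """Within each eligible factor level, test across host species."""
    results = _model(cfg).fit(
        factor=cfg.factor, comparisons=("between_host",),
        n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha,
    )
    return _write_outputs(results, cfg, "between_host")


def run_all(cfg: AnalysisConfig) -> dict[str, FunctionalDiversityResults]:
    return {
        "within_host": run_within_host(cfg),
        "between_host": run_between_host(cfg),
    }
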