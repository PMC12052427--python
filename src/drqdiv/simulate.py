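"""Synthetic host–parasite survey data with controllable group structure.

The generator emulates the statistical shape of multi-region ectoparasite
surveys: for each (host species, sampling unit) a number of host
individuals is examined and per-parasite-species totals are recorded.
Counts are negative-binomial — ectoparasites are strongly aggregated
among host individuals, which is also why assemblages from few examined
hosts are filtered out downstream. Parasite species carry five
quantitative traits (lognormal, later min–max scaled) and one three-level
nominal trait, mirroring typical flea/mite trait sets.

Latent structure: every parasite species has a community-wide mean
abundance; each host species perturbs it (host specificity of parasite
assemblages), and each unit adds lognormal noise. Between-group effects
are injected on these latent relative-abundance profiles — never on the
realised counts — so filters and normalisation behave exactly as on null
data. With ``effect_size = 0`` the units of every factor level are
exchangeable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from .assemblage import GroupingDesign, SurveyRecord, write_survey_csv
from .traits import TraitTable

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_trait_table",
    "simulate_survey",
    "inject_effect",
    "simulate_null_dataset",
]

EFFECT_MODES = ("dominance", "evenness", "trait")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and distributional knobs for the generator.

    Defaults give the standard small scenario: 15 parasite species,
    4 host species, 2 ecological levels × 6 units (12 units, crossed with
    2 geographic levels), 20–100 hosts examined per assemblage, and
    aggregated counts (negative binomial, k = 0.5 per examined host).
    """

    seed: int
    n_parasite_species: int = 15
    n_host_species: int = 4
    n_units_per_level: int = 6
    ecological_levels: tuple[str, ...] = ("forest", "steppe")
    geographic_levels: tuple[str, ...] = ("west", "east")
    n_quant_traits: int = 5
    nominal_traits: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"microhabitat": ("body", "nest", "both")}
    )
    missingness: float = 0.0
    hosts_examined: tuple[int, int] = (20, 100)
    dispersion_k: float = 0.5
    abundance_scale: float = 0.5
    host_divergence: float = 0.5
    unit_sd: float = 0.3
    effect_size: float = 0.0
    effect_factor: str = "ecological"
    effect_level: str | None = None
    effect_mode: str = "dominance"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.dispersion_k <= 0:
            raise ValueError("dispersion k must be positive")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if self.effect_mode not in EFFECT_MODES:
            raise ValueError(f"unknown effect mode {self.effect_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        for key in ("ecological_levels", "geographic_levels", "hosts_examined"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "nominal_traits" in raw:
            raw["nominal_traits"] = {k: tuple(v) for k, v in raw["nominal_traits"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["ecological_levels"] = list(self.ecological_levels)
        raw["geographic_levels"] = list(self.geographic_levels)
        raw["hosts_examined"] = list(self.hosts_examined)
        raw["nominal_traits"] = {k: list(v) for k, v in self.nominal_traits.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated input bundle: traits, pooled survey records, design."""

    config: SyntheticConfig
    traits: TraitTable
    records: list[SurveyRecord]
    design: GroupingDesign

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "traits": outdir / "traits.csv",
            "survey": outdir / "survey.csv",
            "grouping": outdir / "grouping.csv",
            "config": outdir / "config.yaml",
        }
        self.traits.to_csv(paths["traits"])
        write_survey_csv(self.records, paths["survey"])
        self.design.to_csv(paths["grouping"])
        self.config.to_yaml(paths["config"])
        return paths


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


QUANT_NAMES = ("abundance_principal_host", "host_specificity", "host_spectrum_pd",
               "body_size", "sexual_dimorphism")


def simulate_trait_table(cfg: SyntheticConfig) -> TraitTable:
    """Draw a species × trait table (deterministic given the seed).

    Quantitative traits are lognormal(0, 1) draws (scaled downstream);
    nominal categories are drawn uniformly. Missingness, if any, is
    applied cell-wise but never removes a species' last observed trait or
    a trait's last observed value.
    """
    rng = _rng(cfg, 1)
    species = [f"p{i + 1:02d}" for i in range(cfg.n_parasite_species)]
    quant_names = [
        QUANT_NAMES[i] if i < len(QUANT_NAMES) else f"quant_trait_{i + 1}"
        for i in range(cfg.n_quant_traits)
    ]
    data = {
        name: rng.lognormal(mean=0.0, sigma=1.0, size=len(species))
        for name in quant_names
    }
    df = pd.DataFrame(data, index=pd.Index(species, name="species"))
    for name, cats in cfg.nominal_traits.items():
        df[name] = rng.choice(list(cats), size=len(species))
    if cfg.missingness > 0:
        mask = rng.random(df.shape) < cfg.missingness
        # keep at least one observed trait per species and per column
        for i in range(mask.shape[0]):
            if mask[i].all():
                mask[i, rng.integers(mask.shape[1])] = False
        for j in range(mask.shape[1]):
            if mask[:, j].all():
                mask[rng.integers(mask.shape[0]), j] = False
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return TraitTable(df, tuple(quant_names), tuple(cfg.nominal_traits))


def _unit_layout(cfg: SyntheticConfig) -> pd.DataFrame:
    """Units in blocks by ecological level, geographic level alternating."""
    rows = []
    u = 0
    for eco in cfg.ecological_levels:
        for i in range(cfg.n_units_per_level):
            rows.append(
                {
                    "unit": f"u{u + 1:02d}",
                    "ecological": eco,
                    "geographic": cfg.geographic_levels[i % len(cfg.geographic_levels)],
                }
            )
            u += 1
    return pd.DataFrame(rows)


def inject_effect(
    profiles: pd.DataFrame,
    design: GroupingDesign,
    level: str,
    effect_size: float,
    mode: str = "dominance",
    factor: str = "ecological",
    dm: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Shift latent abundance profiles of assemblages in one factor level.

    ``profiles`` is indexed by (host_species, unit), columns are parasite
    species; row totals are preserved. Modes:

    * ``dominance`` — power-tilt p ∝ p^(1+e): concentrates mass on the
      already-dominant species, raising D;
    * ``evenness`` — p ∝ p^(1/(1+e)): flattens the profile, lowering D;
    * ``trait`` — blends toward a reassignment of the same abundance
      values in which mass sits on functionally central (mutually
      similar) species: Q drops, R rises, S is approximately preserved.
      Requires ``dm``.

    ``effect_size = 0`` is the identity.
    """
    if mode not in EFFECT_MODES:
        raise ValueError(f"unknown effect mode {mode!r}; expected one of {EFFECT_MODES}")
    level_col = design.table[factor] if factor in ("ecological", "geographic") else None
    if factor == "host":
        affected_units = None
        if level not in set(design.table["host_species"]):
            raise ValueError(f"unknown host level {level!r}")
    else:
        if level not in set(level_col):
            raise ValueError(f"unknown {factor} level {level!r}")
        affected_units = set(design.table.loc[level_col == level, "unit"])
    if effect_size == 0:
        return profiles.copy()
    if mode == "trait":
        if dm is None:
            raise ValueError("mode 'trait' requires the functional distance matrix")
        centrality = pd.Series(
            np.asarray(dm.data).mean(axis=0), index=list(dm.ids)
        ).reindex(profiles.columns)

    out = profiles.copy()
    lam = effect_size / (1.0 + effect_size)
    for key in out.index:
        host, unit = key
        if factor == "host":
            if host != level:
                continue
        elif unit not in affected_units:
            continue
        p = out.loc[key].to_numpy(dtype=float)
        total = p.sum()
        q = p / total
        if mode == "dominance":
            w = q ** (1.0 + effect_size)
        elif mode == "evenness":
            w = q ** (1.0 / (1.0 + effect_size))
        else:  # trait: same abundance multiset, mass onto similar species
            order_central = np.argsort(centrality.to_numpy(), kind="stable")
            target = np.empty_like(q)
            target[order_central] = np.sort(q)[::-1]
            w = (1.0 - lam) * q + lam * target
        out.loc[key] = w / w.sum() * total
    return out


def simulate_survey(
    cfg: SyntheticConfig, traits: TraitTable, dm: DistanceMatrix | None = None
) -> tuple[list[SurveyRecord], GroupingDesign]:
    """Draw pooled survey records plus the grouping design.

    One record per (host species, unit). Counts are negative binomial with
    mean ``n_examined × latent mean abundance`` and shape
    ``k × n_examined`` (the pooled total over n aggregated hosts). The
    configured effect, if any, tilts the latent profiles of the affected
    factor level before counts are drawn.
    """
    rng = _rng(cfg, 2)
    species = traits.species_ids
    s = len(species)
    hosts = [f"h{i + 1}" for i in range(cfg.n_host_species)]
    layout = _unit_layout(cfg)

    base = cfg.abundance_scale * rng.lognormal(0.0, 1.0, size=s)
    host_profiles = {
        h: base * np.exp(cfg.host_divergence * rng.normal(size=s)) for h in hosts
    }

    index = pd.MultiIndex.from_tuples(
        [(h, u) for h in hosts for u in layout["unit"]], names=["host_species", "unit"]
    )
    latent = pd.DataFrame(
        [
            host_profiles[h] * np.exp(cfg.unit_sd * rng.normal(size=s))
            for h, _ in index
        ],
        index=index,
        columns=species,
    )
    design = GroupingDesign(
        pd.DataFrame(
            [
                {"host_species": h, "unit": r.unit,
                 "ecological": r.ecological, "geographic": r.geographic}
                for h in hosts
                for r in layout.itertuples()
            ]
        )
    )
    if cfg.effect_size > 0:
        level = cfg.effect_level
        if level is None:
            level = {
                "ecological": cfg.ecological_levels[-1],
                "geographic": cfg.geographic_levels[-1],
                "host": hosts[-1],
            }[cfg.effect_factor]
        latent = inject_effect(
            latent, design, level, cfg.effect_size, cfg.effect_mode,
            factor=cfg.effect_factor, dm=dm,
        )

    lo, hi = cfg.hosts_examined
    records = []
    for key in index:
        n_ex = int(rng.integers(lo, hi + 1))
        mu = n_ex * latent.loc[key].to_numpy()
        shape = cfg.dispersion_k * n_ex
        counts = rng.negative_binomial(shape, shape / (shape + mu))
        records.append(
            SurveyRecord(
                key[0], key[1], n_ex,
                {sp: int(c) for sp, c in zip(species, counts)},
            )
        )
    return records, design


def simulate_null_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Full input bundle with no group effect, sized to pass the filters.

    Errors if the configuration cannot satisfy the downstream selection
    rules (≥ 10 hosts examined, ≥ 2 factor levels, ≥ 3 samples per host).
    """
    cfg = replace(cfg, effect_size=0.0)
    if cfg.hosts_examined[0] < 10:
        raise ValueError(
            "hosts_examined lower bound < 10: records would fail the "
            "minimum-hosts-examined filter"
        )
    if len(cfg.ecological_levels) < 2 or len(cfg.geographic_levels) < 2:
        raise ValueError("need >= 2 levels per factor to pass the design filters")
    if cfg.n_units_per_level * len(cfg.ecological_levels) < 3:
        raise ValueError("fewer than 3 units: hosts would fail the min-samples filter")
    traits = simulate_trait_table(cfg)
    records, design = simulate_survey(cfg, traits)
    return SyntheticDataset(cfg, traits, records, design)
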