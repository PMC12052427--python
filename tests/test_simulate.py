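"""Determinism, distributional shape and effect injection of the generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from drqdiv import (
    AssemblageTable,
    FunctionalDiversityModel,
    SyntheticConfig,
    filter_min_hosts,
    gower_dissimilarity,
    inject_effect,
    pool_counts,
    scale_quantitative_traits,
    select_within_host_design,
    simulate_null_dataset,
    simulate_survey,
    simulate_trait_table,
)
from drqdiv.drq import compose_table
from drqdiv.traits import lingoes_correction, rescale_to_unit


def full_distance(traits):
    dm, _ = lingoes_correction(gower_dissimilarity(scale_quantitative_traits(traits)))
    return rescale_to_unit(dm)


class TestTraitSimulation:
    def test_no_missing_cells_by_default(self):
        t = simulate_trait_table(SyntheticConfig(seed=1))
        assert not t.data.isna().any().any()
        assert t.n_species == 15
        assert len(t.quantitative) == 5 and len(t.nominal) == 1

    def test_same_seed_identical_tables(self):
        a = simulate_trait_table(SyntheticConfig(seed=9))
        b = simulate_trait_table(SyntheticConfig(seed=9))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_missingness_respects_floor_constraints(self):
        cfg = SyntheticConfig(seed=3, missingness=0.4)
        t = simulate_trait_table(cfg)
        assert t.data.isna().any().any()
        assert not t.data.isna().all(axis=1).any()
        assert not t.data.isna().all(axis=0).any()

    def test_simulated_traits_survive_the_distance_pipeline(self):
        cfg = SyntheticConfig(seed=5, n_parasite_species=20)
        dm = full_distance(simulate_trait_table(cfg))
        d = dm.data
        np.testing.assert_array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.max() == pytest.approx(1.0)
        assert d.min() >= 0


class TestSurveySimulation:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(seed=2)
        t = simulate_trait_table(cfg)
        r1, d1 = simulate_survey(cfg, t)
        r2, d2 = simulate_survey(cfg, t)
        assert [(r.key, dict(r.counts), r.n_examined) for r in r1] == \
            [(r.key, dict(r.counts), r.n_examined) for r in r2]
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_design_covers_every_record(self):
        cfg = SyntheticConfig(seed=4)
        records, design = simulate_survey(cfg, simulate_trait_table(cfg))
        for rec in records:
            assert design.level(rec.key, "ecological") in cfg.ecological_levels
            assert design.level(rec.key, "geographic") in cfg.geographic_levels

    def test_large_k_approaches_poisson_variance(self):
        # aggregate counts over many replicate units: variance/mean -> 1
        cfg = SyntheticConfig(
            seed=6, dispersion_k=500.0, n_host_species=1, n_units_per_level=150,
            unit_sd=0.0, hosts_examined=(50, 50), n_parasite_species=5,
        )
        records, _ = simulate_survey(cfg, simulate_trait_table(cfg))
        counts = np.array([[r.counts[sp] for sp in sorted(r.counts)] for r in records])
        ratio = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        small_k = dataclasses.replace(cfg, dispersion_k=0.01)
        records2, _ = simulate_survey(small_k, simulate_trait_table(small_k))
        counts2 = np.array([[r.counts[sp] for sp in sorted(r.counts)] for r in records2])
        ratio2 = counts2.var(axis=0, ddof=1) / counts2.mean(axis=0)
        assert np.median(ratio) < 2  # near-Poisson once k is large
        assert np.median(ratio2) > 5 * np.median(ratio)  # aggregation inflates variance


class TestEffectInjection:
    def setup_profiles(self, seed=0):
        cfg = SyntheticConfig(seed=seed)
        traits = simulate_trait_table(cfg)
        records, design = simulate_survey(cfg, traits)
        rng = np.random.default_rng(seed)
        index = pd.MultiIndex.from_tuples([r.key for r in records],
                                          names=["host_species", "unit"])
        profiles = pd.DataFrame(
            rng.lognormal(size=(len(records), traits.n_species)),
            index=index, columns=traits.species_ids,
        )
        return cfg, traits, design, profiles

    def test_zero_effect_is_identity(self):
        _, _, design, profiles = self.setup_profiles()
        out = inject_effect(profiles, design, "steppe", 0.0, "dominance")
        pd.testing.assert_frame_equal(out, profiles)

    def test_unknown_mode_and_level_error(self):
        _, _, design, profiles = self.setup_profiles()
        with pytest.raises(ValueError, match="mode"):
            inject_effect(profiles, design, "steppe", 1.0, "chaos")
        with pytest.raises(ValueError, match="level"):
            inject_effect(profiles, design, "tundra", 1.0, "dominance")

    def test_row_totals_preserved_and_only_level_touched(self):
        _, _, design, profiles = self.setup_profiles()
        out = inject_effect(profiles, design, "steppe", 2.0, "dominance")
        np.testing.assert_allclose(out.sum(axis=1), profiles.sum(axis=1))
        steppe_units = set(
            design.table.loc[design.table.ecological == "steppe", "unit"]
        )
        for key in profiles.index:
            same = np.allclose(out.loc[key], profiles.loc[key])
            assert same != (key[1] in steppe_units)

    def test_dominance_mode_raises_d_component(self):
        d_shift = self._component_shift("dominance", "D")
        assert d_shift > 0.05

    def test_trait_mode_lowers_q_raises_r_keeps_s(self):
        q_shift = self._component_shift("trait", "Q")
        r_shift = self._component_shift("trait", "R")
        s_shift = self._component_shift("trait", "S")
        assert q_shift < -0.02
        assert r_shift > 0.04
        # S moves much less than the redundancy gain ("approximately preserved")
        assert abs(s_shift) < r_shift / 2

    def _component_shift(self, mode, component, n_rep=10, effect=5.0):
        """Mean (affected − unaffected) difference across replicates."""
        shifts = []
        for rep in range(n_rep):
            cfg = SyntheticConfig(
                seed=900 + rep, effect_size=effect, effect_mode=mode,
            )
            traits = simulate_trait_table(cfg)
            dm = full_distance(traits)
            records, design = simulate_survey(cfg, traits, dm=dm)
            table = AssemblageTable.from_records(filter_min_hosts(pool_counts(records)))
            comps = compose_table(table, dm)
            levels = np.array(design.levels(list(comps.index), "ecological"))
            affected = comps[levels == cfg.ecological_levels[-1]][component].mean()
            control = comps[levels != cfg.ecological_levels[-1]][component].mean()
            shifts.append(affected - control)
        return float(np.mean(shifts))


class TestNullDataset:
    def test_default_config_passes_all_filters(self):
        ds = simulate_null_dataset(SyntheticConfig(seed=10))
        pooled = filter_min_hosts(pool_counts(ds.records))
        assert len(pooled) == len(ds.records)  # nothing dropped
        table = AssemblageTable.from_records(pooled)
        report = select_within_host_design(table.keys, ds.design, "ecological")
        assert len(report.selected) >= 1

    def test_effect_size_forced_to_zero(self):
        ds = simulate_null_dataset(SyntheticConfig(seed=11, effect_size=5.0))
        assert ds.config.effect_size == 0.0

    def test_too_small_config_errors_naming_filter(self):
        with pytest.raises(ValueError, match="hosts"):
            simulate_null_dataset(SyntheticConfig(seed=1, hosts_examined=(5, 8)))
        with pytest.raises(ValueError, match="levels"):
            simulate_null_dataset(SyntheticConfig(seed=1, ecological_levels=("one",)))

    def test_same_seed_gives_byte_identical_csv_bundle(self, tmp_path):
        ds1 = simulate_null_dataset(SyntheticConfig(seed=12))
        ds2 = simulate_null_dataset(SyntheticConfig(seed=12))
        p1 = ds1.to_csv(tmp_path / "a")
        p2 = ds2.to_csv(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_between_group_exceeds_within_group_drq_distance_under_effect(self):
        from drqdiv.permutation import bray_curtis_matrix

        gaps = []
        for rep in range(50):
            cfg = SyntheticConfig(seed=2000 + rep, effect_size=3.0)
            traits = simulate_trait_table(cfg)
            dm = full_distance(traits)
            records, design = simulate_survey(cfg, traits, dm=dm)
            table = AssemblageTable.from_records(filter_min_hosts(pool_counts(records)))
            comps = compose_table(table, dm)
            host = comps.index.get_level_values("host_species") == "h1"
            sub = comps[host]
            labels = np.array(design.levels(list(sub.index), "ecological"))
            bc = bray_curtis_matrix(sub).data
            same = np.equal.outer(labels, labels)
            iu = np.triu_indices(len(labels), 1)
            within = bc[iu][same[iu]].mean()
            between = bc[iu][~same[iu]].mean()
            gaps.append(between - within)
        assert np.mean(gaps) > 0
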