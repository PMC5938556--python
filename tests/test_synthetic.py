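import numpy as np
import pytest

from dustair import qc
from dustair.errors import ConfigurationError, DataError
from dustair.synthetic import (
    DEFAULT_GROUP_SIZES,
    EnvironmentProfile,
    SyntheticConfig,
    apply_transfer,
    build_environment_profiles,
    build_taxonomy,
    child_rng,
    default_taxonomy_blocks,
    firmicutes_block_mass,
    generate_dataset,
    simulate_negative_controls,
    simulate_sample_counts,
    write_dataset,
)


@pytest.fixture(scope="module")
def default_dataset():
    return generate_dataset(SyntheticConfig(seed=123))


def small_config(**kwargs):
    defaults = dict(
        group_sizes={("pig_stable", "winter"): 8, ("farm_home", "winter"): 8,
                     ("suburban_home", "winter"): 8},
        n_controls=3, n_replicate_pairs=2, seed=0,
    )
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


class TestProfiles:
    def test_firmicutes_mass_ordered_and_at_defaults(self):
        cfg = SyntheticConfig(seed=0)
        profiles = build_environment_profiles(cfg)
        masses = {e: firmicutes_block_mass(cfg, p) for e, p in profiles.items()}
        assert masses["pig_stable"] == pytest.approx(0.75, abs=0.01)
        assert masses["farm_home"] == pytest.approx(0.55, abs=0.01)
        assert masses["suburban_home"] == pytest.approx(0.35, abs=0.01)
        assert masses["pig_stable"] > masses["farm_home"] > masses["suburban_home"]

    def test_absolute_abundance_ordering_and_stable_home_gap(self):
        profiles = build_environment_profiles(SyntheticConfig(seed=0))
        m = {e: p.log10_abundance_mean for e, p in profiles.items()}
        assert m["pig_stable"] > m["farm_home"] > m["suburban_home"]
        assert m["pig_stable"] - m["farm_home"] >= 1.0

    def test_seasonal_shift_only_in_suburban(self):
        profiles = build_environment_profiles(SyntheticConfig(seed=0))
        sub = profiles["suburban_home"]
        winter = sub.tilted_composition("winter")
        assert not np.allclose(winter, sub.base_composition)
        for env in ("pig_stable", "farm_home"):
            p = profiles[env]
            assert np.allclose(p.tilted_composition("winter"), p.base_composition)

    def test_compositions_are_simplex_points(self):
        profiles = build_environment_profiles(SyntheticConfig(seed=0))
        for p in profiles.values():
            assert p.base_composition.min() >= 0
            assert p.base_composition.sum() == pytest.approx(1.0, abs=1e-9)
            for season in ("winter", "summer"):
                assert p.tilted_composition(season).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_profile_accepted(self):
        k = 10
        profile = EnvironmentProfile("uniform", np.full(k, 1 / k), 5.0, 5.0, 0.1)
        assert np.allclose(profile.base_composition, 1 / k)

    def test_overlapping_blocks_named(self):
        with pytest.raises(ConfigurationError, match="Firmicutes"):
            SyntheticConfig(n_otus=20, taxonomy_blocks={
                "Firmicutes": (0, 12), "Proteobacteria": (10, 20)})

    def test_incomplete_blocks_rejected(self):
        with pytest.raises(ConfigurationError, match="uncovered"):
            SyntheticConfig(n_otus=20, taxonomy_blocks={
                "Firmicutes": (0, 10), "Proteobacteria": (10, 18)})


class TestSamplingPrimitives:
    def test_depth_zero_gives_all_zeros(self):
        profile = EnvironmentProfile("x", np.full(5, 0.2), 10.0, 5.0, 0.1)
        counts = simulate_sample_counts(profile, "winter", 0, np.random.default_rng(0))
        assert counts.sum() == 0 and counts.size == 5

    def test_law_of_large_numbers_at_high_concentration(self):
        profile = EnvironmentProfile("x", np.full(4, 0.25), 1e9, 5.0, 0.1)
        counts = simulate_sample_counts(profile, None, 4_000_000,
                                        np.random.default_rng(1))
        assert counts.sum() == 4_000_000
        assert np.allclose(counts, 1_000_000, rtol=0.01)

    def test_seeded_determinism(self):
        profile = EnvironmentProfile("x", np.full(6, 1 / 6), 20.0, 5.0, 0.1)
        a = simulate_sample_counts(profile, "winter", 5000, np.random.default_rng(9))
        b = simulate_sample_counts(profile, "winter", 5000, np.random.default_rng(9))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "tau, expected",
        [(0.0, (0.8, 0.2)), (1.0, (0.2, 0.8)), (0.5, (0.5, 0.5))],
    )
    def test_apply_transfer_mixture(self, tau, expected):
        got = apply_transfer((0.8, 0.2), (0.2, 0.8), tau)
        assert np.allclose(got, expected)
        assert got.sum() == pytest.approx(1.0)

    def test_apply_transfer_tau_out_of_range(self):
        with pytest.raises(ConfigurationError):
            apply_transfer((1.0, 0.0), (0.0, 1.0), 1.5)


class TestNegativeControls:
    def test_no_tag_switching_means_pure_contaminants(self):
        cfg = small_config(tag_switch_rate=0.0)
        real = np.ones((cfg.n_otus, 5), dtype=np.int64) * 3
        for idx in cfg.contaminant_otus:
            real[idx, :] = 0
        controls = simulate_negative_controls(real, cfg, np.random.default_rng(0))
        contaminant_rows = sorted(cfg.contaminant_otus)
        other = np.delete(controls, contaminant_rows, axis=0)
        assert other.sum() == 0
        assert controls[contaminant_rows, :].sum() > 0

    def test_insufficient_level_raises_advice(self):
        cfg = small_config()
        cfg.contaminant_otus = {next(iter(cfg.contaminant_otus)): 0.0}
        real = np.ones((cfg.n_otus, 5), dtype=np.int64) * 100
        with pytest.raises(ConfigurationError, match="raise its control level"):
            simulate_negative_controls(real, cfg, np.random.default_rng(0))

    def test_planted_contaminants_recovered_exactly_over_seeds(self):
        # generator guarantee + downstream filter as oracle: sensitivity 1,
        # false flags 0, across 20 seeded runs
        for seed in range(20):
            ds = generate_dataset(small_config(seed=seed))
            _, log = qc.remove_contaminant_otus(ds.counts, ds.metadata)
            assert sorted(log.otus_removed) == ds.truth["contaminant_otus"]


class TestQpcrPanel:
    def test_zero_measurement_sd_recovers_truth(self):
        ds = generate_dataset(small_config(qpcr_measurement_sd=0.0,
                                           qpcr_samples_per_group=5))
        truth = ds.truth["log10_copies_per_m2"]
        for _, row in ds.qpcr.iterrows():
            assert row["measured_copies_per_m2"] == pytest.approx(
                10 ** truth[row["sample_id"]], rel=1e-9)

    def test_stable_summer_exceeds_winter_in_expectation(self, default_dataset):
        panel = default_dataset.qpcr
        stable = panel[panel["environment"] == "pig_stable"]
        log_mean = stable.groupby("season")["true_copies_per_m2"].apply(
            lambda v: np.log10(v).mean())
        assert log_mean["summer"] > log_mean["winter"]

    def test_environment_ordering_in_panel(self, default_dataset):
        panel = default_dataset.qpcr
        means = panel.groupby("environment")["measured_copies_per_m2"].apply(
            lambda v: np.log10(v).mean())
        assert means["pig_stable"] > means["farm_home"] > means["suburban_home"]


class TestGenerateDataset:
    def test_default_design_has_267_study_samples(self, default_dataset):
        meta = default_dataset.metadata.df
        study = meta[(~meta["is_control"]) & (meta["replicate_of"] == "")]
        assert len(study) == 267 == sum(DEFAULT_GROUP_SIZES.values())
        counts = study.groupby(["environment", "season"]).size()
        for (env, season), n in DEFAULT_GROUP_SIZES.items():
            assert counts[(env, season)] == n

    def test_no_extras_means_exactly_group_size_columns(self):
        cfg = small_config(n_controls=0, n_replicate_pairs=0)
        ds = generate_dataset(cfg)
        assert ds.counts.n_samples == sum(cfg.group_sizes.values())

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            write_dataset(generate_dataset(small_config(seed=77)), tmp_path / d)
        for name in ("counts.tsv", "metadata.tsv", "taxonomy.tsv", "qpcr.tsv",
                     "truth.json", "config.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_true_compositions_are_simplex_points(self, default_dataset):
        comp = default_dataset.truth["true_compositions"]
        assert np.allclose(comp.sum(axis=0), 1.0, atol=1e-9)

    def test_farm_pairing_is_one_to_one(self, default_dataset):
        meta = default_dataset.metadata.df
        winter = meta[(meta["season"] == "winter") & (meta["replicate_of"] == "")]
        stables = set(winter[winter["environment"] == "pig_stable"]["farm_id"])
        homes = set(winter[winter["environment"] == "farm_home"]["farm_id"])
        assert stables == homes and len(stables) == 43

    def test_firmicutes_ordering_in_generated_counts(self, default_dataset):
        cfg = default_dataset.config
        start, stop = cfg.taxonomy_blocks["Firmicutes"]
        meta = default_dataset.metadata.df
        frac = {}
        for env in ("pig_stable", "farm_home", "suburban_home"):
            sids = meta.index[(meta["environment"] == env)
                              & (meta["replicate_of"] == "")]
            cols = default_dataset.counts.df[list(sids)]
            fractions = cols.iloc[start:stop].sum(axis=0) / cols.sum(axis=0)
            assert len(fractions) >= 30
            frac[env] = fractions.mean()
        assert frac["pig_stable"] > frac["farm_home"] > frac["suburban_home"]

    def test_collection_days_within_reported_range(self, default_dataset):
        days = default_dataset.metadata.df["collection_days"].dropna()
        assert days.min() >= 7 and days.max() <= 73

    def test_taxonomy_covers_every_otu(self, default_dataset):
        tax = default_dataset.taxonomy
        assert set(tax.otu_ids) == set(default_dataset.counts.otu_ids)
        named = [lin[5] for lin in tax.lineages.values() if len(lin) == 6]
        assert "Lactobacillus" in named and "Ruminiclostridium_5" in named

    def test_named_rng_streams_are_stable(self):
        a = child_rng(5, "composition").integers(0, 1000, 4)
        b = child_rng(5, "composition").integers(0, 1000, 4)
        c = child_rng(5, "controls").integers(0, 1000, 4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_default_blocks_partition_otus(self):
        blocks = default_taxonomy_blocks(300)
        covered = np.zeros(300, dtype=int)
        for start, stop in blocks.values():
            covered[start:stop] += 1
        assert (covered == 1).all()
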