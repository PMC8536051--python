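"""Generator moments, determinism, and fixture round-trips."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import small_simulation_config
from vdfreq.catalog import SnpCatalog
from vdfreq.frequencies import (
    GLOBAL,
    PopulationPanel,
    compute_eaf,
    read_frequency_table,
    read_vcf_genotypes,
)
from vdfreq.grs import phase_concordance_filter
from vdfreq.simulate import (
    PopulationSpec,
    SimulationConfig,
    emit_fixtures,
    simulate_allele_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_two_phase,
)


def one_pop_config(fst, n_snps, seed=0, p_range=(0.5, 0.5001)):
    return SimulationConfig(
        populations=(PopulationSpec("P", 10, fst, 0.0),),
        n_snps=n_snps,
        ancestral_freq_range=p_range,
        seed=seed,
    )


class TestAlleleFrequencies:
    def test_small_fst_limit_tracks_ancestral(self):
        config = one_pop_config(1e-6, 2000, p_range=(0.05, 0.95))
        freq, truth = simulate_allele_frequencies(config)
        close = np.abs(freq.loc["P"].to_numpy() - truth.ancestral_freq) < 1e-2
        assert close.mean() >= 0.99

    def test_balding_nichols_variance(self):
        # Var = F p0 (1-p0): at p0 = 0.5, F = 0.1 -> 0.025
        config = one_pop_config(0.1, 10_000)
        freq, _ = simulate_allele_frequencies(config)
        v = float(np.var(freq.loc["P"].to_numpy()))
        assert v == pytest.approx(0.025, abs=0.002)

    def test_deterministic_under_seed(self):
        config = small_simulation_config(seed=3)
        f1, _ = simulate_allele_frequencies(config)
        f2, _ = simulate_allele_frequencies(config)
        pd.testing.assert_frame_equal(f1, f2)

    def test_clade_structure_correlates_within_clades(self):
        config = small_simulation_config(seed=5, n_snps=300)
        freq, truth = simulate_allele_frequencies(config)
        within = np.corrcoef(freq.loc["EAS"], freq.loc["KOR"])[0, 1]
        p0 = truth.ancestral_freq
        # deviations from the ancestral frequency are clade-driven
        dev_eas = freq.loc["EAS"].to_numpy() - p0
        dev_eur = freq.loc["EUR"].to_numpy() - p0
        between = np.corrcoef(dev_eas, dev_eur)[0, 1]
        assert within > 0.9
        assert abs(between) < 0.3


class TestGenotypes:
    def test_fixed_frequency_dosage_moments(self):
        config = SimulationConfig(
            populations=(PopulationSpec("P", 10_000, 0.01, 0.0),), n_snps=1, seed=2
        )
        freq = pd.DataFrame({"snp": [0.3]}, index=["P"])
        gm, _ = simulate_genotypes(freq, config)
        # Binomial(2, 0.3): mean 0.6, SD of the mean over 1e4 draws ~ 0.0065
        assert gm.dosages.mean() == pytest.approx(0.6, abs=0.02)

    def test_extreme_frequencies(self):
        config = SimulationConfig(
            populations=(PopulationSpec("P", 50, 0.01, 0.0),), n_snps=2, seed=2
        )
        freq = pd.DataFrame({"a": [1.0], "b": [0.0]}, index=["P"])
        gm, _ = simulate_genotypes(freq, config)
        assert (gm.dosages[:, 0] == 2).all()
        assert (gm.dosages[:, 1] == 0).all()

    def test_deterministic_under_seed(self, sim_config):
        freq, _ = simulate_allele_frequencies(sim_config)
        g1, _ = simulate_genotypes(freq, sim_config)
        g2, _ = simulate_genotypes(freq, sim_config)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestPhenotypes:
    def test_zero_noise_is_exact_linear_model(self):
        config = replace(small_simulation_config(), sigma=0.0)
        grs = {"A": 0.5, "B": 0.6}
        lat = {"A": 10.0, "B": 50.0}
        table = simulate_phenotypes(grs, lat, config)
        for _, row in table.iterrows():
            expected = (
                config.beta0
                + config.beta_grs * grs[row["population"]]
                + config.beta_lat * lat[row["population"]]
            )
            assert row["concentration_ng_per_ml"] == pytest.approx(expected)

    def test_mismatched_tables_raise(self):
        config = small_simulation_config()
        with pytest.raises(ValueError):
            simulate_phenotypes({"A": 0.5}, {"B": 10.0}, config)


class TestTwoPhase:
    def test_injected_discordance_is_detected_exactly(self):
        config = small_simulation_config(seed=21, n_snps=50)
        freq, _ = simulate_allele_frequencies(config)
        p = freq.loc["KOR"].to_numpy()
        ft, fp, injected = simulate_two_phase(p, 1722, 1099, n_discordant=3,
                                              config=config)
        diffs = np.abs(ft - fp)
        assert len(injected) == 3
        assert (diffs[injected] > 0.10).all()

    def test_equal_phases_identical(self):
        config = small_simulation_config(seed=22)
        freq, _ = simulate_allele_frequencies(config)
        ft, fp, injected = simulate_two_phase(
            freq.loc["KOR"].to_numpy(), 500, 500, 0, config=config
        )
        assert np.array_equal(ft, fp)
        assert injected.size == 0

    def test_sampling_noise_stays_below_threshold(self):
        # without injection, subsampling noise at these cohort sizes should
        # essentially never reach the 0.10 exclusion threshold
        config = small_simulation_config(seed=23, n_snps=300)
        freq, _ = simulate_allele_frequencies(config)
        ft, fp, _ = simulate_two_phase(
            freq.loc["KOR"].to_numpy(), 1722, 1099, 0, config=config
        )
        assert np.max(np.abs(ft - fp)) < 0.10


class TestFixtureRoundTrips:
    def test_vcf_round_trip_reproduces_dosages(self, fixture_dir, sim_config):
        panel = PopulationPanel.from_tsv(fixture_dir["sample_map"])
        freq, _ = simulate_allele_frequencies(sim_config)
        vcf_labels = [l for l in freq.index if l != "KOR"]
        cfg = replace(
            sim_config,
            populations=tuple(p for p in sim_config.populations if p.label != "KOR"),
        )
        genotypes, _ = simulate_genotypes(freq.loc[vcf_labels], cfg)
        from vdfreq.simulate import _simulated_catalog

        catalog = _simulated_catalog(list(freq.columns))
        back = read_vcf_genotypes(fixture_dir["vcf"], panel, catalog)
        assert back.sample_ids == genotypes.sample_ids
        assert np.array_equal(back.dosages, genotypes.dosages, equal_nan=True)

    def test_krgdb_round_trip_reproduces_frequencies(self, fixture_dir, sim_config):
        from vdfreq.simulate import _simulated_catalog

        freq, _ = simulate_allele_frequencies(sim_config)
        catalog = _simulated_catalog(list(freq.columns))
        table = read_frequency_table(fixture_dir["krgdb"], catalog, "KOR")
        for j, rsid in enumerate(freq.columns):
            assert table.eaf(rsid, "KOR") == pytest.approx(
                float(freq.loc["KOR"].iloc[j]), abs=1e-6
            )

    def test_emitted_set_is_deterministic(self, tmp_path, sim_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = emit_fixtures(d1, sim_config)
        p2 = emit_fixtures(d2, sim_config)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_global_pooling_identity_on_fixtures(self, fixture_dir, sim_config):
        from vdfreq.simulate import _simulated_catalog

        freq, _ = simulate_allele_frequencies(sim_config)
        catalog = _simulated_catalog(list(freq.columns))
        panel = PopulationPanel.from_tsv(fixture_dir["sample_map"])
        genotypes = read_vcf_genotypes(fixture_dir["vcf"], panel, catalog)
        pops = compute_eaf(genotypes, panel)
        glob = compute_eaf(genotypes, panel, GLOBAL)
        for rsid in catalog.rsids:
            k = n = 0
            for pop in panel.populations:
                kp, np_ = pops.counts(rsid, pop)
                k, n = k + kp, n + np_
            assert glob.counts(rsid, GLOBAL) == (k, n)
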