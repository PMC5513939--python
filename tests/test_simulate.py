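import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mircascade.enrichment import enrich, filter_downregulated
from mircascade.quant import rpm_normalize
from mircascade.seeds import scan_utr, seed_match_motif
from mircascade.selection import select_candidates
from mircascade.simulate import (
    PlantedMiRNA,
    SyntheticConfig,
    simulate_counts,
    simulate_expression_ratios,
    simulate_gene_sets,
    simulate_mature_mirnas,
    simulate_qpcr,
    simulate_utrs,
    write_bundle,
)
from mircascade.group_stats import relative_quantity

from conftest import default_planted


class TestConfig:
    def test_planted_ids_come_first(self):
        cfg = SyntheticConfig(n_mirnas=10, planted_mirnas=default_planted())
        assert cfg.mirna_ids[:4] == [p.mirna_id for p in default_planted()]
        assert len(cfg.mirna_ids) == 10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_mirnas=2, planted_mirnas=default_planted())
        with pytest.raises(ValueError):
            SyntheticConfig(nb_dispersion=-1)
        with pytest.raises(ValueError):
            SyntheticConfig(enrichment_strength=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=10, n_planted_targets=11)


class TestMatureMirnas:
    def test_deterministic(self):
        cfg = SyntheticConfig(seed=5, n_mirnas=40, planted_mirnas=default_planted())
        a = simulate_mature_mirnas(cfg)
        b = simulate_mature_mirnas(cfg)
        assert [(m.mirna_id, m.sequence) for m in a] == [
            (m.mirna_id, m.sequence) for m in b
        ]

    def test_planted_seeds_unique_in_catalog(self):
        cfg = SyntheticConfig(seed=11, n_mirnas=200, planted_mirnas=default_planted())
        catalog = simulate_mature_mirnas(cfg)
        planted_ids = {p.mirna_id for p in default_planted()}
        seeds = [m.seed for m in catalog]
        for m in catalog:
            if m.mirna_id in planted_ids:
                assert seeds.count(m.seed) == 1


class TestCounts:
    def test_fixed_seed_identical_tables(self):
        cfg = SyntheticConfig(seed=3, n_mirnas=50)
        a = simulate_counts(cfg)
        b = simulate_counts(cfg)
        for name in a:
            pd.testing.assert_frame_equal(a[name][0], b[name][0])
            assert a[name][1] == b[name][1]

    def test_zero_dispersion_zero_planting_equal_group_means(self):
        cfg = SyntheticConfig(
            seed=4, n_mirnas=30, nb_dispersion=0.0, library_size_sigma=0.0
        )
        for table, groups in simulate_counts(cfg).values():
            case = [s for s in table.columns if groups[s] == "case"]
            control = [s for s in table.columns if groups[s] == "control"]
            np.testing.assert_allclose(
                table[case].mean(axis=1), table[control].mean(axis=1)
            )

    def test_cohort_sizes_and_labels(self):
        cfg = SyntheticConfig(seed=0, n_mirnas=20)
        data = simulate_counts(cfg)
        sizes = {
            name: (
                sum(1 for g in groups.values() if g == "case"),
                sum(1 for g in groups.values() if g == "control"),
            )
            for name, (_, groups) in data.items()
        }
        assert sizes == {"human1": (6, 6), "human2": (6, 7), "mouse": (3, 3)}

    def test_planted_effect_visible_in_means(self):
        planted = (PlantedMiRNA("mir-up", 2.0, 2.0, 2.0),)
        cfg = SyntheticConfig(
            seed=8, n_mirnas=50, planted_mirnas=planted,
            nb_dispersion=0.0, library_size_sigma=0.0,
        )
        table, groups = simulate_counts(cfg)["human1"]
        case = [s for s in table.columns if groups[s] == "case"]
        control = [s for s in table.columns if groups[s] == "control"]
        ratio = table.loc["mir-up", case].mean() / table.loc["mir-up", control].mean()
        assert ratio == pytest.approx(4.0, rel=1e-3)

    def test_planted_recovery_regression(self, planted_config):
        """Run-once oracle, frozen: the cascade on the seed-42 bundle returns
        exactly the planted set."""
        data = simulate_counts(planted_config)
        catalog = simulate_mature_mirnas(planted_config)
        rpm = {k: rpm_normalize(t) for k, (t, _) in data.items()}
        report = select_candidates(
            rpm["human1"], rpm["human2"], rpm["mouse"],
            data["human1"][1], data["human2"][1], data["mouse"][1], catalog,
        )
        assert report.candidates == (
            "mir-planted-dn1",
            "mir-planted-dn2",
            "mir-planted-up1",
            "mir-planted-up2",
        )


class TestUtrs:
    def test_planted_sites_found_at_manifest_positions(self):
        cfg = SyntheticConfig(seed=1, n_utrs=20, utr_length=300, n_planted_utrs=8)
        mirna = simulate_mature_mirnas(cfg)[0]
        utrs, manifest = simulate_utrs(cfg, mirna)
        assert len(manifest) == 8
        for entry in manifest:
            sites = scan_utr(utrs[entry["utr_id"]], mirna, entry["utr_id"])
            assert any(
                s.start == entry["position"] and s.site_type in ("7mer-m8", "8mer")
                for s in sites
            )

    def test_empty_manifest_without_planting(self):
        cfg = SyntheticConfig(seed=1, n_utrs=5, n_planted_utrs=0)
        _, manifest = simulate_utrs(cfg, simulate_mature_mirnas(cfg)[0])
        assert manifest == []

    def test_background_site_rate_matches_closed_form(self):
        # expected 6mer-core occurrences per background UTR of length L is
        # about (L - 6 + 1) / 4**6 under the uniform model
        cfg = SyntheticConfig(seed=2, n_utrs=400, utr_length=2000, n_planted_utrs=0)
        mirna = simulate_mature_mirnas(cfg)[0]
        utrs, _ = simulate_utrs(cfg, mirna)
        core = seed_match_motif(mirna)[1:]
        n_sites = sum(len(scan_utr(seq, mirna, uid)) for uid, seq in utrs.items())
        expected = cfg.n_utrs * (cfg.utr_length - 5) / 4**6
        # Poisson-ish: allow 4 standard deviations
        assert abs(n_sites - expected) < 4 * math.sqrt(expected)
        assert len(core) == 6


class TestRatios:
    def test_planted_targets_pass_filter(self):
        cfg = SyntheticConfig(seed=6, n_genes=500, n_planted_targets=50)
        ratios = simulate_expression_ratios(cfg)
        down = filter_downregulated(ratios, 0.8)
        assert set(cfg.planted_target_ids) <= down

    def test_background_pass_fraction_matches_lognormal_cdf(self):
        sigma = 0.25
        cfg = SyntheticConfig(
            seed=7, n_genes=20_000, n_planted_targets=0, background_ratio_sigma=sigma
        )
        ratios = simulate_expression_ratios(cfg)
        frac = (ratios < 0.8).mean()
        expected = norm.cdf(math.log(0.8) / sigma)
        se = math.sqrt(expected * (1 - expected) / cfg.n_genes)
        assert abs(frac - expected) < 4 * se

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=9, n_genes=100)
        pd.testing.assert_series_equal(
            simulate_expression_ratios(cfg), simulate_expression_ratios(cfg)
        )


class TestGeneSets:
    def test_sizes_always_positive(self):
        cfg = SyntheticConfig(seed=10, n_genes=300, n_gene_sets=30, set_size_range=(1, 20))
        for gs in simulate_gene_sets(cfg):
            assert len(gs.members) >= 1

    def test_strong_planting_ranks_first(self):
        cfg = SyntheticConfig(
            seed=12, n_genes=2000, n_planted_targets=120,
            enrichment_strength=0.9, planted_term_size=100,
        )
        ratios = simulate_expression_ratios(cfg)
        down = filter_downregulated(ratios, 0.8)
        results = enrich(down, simulate_gene_sets(cfg), set(ratios.index))
        assert results[0].term_id == cfg.planted_term

    def test_zero_strength_term_is_ordinary(self):
        cfg = SyntheticConfig(seed=13, n_genes=500, n_planted_targets=0, enrichment_strength=0.0)
        sets = simulate_gene_sets(cfg)
        planted = next(gs for gs in sets if gs.term_id == cfg.planted_term)
        assert len(planted.members) > 0


class TestQpcr:
    def test_null_fold_gives_rq_near_one(self):
        cfg = SyntheticConfig(seed=14, qpcr_rq_fold=1.0, qpcr_sigma=0.05)
        out = relative_quantity(simulate_qpcr(cfg), "untreated")
        assert out.loc[out.group == "treated", "rq"].mean() == pytest.approx(1.0, abs=0.15)

    def test_fold_two_recovered_in_low_noise_limit(self):
        cfg = SyntheticConfig(seed=15, qpcr_rq_fold=2.0, qpcr_sigma=1e-9)
        out = relative_quantity(simulate_qpcr(cfg), "untreated")
        treated = out.loc[out.group == "treated", "rq"].mean()
        untreated = out.loc[out.group == "untreated", "rq"].mean()
        assert treated / untreated == pytest.approx(2.0, rel=1e-6)

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=16)
        pd.testing.assert_frame_equal(simulate_qpcr(cfg), simulate_qpcr(cfg))


class TestBundle:
    EXPECTED_FILES = [
        "mirnas.fasta", "utrs.fasta", "ratios.tsv", "targets.txt",
        "gene_sets.gmt", "qpcr.tsv", "manifest.json",
        "counts_human1.tsv", "counts_human2.tsv", "counts_mouse.tsv",
        "groups_human1.tsv", "groups_human2.tsv", "groups_mouse.tsv",
    ]

    def test_bundle_emits_every_stage_input(self, bundle_dir):
        for name in self.EXPECTED_FILES:
            assert (bundle_dir / name).is_file(), name

    def test_manifest_records_planted_truth(self, bundle_dir, small_bundle_config):
        manifest = json.loads((bundle_dir / "manifest.json").read_text())
        assert manifest["planted_term"] == small_bundle_config.planted_term
        assert len(manifest["planted_mirnas"]) == 4
        assert manifest["planted_targets"] == small_bundle_config.planted_target_ids

    def test_bundle_deterministic(self, tmp_path, small_bundle_config):
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        write_bundle(small_bundle_config, d1)
        write_bundle(small_bundle_config, d2)
        for name in self.EXPECTED_FILES:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
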