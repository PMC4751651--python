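"""The generator plants exactly the structure the downstream stages assume."""

import numpy as np
import pandas as pd
import pytest

from haploscan.expression import fold_changes
from haploscan.simulate import (
    CARRIER_IDS,
    RegionTooSmallError,
    SimulationConfig,
    SVRecord,
    demo_allele_pair,
    demo_gain_table,
    emit_ct_table,
    emit_individual_callsets,
    emit_phenotype_table,
    emit_pooled_callset,
    emit_read_pairs,
    generate_truth,
    plant_svs,
    truth_table,
)
from haploscan.genome import GenomeInterval


def _cfg(**kw):
    return SimulationConfig(**kw)


class TestGenerateTruth:
    def test_noise_free_case_plants_only_shared_hets(self):
        cfg = _cfg(
            n_planted_haplotype_snvs=4, n_population_snvs=0, n_planted_indels=0,
            platform_error_rate=0.0, seed=3,
        )
        truth = generate_truth(cfg)
        assert len(truth) == 4
        assert all(r.cls == "haplotype_shared" for r in truth)
        for r in truth:
            assert all(r.genotypes[c] == 1 for c in CARRIER_IDS)

    def test_determinism(self):
        cfg = _cfg(seed=11)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        pd.testing.assert_frame_equal(truth_table(t1), truth_table(t2))

    def test_positions_unique(self, demo_truth):
        positions = [r.pos for r in demo_truth]
        assert len(positions) == len(set(positions))

    def test_population_genotypes_follow_binomial_law(self):
        # fixed-MAF panel: the pooled carrier allele frequency across many
        # variants must match the planted MAF within 3 standard errors
        maf = 0.2
        cfg = _cfg(
            n_planted_haplotype_snvs=0, n_planted_indels=0,
            n_population_snvs=400, population_maf=maf, seed=5,
        )
        truth = generate_truth(cfg)
        freqs = np.array(
            [sum(r.genotypes.values()) / (2 * cfg.n_pool_carriers) for r in truth]
        )
        se = np.sqrt(maf * (1 - maf) / (2 * cfg.n_pool_carriers))
        assert abs(freqs.mean() - maf) < 3 * se / np.sqrt(len(freqs))
        # brute-force tally per variant: ~all within 3 SE
        within = np.mean(np.abs(freqs - maf) < 3 * se)
        assert within > 0.95

    def test_region_too_small(self):
        with pytest.raises(RegionTooSmallError):
            generate_truth(
                _cfg(region=GenomeInterval("chr3", 100, 110), n_population_snvs=50)
            )


class TestIndividualCallsets:
    def test_error_free_calls_trace_to_truth(self, demo_truth, demo_config, demo_callsets):
        truth_keys = {r.key for r in demo_truth}
        for cs, sample in zip(demo_callsets, ("carrier01", "carrier02")):
            assert cs.keys <= truth_keys  # conservation: no orphan calls
            expected = {
                r.key for r in demo_truth
                if r.cls in ("haplotype_shared", "population")
                and r.genotypes.get(sample, 0) > 0
            }
            assert cs.keys == expected

    def test_haplotype_records_het_in_both_individuals(self, demo_truth, demo_callsets):
        a, b = demo_callsets
        for r in demo_truth:
            if r.cls == "haplotype_shared" and not r.is_indel:
                assert a[r.key].genotype == "0/1"
                assert b[r.key].genotype == "0/1"

    def test_platform_errors_confined_to_one_callset(self):
        cfg = _cfg(platform_error_rate=0.05, n_error_opportunities=500,
                   n_population_snvs=0, n_planted_indels=0, seed=13)
        truth = generate_truth(cfg)
        a, b = emit_individual_callsets(truth, cfg)
        err_a = {r.key for r in truth if r.cls == "platform_error_A"}
        err_b = {r.key for r in truth if r.cls == "platform_error_B"}
        assert err_a and err_b  # the scenario actually exercises errors
        assert err_a <= a.keys and not (err_a & b.keys)
        assert err_b <= b.keys and not (err_b & a.keys)

    def test_depth_around_mean(self, demo_callsets, demo_config):
        depths = [c.depth for cs in demo_callsets for c in cs]
        assert abs(np.mean(depths) - demo_config.individual_depth_mean) < 2


class TestPooledCallset:
    def test_all_het_sites_have_half_dosage(self):
        # law of large numbers at high depth: AAF -> 0.5 for shared sites
        cfg = _cfg(pool_depth_mean=10_000, n_population_snvs=0,
                   n_planted_indels=0, n_planted_haplotype_snvs=20, seed=23)
        truth = generate_truth(cfg)
        pool = emit_pooled_callset(truth, cfg)
        aafs = np.array([pool[r.key].aaf for r in truth])
        assert np.all(np.abs(aafs - 0.5) < 3 * np.sqrt(0.25 / 10_000) + 0.01)

    def test_absent_from_all_carriers_means_no_observation(self):
        cfg = _cfg(n_planted_haplotype_snvs=0, n_planted_indels=0,
                   n_population_snvs=50, population_maf=0.0, seed=2)
        truth = generate_truth(cfg)
        pool = emit_pooled_callset(truth, cfg)
        assert len(pool) == 0

    def test_binomial_sampling_at_depth_32(self):
        # Monte-Carlo oracle: many pooled draws of an all-het site at ~32x
        cfg = _cfg(n_planted_haplotype_snvs=200, n_population_snvs=0,
                   n_planted_indels=0, pool_depth_mean=32, seed=29)
        truth = generate_truth(cfg)
        pool = emit_pooled_callset(truth, cfg)
        aafs = np.array([o.aaf for o in pool])
        se = aafs.std(ddof=1) / np.sqrt(len(aafs))
        assert abs(aafs.mean() - 0.5) < 3 * se + 1e-9


class TestReadPairs:
    def test_background_within_five_sd(self):
        cfg = _cfg(n_planted_svs=0, seed=31)
        df = emit_read_pairs(cfg, [])
        dev = np.abs(df["distance"] - cfg.insert_size_mean)
        assert (dev <= 5 * cfg.insert_size_sd).all()

    @pytest.mark.parametrize("size", [300, 1600])
    def test_deletion_shifts_spanning_pairs(self, size):
        cfg = _cfg(seed=37)
        sv = SVRecord("deletion", cfg.region.chrom, cfg.region.start + 10_000, size)
        df = emit_read_pairs(cfg, [sv])
        spanning = df[df["origin"] == f"sv_deletion_{size}"]
        assert len(spanning) == cfg.pairs_per_sv
        shift = spanning["distance"].mean() - cfg.insert_size_mean
        se = cfg.insert_size_sd / np.sqrt(len(spanning))
        assert abs(shift - size) < 4 * se

    def test_insertion_shrinks_distance(self):
        cfg = _cfg(seed=41)
        sv = SVRecord("insertion", cfg.region.chrom, cfg.region.start + 10_000, 200)
        df = emit_read_pairs(cfg, [sv])
        spanning = df[df["origin"] == "sv_insertion_200"]
        assert spanning["distance"].mean() < cfg.insert_size_mean - 100

    def test_sv_outside_region_rejected(self):
        cfg = _cfg()
        bad = SVRecord("deletion", "chr3", cfg.region.end + 10, 300)
        with pytest.raises(ValueError):
            emit_read_pairs(cfg, [bad])

    def test_planted_svs_inside_region(self):
        cfg = _cfg()
        for sv in plant_svs(cfg):
            assert cfg.region.contains(sv.chrom, sv.pos)


class TestCtTable:
    @pytest.mark.parametrize("fold", [0.25, 0.5, 1.0, 2.0])
    def test_noise_free_fold_recovered_exactly(self, fold):
        ct = emit_ct_table({"LHX2": fold}, n_lines=2, seed=1, noise_sd=0.0)
        fc = fold_changes(ct)
        assert np.allclose(fc["fold"], fold)

    def test_noisy_fold_recovered_on_average(self):
        # Monte-Carlo oracle across 100 lines at 0.1-cycle noise
        ct = emit_ct_table({"LHX2": 0.5}, n_lines=100, seed=9, noise_sd=0.1)
        folds = fold_changes(ct)["fold"].to_numpy()
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 0.5) < 3 * se + 1e-9


def test_phenotype_table_has_consistent_binning():
    from haploscan.expression import phenotype_bin

    df = emit_phenotype_table(50, seed=3)
    assert (df["score"] == df["z"].map(phenotype_bin)).all()


def test_config_validation():
    with pytest.raises(ValueError):
        _cfg(n_population_snvs=-1)
    with pytest.raises(ValueError):
        _cfg(platform_error_rate=1.5)
    with pytest.raises(ValueError):
        _cfg(finnish_maf_enrichment=0.5)
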