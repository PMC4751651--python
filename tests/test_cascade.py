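"""Filter-cascade steps against brute-force oracles, and cascade invariants."""

import numpy as np
import pytest

from haploscan.calls import CallSet, PooledCallSet, PooledObservation, VariantCall
from haploscan.cascade import (
    Catalog,
    ConflictingAllelesError,
    FrequencyPanel,
    repeat_context,
    run_indel_cascade,
    run_snv_cascade,
    step_concordant,
    step_frequency,
    step_heterozygous,
    step_indel_presence,
    step_novel,
    step_pool_shared,
    step_region,
)
from haploscan.genome import GenomeInterval, robo1_model
from haploscan.pipeline import _indels_only, _snvs_only
from haploscan.simulate import (
    SimulationConfig,
    emit_individual_callsets,
    emit_pooled_callset,
    frequency_panel,
    generate_truth,
    indel_contexts,
    known_catalog,
)

INTERVAL = GenomeInterval("chr3", 73_842_243, 106_990_161)


def _call(pos, ref="A", alt="G", gt="0/1", sample="S"):
    return VariantCall("chr3", pos, ref, alt, gt, 50, 25, sample=sample)


def _random_callset(rng, n, sample):
    calls = {}
    for _ in range(n):
        pos = int(rng.integers(INTERVAL.start - 1000, INTERVAL.end + 1000))
        gt = rng.choice(["0/1", "1/1"])
        c = _call(pos, gt=gt, sample=sample)
        calls[c.key] = c
    return CallSet(calls.values(), sample=sample)


class TestStepsMatchBruteForce:
    """Each set filter equals an independent set-comprehension oracle."""

    def test_region_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            calls = list(_random_callset(rng, 100, "S"))
            kept = step_region(calls, INTERVAL)
            oracle = [
                c for c in calls if INTERVAL.start <= c.pos <= INTERVAL.end
            ]
            assert {c.key for c in kept} == {c.key for c in oracle}

    def test_region_boundaries_inclusive(self):
        inside_low = _call(73_842_243)
        outside = _call(73_842_242)
        inside_high = _call(106_990_161)
        kept = step_region([inside_low, outside, inside_high], INTERVAL)
        assert {c.pos for c in kept} == {73_842_243, 106_990_161}

    def test_region_empty_input(self):
        assert step_region([], INTERVAL) == []

    def test_concordant_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = _random_callset(rng, 60, "A")
            b = _random_callset(rng, 60, "B")
            kept = step_concordant(a, b)
            oracle = {
                k for k in a.keys
                if k in b.keys and a[k].genotype == b[k].genotype
            }
            assert kept == oracle

    def test_concordant_genotype_mismatch_removed(self):
        a = CallSet([_call(100_000_000, gt="0/1", sample="A")], "A")
        b = CallSet([_call(100_000_000, gt="1/1", sample="B")], "B")
        assert step_concordant(a, b) == set()

    def test_conflicting_ref_alt_raises(self):
        a = CallSet([_call(100, ref="A", alt="G", sample="A")], "A")
        b = CallSet([_call(100, ref="C", alt="G", sample="B")], "B")
        with pytest.raises(ConflictingAllelesError):
            step_concordant(a, b)

    def test_pool_shared_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            keys = {("chr3", int(p), "A", "G") for p in rng.integers(1e6, 2e6, 50)}
            obs = [
                PooledObservation("chr3", int(p), "A", "G", 20, int(rng.integers(0, 5)))
                for p in rng.integers(1e6, 2e6, 50)
            ]
            dedup = {o.key: o for o in obs}
            pool = PooledCallSet(dedup.values())
            kept = step_pool_shared(keys, pool)
            oracle = {
                k for k in keys if k in dedup and dedup[k].alt_count >= 1
            }
            assert kept == oracle

    def test_heterozygous_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = _random_callset(rng, 50, "A")
            b = _random_callset(rng, 50, "B")
            keys = a.keys | b.keys
            kept = step_heterozygous(keys, a, b)
            oracle = {
                k for k in keys
                if k in a.keys and k in b.keys
                and a[k].genotype == "0/1" and b[k].genotype == "0/1"
            }
            assert kept == oracle

    def test_frequency_rules(self):
        keys = {
            ("chr3", 1, "A", "G"),  # enriched locally, rare globally
            ("chr3", 2, "A", "G"),  # exactly at the cutoff -> retained
            ("chr3", 3, "A", "G"),  # absent from panel -> retained
            ("chr3", 4, "A", "G"),  # common everywhere
        }
        panel = FrequencyPanel(
            {
                ("chr3", 1, "A", "G"): {"ALL": 0.04, "FIN": 0.20},
                ("chr3", 2, "A", "G"): {"ALL": 0.05, "FIN": 0.05},
                ("chr3", 4, "A", "G"): {"ALL": 0.30, "FIN": 0.30},
            }
        )
        kept, reasons = step_frequency(keys, panel)
        assert kept == {("chr3", 2, "A", "G"), ("chr3", 3, "A", "G")}
        assert reasons[("chr3", 1, "A", "G")] == "population-enriched"
        assert reasons[("chr3", 4, "A", "G")] == "common"

    def test_novel_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            keys = {("chr3", int(p), "A", "G") for p in rng.integers(0, 500, 60)}
            cats = [
                Catalog(f"c{i}", {("chr3", int(p), "A", "G"): "id"
                                  for p in rng.integers(0, 500, 30)})
                for i in range(3)
            ]
            kept = step_novel(keys, cats)
            union = set().union(*(c.entries for c in cats))
            assert kept == keys - union

    def test_novel_disjunctive_mode(self):
        k1, k2 = ("chr3", 1, "A", "G"), ("chr3", 2, "A", "G")
        c1 = Catalog("c1", {k1: "x"})
        c2 = Catalog("c2", {k1: "x", k2: "y"})
        assert step_novel({k1, k2}, [c1, c2], mode="all") == set()
        assert step_novel({k1, k2}, [c1, c2], mode="any") == {k2}


class TestFullCascade:
    def test_perfect_recovery_of_planted_haplotype(
        self, demo_truth, demo_callsets, demo_pool, demo_panel, demo_catalog, demo_config
    ):
        a, b = demo_callsets
        result = run_snv_cascade(
            _snvs_only(a), _snvs_only(b), demo_pool, demo_config.region,
            demo_panel, [demo_catalog], gene=robo1_model(), upstream_width=5_000_000,
        )
        planted = {
            r.key for r in demo_truth if r.cls == "haplotype_shared" and not r.is_indel
        }
        assert result.survivor_keys == planted  # sensitivity = specificity = 1

    def test_counts_monotone_nonincreasing(
        self, demo_callsets, demo_pool, demo_panel, demo_catalog, demo_config
    ):
        a, b = demo_callsets
        result = run_snv_cascade(
            _snvs_only(a), _snvs_only(b), demo_pool, demo_config.region,
            demo_panel, [demo_catalog],
        )
        counts = [n for _, n in result.steps]
        assert counts == sorted(counts, reverse=True)

    def test_provenance_complete(
        self, demo_callsets, demo_pool, demo_panel, demo_catalog, demo_config
    ):
        a, b = demo_callsets
        result = run_snv_cascade(
            _snvs_only(a), _snvs_only(b), demo_pool, demo_config.region,
            demo_panel, [demo_catalog],
        )
        snv = lambda k: len(k[2]) == len(k[3])
        all_input = {k for k in a.keys | b.keys | demo_pool.keys if snv(k)}
        assert set(result.provenance) == all_input
        survivors = {k for k, fate in result.provenance.items() if fate == "survivor"}
        assert survivors == result.survivor_keys

    def test_commuting_set_filters_reorder(self, demo_callsets, demo_pool,
                                           demo_panel, demo_catalog, demo_config):
        # region, frequency and novelty are pure key filters: applying them
        # in a different order around the core steps gives the same survivors
        a, b = map(_snvs_only, demo_callsets)
        baseline = run_snv_cascade(
            a, b, demo_pool, demo_config.region, demo_panel, [demo_catalog]
        ).survivor_keys

        keys = step_concordant(a, b)
        keys = step_novel(keys, [demo_catalog])
        keys, _ = step_frequency(keys, demo_panel)
        keys = step_pool_shared(keys, demo_pool)
        keys = step_heterozygous(keys, a, b)
        keys = {k for k in keys if demo_config.region.contains(k[0], k[1])}
        assert keys == baseline

    def test_pool_platform_errors_never_survive(self):
        cfg = SimulationConfig(platform_error_rate=0.02, n_error_opportunities=2000,
                               seed=17)
        truth = generate_truth(cfg)
        a, b = emit_individual_callsets(truth, cfg)
        pool = emit_pooled_callset(truth, cfg)
        result = run_snv_cascade(
            _snvs_only(a), _snvs_only(b), pool, cfg.region,
            frequency_panel(truth), [known_catalog(truth)],
        )
        errors = {r.key for r in truth if r.cls.startswith("platform_error")}
        assert errors  # scenario exercised
        assert not (errors & result.survivor_keys)

    def test_planted_variant_with_high_local_maf_excluded(
        self, demo_truth, demo_callsets, demo_pool, demo_catalog, demo_config
    ):
        a, b = map(_snvs_only, demo_callsets)
        planted = next(
            r for r in demo_truth if r.cls == "haplotype_shared" and not r.is_indel
        )
        freqs = {r.key: dict(r.maf) for r in demo_truth if r.maf}
        freqs[planted.key] = {"ALL": 0.04, "FIN": 0.20}
        panel = FrequencyPanel(freqs)
        result = run_snv_cascade(
            a, b, demo_pool, demo_config.region, panel, [demo_catalog]
        )
        assert planted.key not in result.survivor_keys
        assert result.provenance[planted.key] == "removed:frequency:population-enriched"


def _brute_repeat_class(seq, lo, hi, r1, r2):
    """Independent run-length scanner oracle."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        runs.append((i, j, j - i + 1))
        i = j + 1
    if any(n >= r1 and s <= hi and e >= lo for s, e, n in runs):
        return "mononucleotide"
    for phase in (0, 1):
        i = phase
        while i + 1 < len(seq):
            u = seq[i : i + 2]
            if u[0] == u[1]:
                i += 2
                continue
            j = i
            while seq[j + 2 : j + 4] == u:
                j += 2
            if (j - i) // 2 + 1 >= r2 and i <= hi and j + 1 >= lo:
                return "dinucleotide"
            i = j + 2
    return "none"


class TestRepeatContext:
    def test_homopolymer(self):
        seq = "GGCT" + "A" * 6 + "CTGG"
        assert repeat_context(seq, 6, 1) == "mononucleotide"

    def test_dinucleotide(self):
        seq = "GGT" + "AC" * 4 + "TGG"
        assert repeat_context(seq, 6, 2) == "dinucleotide"

    def test_plain_sequence(self):
        assert repeat_context("GATCGTAGCTAGCATG", 8, 1) == "none"

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(bases[rng.integers(0, 4, size=200)])
            off = int(rng.integers(0, 199))
            ln = int(rng.integers(1, 3))
            got = repeat_context(seq, off, ln)
            want = _brute_repeat_class(seq, off, min(199, off + ln), 5, 3)
            assert got == want, (seq, off, ln)

    def test_offset_out_of_range(self):
        with pytest.raises(ValueError):
            repeat_context("ACGT", 10)


class TestIndelCascade:
    def _indel(self, pos, sample, ref="AT", alt="A", gt="0/1"):
        return VariantCall("chr3", pos, ref, alt, gt, 50, 25, sample=sample)

    def _setup(self):
        panel = FrequencyPanel({})
        cat = Catalog("c", {})
        return panel, cat

    def test_pool_plus_one_individual_retained(self):
        panel, cat = self._setup()
        pos = 80_000_000
        a = CallSet([self._indel(pos, "A")], "A")
        b = CallSet([], "B")
        pool = PooledCallSet([PooledObservation("chr3", pos, "AT", "A", 20, 8)])
        result = run_indel_cascade(a, b, pool, INTERVAL, panel, [cat])
        assert result.survivor_keys == {("chr3", pos, "AT", "A")}

    def test_in_neither_individual_removed(self):
        panel, cat = self._setup()
        pos = 80_000_000
        pool = PooledCallSet([PooledObservation("chr3", pos, "AT", "A", 20, 8)])
        result = run_indel_cascade(CallSet([], "A"), CallSet([], "B"),
                                   pool, INTERVAL, panel, [cat])
        assert result.survivor_keys == set()

    def test_short_repeat_indel_flagged_likely_neutral(self):
        panel, cat = self._setup()
        pos = 80_000_000
        a = CallSet([self._indel(pos, "A", ref="A", alt="AA")], "A")
        pool = PooledCallSet([PooledObservation("chr3", pos, "A", "AA", 20, 8)])
        contexts = {("chr3", pos, "A", "AA"): ("GGCT" + "A" * 7 + "CTGG", 6)}
        result = run_indel_cascade(a, CallSet([], "B"), pool, INTERVAL,
                                   panel, [cat], contexts=contexts)
        [survivor] = result.survivors
        assert "likely_neutral" in survivor.flags

    def test_simulated_indels_recovered(self, demo_truth, demo_callsets,
                                        demo_pool, demo_panel, demo_catalog, demo_config):
        a, b = demo_callsets
        result = run_indel_cascade(
            _indels_only(a), _indels_only(b), demo_pool, demo_config.region,
            demo_panel, [demo_catalog], contexts=indel_contexts(demo_truth),
        )
        planted = {r.key for r in demo_truth if r.is_indel}
        assert result.survivor_keys == planted


def test_step_indel_presence_is_a_set_union_rule():
    a = CallSet([VariantCall("chr3", 1, "AT", "A", "0/1", 10, 5, sample="A")], "A")
    b = CallSet([], "B")
    keys = {("chr3", 1, "AT", "A"), ("chr3", 2, "AT", "A")}
    assert step_indel_presence(keys, a, b) == {("chr3", 1, "AT", "A")}
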