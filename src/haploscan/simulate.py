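"""Synthetic inputs with the statistical structure of a pooled-haplotype study.

The emulated design: 19 affected relatives all carry one shared 33-Mb
susceptibility haplotype on chromosome 3, heterozygously.  Two of them are
sequenced individually at ~50x on one platform; an equimolar pool of all 19
is sequenced at ~19x on another.  On top of the haplotype-shared variants
sit population variants (with optionally Finnish-enriched frequencies),
platform-specific false calls, repeat-context INDELs, and insert-size
perturbing structural variants.

All randomness flows from ``SimulationConfig.seed`` through a fixed
stage-splitting scheme (``numpy`` generators seeded with ``[seed, stage]``),
so each stage regenerates identically and independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import CallSet, PooledObservation, PooledCallSet, VariantCall, VariantKey
from .genome import HAPLOTYPE_INTERVAL, GenomeInterval

# stage ids for the seed-splitting scheme; stable across releases
_STAGES = {
    "truth": 1,
    "individuals": 2,
    "pool": 3,
    "read_pairs": 4,
    "ct": 5,
    "phenotype": 6,
}

CARRIER_IDS = tuple(f"carrier{i:02d}" for i in range(1, 20))

TRUTH_CLASSES = (
    "haplotype_shared",
    "population",
    "platform_error_A",
    "platform_error_B",
    "platform_error_pool",
)


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGES[stage]])


class RegionTooSmallError(ValueError):
    """The region cannot host the requested number of distinct positions."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated pooled-haplotype experiment.

    Defaults are the emulated study conditions: 19 pooled heterozygous
    carriers, two ~50x individual call sets, a ~19x pool, and the 33-Mb
    chromosome-3 haplotype interval.
    """

    region: GenomeInterval = HAPLOTYPE_INTERVAL
    n_pool_carriers: int = 19
    n_individual_samples: int = 2
    individual_depth_mean: float = 50.0
    pool_depth_mean: float = 19.0
    n_planted_haplotype_snvs: int = 4
    n_population_snvs: int = 1000
    finnish_maf_enrichment: float = 4.0
    platform_error_rate: float = 0.0
    #: number of sites per platform at which a spurious call may arise;
    #: expected spurious calls per platform = rate * opportunities
    n_error_opportunities: int = 10_000
    n_planted_indels: int = 40
    indel_repeat_fraction: float = 0.8
    n_planted_svs: int = 2
    sv_sizes: Sequence[int] = (300, 1600)
    insert_size_mean: float = 350.0
    insert_size_sd: float = 30.0
    n_background_pairs: int = 5000
    pairs_per_sv: int = 20
    #: if set, every population variant gets this MAF in every panel
    population_maf: float | None = None
    #: concentration for optional per-carrier DNA-amount jitter in the pool;
    #: None = exactly equimolar
    carrier_dirichlet_alpha: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_pool_carriers,
            self.n_individual_samples,
            self.n_planted_haplotype_snvs,
            self.n_population_snvs,
            self.n_planted_indels,
            self.n_planted_svs,
            self.n_error_opportunities,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for p in (self.platform_error_rate, self.indel_repeat_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.finnish_maf_enrichment < 1.0:
            raise ValueError("finnish_maf_enrichment must be >= 1")
        if self.n_individual_samples > self.n_pool_carriers:
            raise ValueError("individuals are drawn from the pool carriers")


@dataclass
class TruthRecord:
    """Ground truth for one simulated variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    cls: str
    #: carrier id -> alternative allele count (0, 1 or 2); empty for errors
    genotypes: Dict[str, int] = field(default_factory=dict)
    in_dbsnp: bool = False
    #: population label -> minor allele frequency; empty for novel variants
    maf: Dict[str, float] = field(default_factory=dict)
    #: local sequence window (INDELs only) and the in-window offset of pos
    context: str | None = None
    context_offset: int | None = None

    def __post_init__(self) -> None:
        if self.cls not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.cls!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class SVRecord:
    """A planted structural variant perturbing read-pair insert distances."""

    type: str  # "deletion" | "insertion"
    chrom: str
    pos: int
    size: int

    def __post_init__(self) -> None:
        if self.type not in ("deletion", "insertion"):
            raise ValueError(f"SV type must be deletion or insertion, got {self.type!r}")
        if self.size <= 0:
            raise ValueError("SV size must be positive")


def _sample_unique_positions(
    rng: np.random.Generator, region: GenomeInterval, n: int
) -> np.ndarray:
    if n > region.length:
        raise RegionTooSmallError(
            f"region of {region.length} bases cannot host {n} distinct variants"
        )
    seen: set[int] = set()
    out: List[int] = []
    while len(out) < n:
        batch = rng.integers(region.start, region.end + 1, size=2 * (n - len(out)) + 16)
        for p in batch:
            p = int(p)
            if p not in seen:
                seen.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return np.array(out, dtype=np.int64)


_ALPHABET = np.array(list("ACGT"))


def _draw_snv_alleles(rng: np.random.Generator, n: int) -> tuple[list, list]:
    refs = _ALPHABET[rng.integers(0, 4, size=n)]
    shifts = rng.integers(1, 4, size=n)
    ref_idx = np.searchsorted(_ALPHABET, refs)
    alts = _ALPHABET[(ref_idx + shifts) % 4]
    return list(refs), list(alts)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=n)])


def _repeat_context_seq(rng: np.random.Generator, flank: int, unit: str) -> tuple[str, int]:
    """A window whose centre sits inside a tandem run of ``unit``."""
    n_units = int(rng.integers(6, 11)) if len(unit) == 1 else int(rng.integers(4, 7))
    run = unit * n_units
    left = _random_seq(rng, flank)
    right = _random_seq(rng, flank)
    # avoid accidentally extending the run at its borders
    while left.endswith(unit[-1]):
        left = left[:-1] + ("C" if unit[-1] != "C" else "G")
    while right.startswith(unit[0]):
        right = ("C" if unit[0] != "C" else "G") + right[1:]
    offset = len(left) + len(run) // 2
    return left + run + right, offset


def generate_truth(config: SimulationConfig) -> List[TruthRecord]:
    """Plant haplotype-shared, population, error and INDEL variants.

    Haplotype-shared records are heterozygous in every pool carrier (and
    hence in both individually sequenced carriers).  Population records get
    genotypes by independent binomial(2, MAF) draws per carrier from the
    Finnish-panel frequency, and are members of the known-variant catalog.
    Platform-error records are spurious calls confined to a single
    platform's call set.  Deterministic for a fixed seed.
    """
    rng = _rng(config.seed, "truth")
    chrom = config.region.chrom

    n_err_a = rng.poisson(config.platform_error_rate * config.n_error_opportunities)
    n_err_b = rng.poisson(config.platform_error_rate * config.n_error_opportunities)
    n_err_p = rng.poisson(config.platform_error_rate * config.n_error_opportunities)
    n_total = (
        config.n_planted_haplotype_snvs
        + config.n_population_snvs
        + config.n_planted_indels
        + n_err_a
        + n_err_b
        + n_err_p
    )
    positions = _sample_unique_positions(rng, config.region, n_total)
    cursor = 0
    records: List[TruthRecord] = []

    # haplotype-shared SNVs: het in all carriers
    n_hap = config.n_planted_haplotype_snvs
    refs, alts = _draw_snv_alleles(rng, n_hap)
    for i in range(n_hap):
        records.append(
            TruthRecord(
                chrom=chrom,
                pos=int(positions[cursor + i]),
                ref=refs[i],
                alt=alts[i],
                cls="haplotype_shared",
                genotypes={c: 1 for c in CARRIER_IDS[: config.n_pool_carriers]},
            )
        )
    cursor += n_hap

    # population SNVs: catalogued, frequencies per panel, binomial genotypes
    n_pop = config.n_population_snvs
    refs, alts = _draw_snv_alleles(rng, n_pop)
    if config.population_maf is not None:
        maf_all = np.full(n_pop, config.population_maf)
        maf_fin = maf_all.copy()
    else:
        maf_all = 10 ** rng.uniform(-3, math.log10(0.5), size=n_pop)
        enriched = rng.random(n_pop) < 0.3
        maf_fin = np.where(
            enriched,
            np.minimum(0.5, maf_all * config.finnish_maf_enrichment),
            np.minimum(0.5, maf_all * np.exp(rng.normal(0, 0.2, size=n_pop))),
        )
    carriers = CARRIER_IDS[: config.n_pool_carriers]
    for i in range(n_pop):
        gts = rng.binomial(2, maf_fin[i], size=len(carriers))
        records.append(
            TruthRecord(
                chrom=chrom,
                pos=int(positions[cursor + i]),
                ref=refs[i],
                alt=alts[i],
                cls="population",
                genotypes={c: int(g) for c, g in zip(carriers, gts)},
                in_dbsnp=True,
                maf={"ALL": float(maf_all[i]), "FIN": float(maf_fin[i])},
            )
        )
    cursor += n_pop

    # INDELs: haplotype-shared 1-2 bp events, most inside repeat runs
    for i in range(config.n_planted_indels):
        pos = int(positions[cursor + i])
        in_repeat = rng.random() < config.indel_repeat_fraction
        indel_len = int(rng.integers(1, 3))
        if in_repeat:
            unit = (
                str(_ALPHABET[rng.integers(0, 4)])
                if rng.random() < 0.5
                else _random_seq(rng, 2)
            )
            while len(unit) == 2 and unit[0] == unit[1]:
                unit = _random_seq(rng, 2)
            context, offset = _repeat_context_seq(rng, 15, unit)
            inserted = (unit * 2)[:indel_len] if len(unit) >= 1 else unit
        else:
            context = _random_seq(rng, 31)
            offset = 15
            inserted = _random_seq(rng, indel_len)
        anchor_base = context[offset]
        if rng.random() < 0.5:  # insertion
            ref, alt = anchor_base, anchor_base + inserted
        else:  # deletion
            ref, alt = anchor_base + context[offset + 1 : offset + 1 + indel_len], anchor_base
            if len(ref) == 1:  # context too short; force insertion instead
                ref, alt = anchor_base, anchor_base + inserted
        records.append(
            TruthRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                cls="haplotype_shared",
                genotypes={c: 1 for c in carriers},
                context=context,
                context_offset=offset,
            )
        )
    cursor += config.n_planted_indels

    # platform-specific spurious calls
    for cls, n_err in (
        ("platform_error_A", n_err_a),
        ("platform_error_B", n_err_b),
        ("platform_error_pool", n_err_p),
    ):
        refs, alts = _draw_snv_alleles(rng, n_err)
        for i in range(n_err):
            records.append(
                TruthRecord(
                    chrom=chrom,
                    pos=int(positions[cursor + i]),
                    ref=refs[i],
                    alt=alts[i],
                    cls=cls,
                )
            )
        cursor += n_err

    records.sort(key=lambda r: r.pos)
    return records


def individual_sample_ids(config: SimulationConfig) -> List[str]:
    """The carriers sequenced individually (the first two pedigree carriers)."""
    return list(CARRIER_IDS[: config.n_individual_samples])


def emit_individual_callsets(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> List[CallSet]:
    """Per-individual call sets: true genotypes plus platform-specific errors.

    Depth is Poisson around ``individual_depth_mean`` (floored at 1);
    alt reads are binomial at the allele dosage, floored at 1 for a called
    variant.
    """
    rng = _rng(config.seed, "individuals")
    samples = individual_sample_ids(config)
    error_cls = {0: "platform_error_A", 1: "platform_error_B"}
    callsets = []
    for idx, sample in enumerate(samples):
        calls = []
        for rec in truth:
            if rec.cls in ("haplotype_shared", "population"):
                dosage = rec.genotypes.get(sample, 0)
                if dosage == 0:
                    continue
                gt = "0/1" if dosage == 1 else "1/1"
                p = dosage / 2
            elif rec.cls == error_cls[idx]:
                gt, p = "0/1", 0.5
            else:
                continue
            depth = max(1, int(rng.poisson(config.individual_depth_mean)))
            alt_depth = min(depth, max(1, int(rng.binomial(depth, p))))
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alt,
                    genotype=gt,
                    depth=depth,
                    alt_depth=alt_depth,
                    sample=sample,
                    platform="CGI",
                )
            )
        callsets.append(CallSet(calls, sample=sample, platform="CGI"))
    return callsets


def emit_pooled_callset(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> PooledCallSet:
    """Pooled observations: binomial alt counts at the pooled allele dosage.

    Per site the pooled dosage is (sum of alt alleles over carriers) /
    (2 * n_carriers) — 0.5 when all 19 carriers are heterozygous.  Depth is
    Poisson around ``pool_depth_mean``; sites with zero depth or zero drawn
    alt reads produce no observation (a caller would not report them).
    Pool-platform spurious calls appear as low-fraction observations.
    """
    rng = _rng(config.seed, "pool")
    carriers = CARRIER_IDS[: config.n_pool_carriers]
    if config.carrier_dirichlet_alpha is not None:
        weights = rng.dirichlet(
            np.full(len(carriers), config.carrier_dirichlet_alpha)
        )
    else:
        weights = np.full(len(carriers), 1.0 / len(carriers))
    obs = []
    for rec in truth:
        if rec.cls in ("haplotype_shared", "population"):
            dosages = np.array([rec.genotypes.get(c, 0) for c in carriers])
            p = float(np.dot(weights, dosages) / 2.0)
            if p == 0.0:
                continue
        elif rec.cls == "platform_error_pool":
            p = 0.15  # spurious low-fraction signal
        else:
            continue
        depth = int(rng.poisson(config.pool_depth_mean))
        if depth == 0:
            continue
        alt = int(rng.binomial(depth, p))
        if rec.cls == "platform_error_pool":
            alt = max(1, alt)
        if alt == 0:
            continue
        obs.append(
            PooledObservation(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                depth=depth,
                alt_count=alt,
            )
        )
    return PooledCallSet(obs)


def plant_svs(config: SimulationConfig) -> List[SVRecord]:
    """Deletions of the configured sizes, evenly placed inside the region."""
    n = config.n_planted_svs
    svs = []
    for i in range(n):
        size = int(config.sv_sizes[i % len(config.sv_sizes)])
        frac = (i + 1) / (n + 1)
        pos = int(config.region.start + frac * (config.region.length - size))
        svs.append(SVRecord(type="deletion", chrom=config.region.chrom, pos=pos, size=size))
    return svs


MIN_PAIR_DISTANCE = 10


def emit_read_pairs(
    config: SimulationConfig, sv_list: Sequence[SVRecord]
) -> pd.DataFrame:
    """Read-pair table with insert distances perturbed by planted SVs.

    Background pairs have distance ~ Normal(insert mean, insert sd).  Pairs
    spanning a deletion of size s map s bases further apart (+s); pairs
    spanning an insertion map closer (-s, floored at a small positive
    distance).  Columns: chrom, pos1, pos2, distance, origin.
    """
    rng = _rng(config.seed, "read_pairs")
    region = config.region
    for sv in sv_list:
        if not region.contains(sv.chrom, sv.pos) or not region.contains(
            sv.chrom, sv.pos + sv.size - 1
        ):
            raise ValueError(f"SV at {sv.chrom}:{sv.pos} (size {sv.size}) outside region")

    rows = []
    n_bg = config.n_background_pairs
    lefts = rng.integers(region.start, region.end - 2000, size=n_bg)
    dists = rng.normal(config.insert_size_mean, config.insert_size_sd, size=n_bg)
    for left, d in zip(lefts, dists):
        d = max(MIN_PAIR_DISTANCE, int(round(d)))
        rows.append((region.chrom, int(left), int(left) + d, d, "background"))

    for sv in sv_list:
        for _ in range(config.pairs_per_sv):
            # left read ends just before the event; mapped distance absorbs it
            left = sv.pos - int(rng.integers(50, max(51, int(config.insert_size_mean) - 100)))
            d = rng.normal(config.insert_size_mean, config.insert_size_sd)
            if sv.type == "deletion":
                d += sv.size
            else:
                d -= sv.size
            d = max(MIN_PAIR_DISTANCE, int(round(d)))
            rows.append((sv.chrom, int(left), int(left) + d, d, f"sv_{sv.type}_{sv.size}"))

    df = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "distance", "origin"])
    return df.sort_values("pos1", kind="stable").reset_index(drop=True)


# qPCR base cycle-threshold values per assay (typical lymphoblast values)
_BASE_CT = {"LHX2": 25.0, "ROBO1": 27.0, "GAPDH": 20.0, "18S": 12.0}
REFERENCE_GENES = ("GAPDH", "18S")


def emit_ct_table(
    effect_sizes: Mapping[str, float],
    n_lines: int,
    seed: int,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for a knockdown-vs-scramble experiment.

    ``effect_sizes`` maps target gene -> intended fold change (knockdown
    relative to scramble).  A fold f is encoded by raising the knockdown
    target Ct by -log2(f) cycles, so the 2^-ddCt readout recovers f exactly
    in the noise-free case.  Gaussian noise of ``noise_sd`` cycles is added
    per replicate.  Columns: line, condition, gene, role, replicate, ct.
    """
    rng = np.random.default_rng([seed, _STAGES["ct"]])
    rows = []
    for line_idx in range(1, n_lines + 1):
        line = f"line{line_idx:02d}"
        for condition in ("scramble", "knockdown"):
            for gene in REFERENCE_GENES:
                for rep in range(1, n_replicates + 1):
                    ct = _BASE_CT[gene] + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                    rows.append((line, condition, gene, "reference", rep, ct))
            for gene, fold in effect_sizes.items():
                base = _BASE_CT.get(gene, 26.0)
                shift = -math.log2(fold) if condition == "knockdown" else 0.0
                for rep in range(1, n_replicates + 1):
                    ct = base + shift + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                    rows.append((line, condition, gene, "target", rep, ct))
    return pd.DataFrame(
        rows, columns=["line", "condition", "gene", "role", "replicate", "ct"]
    )


def emit_phenotype_table(
    n_subjects: int,
    seed: int,
    slope: float = 0.6,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Subjects with phonological-coding z-scores and expression values.

    Expression increases with z (slope > 0), so the ordinal deficit score
    (which increases as z decreases) is negatively correlated with
    expression — the planted direction of the phenotype-expression trend.
    Columns: subject, z, score, expression.
    """
    from .expression import phenotype_bin

    rng = np.random.default_rng([seed, _STAGES["phenotype"]])
    z = rng.normal(-1.5, 1.2, size=n_subjects)
    expr = 1.0 + slope * (z - z.mean()) + rng.normal(0, noise_sd, size=n_subjects)
    rows = [
        (f"subject{i + 1:02d}", float(zi), phenotype_bin(zi), float(ei))
        for i, (zi, ei) in enumerate(zip(z, expr))
    ]
    return pd.DataFrame(rows, columns=["subject", "z", "score", "expression"])


def panel_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """Population allele-frequency panel table for the catalogued variants."""
    rows = [
        {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "id": f"rs{900_000_000 + i}",
            "ALL": r.maf.get("ALL", 0.0), "FIN": r.maf.get("FIN", 0.0),
        }
        for i, r in enumerate(truth)
        if r.cls == "population"
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id", "ALL", "FIN"])


def catalog_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """Known-variant catalog table (dbSNP-like) of the catalogued variants."""
    rows = [
        {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
         "id": f"rs{900_000_000 + i}"}
        for i, r in enumerate(truth)
        if r.in_dbsnp
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])


def frequency_panel(truth: Sequence[TruthRecord]):
    """In-memory :class:`~haploscan.cascade.FrequencyPanel` from truth records."""
    from .cascade import FrequencyPanel

    return FrequencyPanel(
        frequencies={r.key: dict(r.maf) for r in truth if r.maf},
        populations=("ALL", "FIN"),
    )


def known_catalog(truth: Sequence[TruthRecord]):
    """In-memory dbSNP-like :class:`~haploscan.cascade.Catalog` from truth records."""
    from .cascade import Catalog

    return Catalog(
        name="dbsnp_like",
        entries={
            r.key: f"rs{900_000_000 + i}" for i, r in enumerate(truth) if r.in_dbsnp
        },
    )


def indel_contexts(truth: Sequence[TruthRecord]) -> Dict[VariantKey, tuple]:
    """Variant key -> (local sequence window, anchor offset) for the INDELs."""
    return {
        r.key: (r.context, r.context_offset)
        for r in truth
        if r.is_indel and r.context is not None
    }


def demo_allele_pair():
    """The two published allele insert oligos as an allele sequence pair."""
    from .motifs import (
        CANDIDATE_C_ALLELE_INSERT,
        CANDIDATE_T_ALLELE_INSERT,
        AlleleSequencePair,
    )

    return AlleleSequencePair.from_sequences(
        CANDIDATE_C_ALLELE_INSERT, CANDIDATE_T_ALLELE_INSERT
    )


def demo_gain_table(pair=None, n_gained: int = 2, n_shared: int = 3, threshold: float = 0.45):
    """A constructed 8-mer table in which the alt allele gains extra sites.

    Scores are assigned so that, over the windows covering the variant,
    ``n_shared`` positions are called for both alleles (alt scoring
    slightly higher) and ``n_gained`` further positions are called for the
    alt allele only.  The construction checks itself against reverse-
    complement collisions between the two allele's words and raises if the
    requested pattern cannot be realised on the given pair.
    """
    from .motifs import KmerTable, revcomp

    if pair is None:
        pair = demo_allele_pair()
    k = 8
    off = pair.offset
    covering = list(range(max(0, off - k + 1), min(off, len(pair.ref_seq) - k) + 1))
    ref_words = {i: pair.ref_seq[i : i + k] for i in covering}
    alt_words = {i: pair.alt_seq[i : i + k] for i in covering}

    def clashes(word: str, assigned: Mapping[str, float], forbidden: set) -> bool:
        return word in forbidden or revcomp(word) in forbidden or word in assigned

    scores: Dict[str, float] = {}
    ref_word_set = set(ref_words.values()) | {revcomp(w) for w in ref_words.values()}

    shared_done = gained_done = 0
    for i in covering:
        rw, aw = ref_words[i], alt_words[i]
        if shared_done < n_shared:
            if rw not in scores and aw not in scores and revcomp(rw) != aw:
                scores[rw] = 0.46
                scores[aw] = 0.47
                shared_done += 1
            continue
        if gained_done < n_gained and not clashes(aw, scores, ref_word_set):
            scores[aw] = 0.50
            gained_done += 1
    if shared_done < n_shared or gained_done < n_gained:
        raise ValueError(
            f"could not construct table: {shared_done}/{n_shared} shared, "
            f"{gained_done}/{n_gained} gained"
        )
    table = KmerTable(k=k, scores=scores, threshold=threshold, collapsed=True)

    # self-check: the realised site pattern must match the requested one
    from .motifs import compare_alleles

    comp = compare_alleles(pair, table)
    if comp.count_difference != n_gained or len(comp.shared_scores) != n_shared:
        raise ValueError("constructed table does not realise the requested site pattern")
    if any(d <= 0 for d in comp.score_deltas.values()):
        raise ValueError("shared windows must score higher for the alt allele")
    return table


def truth_table(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """Flatten truth records to a TSV-ready table."""
    rows = []
    for r in truth:
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "class": r.cls,
                "n_carrier_alt_alleles": sum(r.genotypes.values()),
                "in_dbsnp": r.in_dbsnp,
                "maf_all": r.maf.get("ALL", ""),
                "maf_fin": r.maf.get("FIN", ""),
                "context": r.context or "",
                "context_offset": "" if r.context_offset is None else r.context_offset,
            }
        )
    return pd.DataFrame(rows)
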