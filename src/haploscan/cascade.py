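"""The six-step haplotype-variant filter cascade and its INDEL variant.

The cascade isolates variants compatible with a dominantly inherited
haplotype shared by all pooled carriers:

1. region      — inside the linked haplotype interval (closed at both ends)
2. concordant  — identical genotype in both individually sequenced samples
3. pool_shared — at least one alternative read in the pooled sample
4. heterozygous— 0/1 in both individuals (dominant inheritance)
5. frequency   — population MAF at most the cutoff (default 5%), with
                 "population-enriched" recorded when only the local panel
                 exceeds it
6. novel       — absent from every known-variant catalog

Every step is a pure set filter; the cascade records per-step counts and a
complete provenance log (each input key is a survivor or carries exactly
one removal reason).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .calls import CallSet, PooledCallSet, VariantCall, VariantKey
from .genome import GeneModel, GenomeInterval, RegionClass, classify_region, signed_distance


class ConflictingAllelesError(ValueError):
    """Same position and alt allele reported with different ref alleles."""


@dataclass
class FrequencyPanel:
    """Per-population minor allele frequencies keyed by variant."""

    frequencies: Mapping[VariantKey, Mapping[str, float]]
    populations: Tuple[str, ...] = ("ALL", "FIN")

    def __post_init__(self) -> None:
        for key, pops in self.frequencies.items():
            for pop, f in pops.items():
                if not 0.0 <= f <= 0.5:
                    raise ValueError(f"MAF {f} for {key}/{pop} outside [0, 0.5]")

    def maf(self, key: VariantKey, population: str) -> float | None:
        pops = self.frequencies.get(key)
        if pops is None:
            return None
        return pops.get(population)

    @classmethod
    def from_tsv(cls, path: str) -> "FrequencyPanel":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        pops = tuple(c for c in df.columns if c not in ("chrom", "pos", "ref", "alt", "id"))
        freqs = {
            (r.chrom, int(r.pos), r.ref, r.alt): {p: float(getattr(r, p)) for p in pops}
            for r in df.itertuples()
        }
        return cls(frequencies=freqs, populations=pops)


@dataclass
class Catalog:
    """A known-variant catalog (dbSNP-like): keys with identifiers."""

    name: str
    entries: Mapping[VariantKey, str]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    @classmethod
    def from_tsv(cls, path: str, name: str = "catalog") -> "Catalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        entries = {
            (r.chrom, int(r.pos), r.ref, r.alt): str(getattr(r, "id", ""))
            for r in df.itertuples()
        }
        return cls(name=name, entries=entries)


def step_region(calls: Iterable[VariantCall], interval: GenomeInterval) -> List[VariantCall]:
    """Keep calls inside the closed interval (both boundary bases included)."""
    return [c for c in calls if interval.contains(c.chrom, c.pos)]


def step_concordant(calls_a: CallSet, calls_b: CallSet) -> Set[VariantKey]:
    """Keys called in both individuals with identical genotype strings."""
    _check_allele_conflicts(calls_a, calls_b)
    return {
        k for k in calls_a.keys & calls_b.keys
        if calls_a[k].genotype == calls_b[k].genotype
    }


def _check_allele_conflicts(calls_a: CallSet, calls_b: CallSet) -> None:
    by_pos_alt = {(c.chrom, c.pos, c.alt): c.ref for c in calls_a}
    for c in calls_b:
        ref = by_pos_alt.get((c.chrom, c.pos, c.alt))
        if ref is not None and ref != c.ref:
            raise ConflictingAllelesError(
                f"{c.chrom}:{c.pos} alt {c.alt}: ref {ref!r} vs {c.ref!r}"
            )


def step_pool_shared(keys: Set[VariantKey], pooled: PooledCallSet) -> Set[VariantKey]:
    """Keys with a pooled observation carrying at least one alternative read."""
    return {k for k in keys if (o := pooled.get(k)) is not None and o.alt_count >= 1}


def step_heterozygous(
    keys: Set[VariantKey], calls_a: CallSet, calls_b: CallSet
) -> Set[VariantKey]:
    """Keys genotyped 0/1 in both individuals (dominant-model filter)."""
    return {
        k for k in keys
        if calls_a.genotype(k) == "0/1" and calls_b.genotype(k) == "0/1"
    }


def step_frequency(
    keys: Set[VariantKey],
    panel: FrequencyPanel,
    population: str = "FIN",
    max_maf: float = 0.05,
    global_population: str = "ALL",
) -> Tuple[Set[VariantKey], Dict[VariantKey, str]]:
    """Keep keys rare (MAF <= cutoff, boundary retained) or absent from the panel.

    Returns (retained, removal reasons).  A removed key whose local-panel
    MAF exceeds the cutoff while the global MAF does not is recorded as
    "population-enriched"; otherwise as "common".
    """
    retained: Set[VariantKey] = set()
    reasons: Dict[VariantKey, str] = {}
    for k in keys:
        f = panel.maf(k, population)
        if f is None or f <= max_maf:
            retained.add(k)
            continue
        f_global = panel.maf(k, global_population)
        if f_global is not None and f_global <= max_maf:
            reasons[k] = "population-enriched"
        else:
            reasons[k] = "common"
    return retained, reasons


def step_novel(
    keys: Set[VariantKey], catalogs: Sequence[Catalog], mode: str = "all"
) -> Set[VariantKey]:
    """Keep keys not annotated in the catalogs.

    ``mode="all"`` (default) requires absence from every catalog — the
    strict reading of "not annotated in A and/or B and/or C".  ``mode="any"``
    exposes the disjunctive reading (absent from at least one catalog).
    """
    if mode == "all":
        return {k for k in keys if not any(k in cat for cat in catalogs)}
    if mode == "any":
        return {k for k in keys if any(k not in cat for cat in catalogs)} if catalogs else set(keys)
    raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")


@dataclass
class Survivor:
    """A cascade survivor with its annotations."""

    key: VariantKey
    genotype: str
    depth: int | None
    aaf: float | None
    region: RegionClass | None
    distance: int | None
    flags: Tuple[str, ...] = ()


@dataclass
class CascadeResult:
    """Per-step retained sets and counts, survivors, and provenance."""

    steps: List[Tuple[str, int]]
    retained: Dict[str, Set[VariantKey]]
    survivors: List[Survivor]
    provenance: Dict[VariantKey, str]

    @property
    def survivor_keys(self) -> Set[VariantKey]:
        return {s.key for s in self.survivors}

    def counts_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "retained"])

    def survivor_table(self) -> pd.DataFrame:
        rows = []
        for s in sorted(self.survivors, key=lambda s: s.key[1]):
            chrom, pos, ref, alt = s.key
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "genotype": s.genotype,
                    "pool_depth": s.depth,
                    "pool_aaf": None if s.aaf is None else round(s.aaf, 2),
                    "region": s.region.display if s.region else "",
                    "distance_bp": s.distance,
                    "flags": ";".join(s.flags),
                }
            )
        return pd.DataFrame(rows)

    def provenance_table(self) -> pd.DataFrame:
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "fate": fate}
            for k, fate in sorted(self.provenance.items(), key=lambda kv: kv[0][1])
        ]
        return pd.DataFrame(rows)


def _annotate(
    keys: Set[VariantKey],
    calls_a: CallSet,
    pooled: PooledCallSet,
    gene: GeneModel | None,
    upstream_width: int,
    flag_fn=None,
) -> List[Survivor]:
    out = []
    for k in keys:
        chrom, pos, _, _ = k
        obs = pooled.get(k)
        call = calls_a.get(k)
        region = dist = None
        if gene is not None and chrom == gene.chrom:
            region = classify_region(pos, gene, upstream_window=upstream_width)
            dist = signed_distance(pos, gene)
        elif gene is not None:
            region = RegionClass.INTERGENIC
        out.append(
            Survivor(
                key=k,
                genotype=call.genotype if call else "",
                depth=obs.depth if obs else None,
                aaf=obs.aaf if obs else None,
                region=region,
                distance=dist,
                flags=tuple(flag_fn(k)) if flag_fn else (),
            )
        )
    return out


def run_snv_cascade(
    calls_a: CallSet,
    calls_b: CallSet,
    pooled: PooledCallSet,
    interval: GenomeInterval,
    panel: FrequencyPanel,
    catalogs: Sequence[Catalog],
    gene: GeneModel | None = None,
    upstream_width: int = 1_000_000,
    max_maf: float = 0.05,
    population: str = "FIN",
    novel_mode: str = "all",
) -> CascadeResult:
    """Run the six SNV filter steps in their stated order and annotate survivors."""
    provenance: Dict[VariantKey, str] = {}
    is_snv = lambda k: len(k[2]) == len(k[3])
    all_input = {k for k in calls_a.keys | calls_b.keys | pooled.keys if is_snv(k)}

    in_region_a = CallSet(step_region(calls_a, interval), calls_a.sample, calls_a.platform)
    in_region_b = CallSet(step_region(calls_b, interval), calls_b.sample, calls_b.platform)
    region_keys = {
        k for k in all_input if interval.contains(k[0], k[1])
    }
    for k in all_input - region_keys:
        provenance[k] = "removed:region"

    concordant = step_concordant(in_region_a, in_region_b)
    for k in region_keys - concordant:
        if k not in calls_a.keys or k not in calls_b.keys:
            provenance[k] = "removed:concordant:missing-in-one-individual"
        else:
            provenance[k] = "removed:concordant:genotype-mismatch"

    shared = step_pool_shared(concordant, pooled)
    for k in concordant - shared:
        provenance[k] = "removed:pool_shared"

    het = step_heterozygous(shared, in_region_a, in_region_b)
    for k in shared - het:
        provenance[k] = "removed:heterozygous"

    rare, freq_reasons = step_frequency(het, panel, population=population, max_maf=max_maf)
    for k, why in freq_reasons.items():
        provenance[k] = f"removed:frequency:{why}"

    novel = step_novel(rare, catalogs, mode=novel_mode)
    for k in rare - novel:
        provenance[k] = "removed:novel:catalogued"

    for k in novel:
        provenance[k] = "survivor"

    steps = [
        ("region", len(region_keys)),
        ("concordant", len(concordant)),
        ("pool_shared", len(shared)),
        ("heterozygous", len(het)),
        ("frequency", len(rare)),
        ("novel", len(novel)),
    ]
    retained = {
        "region": region_keys,
        "concordant": concordant,
        "pool_shared": shared,
        "heterozygous": het,
        "frequency": rare,
        "novel": novel,
    }
    survivors = _annotate(novel, in_region_a, pooled, gene, upstream_width)
    return CascadeResult(steps=steps, retained=retained, survivors=survivors, provenance=provenance)


# -- INDEL repeat-context triage ---------------------------------------------


def repeat_context(
    seq: str, offset: int, event_len: int = 1, r1: int = 5, r2: int = 3
) -> str:
    """Repeat class of the sequence context around an INDEL.

    ``offset`` indexes the anchor base of the event within ``seq``; the
    event occupies ``[offset, offset + event_len]``.  Returns
    "mononucleotide" if a homopolymer run of at least ``r1`` bases overlaps
    the event, else "dinucleotide" if a tandem two-base run of at least
    ``r2`` units does, else "none".
    """
    if not 0 <= offset < len(seq):
        raise ValueError(f"offset {offset} outside sequence of length {len(seq)}")
    lo, hi = offset, min(len(seq) - 1, offset + event_len)

    # homopolymer runs
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= r1 and i <= hi and j >= lo:
            return "mononucleotide"
        i = j + 1

    # tandem dinucleotide runs (unit of two distinct bases)
    for phase in (0, 1):
        i = phase
        while i + 1 < len(seq):
            unit = seq[i : i + 2]
            if unit[0] == unit[1]:
                i += 2
                continue
            j = i
            while seq[j + 2 : j + 4] == unit:
                j += 2
            n_units = (j - i) // 2 + 1
            if n_units >= r2 and i <= hi and j + 1 >= lo:
                return "dinucleotide"
            i = j + 2
    return "none"


def step_indel_presence(
    pooled_keys: Set[VariantKey], calls_a: CallSet, calls_b: CallSet
) -> Set[VariantKey]:
    """INDEL concordance rule: in the pool AND in at least one individual."""
    return {k for k in pooled_keys if k in calls_a or k in calls_b}


def run_indel_cascade(
    calls_a: CallSet,
    calls_b: CallSet,
    pooled: PooledCallSet,
    interval: GenomeInterval,
    panel: FrequencyPanel,
    catalogs: Sequence[Catalog],
    contexts: Mapping[VariantKey, Tuple[str, int]] | None = None,
    gene: GeneModel | None = None,
    upstream_width: int = 1_000_000,
    max_maf: float = 0.05,
    population: str = "FIN",
    r1: int = 5,
    r2: int = 3,
) -> CascadeResult:
    """INDEL cascade: relaxed presence rule plus repeat-context triage.

    Unlike the SNV cascade, an INDEL is kept when present in the pooled
    sample and at least one individual.  Heterozygosity is required in every
    individual that carries it.  Survivors of length <= 2 bases inside a
    mono-/dinucleotide repeat run are flagged "likely_neutral" — short
    microsatellite slippage events with no expected functional consequence.
    ``contexts`` maps variant key -> (local sequence, offset of the anchor
    base within it).
    """
    provenance: Dict[VariantKey, str] = {}
    is_indel = lambda k: len(k[2]) != len(k[3])
    all_input = {k for k in calls_a.keys | calls_b.keys | pooled.keys if is_indel(k)}
    region_keys = {k for k in all_input if interval.contains(k[0], k[1])}
    for k in all_input - region_keys:
        provenance[k] = "removed:region"

    pooled_in_region = {k for k in pooled.keys & region_keys if pooled[k].alt_count >= 1}
    present = step_indel_presence(pooled_in_region, calls_a, calls_b)
    for k in region_keys - present:
        provenance[k] = "removed:presence"

    het = {
        k for k in present
        if all(cs.genotype(k) == "0/1" for cs in (calls_a, calls_b) if k in cs)
    }
    for k in present - het:
        provenance[k] = "removed:heterozygous"

    rare, freq_reasons = step_frequency(het, panel, population=population, max_maf=max_maf)
    for k, why in freq_reasons.items():
        provenance[k] = f"removed:frequency:{why}"

    novel = step_novel(rare, catalogs)
    for k in rare - novel:
        provenance[k] = "removed:novel:catalogued"
    for k in novel:
        provenance[k] = "survivor"

    def flags(k: VariantKey) -> List[str]:
        out: List[str] = []
        if contexts and k in contexts:
            seq, off = contexts[k]
            event_len = abs(len(k[2]) - len(k[3]))
            if event_len <= 2 and repeat_context(seq, off, event_len, r1, r2) != "none":
                out.append("likely_neutral")
        return out

    steps = [
        ("region", len(region_keys)),
        ("presence", len(present)),
        ("heterozygous", len(het)),
        ("frequency", len(rare)),
        ("novel", len(novel)),
    ]
    retained = {
        "region": region_keys,
        "presence": present,
        "heterozygous": het,
        "frequency": rare,
        "novel": novel,
    }
    # annotate genotype from whichever individual carries the indel
    merged = {}
    for cs in (calls_b, calls_a):  # A takes precedence when both carry it
        for c in cs:
            if c.key in novel:
                merged[c.key] = c
    carrier_calls = CallSet(merged.values(), sample="either")
    survivors = _annotate(novel, carrier_calls, pooled, gene, upstream_width, flag_fn=flags)
    return CascadeResult(steps=steps, retained=retained, survivors=survivors, provenance=provenance)
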