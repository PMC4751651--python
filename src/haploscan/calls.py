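"""Variant calls, call sets and pooled observations.

A variant is identified across platforms by its *key* ``(chrom, pos, ref,
alt)`` after reference-free left normalization (common suffix then common
prefix trimming, always keeping at least one base of each allele).  The two
individually sequenced samples carry genotypes; the pooled sample carries
only depth and alternative-read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Tuple

VariantKey = Tuple[str, int, str, str]

_BASES = frozenset("ACGT")

GENOTYPES = ("0/0", "0/1", "1/1")


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Left-normalized (chrom, pos, ref, alt) key.

    Trims the longest common suffix, then the longest common prefix,
    keeping at least one base of each allele and shifting ``pos`` right by
    the number of prefix bases removed.  SNVs pass through unchanged.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


@dataclass
class VariantCall:
    """One called variant in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    depth: int
    alt_depth: int
    sample: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"allele {allele!r} not a non-empty ACGT string")

    @property
    def key(self) -> VariantKey:
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_het(self) -> bool:
        return self.genotype == "0/1"


class CallSet:
    """Variant calls of one sample, indexed by normalized key."""

    def __init__(self, calls: Iterable[VariantCall], sample: str = "", platform: str = ""):
        self.sample = sample
        self.platform = platform
        self._by_key: Dict[VariantKey, VariantCall] = {}
        for c in calls:
            k = c.key
            if k in self._by_key:
                raise ValueError(f"duplicate variant key {k} in call set {sample!r}")
            self._by_key[k] = c

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self._by_key.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def __getitem__(self, key: VariantKey) -> VariantCall:
        return self._by_key[key]

    def get(self, key: VariantKey) -> VariantCall | None:
        return self._by_key.get(key)

    @property
    def keys(self) -> set:
        return set(self._by_key)

    def genotype(self, key: VariantKey) -> str | None:
        c = self._by_key.get(key)
        return c.genotype if c else None


@dataclass
class PooledObservation:
    """Per-site pooled depth and alternative-read count.

    ``aaf`` is the alternative allele fraction alt_count/depth — the pooled
    analogue of a genotype; for a pool in which every contributor is
    heterozygous its expectation is 0.5.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("pooled observation requires depth >= 1")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(f"alt_count {self.alt_count} outside [0, depth={self.depth}]")

    @property
    def key(self) -> VariantKey:
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def aaf(self) -> float:
        return self.alt_count / self.depth


class PooledCallSet:
    """Pooled observations indexed by normalized key."""

    def __init__(self, observations: Iterable[PooledObservation]):
        self._by_key: Dict[VariantKey, PooledObservation] = {}
        for o in observations:
            k = o.key
            if k in self._by_key:
                raise ValueError(f"duplicate pooled key {k}")
            self._by_key[k] = o

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[PooledObservation]:
        return iter(self._by_key.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def __getitem__(self, key: VariantKey) -> PooledObservation:
        return self._by_key[key]

    def get(self, key: VariantKey) -> PooledObservation | None:
        return self._by_key.get(key)

    @property
    def keys(self) -> set:
        return set(self._by_key)
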