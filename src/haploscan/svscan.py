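"""Insert-size structural-variant scan.

A paired-end library has a characteristic insert-size distribution.  Read
pairs spanning a deletion map further apart than the library average; pairs
spanning an insertion map closer.  The scan estimates robust insert
statistics, flags discordant pairs beyond a z-threshold, and clusters
same-sign discordant pairs into SV candidates whose size estimate is the
cluster's mean deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeInterval


@dataclass(frozen=True)
class ReadPair:
    """A mapped read pair with its implied insert distance."""

    chrom: str
    left: int
    right: int
    distance: int
    orientation: str = "FR"

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError(f"left {self.left} > right {self.right}")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass(frozen=True)
class InsertStats:
    mean: float
    sd: float


@dataclass
class SVCandidate:
    """A clustered structural-variant candidate."""

    type: str  # "deletion" | "insertion"
    interval: GenomeInterval
    size: float
    support: int
    mean_deviation: float


def pairs_from_frame(df: pd.DataFrame) -> List[ReadPair]:
    """Read pairs from a table with chrom/pos1/pos2[/distance] columns."""
    pairs = []
    has_dist = "distance" in df.columns
    for r in df.itertuples():
        d = int(r.distance) if has_dist else int(r.pos2) - int(r.pos1)
        pairs.append(ReadPair(chrom=str(r.chrom), left=int(r.pos1), right=int(r.pos2), distance=d))
    return pairs


def insert_stats(pairs: Sequence[ReadPair]) -> InsertStats:
    """Robust insert mean and spread: median and MAD scaled to Gaussian sd."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to estimate insert statistics")
    d = np.array([p.distance for p in pairs], dtype=float)
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    return InsertStats(mean=med, sd=1.4826 * mad)


def flag_discordant(
    pairs: Sequence[ReadPair], stats: InsertStats, z_threshold: float = 4.0
) -> List[Tuple[ReadPair, float]]:
    """Pairs whose distance deviates from the mean by more than z*sd.

    Returns (pair, deviation); positive deviation is deletion-like (mapped
    too far apart), negative is insertion-like.
    """
    if stats.sd <= 0:
        return [(p, p.distance - stats.mean) for p in pairs if p.distance != stats.mean]
    out = []
    for p in pairs:
        dev = p.distance - stats.mean
        if abs(dev) > z_threshold * stats.sd:
            out.append((p, dev))
    return out


def cluster_candidates(
    discordant: Sequence[Tuple[ReadPair, float]],
    max_gap: float,
    min_support: int = 3,
) -> List[SVCandidate]:
    """Single-linkage clustering of same-sign discordant pairs into candidates.

    Pairs of the same deviation sign whose left positions lie within
    ``max_gap`` of the previous pair join one cluster.  A cluster of at
    least ``min_support`` pairs becomes a candidate whose size estimate is
    the mean absolute deviation of its members and whose interval spans the
    supporting pairs.
    """
    candidates: List[SVCandidate] = []
    for sign in (+1, -1):
        members = sorted(
            ((p, dev) for p, dev in discordant if np.sign(dev) == sign),
            key=lambda t: t[0].left,
        )
        cluster: List[Tuple[ReadPair, float]] = []
        for item in members:
            if cluster and item[0].left - cluster[-1][0].left > max_gap:
                _flush(cluster, sign, min_support, candidates)
                cluster = []
            cluster.append(item)
        _flush(cluster, sign, min_support, candidates)
    candidates.sort(key=lambda c: c.interval.start)
    return candidates


def _flush(
    cluster: List[Tuple[ReadPair, float]],
    sign: int,
    min_support: int,
    out: List[SVCandidate],
) -> None:
    if len(cluster) < min_support:
        return
    devs = np.array([dev for _, dev in cluster])
    size = float(np.mean(np.abs(devs)))
    chrom = cluster[0][0].chrom
    start = min(p.left for p, _ in cluster)
    end = max(p.right for p, _ in cluster)
    out.append(
        SVCandidate(
            type="deletion" if sign > 0 else "insertion",
            interval=GenomeInterval(chrom, start, end),
            size=size,
            support=len(cluster),
            mean_deviation=float(np.mean(devs)),
        )
    )


def scan_svs(
    pairs: Sequence[ReadPair],
    z_threshold: float = 4.0,
    min_support: int = 3,
    max_gap: float | None = None,
) -> Tuple[InsertStats, List[SVCandidate]]:
    """Full scan: estimate insert stats, flag discordant pairs, cluster."""
    stats = insert_stats(pairs)
    if max_gap is None:
        max_gap = stats.mean
    discordant = flag_discordant(pairs, stats, z_threshold)
    return stats, cluster_candidates(discordant, max_gap=max_gap, min_support=min_support)


def candidates_table(candidates: Sequence[SVCandidate]) -> pd.DataFrame:
    """BEDPE-like candidate table."""
    return pd.DataFrame(
        [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "type": c.type,
                "size": round(c.size, 1),
                "support": c.support,
            }
            for c in candidates
        ]
    )
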