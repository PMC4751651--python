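"""Pooled allele-fraction model and coverage summaries.

In an equimolar pool of n diploid carriers, a site's alternative allele
fraction (AAF = alt reads / depth) estimates the pooled allele dosage
(sum of alt alleles)/(2n).  For a haplotype heterozygous in every carrier
the expectation is exactly 0.5, and the read-level sampling is
binomial(depth, 0.5) — the basis of the consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def estimate_aaf(alt_count: int, depth: int, precision: int | None = None) -> float:
    """Alternative allele fraction alt_count/depth.

    ``precision`` rounds half-up to that many decimals (2 matches the
    conventional display precision).  Depth must be at least 1.
    """
    if depth < 1:
        raise ValueError("AAF undefined at zero depth")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count {alt_count} outside [0, {depth}]")
    aaf = alt_count / depth
    if precision is None:
        return aaf
    q = Decimal(1).scaleb(-precision)
    return float((Decimal(alt_count) / Decimal(depth)).quantize(q, rounding=ROUND_HALF_UP))


def expected_pool_aaf(
    n_carriers: int, carrier_genotypes: str | Sequence[int] = "het"
) -> float:
    """Expected pooled AAF for a given carrier genotype configuration.

    ``carrier_genotypes`` is either a label applied to all carriers
    ("het", "hom_alt", "hom_ref") or a sequence of per-carrier alternative
    allele counts (0, 1 or 2).  19 all-heterozygous carriers give 19/38 = 0.5.
    """
    if n_carriers < 1:
        raise ValueError("need at least one carrier")
    if isinstance(carrier_genotypes, str):
        dosage = {"het": 1, "hom_alt": 2, "hom_ref": 0}
        if carrier_genotypes not in dosage:
            raise ValueError(f"unknown genotype label {carrier_genotypes!r}")
        total = dosage[carrier_genotypes] * n_carriers
    else:
        if len(carrier_genotypes) != n_carriers:
            raise ValueError("one genotype per carrier required")
        if any(g not in (0, 1, 2) for g in carrier_genotypes):
            raise ValueError("allele counts must be 0, 1 or 2")
        total = sum(carrier_genotypes)
    return total / (2 * n_carriers)


@dataclass(frozen=True)
class ConsistencyResult:
    """Central interval of the AAF sampling distribution and a verdict."""

    aaf: float
    expected: float
    lower: float
    upper: float
    inside: bool
    method: str
    n_sim: int | None
    seed: int | None


def aaf_consistency(
    alt_count: int,
    depth: int,
    expected: float,
    n_sim: int = 10_000,
    seed: int = 0,
    method: str = "simulate",
) -> ConsistencyResult:
    """Is an observed AAF consistent with a binomial model at ``expected``?

    Builds the central 95% interval of AAF under binomial(depth, expected)
    — by Monte-Carlo simulation (default) or exact binomial quantiles —
    and reports whether the observation falls inside.
    """
    if not 0.0 <= expected <= 1.0:
        raise ValueError("expected AAF must lie in [0, 1]")
    aaf = estimate_aaf(alt_count, depth)
    if method == "simulate":
        rng = np.random.default_rng(seed)
        sims = rng.binomial(depth, expected, size=n_sim) / depth
        lower, upper = np.quantile(sims, [0.025, 0.975])
        return ConsistencyResult(
            aaf=aaf, expected=expected, lower=float(lower), upper=float(upper),
            inside=bool(lower <= aaf <= upper), method="simulate", n_sim=n_sim, seed=seed,
        )
    if method == "exact":
        lo = stats.binom.ppf(0.025, depth, expected) / depth
        hi = stats.binom.ppf(0.975, depth, expected) / depth
        return ConsistencyResult(
            aaf=aaf, expected=expected, lower=float(lo), upper=float(hi),
            inside=bool(lo <= aaf <= hi), method="exact", n_sim=None, seed=None,
        )
    raise ValueError(f"method must be 'simulate' or 'exact', got {method!r}")


@dataclass
class CoverageSummary:
    """Fraction of assayed positions reaching each depth threshold."""

    thresholds: Sequence[int]
    fractions: Mapping[str, Sequence[float]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(dict(self.fractions), index=list(self.thresholds))
        df.index.name = "min_depth"
        return df


def coverage_summary(
    depth_tracks: Mapping[str, Sequence[int]] | Sequence[int],
    thresholds: Sequence[int] = (5, 10, 20, 30),
) -> CoverageSummary:
    """Per-sample fractions of positions with depth >= each threshold."""
    if not isinstance(depth_tracks, Mapping):
        depth_tracks = {"sample": depth_tracks}
    fractions = {}
    for sample, depths in depth_tracks.items():
        d = np.asarray(depths)
        if d.size == 0:
            raise ValueError(f"empty depth track for {sample!r}")
        fractions[sample] = [float(np.mean(d >= t)) for t in thresholds]
    return CoverageSummary(thresholds=list(thresholds), fractions=fractions)
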