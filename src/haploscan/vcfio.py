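"""VCF and TSV input/output.

Individual call sets are VCF v4.2 with GT/DP/AD sample fields; the pooled
call set is a single-sample VCF carrying DP and AD (no genotype — a pool
has allele counts, not a diploid genotype).  All positions are written and
read 1-based per the VCF convention.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
import pysam

from .calls import CallSet, PooledCallSet, PooledObservation, VariantCall

POOL_SAMPLE = "POOL"


def _base_header(chroms: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(chroms):  # preserve order, dedupe
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    return header


def write_vcf(callset: CallSet, path: str) -> None:
    """Write an individual sample's calls as VCF v4.2."""
    calls = sorted(callset, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    header = _base_header(c.chrom for c in calls)
    sample = callset.sample or "SAMPLE"
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for c in calls:
            rec = vf.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt)
            )
            gt = tuple(int(a) for a in c.genotype.split("/"))
            rec.samples[sample]["GT"] = gt
            rec.samples[sample]["DP"] = c.depth
            rec.samples[sample]["AD"] = (c.depth - c.alt_depth, c.alt_depth)
            vf.write(rec)


def read_vcf(path: str, platform: str = "") -> CallSet:
    """Read a single-sample VCF back into a :class:`CallSet`."""
    calls = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, got {samples}")
        sample = samples[0]
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"multiallelic record at {rec.contig}:{rec.pos}")
            fmt = rec.samples[sample]
            gt = "/".join(str(a) for a in fmt["GT"])
            depth = int(fmt["DP"])
            ad = fmt.get("AD")
            alt_depth = int(ad[1]) if ad is not None else 0
            calls.append(
                VariantCall(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype=gt,
                    depth=depth,
                    alt_depth=alt_depth,
                    sample=sample,
                    platform=platform,
                )
            )
    return CallSet(calls, sample=sample, platform=platform)


def write_pool_vcf(pooled: PooledCallSet, path: str) -> None:
    """Write pooled observations as a single-sample VCF with DP and AD."""
    obs = sorted(pooled, key=lambda o: (o.chrom, o.pos, o.ref, o.alt))
    header = _base_header(o.chrom for o in obs)
    header.add_sample(POOL_SAMPLE)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for o in obs:
            rec = vf.new_record(contig=o.chrom, start=o.pos - 1, alleles=(o.ref, o.alt))
            rec.samples[POOL_SAMPLE]["GT"] = (None, None)  # pool has no genotype
            rec.samples[POOL_SAMPLE]["DP"] = o.depth
            rec.samples[POOL_SAMPLE]["AD"] = (o.depth - o.alt_count, o.alt_count)
            vf.write(rec)


def read_pool_vcf(path: str) -> PooledCallSet:
    """Read a pooled-sample VCF back into a :class:`PooledCallSet`."""
    obs = []
    with pysam.VariantFile(path) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            fmt = rec.samples[sample]
            depth = int(fmt["DP"])
            alt_count = int(fmt["AD"][1])
            obs.append(
                PooledObservation(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    depth=depth,
                    alt_count=alt_count,
                )
            )
    return PooledCallSet(obs)


def write_tsv(df: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    """Write a TSV, optionally preceded by '#'-prefixed header comments."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
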