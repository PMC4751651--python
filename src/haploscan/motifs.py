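"""Allele-aware 8-mer binding-site scanning.

Protein binding microarrays (PBM) assign every k-base word an enrichment
score summarising a transcription factor's affinity for it; a word above a
chosen cutoff is a predicted binding site.  Scanning the two alleles of a
variant and comparing the above-threshold windows that cover the variant
base shows whether one allele creates or destroys predicted sites — here
used for a homeobox factor (LHX2) whose high-affinity consensus is the
palindromic TAATTA element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = frozenset("ACGT")

#: conventional PBM enrichment-score cutoff for calling a site
DEFAULT_SITE_THRESHOLD = 0.45


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: Published 35-nt minus-strand oligos around the candidate regulatory SNV
#: upstream of ROBO1 (the gene is minus-strand, so the plus-strand C/T
#: alleles read as G/A here).  They share all flanks and differ at exactly
#: one base; both contain the homeobox TAATTA consensus.
CANDIDATE_C_ALLELE_INSERT = "CGTTCTTACAAAGTCCCGTTAATTAATATTGGTGG"
CANDIDATE_T_ALLELE_INSERT = "CGTTCTTACAAAGTCCCATTAATTAATATTGGTGG"


def _validate_seq(seq: str) -> None:
    for i, b in enumerate(seq):
        if b not in _BASES:
            raise ValueError(f"non-ACGT character {b!r} at offset {i}")


@dataclass
class KmerTable:
    """k-mer enrichment scores with an above-threshold site cutoff.

    When ``collapsed`` is true a word and its reverse complement share one
    score, so a scan needs only one pass over the forward strand.
    """

    k: int
    scores: Dict[str, float]
    threshold: float = DEFAULT_SITE_THRESHOLD
    collapsed: bool = True

    def __post_init__(self) -> None:
        for w in self.scores:
            if len(w) != self.k or set(w) - _BASES:
                raise ValueError(f"bad {self.k}-mer key {w!r}")
        if self.collapsed:
            for w in list(self.scores):
                rc = revcomp(w)
                if rc in self.scores and self.scores[rc] != self.scores[w]:
                    raise ValueError(f"conflicting scores for {w}/{rc} in collapsed table")
                self.scores[rc] = self.scores[w]

    def score(self, word: str) -> float | None:
        s = self.scores.get(word)
        if s is None and self.collapsed:
            s = self.scores.get(revcomp(word))
        return s


@dataclass(frozen=True)
class SiteCall:
    """An above-threshold k-mer window."""

    start: int
    strand: str  # "+", "-" or "." for a strand-collapsed call
    kmer: str
    score: float


def scan_sites(seq: str, table: KmerTable, both_strands: bool = True) -> List[SiteCall]:
    """All above-threshold k-mer windows of ``seq``, left to right.

    With a collapsed table each window yields at most one call (strand ".");
    otherwise the forward word and, if ``both_strands``, its reverse
    complement are scored separately.
    """
    _validate_seq(seq)
    k = table.k
    calls: List[SiteCall] = []
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if table.collapsed:
            s = table.score(word)
            if s is not None and s >= table.threshold:
                calls.append(SiteCall(start=i, strand=".", kmer=word, score=s))
        else:
            s = table.scores.get(word)
            if s is not None and s >= table.threshold:
                calls.append(SiteCall(start=i, strand="+", kmer=word, score=s))
            if both_strands:
                rc = revcomp(word)
                s = table.scores.get(rc)
                if s is not None and s >= table.threshold:
                    calls.append(SiteCall(start=i, strand="-", kmer=rc, score=s))
    return calls


@dataclass(frozen=True)
class AlleleSequencePair:
    """Two allele sequences sharing flanks, differing at one base."""

    left_flank: str
    right_flank: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("degenerate pair: ref and alt base are identical")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("allele comparison is defined for single-base alleles")
        _validate_seq(self.left_flank + self.ref + self.alt + self.right_flank)

    @property
    def offset(self) -> int:
        return len(self.left_flank)

    @property
    def ref_seq(self) -> str:
        return self.left_flank + self.ref + self.right_flank

    @property
    def alt_seq(self) -> str:
        return self.left_flank + self.alt + self.right_flank

    @classmethod
    def from_sequences(cls, ref_seq: str, alt_seq: str) -> "AlleleSequencePair":
        """Build from two equal-length sequences differing at exactly one base."""
        if len(ref_seq) != len(alt_seq):
            raise ValueError("allele sequences must have equal length")
        diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
        if len(diffs) != 1:
            raise ValueError(f"sequences differ at {len(diffs)} positions, expected exactly 1")
        i = diffs[0]
        return cls(
            left_flank=ref_seq[:i],
            right_flank=ref_seq[i + 1 :],
            ref=ref_seq[i],
            alt=alt_seq[i],
        )


@dataclass
class AlleleComparison:
    """Variant-covering site calls per allele and their differences."""

    ref_calls: List[SiteCall]
    alt_calls: List[SiteCall]
    #: |alt calls| - |ref calls| over variant-covering windows
    count_difference: int
    #: start -> (ref score, alt score) for windows called in both alleles
    shared_scores: Dict[int, Tuple[float, float]] = field(default_factory=dict)

    @property
    def score_deltas(self) -> Dict[int, float]:
        return {i: alt - ref for i, (ref, alt) in self.shared_scores.items()}


def compare_alleles(pair: AlleleSequencePair, table: KmerTable) -> AlleleComparison:
    """Compare predicted sites between the two alleles of a variant.

    Only the k windows covering the variant base are compared — windows
    entirely inside the shared flanks are identical between alleles and
    carry no allelic information.
    """
    k = table.k
    off = pair.offset
    covering = range(max(0, off - k + 1), min(off, len(pair.ref_seq) - k) + 1)

    def covering_calls(seq: str) -> Dict[int, SiteCall]:
        return {c.start: c for c in scan_sites(seq, table) if c.start in covering}

    ref_calls = covering_calls(pair.ref_seq)
    alt_calls = covering_calls(pair.alt_seq)
    shared = {
        i: (ref_calls[i].score, alt_calls[i].score)
        for i in sorted(set(ref_calls) & set(alt_calls))
    }
    return AlleleComparison(
        ref_calls=[ref_calls[i] for i in sorted(ref_calls)],
        alt_calls=[alt_calls[i] for i in sorted(alt_calls)],
        count_difference=len(alt_calls) - len(ref_calls),
        shared_scores=shared,
    )


def find_consensus(seq: str, motif: str = "TAATTA", both_strands: bool = True) -> List[int]:
    """All (possibly overlapping) exact-match offsets of a consensus motif.

    A palindromic motif (equal to its reverse complement, like TAATTA) is
    reported once per position.
    """
    _validate_seq(seq)
    _validate_seq(motif)
    targets = {motif}
    if both_strands:
        targets.add(revcomp(motif))
    hits = set()
    for t in targets:
        start = 0
        while (i := seq.find(t, start)) != -1:
            hits.add(i)
            start = i + 1
    return sorted(hits)


def load_kmer_table(
    path: str, threshold: float = DEFAULT_SITE_THRESHOLD, collapse: bool = True
) -> KmerTable:
    """Read a k-mer score TSV (k-mer [, reverse-complement k-mer], score).

    The score is taken from the last numeric column; word length is
    inferred from the first row and enforced.  Conflicting duplicate scores
    raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("k-mer table needs at least a k-mer and a score column")
    k = len(str(df.iloc[0, 0]))
    scores: Dict[str, float] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        word = str(row[0]).upper()
        try:
            score = float(row[-1])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line_no}: unparseable score {row[-1]!r}") from exc
        if len(word) != k or set(word) - _BASES:
            raise ValueError(f"line {line_no}: bad {k}-mer {word!r}")
        if word in scores and scores[word] != score:
            raise ValueError(f"line {line_no}: conflicting duplicate score for {word}")
        scores[word] = score
    return KmerTable(k=k, scores=scores, threshold=threshold, collapsed=collapse)


def comparison_table(comparison: AlleleComparison, pair: AlleleSequencePair) -> pd.DataFrame:
    """Alignment-style report: one row per variant-covering called window."""
    rows = []
    ref_by_start = {c.start: c for c in comparison.ref_calls}
    alt_by_start = {c.start: c for c in comparison.alt_calls}
    for start in sorted(set(ref_by_start) | set(alt_by_start)):
        r, a = ref_by_start.get(start), alt_by_start.get(start)
        rows.append(
            {
                "window_start": start,
                "ref_kmer": r.kmer if r else "",
                "ref_score": r.score if r else None,
                "alt_kmer": a.kmer if a else "",
                "alt_score": a.score if a else None,
            }
        )
    return pd.DataFrame(rows)
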