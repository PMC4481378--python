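"""71-mer probe construction and convertibility scoring.

Each SNP with clean 35-nt flanks yields a forward probe
``flank_left + ref + flank_right`` (SNP at position 36) and its reverse
complement. The vendor's conversion-probability model is proprietary, so
probes are scored with a fixed, documented surrogate that penalises the
same failure modes the vendor model reports on: extreme base composition,
homopolymer runs, and non-unique flanks that invite cross-hybridisation::

    score = 1 - (0.4 * g + 0.3 * h + 0.3 * u)

with g the GC-composition penalty (zero inside GC 0.35-0.65, then
``min(1, excess / 0.35)``), h the homopolymer penalty (zero for runs <= 6,
then ``min(1, (run - 6) / 10)``) and u = 1 iff either 35-nt flank occurs
elsewhere in the genome k-mer index. The decision surface keeps the
published thresholds: a SNP is included iff its best probe scores > 0.30,
and 'recommended' means best >= 0.6.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .models import SNPRecord

PROBE_LEN = 71
FLANK = 35
INCLUDE_THRESHOLD = 0.30
RECOMMEND_THRESHOLD = 0.60

GC_LOW, GC_HIGH = 0.35, 0.65
GC_WEIGHT, HOMOPOLYMER_WEIGHT, UNIQUENESS_WEIGHT = 0.4, 0.3, 0.3
MAX_CLEAN_RUN = 6


@dataclass
class ProbePair:
    """Forward/reverse 71-mer probes for one SNP, with tiering."""

    snp_id: str
    probe_fwd: str
    probe_rev: str
    score_fwd: float | None = None
    score_rev: float | None = None
    tier: str | None = None
    included: bool | None = None

    def __post_init__(self) -> None:
        if len(self.probe_fwd) != PROBE_LEN or len(self.probe_rev) != PROBE_LEN:
            raise ValueError(f"{self.snp_id}: probes must be {PROBE_LEN} nt")
        if self.probe_rev != revcomp(self.probe_fwd):
            raise ValueError(
                f"{self.snp_id}: probe_rev is not the reverse complement"
            )

    @property
    def best_score(self) -> float:
        if self.score_fwd is None or self.score_rev is None:
            raise ValueError(f"{self.snp_id}: probes not scored yet")
        return max(self.score_fwd, self.score_rev)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_probes(snp: SNPRecord) -> ProbePair:
    """Construct the unscored probe pair for a flank-complete SNP."""
    if snp.flank_left is None or snp.flank_right is None:
        raise ValueError(f"{snp.snp_id}: missing 35-nt flanks")
    fwd = snp.flank_left + snp.ref + snp.flank_right
    if "N" in fwd:
        raise ValueError(f"{snp.snp_id}: probe window contains N")
    return ProbePair(snp_id=snp.snp_id, probe_fwd=fwd, probe_rev=revcomp(fwd))


class KmerIndex:
    """Exact 35-mer occurrence counts over a genome, both strands."""

    def __init__(self, k: int = FLANK) -> None:
        self.k = k
        self.counts: Counter = Counter()

    @classmethod
    def from_sequences(
        cls, sequences: dict[str, str], k: int = FLANK
    ) -> "KmerIndex":
        index = cls(k)
        for seq in sequences.values():
            index.add(seq)
        return index

    def add(self, sequence: str) -> None:
        seq = sequence.upper()
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - self.k + 1):
                kmer = strand_seq[i: i + self.k]
                if "N" not in kmer:
                    self.counts[kmer] += 1

    def occurrences(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        return self.counts[kmer]

    def is_duplicated(self, kmer: str) -> bool:
        """True iff the k-mer occurs at more than one genomic site."""
        return self.occurrences(kmer) >= 2


def gc_penalty(probe: str) -> float:
    gc = (probe.count("G") + probe.count("C")) / len(probe)
    if GC_LOW <= gc <= GC_HIGH:
        return 0.0
    excess = GC_LOW - gc if gc < GC_LOW else gc - GC_HIGH
    return min(1.0, excess / 0.35)


def homopolymer_penalty(probe: str) -> float:
    run = best = 1
    for a, b in zip(probe, probe[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    if best <= MAX_CLEAN_RUN:
        return 0.0
    return min(1.0, (best - MAX_CLEAN_RUN) / 10.0)


def convertibility_score(probe: str, genome_index: KmerIndex | None = None) -> float:
    """Deterministic surrogate conversion score in [0, 1].

    Without a genome index the non-specific-hybridisation term is zero
    (no duplication evidence).
    """
    if len(probe) != PROBE_LEN:
        raise ValueError(f"probe must be {PROBE_LEN} nt")
    if set(probe) - set("ACGT"):
        raise ValueError("probe must be over ACGT")
    g = gc_penalty(probe)
    h = homopolymer_penalty(probe)
    u = 0.0
    if genome_index is not None:
        left, right = probe[:FLANK], probe[-FLANK:]
        if genome_index.is_duplicated(left) or genome_index.is_duplicated(right):
            u = 1.0
    # round away float noise so threshold comparisons are exact
    return round(
        1.0 - (GC_WEIGHT * g + HOMOPOLYMER_WEIGHT * h + UNIQUENESS_WEIGHT * u),
        12,
    )


def score_pair(pair: ProbePair, genome_index: KmerIndex | None = None) -> ProbePair:
    pair.score_fwd = convertibility_score(pair.probe_fwd, genome_index)
    pair.score_rev = convertibility_score(pair.probe_rev, genome_index)
    return pair


def tier_and_select(pair: ProbePair) -> ProbePair:
    """Apply the published thresholds: include iff best > 0.30; tiers at 0.6.

    A best score of exactly 0.30 is excluded (strict inequality).
    """
    best = pair.best_score
    if best >= RECOMMEND_THRESHOLD:
        pair.tier = "recommended"
    elif best > INCLUDE_THRESHOLD:
        pair.tier = "neutral"
    else:
        pair.tier = "not_recommended"
    pair.included = best > INCLUDE_THRESHOLD
    return pair


def design_probes(
    snps: list[SNPRecord], genome_index: KmerIndex | None = None
) -> list[ProbePair]:
    """Build, score and tier probes for every flank-complete SNP."""
    return [
        tier_and_select(score_pair(build_probes(snp), genome_index))
        for snp in snps
    ]


def conversion_rate(pairs: list[ProbePair]) -> float:
    """Percent of screened candidates whose best probe passes inclusion."""
    if not pairs:
        raise ValueError("no candidates screened")
    n_inc = sum(1 for p in pairs if p.included)
    return 100.0 * n_inc / len(pairs)
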