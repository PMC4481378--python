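"""Core domain types shared across the array-design pipeline.

Coordinates are 1-based and inclusive everywhere in memory; only BED output
converts to 0-based half-open. Genotype calls are unphased and live in the
four-state alphabet {AA, AB, BB, NoCall}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CATEGORIES = ("CSCWR", "SCR", "AGCR", "MCR", "UNASSIGNED")
FEATURE_KINDS = ("CDS", "intron", "utr5", "utr3")
REGIONS = ("synonymous", "nonsynonymous", "intron", "utr5", "utr3", "unknown")
NUCLEOTIDES = frozenset("ACGT")

#: integer encoding of genotype calls used in :class:`GenotypeMatrix`
AA, AB, BB, NOCALL = 0, 1, 2, -1
CALL_TO_CODE = {"AA": AA, "AB": AB, "BB": BB, "NC": NOCALL}
CODE_TO_CALL = {v: k for k, v in CALL_TO_CODE.items()}


class FormatError(ValueError):
    """An input file or record violates its format contract."""


@dataclass(frozen=True)
class Feature:
    """One sub-gene interval (CDS, intron or UTR), genomic 1-based inclusive."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"feature {self.kind} has start > end")


@dataclass
class GeneModel:
    """A gene's coordinates, strand, category and substructure.

    ``sequence``, when present, is the plus-strand genomic slice covering
    [start, end]; minus-strand genes are reverse-complemented on demand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    category: str = "UNASSIGNED"
    features: list[Feature] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")
        for f in self.features:
            if f.start < self.start or f.end > self.end:
                raise FormatError(
                    f"{self.gene_id}: feature {f.kind} [{f.start},{f.end}] "
                    f"outside gene span [{self.start},{self.end}]"
                )
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.gene_id}: sequence length {len(self.sequence)} "
                    f"!= span {self.length}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def local_pos(self, genomic_pos: int) -> int:
        """Map a genomic position to a 1-based offset on the stored sequence."""
        if not self.start <= genomic_pos <= self.end:
            raise ValueError(f"position {genomic_pos} outside {self.gene_id}")
        return genomic_pos - self.start + 1

    def cds_intervals(self) -> list[tuple[int, int]]:
        """CDS intervals in ascending genomic order."""
        return sorted(
            (f.start, f.end) for f in self.features if f.kind == "CDS"
        )

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals())

    def check_protein_coding(self) -> None:
        """Raise if the total CDS length is not a whole number of codons."""
        n = self.cds_length()
        if n == 0 or n % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {n} not divisible by 3"
            )

    def feature_at(self, genomic_pos: int) -> str | None:
        """Kind of the feature containing the position, or None."""
        for f in self.features:
            if f.start <= genomic_pos <= f.end:
                return f.kind
        return None


@dataclass
class SNPRecord:
    """One bi-allelic SNP with optional 35-nt probe flanks and region class."""

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str = ""
    flank_left: str | None = None
    flank_right: str | None = None
    region: str = "unknown"

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"{self.snp_id}: alleles must be single A/C/G/T")
        if self.ref == self.alt:
            raise ValueError(f"{self.snp_id}: ref == alt ({self.ref})")
        for name, flank in (("flank_left", self.flank_left),
                            ("flank_right", self.flank_right)):
            if flank is not None and len(flank) != 35:
                raise ValueError(
                    f"{self.snp_id}: {name} must be exactly 35 nt, "
                    f"got {len(flank)}"
                )
        if self.region not in REGIONS:
            raise ValueError(f"{self.snp_id}: unknown region {self.region!r}")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity hit (BLAST-style tabular row, condensed)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    raw_score: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


class GenotypeMatrix:
    """Samples x markers call matrix over {AA, AB, BB, NoCall}.

    Calls are stored as an int8 array using the module-level codes. Marker
    positions must be non-decreasing within each chromosome.
    """

    def __init__(
        self,
        sample_ids: list[str],
        marker_ids: list[str],
        marker_chrom: list[str],
        marker_pos: list[int],
        calls: np.ndarray,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.marker_ids = list(marker_ids)
        self.marker_chrom = np.asarray(marker_chrom, dtype=object)
        self.marker_pos = np.asarray(marker_pos, dtype=np.int64)
        self.calls = np.asarray(calls, dtype=np.int8)

        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise FormatError("duplicate marker ids")
        n, m = len(self.sample_ids), len(self.marker_ids)
        if self.calls.shape != (n, m):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {m} markers"
            )
        if len(self.marker_chrom) != m or len(self.marker_pos) != m:
            raise FormatError("marker metadata length mismatch")
        valid = set(CODE_TO_CALL)
        bad = set(np.unique(self.calls)) - valid
        if bad:
            raise FormatError(f"invalid call codes {sorted(bad)}")
        for chrom in self.chromosomes():
            pos = self.marker_pos[self.marker_chrom == chrom]
            if np.any(np.diff(pos) < 0):
                raise FormatError(
                    f"marker positions decrease within chromosome {chrom}"
                )
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._marker_index = {s: i for i, s in enumerate(self.marker_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chromosomes(self) -> list[str]:
        """Chromosome names in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.marker_chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.marker_chrom == chrom)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def subset(
        self,
        samples: list[str] | None = None,
        markers: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given samples/markers (original order kept)."""
        si = (
            [self._sample_index[s] for s in samples]
            if samples is not None
            else list(range(self.n_samples))
        )
        keep = set(markers) if markers is not None else None
        mi = [
            j
            for j, mid in enumerate(self.marker_ids)
            if keep is None or mid in keep
        ]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in si],
            [self.marker_ids[j] for j in mi],
            [self.marker_chrom[j] for j in mi],
            [int(self.marker_pos[j]) for j in mi],
            self.calls[np.ix_(si, mi)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as a samples x markers DataFrame of AA/AB/BB/NC strings."""
        tokens = np.vectorize(CODE_TO_CALL.get)(self.calls)
        return pd.DataFrame(
            tokens, index=self.sample_ids, columns=self.marker_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and list(self.marker_chrom) == list(other.marker_chrom)
            and np.array_equal(self.marker_pos, other.marker_pos)
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x "
            f"{self.n_markers} markers)"
        )
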