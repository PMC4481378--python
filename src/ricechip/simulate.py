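"""Seeded generators for every fixture class the pipeline consumes.

All generators are deterministic under (config, seed) and every truth
table is produced by independent brute-force logic, never by calling the
pipeline module it is meant to validate.

The backcross generator follows the Haldane model: per meiosis the
crossover count on a chromosome is Poisson in its genetic length (Morgans)
with breakpoints uniform, no interference. Genetic and physical
coordinates are related linearly per chromosome. Defaults emulate a
rice-like genome: 12 chromosomes of 1.25 Morgans / 30 Mbp each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import AA, AB, BB, NOCALL, GenotypeMatrix

RICE_N_CHROM = 12
RICE_CHROM_MORGANS = 1.25
RICE_CHROM_BP = 30_000_000

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Aggregate simulation settings (CLI/yaml convenience wrapper)."""

    seed: int = 0
    n_genes: int = 100
    duplication: dict = field(
        default_factory=lambda: {
            "n_families": 5, "copies_per_family": 3, "mutation_rate": 0.01,
        }
    )
    snp_density_per_kbp: float = 1.0
    chrom_morgans: list[float] = field(
        default_factory=lambda: [RICE_CHROM_MORGANS] * RICE_N_CHROM
    )
    chrom_bp: list[int] = field(
        default_factory=lambda: [RICE_CHROM_BP] * RICE_N_CHROM
    )
    backcross: dict = field(
        default_factory=lambda: {
            "n_generations": 2, "n_lines": 50, "markers_per_chrom": 100,
            "selection_at": None,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# gene sets with duplication families

def simulate_gene_set(
    n_sc_genes: int,
    n_families: int = 0,
    copies_per_family: int = 2,
    mutation_rate: float = 0.0,
    length_range: tuple[int, int] = (500, 3000),
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random single-copy genes plus mutated-copy paralog families.

    Returns (gene_id -> sequence, truth table). Truth columns:
    gene_id, status (SC/MC), family_id, copy_count.
    """
    if copies_per_family < 2 and n_families:
        raise ValueError("families need >= 2 copies")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    rows: list[dict] = []

    def random_seq(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    for i in range(n_sc_genes):
        gid = f"sc_{i + 1:05d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        sequences[gid] = random_seq(length)
        rows.append(
            {"gene_id": gid, "status": "SC", "family_id": gid, "copy_count": 1}
        )

    for f in range(n_families):
        fam = f"fam_{f + 1:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        founder = np.array(list(random_seq(length)))
        for c in range(copies_per_family):
            gid = f"{fam}_c{c + 1}"
            copy = founder.copy()
            if mutation_rate > 0:
                mask = rng.random(length) < mutation_rate
                for idx in np.flatnonzero(mask):
                    options = [b for b in "ACGT" if b != copy[idx]]
                    copy[idx] = options[rng.integers(3)]
            sequences[gid] = "".join(copy)
            rows.append(
                {
                    "gene_id": gid, "status": "MC", "family_id": fam,
                    "copy_count": copies_per_family,
                }
            )
    return sequences, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP layouts under the clear-flank rule

def simulate_snp_layout(
    gene_length: int,
    n_snps: int,
    min_gap: int = 0,
    seed: int = 0,
    window: int = 35,
) -> tuple[list[int], set[int]]:
    """Random SNP positions plus the brute-force clear-flank survivor set.

    Positions are distinct, drawn from [window + 1, gene_length - window]
    (so rule (a) holds by construction) with consecutive separation of at
    least ``min_gap`` when requested. The survivor truth is an independent
    window scan: a position survives iff no other position lies within
    +/- ``window`` of it.
    """
    lo, hi = window + 1, gene_length - window
    span = hi - lo + 1
    if span < 1:
        raise ValueError("gene too short for the flank window")
    rng = np.random.default_rng(seed)
    if min_gap <= 1:
        if n_snps > span:
            raise ValueError("cannot place that many distinct positions")
        pos = sorted(rng.choice(np.arange(lo, hi + 1), n_snps, replace=False))
    else:
        shrink = span - (n_snps - 1) * (min_gap - 1)
        if shrink < n_snps:
            raise ValueError("spacing infeasible for requested SNP count")
        base = np.sort(rng.choice(np.arange(shrink), n_snps, replace=False))
        pos = [int(lo + b + i * (min_gap - 1)) for i, b in enumerate(base)]

    survivors = {
        p for p in pos
        if not any(q != p and abs(q - p) <= window for q in pos)
    }
    return [int(p) for p in pos], survivors


# ---------------------------------------------------------------------------
# backcross populations

def _gamete(
    donor_intervals: list[tuple[float, float]],
    length_morgans: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Donor intervals transmitted by one meiosis of a line whose two
    homologues are (mosaic-with-donor, pure recipient)."""
    n_co = rng.poisson(length_morgans)
    points = np.sort(rng.uniform(0.0, length_morgans, size=n_co))
    bounds = [0.0, *points.tolist(), length_morgans]
    carry = int(rng.integers(2))  # which homologue starts the gamete
    picked: list[tuple[float, float]] = []
    hap = carry
    for s, e in zip(bounds, bounds[1:]):
        if hap == 0:
            picked.append((s, e))
        hap ^= 1
    # intersect segments copied from the mosaic homologue with its donor runs
    out: list[tuple[float, float]] = []
    for ps, pe in picked:
        for ds, de in donor_intervals:
            s, e = max(ps, ds), min(pe, de)
            if e > s:
                out.append((s, e))
    return out


def _covers(intervals: list[tuple[float, float]], x: float) -> bool:
    return any(s <= x <= e for s, e in intervals)


def simulate_backcross(
    n_generations: int,
    n_lines: int,
    markers_per_chrom: int,
    chrom_morgans: list[float] | None = None,
    chrom_bp: list[int] | None = None,
    selection_at: tuple[str, int] | None = None,
    seed: int = 0,
    recipient_id: str = "recipient",
    donor_id: str = "donor",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Backcross lines with a known realised donor-genome fraction.

    ``n_generations`` counts backcrosses to the recipient: 0 is the F1
    (heterozygous everywhere, donor fraction 0.5); each backcross halves
    the expected donor fraction. ``selection_at = (chrom, bp)`` retains
    the donor allele at that locus every generation (foreground
    selection at a target gene). The recipient parent is AA and the donor
    BB at every marker, so all markers are informative by construction.

    Returns (matrix, truth) where truth has one row per line with the
    realised diploid donor fraction.
    """
    morgans = list(chrom_morgans or [RICE_CHROM_MORGANS] * RICE_N_CHROM)
    bp = list(chrom_bp or [RICE_CHROM_BP] * len(morgans))
    if len(morgans) != len(bp):
        raise ValueError("chrom_morgans and chrom_bp length mismatch")
    chroms = [f"chr{i + 1}" for i in range(len(morgans))]
    rng = np.random.default_rng(seed)

    sel_chrom_idx = None
    sel_genetic = None
    if selection_at is not None:
        sel_chrom, sel_bp = selection_at
        sel_chrom_idx = chroms.index(sel_chrom)
        sel_genetic = sel_bp / bp[sel_chrom_idx] * morgans[sel_chrom_idx]

    marker_ids: list[str] = []
    marker_chrom: list[str] = []
    marker_pos: list[int] = []
    marker_genetic: list[tuple[int, float]] = []  # (chrom index, Morgans)
    for ci, chrom in enumerate(chroms):
        for j in range(markers_per_chrom):
            pos_bp = int((j + 0.5) * bp[ci] / markers_per_chrom)
            marker_ids.append(f"{chrom}_m{j + 1:04d}")
            marker_chrom.append(chrom)
            marker_pos.append(pos_bp)
            marker_genetic.append((ci, pos_bp / bp[ci] * morgans[ci]))

    total_morgans = float(sum(morgans))
    n_markers = len(marker_ids)
    sample_ids = [recipient_id, donor_id] + [
        f"line_{i + 1:03d}" for i in range(n_lines)
    ]
    calls = np.full((len(sample_ids), n_markers), AA, dtype=np.int8)
    calls[1, :] = BB

    truth_rows = []
    for li in range(n_lines):
        donor: list[list[tuple[float, float]]] = [
            [(0.0, L)] for L in morgans
        ]
        for _ in range(n_generations):
            nxt: list[list[tuple[float, float]]] = []
            for ci, L in enumerate(morgans):
                if ci == sel_chrom_idx:
                    if not _covers(donor[ci], sel_genetic):
                        raise RuntimeError("selection target lost upstream")
                    while True:
                        g = _gamete(donor[ci], L, rng)
                        if _covers(g, sel_genetic):
                            break
                else:
                    g = _gamete(donor[ci], L, rng)
                nxt.append(g)
            donor = nxt
        donor_len = sum(e - s for ivs in donor for s, e in ivs)
        fraction = donor_len / (2.0 * total_morgans)
        truth_rows.append(
            {"line": sample_ids[2 + li], "donor_fraction": fraction}
        )
        for m, (ci, gpos) in enumerate(marker_genetic):
            if _covers(donor[ci], gpos):
                calls[2 + li, m] = AB

    matrix = GenotypeMatrix(
        sample_ids, marker_ids, marker_chrom, marker_pos, calls
    )
    return matrix, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# genotype matrices with controlled missingness

def simulate_genotype_matrix(
    n_samples: int,
    n_markers: int,
    missing_rate: float = 0.0,
    replicate_pairs: int = 0,
    seed: int = 0,
    n_chrom: int = 1,
    marker_spacing: int = 1000,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Random diversity-panel calls with injected missingness.

    Genotypes are drawn per marker under Hardy-Weinberg with allele
    frequency uniform on (0.1, 0.9). Each declared replicate pair is an
    exact copy of a base sample with its own independent missingness, so
    co-called concordance is 1 by construction.

    Returns (matrix, declared replicate pairs).
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if replicate_pairs > n_samples:
        raise ValueError("more replicate pairs than samples")
    rng = np.random.default_rng(seed)

    p = rng.uniform(0.1, 0.9, size=n_markers)
    probs = np.stack([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)], axis=1)
    clean = np.empty((n_samples, n_markers), dtype=np.int8)
    for j in range(n_markers):
        clean[:, j] = rng.choice([AA, AB, BB], size=n_samples, p=probs[j])

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    pairs = []
    rows = [clean]
    for i in range(replicate_pairs):
        rows.append(clean[i: i + 1])
        rep_id = f"{sample_ids[i]}_rep"
        sample_ids.append(rep_id)
        pairs.append((sample_ids[i], rep_id))
    calls = np.vstack(rows)

    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, np.int8(NOCALL), calls)

    per_chrom = [n_markers // n_chrom] * n_chrom
    for k in range(n_markers % n_chrom):
        per_chrom[k] += 1
    marker_ids, chrom_col, pos_col = [], [], []
    m = 0
    for c, count in enumerate(per_chrom):
        for j in range(count):
            marker_ids.append(f"M{m + 1:05d}")
            chrom_col.append(f"chr{c + 1}")
            pos_col.append((j + 1) * marker_spacing)
            m += 1

    matrix = GenotypeMatrix(sample_ids, marker_ids, chrom_col, pos_col, calls)
    return matrix, pairs
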