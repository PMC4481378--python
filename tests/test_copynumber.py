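"""Local alignment bit scores (against enumeration and an independent
Gotoh DP), copy-number graph classification, and category partitioning."""

import itertools
import math
import random

import pytest

from ricechip import copynumber as cn
from ricechip.models import SimilarityHit

SCHEME = cn.ScoringScheme()


def _hit(a, b, bits):
    return SimilarityHit(a, b, 100.0, 100, bits / 0.625, bits)


# ---------------------------------------------------------------------------
# independent oracles

def _enumerate_global(a, b, scheme):
    """Max affine-gap global alignment score by exhaustive enumeration."""
    best = -math.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = scheme.match if a[i] == b[j] else scheme.mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            pen = scheme.gap_extend + (scheme.gap_open if last != "A" else 0)
            rec(i + 1, j, score - pen, "A")
        if j < len(b):
            pen = scheme.gap_extend + (scheme.gap_open if last != "B" else 0)
            rec(i, j + 1, score - pen, "B")

    rec(0, 0, 0, "M")
    return best


def _enumerate_local(a, b, scheme):
    """Max local score = best global score over all substring pairs."""
    best = 0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, _enumerate_global(a[i1:i2], b[j1:j2], scheme))
    return best


def _gotoh_local(a, b, scheme):
    """Smith-Waterman with affine gaps, written independently as a plain
    three-state DP (BLAST gap convention: open + k * extend)."""
    n, m = len(a), len(b)
    neg = -1e9
    open_cost = scheme.gap_open + scheme.gap_extend
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]),
            )
            Ix[i][j] = max(
                M[i - 1][j] - open_cost, Ix[i - 1][j] - scheme.gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - open_cost, Iy[i][j - 1] - scheme.gap_extend
            )
            best = max(best, M[i][j])
    return best


# ---------------------------------------------------------------------------
# local_align

def test_bit_score_closed_form_identical_sequences():
    hit = cn.local_align("A" * 100 + "C" * 0, "A" * 100)
    assert hit.raw_score == 200
    assert hit.bit_score == pytest.approx(181.62, abs=0.01)
    hit = cn.local_align("ACGT" * 30, "ACGT" * 30)
    assert hit.raw_score == 240
    assert hit.bit_score == pytest.approx(217.69, abs=0.01)


def test_no_positive_local_match_returns_none():
    assert cn.local_align("AAAA", "TTTT") is None
    assert cn.local_align("", "ACGT") is None


def test_local_align_matches_exhaustive_enumeration():
    rnd = random.Random(7)
    for _ in range(25):
        a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 5)))
        b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 5)))
        expected = _enumerate_local(a, b, SCHEME)
        hit = cn.local_align(a, b)
        got = hit.raw_score if hit else 0
        assert got == expected, (a, b)


def test_local_align_matches_independent_gotoh_dp():
    rnd = random.Random(11)
    for _ in range(60):
        a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 12)))
        b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 12)))
        expected = _gotoh_local(a, b, SCHEME)
        hit = cn.local_align(a, b)
        got = hit.raw_score if hit else 0
        assert got == expected, (a, b)


# ---------------------------------------------------------------------------
# classification

def test_no_hits_means_all_single_copy():
    results = cn.classify_copy_number([f"g{i}" for i in range(5)], [])
    assert all(r.status == "SC" and r.copy_count == 1 for r in results)


def test_one_strong_hit_makes_a_two_copy_family():
    results = cn.classify_copy_number(["A", "B"], [_hit("A", "B", 250)])
    assert all(r.status == "MC" and r.copy_count == 2 for r in results)
    assert len({r.family_id for r in results}) == 1


def test_threshold_is_inclusive_at_200_bits():
    at = cn.classify_copy_number(["A", "B"], [_hit("A", "B", 200.0)])
    below = cn.classify_copy_number(["A", "B"], [_hit("A", "B", 199.9)])
    assert all(r.status == "MC" for r in at)
    assert all(r.status == "SC" for r in below)


def test_self_hits_ignored_and_unknown_gene_rejected():
    results = cn.classify_copy_number(["A"], [_hit("A", "A", 900)])
    assert results[0].status == "SC"
    with pytest.raises(ValueError, match="unknown gene"):
        cn.classify_copy_number(["A"], [_hit("A", "Z", 900)])


def test_classification_invariant_to_hit_order_and_orientation():
    genes = [f"g{i}" for i in range(6)]
    hits = [_hit("g0", "g1", 300), _hit("g1", "g2", 220), _hit("g4", "g5", 500)]
    base = cn.classify_copy_number(genes, hits)
    swapped = [
        _hit(h.subject_id, h.query_id, h.bit_score) for h in reversed(hits)
    ]
    assert cn.classify_copy_number(genes, swapped) == base


def test_raising_threshold_never_decreases_sc_count():
    rnd = random.Random(3)
    genes = [f"g{i}" for i in range(20)]
    hits = [
        _hit(rnd.choice(genes), rnd.choice(genes), rnd.uniform(100, 400))
        for _ in range(40)
    ]
    hits = [h for h in hits if not h.is_self]
    sc_counts = [
        sum(
            r.status == "SC"
            for r in cn.classify_copy_number(genes, hits, threshold_bits=t)
        )
        for t in (100, 150, 200, 250, 300, 350, 401)
    ]
    assert sc_counts == sorted(sc_counts)


def test_family_copy_counts_partition_the_gene_set():
    genes = [f"g{i}" for i in range(10)]
    hits = [_hit("g0", "g1", 300), _hit("g1", "g2", 300), _hit("g5", "g6", 210)]
    results = cn.classify_copy_number(genes, hits)
    sizes = cn.family_sizes(results)
    assert sum(sizes.values()) == len(genes)


def test_transitive_paralogs_collapse_to_one_family():
    # g0-g1 and g1-g2 linked: one family of 3 even without a g0-g2 hit
    results = cn.classify_copy_number(
        ["g0", "g1", "g2"], [_hit("g0", "g1", 300), _hit("g1", "g2", 300)]
    )
    assert all(r.copy_count == 3 for r in results)


def test_mcr_census_mean_copies():
    """117 families totalling 1,881 members average 16 copies per family."""
    sizes = [16] * 108 + [17] * 9
    assert sum(sizes) == 1881 and len(sizes) == 117
    genes, hits = [], []
    for f, size in enumerate(sizes):
        members = [f"fam{f:03d}_c{c}" for c in range(size)]
        genes.extend(members)
        hits.extend(
            _hit(a, b, 400) for a, b in zip(members, members[1:])
        )
    results = cn.classify_copy_number(genes, hits)
    mean = cn.mean_family_copies(results)
    assert mean == pytest.approx(1881 / 117)
    assert round(mean) == 16


# ---------------------------------------------------------------------------
# category partition

def _sc(gid):
    return cn.CopyNumberResult(gid, "SC", gid, 1)


def _mc(gid, fam, size):
    return cn.CopyNumberResult(gid, "MC", fam, size)


def test_sc_genes_default_to_scr():
    cats = cn.partition_categories([_sc("a"), _sc("b")], set(), set())
    assert cats == {"a": "SCR", "b": "SCR"}


def test_conserved_sc_genes_become_cscwr_and_agcr_overrides():
    results = [_sc("a"), _sc("b"), _mc("c", "fam", 2), _mc("d", "fam", 2)]
    cats = cn.partition_categories(results, {"a"}, {"d"})
    assert cats == {"a": "CSCWR", "b": "SCR", "c": "MCR", "d": "AGCR"}


def test_gene_in_both_lists_rejected():
    with pytest.raises(ValueError, match="both"):
        cn.partition_categories([_sc("a")], {"a"}, {"a"})


def test_category_census_sums_to_gene_total():
    """3,710 CSCWR + 14,959 SCR + 194 AGCR + 117 MCR = 18,980 genes."""
    results = []
    conserved, agcr = set(), set()
    for i in range(3710):
        gid = f"wr{i}"
        results.append(_sc(gid))
        conserved.add(gid)
    for i in range(14959):
        results.append(_sc(f"sc{i}"))
    for i in range(194):
        gid = f"ag{i}"
        results.append(_sc(gid))
        agcr.add(gid)
    for i in range(117):
        results.append(_mc(f"mc{i}", f"fam{i}", 2))
    cats = cn.partition_categories(results, conserved, agcr)
    assert len(cats) == 18980
    census = {c: sum(1 for v in cats.values() if v == c) for c in set(cats.values())}
    assert census == {"CSCWR": 3710, "SCR": 14959, "AGCR": 194, "MCR": 117}
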